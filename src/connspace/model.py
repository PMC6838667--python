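"""Model/Results interface for the connectivity-gradient analysis.

:class:`ConnectivityGradientModel` is built from seed-voxel connectivity
profiles (one processed :class:`~connspace.profiles.ProfileSet`, or a list
of per-subject sets to be thresholded, binarized, downsampled and
averaged first).  Its :meth:`~ConnectivityGradientModel.fit` runs the
spectral analysis — cosine similarity graph, Laplacian, generalized
eigendecomposition L X = D X Lambda — and returns a
:class:`ConnectivityGradientResults` carrying the spectrum, the 3-D
similarity-space coordinates, RGB gradient maps, the centre-of-mass
convergence zone, and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import mapping as _mapping
from .embedding import (Embedding, generalized_eigendecomposition,
                        select_embedding)
from .profiles import (DEFAULT_THRESHOLD_FRACTION, ProfileSet, drop_empty_seeds,
                       load_profiles, preprocess)
from .similarity import SimilarityGraph, build_laplacian, cosine_similarity_matrix

__all__ = ["ConnectivityGradientModel", "ConnectivityGradientResults"]


class ConnectivityGradientModel:
    """Spectral-embedding model of seed-voxel connective similarity.

    Parameters
    ----------
    profiles : ProfileSet or sequence of ProfileSet
        A single profile set ready for similarity analysis, or a list of
        per-subject raw sets.  A list is always pushed through the
        preprocessing chain (threshold -> binarize -> downsample ->
        group average); a single set is used as-is unless
        ``preprocess=True``.
    preprocess : bool, optional
        Force (or, for a list of length one, it is implied) the
        preprocessing chain.  Default: only for multi-subject input.
    threshold_fraction : float
        Threshold as a fraction of the profile-set maximum (default
        0.0005, i.e. 0.05%).
    downsample_factor : int or None
        Spatial downsampling factor (default 2); ignored when the input
        carries no target geometry.
    threshold_scope : {"set", "seed"}
        Whether the thresholding maximum is taken over the whole profile
        set or per seed row.
    zero_diagonal : bool
        Drop the unit self-similarity diagonal of A before computing the
        degree matrix.  L is unaffected; D (hence the generalized problem's
        normalization) is not.
    """

    def __init__(
        self,
        profiles: ProfileSet | Sequence[ProfileSet],
        *,
        preprocess: bool | None = None,
        threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
        downsample_factor: int | None = 2,
        threshold_scope: str = "set",
        zero_diagonal: bool = False,
    ):
        if isinstance(profiles, ProfileSet):
            self.subjects = None
            self.raw = profiles
            self._preprocess = bool(preprocess)
        else:
            self.subjects = list(profiles)
            if not self.subjects:
                raise ValueError("need at least one subject ProfileSet")
            self.raw = None
            self._preprocess = True
        self.threshold_fraction = threshold_fraction
        self.downsample_factor = downsample_factor
        self.threshold_scope = threshold_scope
        self.zero_diagonal = zero_diagonal

    @classmethod
    def from_hdf5(cls, path, **kwargs) -> "ConnectivityGradientModel":
        """Build a model from a single HDF5 profile container."""
        return cls(load_profiles(path), **kwargs)

    def fit(
        self,
        n_dims: int = 3,
        k: int | None = None,
        percentile: float = 10.0,
        rgb_per_column: bool = False,
    ) -> "ConnectivityGradientResults":
        """Run the full spectral analysis.

        Parameters
        ----------
        n_dims : int
            Embedding dimensions (the eigenvectors of the ``n_dims``
            smallest non-zero eigenvalues); 3 matches the RGB colour
            mapping and is the analysed default.
        k : int, optional
            Eigenpairs to compute (default: zero multiplicity + 8).
        percentile : float
            Retention percentile for the convergence zone (default 10).
        rgb_per_column : bool
            Per-column instead of global feature scaling for the raw RGB
            map.
        """
        if self.subjects is not None or self._preprocess:
            subjects = self.subjects if self.subjects is not None else [self.raw]
            group, dropped = preprocess(
                subjects,
                fraction=self.threshold_fraction,
                downsample_factor=self.downsample_factor,
                threshold_scope=self.threshold_scope,
            )
        else:
            group, dropped = drop_empty_seeds(self.raw)

        graph = build_laplacian(cosine_similarity_matrix(group),
                                zero_diagonal=self.zero_diagonal)
        k_eff = k
        if k_eff is not None:
            k_eff = max(k_eff, n_dims + 1)
        emb = generalized_eigendecomposition(graph, k=k_eff)
        emb = select_embedding(emb, n_dims=n_dims)
        colours = _mapping.colour_maps(emb.coords, per_column=rgb_per_column)
        zone = _mapping.convergence_zone(emb.coords, percentile=percentile)
        return ConnectivityGradientResults(
            model=self, profiles=group, dropped_seeds=dropped, graph=graph,
            embedding=emb, colours=colours, zone=zone,
            params=dict(n_dims=n_dims, k=k, percentile=percentile,
                        rgb_per_column=rgb_per_column,
                        threshold_fraction=self.threshold_fraction,
                        downsample_factor=self.downsample_factor,
                        threshold_scope=self.threshold_scope,
                        zero_diagonal=self.zero_diagonal),
        )


class ConnectivityGradientResults:
    """Fitted similarity-space embedding with colour maps and zone.

    Attributes
    ----------
    profiles : ProfileSet
        The processed group profile set actually analysed.
    dropped_seeds : list of int
        Indices of empty seeds removed before graph construction.
    graph : SimilarityGraph
        Adjacency, degree and Laplacian matrices.
    embedding : Embedding
        Generalized eigenpairs, diagnostics and the n x 3 coordinates.
    colours : ColourMap
        Raw and rank-order RGB maps of the coordinates.
    zone : ConvergenceZone
        Centre-of-mass convergence zone on the raw coordinates.
    """

    def __init__(self, *, model, profiles, dropped_seeds, graph, embedding,
                 colours, zone, params):
        self.model: ConnectivityGradientModel = model
        self.profiles: ProfileSet = profiles
        self.dropped_seeds: list[int] = dropped_seeds
        self.graph: SimilarityGraph = graph
        self.embedding: Embedding = embedding
        self.colours = colours
        self.zone = zone
        self.params = params

    # -- convenience views ---------------------------------------------------

    @property
    def coords(self) -> np.ndarray:
        """n x 3 raw similarity-space coordinates."""
        return self.embedding.coords

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.embedding.eigenvalues

    @property
    def diagnostics(self) -> dict:
        return self.embedding.diagnostics

    def to_frame(self) -> pd.DataFrame:
        """Per-seed table: coordinates, RGB values, distance, zone membership."""
        emb = self.embedding
        df = pd.DataFrame({
            "seed": self.graph.seed_index,
            "x": emb.coords[:, 0],
            "y": emb.coords[:, 1],
            "z": emb.coords[:, 2] if emb.coords.shape[1] > 2 else np.nan,
        })
        for i, ch in enumerate("rgb"):
            if i < self.colours.rgb_raw.shape[1]:
                df[f"{ch}_raw"] = self.colours.rgb_raw[:, i]
                df[f"{ch}_ranked"] = self.colours.rgb_ranked[:, i]
        df["distance"] = self.zone.distances
        df["in_zone"] = self.zone.mask
        return df

    def summary(self) -> str:
        """Plain-text summary of the fitted embedding."""
        d = self.diagnostics
        ev = ", ".join(f"{v:.4f}" for v in self.eigenvalues[:8])
        lines = [
            "Connectivity gradient embedding",
            "=" * 47,
            f"seeds analysed:          {self.profiles.n_seeds}"
            + (f"  ({len(self.dropped_seeds)} empty dropped)"
               if self.dropped_seeds else ""),
            f"target dimensions:       {self.profiles.m_targets}",
            f"connected components:    {d['n_components']}",
            f"algebraic connectivity:  {d['algebraic_connectivity']:.4f}",
            f"eigenvalues (leading):   {ev}",
            f"largest eigengap after:  index {d['largest_gap_index']}",
            f"embedding dimensions:    {self.coords.shape[1]}",
            f"zone percentile:         {self.zone.percentile:.0f}"
            f"  (cut {self.zone.cut:.4g}, retained {self.zone.n_retained}"
            f"/{self.profiles.n_seeds})",
        ]
        return "\n".join(lines)

    # -- output --------------------------------------------------------------

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save_volumes(self, outdir, *, reference=None) -> list[str]:
        """Write RGB (raw 4-D + per-channel) and zone-mask NIfTI volumes.

        Requires seed coordinates to index a voxel grid; the grid is sized
        to enclose all seed coordinates unless the ProfileSet's own
        target grid applies.
        """
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        coords = self.profiles.seed_coords
        grid = tuple(int(c) + 1 for c in np.max(coords, axis=0))
        written = []
        rgb_vol = _mapping.project_to_anatomy(self.colours.rgb_raw, coords, grid)
        p = outdir / "rgb_raw.nii"
        _mapping.save_volume(p, rgb_vol, reference=reference)
        written.append(str(p))
        for i, ch in enumerate("rgb"):
            vol = _mapping.project_to_anatomy(self.colours.rgb_ranked[:, i],
                                              coords, grid)
            p = outdir / f"rgb_ranked_{ch}.nii"
            _mapping.save_volume(p, vol, reference=reference)
            written.append(str(p))
        mask_vol = _mapping.project_to_anatomy(
            self.zone.mask.astype(float), coords, grid)
        p = outdir / "zone_mask.nii"
        _mapping.save_volume(p, mask_vol, reference=reference, mask=True)
        written.append(str(p))
        return written

    def plot_similarity_space(self, path=None, *, ranked_colours: bool = True):
        """3-D scatter of the similarity space coloured by the RGB map."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
        cols = (self.colours.rgb_ranked if ranked_colours
                else self.colours.rgb_raw)
        X = self.coords
        ax.scatter(X[:, 0], X[:, 1], X[:, 2], c=np.clip(cols, 0, 1), s=12)
        ax.set_xlabel("eigenvector 1")
        ax.set_ylabel("eigenvector 2")
        ax.set_zlabel("eigenvector 3")
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            return None
        return fig
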