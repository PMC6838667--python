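"""RGB gradient maps, the convergence zone, and anatomical projection.

Each seed voxel's position in the 3-D similarity space is turned into a
colour by feature-scaling the coordinate matrix X to [0, 1]:

    RGB = (X - 1 * Xmin) / (Xmax - Xmin)

where Xmin and Xmax are the global minimum and maximum over the whole
matrix and 1 is a matrix of ones.  Because raw eigenvectors are outlier-
sensitive and compress the usable colour range, a "ranked" variant replaces
each coordinate column by its within-column rank order before scaling.

The convergence zone operationalises a graded hub: the centre of mass of
the raw similarity-space point cloud is computed, and the seeds within the
closest 10th percentile of Euclidean distance to it are retained — the
seeds whose connectivity is least distinct from all others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ColourMap",
    "ConvergenceZone",
    "rgb_scale",
    "rank_rgb",
    "colour_maps",
    "convergence_zone",
    "project_to_anatomy",
    "save_volume",
]


@dataclass
class ColourMap:
    """Per-seed RGB triples in [0, 1], raw and rank-order variants."""

    rgb_raw: np.ndarray | None = None
    rgb_ranked: np.ndarray | None = None
    scaling_record: dict | None = None


@dataclass
class ConvergenceZone:
    """Centre-of-mass zone of the raw similarity space.

    ``mask`` is true for seeds whose Euclidean distance to the centroid is
    at or below the ``percentile`` cut of the distance distribution.
    """

    centroid: np.ndarray
    distances: np.ndarray
    percentile: float
    cut: float
    mask: np.ndarray

    @property
    def retained_fraction(self) -> float:
        return float(self.mask.mean())

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())


def _as_coords(coords) -> np.ndarray:
    coords = np.asarray(coords, float)
    if coords.ndim != 2:
        raise ValueError("coords must be a 2-D (n_seeds, n_dims) matrix")
    return coords


def rgb_scale(coords) -> ColourMap:
    """Feature-scale coordinates to RGB with a single global min and max.

    The scaling is one affine map applied to the whole matrix (not per
    column), so relative spread between the three axes is preserved; the
    global output minimum is exactly 0 and the global maximum exactly 1.
    """
    X = _as_coords(coords)
    xmin, xmax = float(X.min()), float(X.max())
    if xmax <= xmin:
        raise ValueError(
            "degenerate embedding: all coordinates identical, cannot "
            "feature-scale (Xmax == Xmin)"
        )
    rgb = (X - xmin) / (xmax - xmin)
    return ColourMap(rgb_raw=rgb,
                     scaling_record={"Xmin": xmin, "Xmax": xmax, "mode": "global"})


def rank_rgb(coords) -> ColourMap:
    """Rank-transform each coordinate column, then scale each to [0, 1].

    Ties receive average ranks.  Every output column spans the full [0, 1]
    range (for n >= 2 untied extremes), which spreads outlier-compressed
    gradients across the whole colour space.
    """
    X = _as_coords(coords)
    if X.shape[0] < 2:
        raise ValueError("rank colouring needs at least 2 seeds")
    ranks = np.column_stack([rankdata(X[:, j], method="average")
                             for j in range(X.shape[1])])
    lo = ranks.min(axis=0)
    hi = ranks.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return ColourMap(rgb_ranked=(ranks - lo) / span,
                     scaling_record={"mode": "rank-per-column"})


def colour_maps(coords, *, per_column: bool = False) -> ColourMap:
    """Compute both raw and ranked RGB maps for an embedding.

    ``per_column=True`` switches the raw scaling to independent per-column
    min/max (uses the colour cube more fully, but distorts relative axis
    spread); the default is the single global scaling.
    """
    X = _as_coords(coords)
    if per_column:
        lo, hi = X.min(axis=0), X.max(axis=0)
        if np.any(hi <= lo):
            raise ValueError("degenerate embedding column: min == max")
        raw = (X - lo) / (hi - lo)
        record = {"Xmin": lo.tolist(), "Xmax": hi.tolist(), "mode": "per-column"}
    else:
        cm = rgb_scale(X)
        raw, record = cm.rgb_raw, cm.scaling_record
    ranked = rank_rgb(X).rgb_ranked
    return ColourMap(rgb_raw=raw, rgb_ranked=ranked, scaling_record=record)


def convergence_zone(coords, percentile: float = 10.0) -> ConvergenceZone:
    """Seeds within the closest ``percentile`` of distance to the centre of mass.

    Operates on the RAW embedding coordinates (not ranked or RGB-scaled):
    distances in the raw space are what encode connective similarity.  The
    centroid is the unweighted column mean; the cut is the
    linear-interpolation percentile of the distance distribution and seeds
    with ``distance <= cut`` are retained (ties at the cut all retained).
    """
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must lie in (0, 100); got {percentile}")
    X = _as_coords(coords)
    centroid = X.mean(axis=0)
    distances = np.linalg.norm(X - centroid, axis=1)
    cut = float(np.percentile(distances, percentile))
    mask = distances <= cut
    return ConvergenceZone(centroid=centroid, distances=distances,
                           percentile=float(percentile), cut=cut, mask=mask)


# ---------------------------------------------------------------------------
# anatomical projection
# ---------------------------------------------------------------------------

def project_to_anatomy(
    per_seed_values,
    seed_coords,
    grid_shape,
) -> np.ndarray:
    """Scatter per-seed values into a volumetric grid.

    Returns a ``grid_shape + (c,)`` float array (``c = 1`` for a vector
    input) with each seed voxel carrying its value and all other voxels
    zero.  Coordinates outside the grid are an error listing the offending
    seeds.
    """
    vals = np.asarray(per_seed_values, float)
    if vals.ndim == 1:
        vals = vals[:, None]
    coords = np.asarray(seed_coords)
    grid_shape = tuple(int(d) for d in grid_shape)
    if coords.shape != (vals.shape[0], 3):
        raise ValueError("seed_coords must be (n_seeds, 3) matching values")
    ijk = np.round(coords).astype(int)
    oob = np.flatnonzero(
        (ijk < 0).any(axis=1) | (ijk >= np.array(grid_shape)).any(axis=1)
    )
    if oob.size:
        raise ValueError(
            f"seed(s) {oob.tolist()} lie outside the {grid_shape} grid: "
            f"{[tuple(c) for c in ijk[oob][:5]]}"
        )
    vol = np.zeros(grid_shape + (vals.shape[1],), dtype=np.float32)
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2], :] = vals
    return vol


def save_volume(path, volume, *, reference=None, mask: bool = False) -> None:
    """Write a 3-D or 4-D volume to NIfTI.

    The affine and header are copied from ``reference`` (a path or a
    nibabel image) when given, identity otherwise.  ``mask=True`` stores
    uint8 instead of float32.
    """
    import nibabel as nib

    vol = np.asarray(volume)
    if vol.ndim == 4 and vol.shape[3] == 1:
        vol = vol[..., 0]
    dtype = np.uint8 if mask else np.float32
    if reference is not None:
        ref = nib.load(str(reference)) if not hasattr(reference, "affine") else reference
        affine = ref.affine
    else:
        affine = np.eye(4)
    img = nib.Nifti1Image(vol.astype(dtype), affine)
    nib.save(img, str(path))
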