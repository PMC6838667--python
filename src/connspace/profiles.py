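"""Seed-voxel connectivity profiles and their post-processing.

A connectivity profile is, for one seed voxel, the vector of streamline
counts (or binarized hits) to every target voxel in the brain — the seed's
connectional fingerprint.  This module holds the :class:`ProfileSet`
container and the standard post-processing chain applied to per-subject
profile sets before similarity analysis:

    threshold -> binarize -> downsample -> group average

Thresholding removes very low-level tractography noise (the cut is a small
fraction, by default 0.05%, of the maximum streamline count in the subject's
profile set); binarization turns counts into hit maps; block downsampling
halves each spatial dimension of the target grid to reduce memory; group
averaging produces per-seed connection probabilities in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "ProfileSet",
    "EmptyProfileWarning",
    "threshold_binarize",
    "downsample",
    "group_average",
    "drop_empty_seeds",
    "preprocess",
    "save_profiles",
    "load_profiles",
    "load_nifti_profiles",
]

#: default threshold: 0.05% of the maximum value in the profile set
DEFAULT_THRESHOLD_FRACTION = 0.0005


class EmptyProfileWarning(UserWarning):
    """A seed's profile became (or was) entirely zero during processing."""


@dataclass
class ProfileSet:
    """n_seeds x m_targets non-negative connectivity matrix with metadata.

    Parameters
    ----------
    values : ndarray, shape (n_seeds, m_targets)
        Non-negative connectivity values: raw streamline counts, binary hit
        maps after thresholding, or proportions in [0, 1] after group
        averaging.
    seed_coords : ndarray, shape (n_seeds, 3)
        Voxel coordinates of each seed in a stated reference grid.
    target_shape : tuple of int or None
        3-D grid dimensions of the target space; ``m_targets`` must equal
        ``prod(target_shape)`` when set.  ``None`` for matrix-only inputs,
        in which case spatial downsampling is unavailable.
    processing_log : list of dict
        Ordered record of the transforms applied so far.
    """

    values: np.ndarray
    seed_coords: np.ndarray
    target_shape: tuple[int, int, int] | None = None
    processing_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.seed_coords = np.asarray(self.seed_coords)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_seeds, m_targets) matrix")
        if np.any(self.values < 0):
            raise ValueError("connectivity values must be non-negative")
        if self.seed_coords.shape != (self.values.shape[0], 3):
            raise ValueError(
                f"seed_coords must be (n_seeds, 3); got {self.seed_coords.shape} "
                f"for n_seeds={self.values.shape[0]}"
            )
        if self.target_shape is not None:
            self.target_shape = tuple(int(d) for d in self.target_shape)
            if len(self.target_shape) != 3:
                raise ValueError("target_shape must be 3-D")
            if int(np.prod(self.target_shape)) != self.values.shape[1]:
                raise ValueError(
                    f"target_shape {self.target_shape} does not match "
                    f"m_targets={self.values.shape[1]}"
                )

    @property
    def n_seeds(self) -> int:
        return self.values.shape[0]

    @property
    def m_targets(self) -> int:
        return self.values.shape[1]

    def log(self, step: str, **params) -> "ProfileSet":
        """Return a copy with ``step`` appended to the processing log."""
        entry = {"step": step, **params}
        return replace(self, processing_log=self.processing_log + [entry])


def _check_positive_fraction(fraction: float) -> None:
    if not 0 < fraction < 1:
        raise ValueError(f"threshold fraction must lie in (0, 1); got {fraction}")


def threshold_binarize(
    profiles: ProfileSet,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    *,
    scope: str = "set",
) -> ProfileSet:
    """Threshold a profile set at ``fraction`` of its maximum and binarize.

    Entries at or above ``cut = fraction * max`` become 1, entries strictly
    below become 0 (the maximum itself always survives).  By default the
    maximum is taken over the subject's whole profile set (``scope="set"``);
    ``scope="seed"`` uses each seed's own row maximum instead.

    All-zero inputs are passed through as zeros with an
    :class:`EmptyProfileWarning` per affected seed.
    """
    _check_positive_fraction(fraction)
    if scope not in ("set", "seed"):
        raise ValueError(f"scope must be 'set' or 'seed'; got {scope!r}")
    vals = profiles.values
    if scope == "set":
        cut = fraction * (vals.max() if vals.size else 0.0)
        binarized = (vals >= cut).astype(float) if cut > 0 else np.zeros_like(vals)
    else:
        row_max = vals.max(axis=1, keepdims=True)
        cut_rows = fraction * row_max
        binarized = np.where(row_max > 0, vals >= cut_rows, 0.0).astype(float)
        cut = None
    empty = np.flatnonzero(vals.max(axis=1) == 0)
    for idx in empty:
        warnings.warn(
            f"seed {idx} at {tuple(profiles.seed_coords[idx])} has an empty "
            "profile (all zeros) at thresholding",
            EmptyProfileWarning,
            stacklevel=2,
        )
    out = replace(profiles, values=binarized)
    return out.log("threshold_binarize", fraction=fraction, scope=scope,
                   cut=cut, n_empty=int(empty.size))


def _pad_to_even(vol: np.ndarray) -> np.ndarray:
    pads = [(0, d % 2) for d in vol.shape]
    if any(p[1] for p in pads):
        vol = np.pad(vol, pads, mode="constant")
    return vol


def downsample(profiles: ProfileSet, factor: int = 2) -> ProfileSet:
    """Block-mean downsample each profile's target volume by ``factor``.

    Each ``factor**3`` block of target voxels is aggregated to its mean,
    halving (for factor 2) every dimension of the target grid.  Odd
    dimensions are zero-padded first, so the operation is deterministic and
    mass-preserving up to the fixed block volume.  Requires a known
    ``target_shape``.
    """
    if factor != 2:
        raise ValueError("only factor=2 downsampling is supported")
    if profiles.target_shape is None:
        raise ValueError(
            "downsampling requires target_shape; matrix-only inputs carry no "
            "target geometry"
        )
    shape = profiles.target_shape
    new_shape = tuple(-(-d // 2) for d in shape)  # ceil division
    rows = []
    for row in profiles.values:
        vol = _pad_to_even(row.reshape(shape))
        d0, d1, d2 = vol.shape
        blocks = vol.reshape(d0 // 2, 2, d1 // 2, 2, d2 // 2, 2)
        rows.append(blocks.mean(axis=(1, 3, 5)).ravel())
    out = replace(profiles, values=np.array(rows), target_shape=new_shape)
    return out.log("downsample", factor=factor, old_shape=shape,
                   new_shape=new_shape)


def group_average(subjects: Sequence[ProfileSet]) -> ProfileSet:
    """Elementwise mean of per-subject profile sets sharing seed correspondence.

    With binarized inputs the result holds, per seed and target, the fraction
    of subjects in which the connection was present — a group connection
    probability in [0, 1].
    """
    if len(subjects) == 0:
        raise ValueError("group_average requires at least one subject")
    ref = subjects[0]
    for i, s in enumerate(subjects[1:], start=1):
        if s.values.shape != ref.values.shape:
            raise ValueError(
                f"subject {i} shape {s.values.shape} does not match subject 0 "
                f"shape {ref.values.shape}"
            )
        if s.target_shape != ref.target_shape:
            raise ValueError(f"subject {i} target_shape differs from subject 0")
    mean = np.mean([s.values for s in subjects], axis=0)
    out = replace(ref, values=mean)
    return out.log("group_average", n_subjects=len(subjects))


def drop_empty_seeds(profiles: ProfileSet) -> tuple[ProfileSet, list[int]]:
    """Remove seeds whose processed profile is entirely zero.

    Zero profiles have no direction, so cosine similarity is undefined for
    them; they are removed here before graph construction.  Returns the
    reduced set and the list of dropped seed indices (indices into the input
    ordering).  Raises if every seed is empty.
    """
    nonzero = profiles.values.max(axis=1) > 0
    dropped = np.flatnonzero(~nonzero).tolist()
    if not nonzero.any():
        raise ValueError("all seed profiles are empty; nothing to analyse")
    if not dropped:
        return profiles.log("drop_empty_seeds", dropped=[]), []
    coords = [tuple(int(c) for c in profiles.seed_coords[i]) for i in dropped]
    out = replace(
        profiles,
        values=profiles.values[nonzero],
        seed_coords=profiles.seed_coords[nonzero],
    )
    return out.log("drop_empty_seeds", dropped=dropped, coords=coords), dropped


def preprocess(
    subjects: Sequence[ProfileSet],
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    downsample_factor: int | None = 2,
    *,
    threshold_scope: str = "set",
) -> tuple[ProfileSet, list[int]]:
    """Apply the full per-subject chain and return the cleaned group profile.

    Order is fixed: threshold+binarize, then downsample (skipped when
    ``downsample_factor`` is None or no target geometry is present), then
    average across subjects, then drop empty seeds.  Returns the group
    :class:`ProfileSet` and the dropped-seed index list.
    """
    processed = []
    for s in subjects:
        p = threshold_binarize(s, fraction, scope=threshold_scope)
        if downsample_factor is not None and p.target_shape is not None:
            p = downsample(p, downsample_factor)
        processed.append(p)
    group = group_average(processed)
    return drop_empty_seeds(group)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_profiles(path, profiles: ProfileSet) -> None:
    """Write a ProfileSet to an HDF5 container."""
    import json

    with h5py.File(path, "w") as f:
        # track_times=False keeps files byte-identical across reruns
        f.create_dataset("values", data=profiles.values, track_times=False)
        f.create_dataset("seed_coords", data=profiles.seed_coords,
                         track_times=False)
        if profiles.target_shape is not None:
            f.attrs["target_shape"] = profiles.target_shape
        f.attrs["processing_log"] = json.dumps(profiles.processing_log,
                                               default=str)


def load_profiles(path) -> ProfileSet:
    """Read a ProfileSet from an HDF5 container written by :func:`save_profiles`."""
    import json

    with h5py.File(path, "r") as f:
        values = f["values"][()]
        seed_coords = f["seed_coords"][()]
        target_shape = (
            tuple(int(d) for d in f.attrs["target_shape"])
            if "target_shape" in f.attrs else None
        )
        log = json.loads(f.attrs.get("processing_log", "[]"))
    return ProfileSet(values, seed_coords, target_shape, log)


def load_nifti_profiles(path, seed_coords: np.ndarray) -> ProfileSet:
    """Load a 4-D NIfTI stack (x, y, z, seed) as a ProfileSet.

    Each volume along the fourth axis is one seed's connectivity map over
    the target grid; volumes are flattened in C order to rows of the
    profile matrix.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D seed-indexed stack; got {data.ndim}-D")
    target_shape = data.shape[:3]
    values = np.stack([data[..., i].ravel() for i in range(data.shape[3])])
    return ProfileSet(values, np.asarray(seed_coords), tuple(target_shape))
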