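"""Synthetic connectivity-profile generators with planted ground truth.

Real seed-voxel tractography profiles are not publicly archivable, so the
test bed is synthetic.  The generators emulate the qualitative structure a
temporal-lobe analysis must recover:

* a **gradient** population whose profiles shift gradually along a latent
  axis (lateral-cortex-like graded connectivity),
* a sharply distinct **cluster** population with (almost) disjoint target
  support (hippocampus-like),
* **hub** seeds whose profiles are equal-weight mixtures of the gradient
  extremes — by construction the seeds most similar on average to all
  others,
* multi-subject noisy replicates of a template.

Extreme profiles are smooth Gaussian bumps over a 1-D target index with
hard-truncated, mutually disjoint supports; cosine similarity depends only
on the vector values, so no 3-D target geometry is needed.  Noise is
additive Gaussian truncated at zero, preserving non-negativity.  A toy 3-D
seed-coordinate lattice is attached so anatomical projection can be tested.

Every generator is bit-deterministic given its parameters and integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .profiles import ProfileSet

__all__ = [
    "SyntheticTruth",
    "generate_graded_profiles",
    "generate_cluster_profiles",
    "generate_hub_profiles",
    "generate_multisubject",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth for a synthetic ProfileSet.

    ``latent_coordinate`` is the position on the planted gradient (NaN for
    non-gradient seeds); ``population_label`` is one of ``gradient``,
    ``cluster``, ``hub`` per seed; ``hub_mask`` is true exactly where the
    profile was built as a mixture of the extreme profiles.  ``extremes``
    holds the fixed extreme profiles the gradient interpolates between.
    """

    latent_coordinate: np.ndarray
    population_label: np.ndarray
    hub_mask: np.ndarray
    generator_params: dict = field(default_factory=dict)
    extremes: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.latent_coordinate)
        if len(self.population_label) != n or len(self.hub_mask) != n:
            raise ValueError("truth fields must have equal length")
        if np.any(self.hub_mask & (self.population_label != "hub")):
            raise ValueError("hub_mask true implies population_label == 'hub'")
        grad = self.population_label == "gradient"
        if np.any(np.isnan(self.latent_coordinate[grad])):
            raise ValueError("gradient seeds must have a latent coordinate")


def _seed_lattice(n: int, offset: int = 0) -> np.ndarray:
    """Toy 3-D seed coordinates: the first n cells of a cubic lattice."""
    total = n + offset
    side = int(np.ceil(total ** (1 / 3)))
    while side ** 3 < total:
        side += 1
    idx = np.arange(offset, total)
    return np.column_stack([idx // (side * side),
                            (idx // side) % side,
                            idx % side])


def _extreme_profiles(m_targets: int, n_extremes: int,
                      bump_width: float) -> np.ndarray:
    """Disjoint truncated-Gaussian bumps over the 1-D target index.

    Extreme k peaks at the centre of the k-th of ``n_extremes`` equal
    blocks of the target axis and is exactly zero outside +/- 4 widths, so
    distinct extremes are orthogonal.
    """
    block = m_targets / n_extremes
    if 8 * bump_width > block:
        raise ValueError(
            f"bump_width {bump_width} too wide: need 8*width <= "
            f"{block:.1f} (targets per extreme) for disjoint supports"
        )
    x = np.arange(m_targets, dtype=float)
    extremes = np.zeros((n_extremes, m_targets))
    for k in range(n_extremes):
        c = (k + 0.5) * block
        bump = np.exp(-0.5 * ((x - c) / bump_width) ** 2)
        bump[np.abs(x - c) > 4 * bump_width] = 0.0
        extremes[k] = bump
    return extremes


def _mixture_weights(t: np.ndarray, n_extremes: int) -> np.ndarray:
    """Smooth convex weights over the extremes as a function of latent t.

    Two extremes: convex weights (1-s, s) with the angular
    reparametrization s = sin(phi) / (sin(phi) + cos(phi)), phi = t*pi/2.
    This keeps the endpoint and midpoint identities (t=0 and t=1 reproduce
    the extremes, t=0.5 the equal mixture) while making the profile's
    direction rotate at constant angular speed between the two orthogonal
    extremes — so cosine similarity is exactly cos(pi/2 * |t_i - t_j|), a
    strictly decreasing function of latent distance.  More extremes:
    normalized Gaussian kernel weights around centres evenly spaced in
    [0, 1], which keeps every weight positive and the profile drifting
    smoothly (monotone decay of similarity holds locally, not as an exact
    global function of |t_i - t_j|).
    """
    t = np.asarray(t, float)
    if n_extremes == 2:
        phi = t * (np.pi / 2.0)
        s = np.sin(phi) / (np.sin(phi) + np.cos(phi))
        return np.column_stack([1.0 - s, s])
    centres = (np.arange(n_extremes) + 0.5) / n_extremes
    sigma = 1.0 / n_extremes
    w = np.exp(-0.5 * ((t[:, None] - centres[None, :]) / sigma) ** 2)
    return w / w.sum(axis=1, keepdims=True)


def _add_noise(expected: np.ndarray, noise_sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise truncated at zero (counts stay non-negative)."""
    if noise_sd == 0:
        return expected.copy()
    return np.clip(expected + rng.normal(0.0, noise_sd, expected.shape),
                   0.0, None)


def generate_graded_profiles(
    n_seeds: int,
    m_targets: int,
    n_extremes: int = 2,
    bump_width: float | None = None,
    noise_sd: float = 0.05,
    rng_seed: int = 0,
) -> tuple[ProfileSet, SyntheticTruth]:
    """Gradient population: profiles drifting smoothly along a latent axis.

    Seed i gets latent coordinate ``t_i`` evenly spaced in [0, 1]; its
    expected profile is a convex combination of ``n_extremes`` fixed
    extreme profiles with weights varying smoothly in ``t_i``, plus
    truncated noise.  Adjacent seeds in t are more cosine-similar than
    distant ones.
    """
    if n_seeds <= 0 or m_targets <= 0:
        raise ValueError("n_seeds and m_targets must be positive")
    if n_extremes < 2:
        raise ValueError("need at least 2 extreme profiles")
    if n_seeds < n_extremes:
        raise ValueError("n_seeds must be >= n_extremes")
    if m_targets < n_seeds:
        raise ValueError("m_targets must be >= n_seeds")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if bump_width is None:
        bump_width = m_targets / (10.0 * n_extremes)

    rng = np.random.default_rng(rng_seed)
    t = np.linspace(0.0, 1.0, n_seeds)
    extremes = _extreme_profiles(m_targets, n_extremes, bump_width)
    expected = _mixture_weights(t, n_extremes) @ extremes
    values = _add_noise(expected, noise_sd, rng)

    params = dict(kind="gradient", n_seeds=n_seeds, m_targets=m_targets,
                  n_extremes=n_extremes, bump_width=bump_width,
                  noise_sd=noise_sd, rng_seed=rng_seed)
    profiles = ProfileSet(values, _seed_lattice(n_seeds),
                          processing_log=[{"step": "synthetic", **params}])
    truth = SyntheticTruth(
        latent_coordinate=t,
        population_label=np.array(["gradient"] * n_seeds, dtype=object),
        hub_mask=np.zeros(n_seeds, dtype=bool),
        generator_params=params,
        extremes=extremes,
    )
    return profiles, truth


def _free_targets(truth: SyntheticTruth) -> np.ndarray:
    """Target columns untouched by every extreme profile."""
    if truth.extremes is None:
        raise ValueError("base truth carries no extreme profiles")
    return np.flatnonzero((truth.extremes == 0).all(axis=0))


def generate_cluster_profiles(
    base: ProfileSet,
    base_truth: SyntheticTruth,
    n_cluster: int,
    overlap: float = 0.1,
    rng_seed: int = 0,
) -> tuple[ProfileSet, SyntheticTruth]:
    """Append a sharply distinct cluster population to a gradient base.

    The cluster's profiles live on target voxels the gradient never uses,
    except for a fraction ``overlap`` of their support drawn from the
    gradient's targets.  With ``overlap=0`` cluster and gradient profiles
    are exactly orthogonal, so the similarity graph splits into two
    connected components.
    """
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must lie in [0, 1); got {overlap}")
    if n_cluster <= 0:
        raise ValueError("n_cluster must be positive")
    rng = np.random.default_rng(rng_seed)
    free = _free_targets(base_truth)
    used = np.setdiff1d(np.arange(base.m_targets), free)
    support_size = max(8, int(0.5 * free.size))
    n_shared = int(round(overlap * support_size))
    n_free = support_size - n_shared
    if n_free > free.size or n_shared > used.size:
        raise ValueError("not enough target voxels for the requested cluster")
    own = rng.choice(free, size=n_free, replace=False)
    shared = rng.choice(used, size=n_shared, replace=False) if n_shared else np.array([], int)
    support = np.concatenate([own, shared])

    # one smooth template over the support, shared by the whole cluster
    template = np.zeros(base.m_targets)
    u = np.linspace(-1.0, 1.0, support.size)
    template[support] = np.exp(-0.5 * (u / 0.5) ** 2)
    noise_sd = float(base_truth.generator_params.get("noise_sd", 0.0))
    values = _add_noise(np.tile(template, (n_cluster, 1)), noise_sd, rng)
    # keep noise off the non-support targets so overlap=0 stays exact
    mask = np.zeros(base.m_targets, dtype=bool)
    mask[support] = True
    values[:, ~mask] = 0.0

    all_values = np.vstack([base.values, values])
    coords = np.vstack([base.seed_coords,
                        _seed_lattice(n_cluster, offset=base.n_seeds)])
    params = dict(base_truth.generator_params,
                  cluster=dict(n_cluster=n_cluster, overlap=overlap,
                               rng_seed=rng_seed, support_size=support_size))
    profiles = replace(base, values=all_values, seed_coords=coords,
                       processing_log=base.processing_log
                       + [{"step": "synthetic_cluster", **params["cluster"]}])
    truth = SyntheticTruth(
        latent_coordinate=np.concatenate([base_truth.latent_coordinate,
                                          np.full(n_cluster, np.nan)]),
        population_label=np.concatenate([base_truth.population_label,
                                         np.array(["cluster"] * n_cluster,
                                                  dtype=object)]),
        hub_mask=np.concatenate([base_truth.hub_mask,
                                 np.zeros(n_cluster, bool)]),
        generator_params=params,
        extremes=base_truth.extremes,
    )
    return profiles, truth


def generate_hub_profiles(
    base: ProfileSet,
    base_truth: SyntheticTruth,
    n_hub: int,
    rng_seed: int = 0,
) -> tuple[ProfileSet, SyntheticTruth]:
    """Append hub seeds: equal-weight mixtures of all extreme profiles.

    A hub's expected profile is the plain average of the gradient's extreme
    profiles (plus the base noise level), making it maximally similar, on
    average, to the rest of the population — the planted convergence-zone
    ground truth.
    """
    if n_hub <= 0:
        raise ValueError("n_hub must be positive")
    if base_truth.extremes is None or base_truth.extremes.shape[0] < 2:
        raise ValueError("base must carry a gradient with >= 2 extremes")
    rng = np.random.default_rng(rng_seed)
    expected = base_truth.extremes.mean(axis=0)
    noise_sd = float(base_truth.generator_params.get("noise_sd", 0.0))
    values = _add_noise(np.tile(expected, (n_hub, 1)), noise_sd, rng)

    all_values = np.vstack([base.values, values])
    coords = np.vstack([base.seed_coords,
                        _seed_lattice(n_hub, offset=base.n_seeds)])
    params = dict(base_truth.generator_params,
                  hub=dict(n_hub=n_hub, rng_seed=rng_seed))
    profiles = replace(base, values=all_values, seed_coords=coords,
                       processing_log=base.processing_log
                       + [{"step": "synthetic_hub", **params["hub"]}])
    truth = SyntheticTruth(
        latent_coordinate=np.concatenate([base_truth.latent_coordinate,
                                          np.full(n_hub, np.nan)]),
        population_label=np.concatenate([base_truth.population_label,
                                         np.array(["hub"] * n_hub, dtype=object)]),
        hub_mask=np.concatenate([base_truth.hub_mask, np.ones(n_hub, bool)]),
        generator_params=params,
        extremes=base_truth.extremes,
    )
    return profiles, truth


def generate_multisubject(
    template: ProfileSet,
    n_subjects: int,
    subject_noise_sd: float = 0.1,
    rng_seed: int = 0,
) -> list[ProfileSet]:
    """Independent noisy per-subject realisations of a template.

    All subjects share the template's seed correspondence; averaging the
    realisations shrinks the noise as 1/sqrt(n_subjects).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if subject_noise_sd < 0:
        raise ValueError("subject_noise_sd must be non-negative")
    rng = np.random.default_rng(rng_seed)
    subjects = []
    for s in range(n_subjects):
        values = _add_noise(template.values, subject_noise_sd, rng)
        log = template.processing_log + [
            {"step": "synthetic_subject", "subject": s,
             "subject_noise_sd": subject_noise_sd, "rng_seed": rng_seed}]
        subjects.append(replace(template, values=values, processing_log=log))
    return subjects
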