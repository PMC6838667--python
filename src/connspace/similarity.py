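"""Cosine similarity graph of seed voxels and its Laplacian.

Pairwise similarity of connectivity profiles is the cosine of the angle
between the two profile vectors, so the n x n similarity matrix of a
non-negative profile set has entries in [0, 1] and unit diagonal.  Treated
as a weighted adjacency matrix A, it defines a degree matrix
D = diag(row sums of A) and the graph Laplacian

    L = D - A

which is symmetric positive semidefinite; the dimension of its null space
equals the number of connected components of the graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .profiles import ProfileSet

__all__ = ["SimilarityGraph", "cosine_similarity_matrix", "build_laplacian"]

SYMMETRY_TOL = 1e-10


@dataclass
class SimilarityGraph:
    """Weighted seed-similarity graph: adjacency A, degree D, Laplacian L.

    ``seed_index`` maps graph node position to the seed's row in the source
    ProfileSet (identity unless seeds were dropped upstream).
    """

    A: np.ndarray
    D: np.ndarray | None = None
    L: np.ndarray | None = None
    seed_index: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    def degrees(self) -> np.ndarray:
        if self.D is None:
            raise ValueError("degree matrix not built; call build_laplacian")
        return np.diag(self.D)


def cosine_similarity_matrix(profiles: ProfileSet | np.ndarray) -> SimilarityGraph:
    """Pairwise cosine similarity of seed connectivity profiles.

    ``A[i, j] = <p_i, p_j> / (||p_i|| ||p_j||)``; the diagonal is exactly 1.
    Zero-norm rows are rejected by name — run
    :func:`connspace.profiles.drop_empty_seeds` first.
    """
    values = profiles.values if isinstance(profiles, ProfileSet) else np.asarray(profiles, float)
    norms = np.linalg.norm(values, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(
            f"cannot compute cosine similarity: seed(s) {bad.tolist()} have "
            "zero-norm (empty) profiles"
        )
    A = _sk_cosine(values)
    A = np.clip((A + A.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry, [0,1] range
    np.fill_diagonal(A, 1.0)
    return SimilarityGraph(A=A, seed_index=np.arange(values.shape[0]))


def build_laplacian(
    graph: SimilarityGraph, *, zero_diagonal: bool = False
) -> SimilarityGraph:
    """Fill in D and L = D - A for a similarity graph.

    With ``zero_diagonal=True`` the self-similarity diagonal of A is removed
    before computing degrees.  L itself is identical either way (the
    diagonal cancels in D - A), but D — which normalizes the generalized
    eigenproblem downstream — is not; the default keeps the diagonal as
    computed.
    """
    A = np.asarray(graph.A, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    asym = np.abs(A - A.T).max()
    if asym > SYMMETRY_TOL:
        raise ValueError(f"adjacency is asymmetric beyond tolerance ({asym:.2e})")
    if np.any(A < 0):
        raise ValueError("adjacency must be non-negative")
    if zero_diagonal:
        A = A.copy()
        np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=1)
    D = np.diag(deg)
    L = D - A
    seed_index = graph.seed_index
    if seed_index is None:
        seed_index = np.arange(A.shape[0])
    return SimilarityGraph(A=A, D=D, L=L, seed_index=seed_index)
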