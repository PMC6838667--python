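"""Generalized Laplacian eigendecomposition and spectrum diagnostics.

The similarity space is obtained by solving the generalized eigenproblem

    L X = D X Lambda

for the graph Laplacian L and degree matrix D — the normalized-cut
(Shi & Malik) formulation of Laplacian eigenmaps.  Eigenvalues lie in
[0, 2]; the multiplicity of the zero eigenvalue equals the number of
connected components of the similarity graph, and the eigenvectors of the
three smallest non-zero eigenvalues give each seed voxel its coordinates
in a three-dimensional connective-similarity space.

The solver works through the symmetric substitution: with
``M = D^{-1/2} L D^{-1/2}`` (symmetric, PSD), the eigenpairs ``(lam, y)``
of M map to generalized eigenpairs ``(lam, D^{-1/2} y)`` of (L, D).  This
keeps the numerics in a single symmetric dense eigensolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .similarity import SimilarityGraph

__all__ = [
    "Embedding",
    "generalized_eigendecomposition",
    "spectrum_diagnostics",
    "select_embedding",
    "fix_signs",
]

#: an eigenvalue counts as "zero" below ZERO_TOL_FACTOR * max(1, lambda_max)
ZERO_TOL_FACTOR = 1e-8
#: default number of eigenpairs beyond the expected zeros, so diagnostics
#: can report gaps past the three embedding dimensions
EXTRA_EIGENPAIRS = 8


@dataclass
class Embedding:
    """Generalized eigenpairs of (L, D) and the 3-D similarity coordinates.

    ``eigenvalues`` are ascending; ``eigenvectors`` holds the matching
    columns of X, D-orthogonal and sign-fixed.  ``coords`` (filled by
    :func:`select_embedding`) are the columns at positions
    ``zero_multiplicity .. zero_multiplicity + 2`` — the eigenvectors of the
    three smallest non-zero eigenvalues.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    zero_multiplicity: int
    tol_zero: float
    coords: np.ndarray | None = None
    residuals: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_seeds(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def algebraic_connectivity(self) -> float:
        """First non-zero eigenvalue (for a connected graph)."""
        nz = self.eigenvalues[self.zero_multiplicity:]
        return float(nz[0]) if nz.size else float("nan")


def fix_signs(X: np.ndarray) -> np.ndarray:
    """Orient each eigenvector so its largest-|entry| element is positive.

    Eigensolvers return arbitrary per-vector signs; this convention makes
    the embedding deterministic.  Ties on |entry| break to the lowest index.
    """
    X = np.array(X, float, copy=True)
    for j in range(X.shape[1]):
        col = X[:, j]
        i = int(np.argmax(np.abs(col)))  # argmax takes the first maximizer
        if col[i] < 0:
            X[:, j] = -col
    return X


def generalized_eigendecomposition(
    graph: SimilarityGraph, k: int | None = None
) -> Embedding:
    """Solve ``L X = D X Lambda`` for the k smallest generalized eigenpairs.

    Parameters
    ----------
    graph : SimilarityGraph
        Must have D and L built (see :func:`connspace.similarity.build_laplacian`).
    k : int, optional
        Number of smallest eigenpairs to return.  Defaults to
        ``zero_multiplicity + 8`` (capped at n) so the diagnostics can
        report eigengaps beyond the three embedding dimensions.

    Returns
    -------
    Embedding
        With ascending eigenvalues, D-orthogonal sign-fixed eigenvectors,
        per-pair residuals ``||L x - lam D x|| / ||x||`` and the detected
        zero-eigenvalue multiplicity.
    """
    if graph.L is None or graph.D is None:
        raise ValueError("graph needs D and L; call build_laplacian first")
    L = np.asarray(graph.L, float)
    deg = np.diag(graph.D).astype(float)
    n = L.shape[0]
    zero_deg = np.flatnonzero(deg <= 0)
    if zero_deg.size:
        raise ValueError(
            f"node(s) {zero_deg.tolist()} have zero degree; the generalized "
            "eigenproblem is singular"
        )
    if k is not None and not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]; got {k}")

    d_isqrt = 1.0 / np.sqrt(deg)
    M = d_isqrt[:, None] * L * d_isqrt[None, :]
    M = (M + M.T) / 2.0
    evals, Y = scipy.linalg.eigh(M)

    tol = ZERO_TOL_FACTOR * max(1.0, float(evals[-1]))
    zero_mult = int(np.count_nonzero(evals < tol))
    if k is None:
        k = min(n, zero_mult + EXTRA_EIGENPAIRS)
    evals = evals[:k]
    X = d_isqrt[:, None] * Y[:, :k]
    X = fix_signs(X)

    # residual check on the original generalized problem
    DX = deg[:, None] * X
    res = np.linalg.norm(L @ X - DX * evals[None, :], axis=0)
    res /= np.linalg.norm(X, axis=0)
    if np.any(res > 1e-6 * max(1.0, np.abs(evals).max())):
        raise RuntimeError(
            f"eigensolver residuals too large (max {res.max():.2e}); "
            "decomposition unreliable"
        )
    emb = Embedding(
        eigenvalues=np.maximum(evals, 0.0),
        eigenvectors=X,
        zero_multiplicity=min(zero_mult, k),
        tol_zero=tol,
        residuals=res,
    )
    emb.diagnostics = spectrum_diagnostics(emb)
    return emb


def spectrum_diagnostics(emb: Embedding) -> dict:
    """Connectedness and eigengap report for an eigenvalue spectrum.

    The zero-eigenvalue multiplicity counts the graph's connected
    components; clear clusters show as near-zero leading eigenvalues
    followed by a large gap, while graded organisation shows a smoothly
    rising spectrum.  Reports successive gaps among the returned
    eigenvalues and the index of the largest gap (``gaps[i]`` is
    ``lambda_{i+1} - lambda_i``, 0-based).
    """
    ev = np.asarray(emb.eigenvalues, float)
    gaps = np.diff(ev)
    zero_mult = int(np.count_nonzero(ev < emb.tol_zero))
    report = {
        "n_eigenvalues": int(ev.size),
        "zero_multiplicity": zero_mult,
        "n_components": zero_mult,
        "connected": emb.zero_multiplicity == 1,
        "tol_zero": float(emb.tol_zero),
        "eigenvalues": ev.tolist(),
        "eigengaps": gaps.tolist(),
        "largest_gap_index": int(np.argmax(gaps)) if gaps.size else None,
        "algebraic_connectivity": float(ev[zero_mult]) if ev.size > zero_mult
        else float("nan"),
    }
    return report


def select_embedding(emb: Embedding, n_dims: int = 3) -> Embedding:
    """Fill ``coords`` with the eigenvectors of the smallest non-zero eigenvalues.

    All ``zero_multiplicity`` null-space eigenvectors are skipped (for a
    connected graph that is just the constant vector), then the next
    ``n_dims`` columns of X become the similarity-space coordinates.
    """
    start = emb.zero_multiplicity
    if emb.eigenvectors.shape[1] < start + n_dims:
        raise ValueError(
            f"need at least {start + n_dims} eigenpairs "
            f"({start} zero + {n_dims} embedding) but only "
            f"{emb.eigenvectors.shape[1]} were computed; re-run the "
            "decomposition with a larger k"
        )
    emb.coords = emb.eigenvectors[:, start:start + n_dims]
    return emb
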