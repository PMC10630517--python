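"""Eigenmode decomposition of structural and functional connectomes.

The structural connectome SC decomposes as SC = V Lambda^s V^T with
eigenvalues sorted descending: large positive eigenvalues mark modes whose
spatial pattern is aligned with the anatomy (connected nodes share sign),
negative eigenvalues mark modes that deviate from it. The functional
connectome FC decomposes as FC = U Lambda^f U^T; small negative functional
eigenvalues are treated as noise and clipped to zero, and the eigenvalue of
each remaining mode measures its contribution to the functional network.

Functional modes are expressed in the structural eigenbasis through the
projection weights m_ij = V_j^T U_i; since both bases are orthonormal the
squared weights of any functional mode sum to one, so m_ij^2 is the
fractional contribution of structural mode j to functional mode i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import ConnectomeMatrix, InvalidInputError

#: eigenvalues in (-CLIP_TOL, 0) are treated as numerical noise and set to 0;
#: n_positive counts eigenvalues strictly above CLIP_TOL
CLIP_TOL = 1e-10


@dataclass(frozen=True)
class ModeSet:
    """Eigenvalues (descending) and orthonormal eigenvectors of a connectome.

    Column j of ``eigenvectors`` is mode j (unit Euclidean norm). For the
    functional role the stored eigenvalues are clipped at zero.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    role: str

    @property
    def n(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.eigenvalues > CLIP_TOL))

    def reconstruct(self) -> np.ndarray:
        """Sum_i lambda_i u_i u_i^T (the clipped matrix for functional role)."""
        return (self.eigenvectors * self.eigenvalues) @ self.eigenvectors.T


@dataclass(frozen=True)
class ContributionMatrix:
    """Projection weights of functional modes onto structural modes.

    ``weights[i, j]`` is m_ij = V_j^T U_i; each row has unit squared sum.
    """

    weights: np.ndarray

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def squared(self) -> np.ndarray:
        return self.weights**2


def _sorted_eigh(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition, eigenvalues descending, sign-fixed.

    Ties in the (descending) sort are broken by original index (stable sort);
    each eigenvector's largest-magnitude element is made positive so results
    are reproducible across runs. Downstream quantities use squares or outer
    products and are sign-invariant anyway.
    """
    vals, vecs = np.linalg.eigh(matrix)
    order = np.argsort(-vals, kind="stable")
    vals = vals[order]
    vecs = vecs[:, order]
    lead = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[lead, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vals, vecs * signs


def decompose_fc(fc: ConnectomeMatrix) -> ModeSet:
    """Eigendecompose a functional connectome, clipping negative eigenvalues.

    Negative functional eigenvalues are noise artifacts of finite scan length
    and are set to zero, so the returned ModeSet reconstructs the clipped FC.
    """
    if fc.role != "functional":
        raise InvalidInputError(f"expected functional role, got {fc.role!r}")
    vals, vecs = _sorted_eigh(fc.values)
    vals = np.where(vals > 0.0, vals, 0.0)
    return ModeSet(eigenvalues=vals, eigenvectors=vecs, role="functional")


def decompose_sc(sc: ConnectomeMatrix) -> ModeSet:
    """Eigendecompose a structural connectome (no clipping).

    Negative structural eigenvalues are meaningful: they index modes that
    deviate from the anatomical wiring. The zero diagonal of SC forces the
    spectrum to sum to zero.
    """
    if sc.role != "structural":
        raise InvalidInputError(f"expected structural role, got {sc.role!r}")
    vals, vecs = _sorted_eigh(sc.values)
    return ModeSet(eigenvalues=vals, eigenvectors=vecs, role="structural")


def mode_alignment(mode: np.ndarray, sc: ConnectomeMatrix) -> float:
    """Rayleigh quotient v^T SC v of a unit-norm spatial pattern.

    Positive when connected nodes carry values of the same sign (the pattern
    is organized along the anatomy), negative when they oppose. For an
    eigenvector of SC this returns its eigenvalue.
    """
    mode = np.asarray(mode, dtype=float)
    if mode.shape != (sc.n,):
        raise InvalidInputError(f"mode shape {mode.shape} does not match n={sc.n}")
    return float(mode @ sc.values @ mode)


def binned_alignment(
    mode: np.ndarray,
    sc: ConnectomeMatrix,
    distances: np.ndarray,
    n_bins: int = 10,
) -> np.ndarray:
    """Alignment of a mode with respect to edges in distance bins.

    Existing edges (SC > 0, unordered) are sorted by length and partitioned
    into ``n_bins`` bins of equal edge count (+/- 1). Element k is
    sum over edges (n1, n2) in bin k of SC(n1, n2) v(n1) v(n2), each
    unordered edge counted once; twice the total over bins equals the
    ordered-pair alignment v^T SC v.
    """
    mode = np.asarray(mode, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if mode.shape != (sc.n,):
        raise InvalidInputError(f"mode shape {mode.shape} does not match n={sc.n}")
    if distances.shape != (sc.n, sc.n):
        raise InvalidInputError("distance matrix shape mismatch")
    ii, jj = np.triu_indices(sc.n, k=1)
    present = sc.values[ii, jj] > 0
    ii, jj = ii[present], jj[present]
    if ii.size < n_bins:
        raise InvalidInputError(f"{ii.size} edges cannot fill {n_bins} bins")
    order = np.argsort(distances[ii, jj], kind="stable")
    contrib = sc.values[ii, jj] * mode[ii] * mode[jj]
    chunks = np.array_split(contrib[order], n_bins)
    return np.array([chunk.sum() for chunk in chunks])


def contribution_weights(fmodes: ModeSet, smodes: ModeSet) -> ContributionMatrix:
    """Project functional modes onto the structural eigenbasis.

    Returns the matrix M with M[i, j] = V_j^T U_i. Because V spans R^n and
    U_i has unit norm, every row of M has squared-entry sum exactly 1.
    """
    if fmodes.n != smodes.n:
        raise InvalidInputError(f"node counts differ: {fmodes.n} vs {smodes.n}")
    return ContributionMatrix(weights=fmodes.eigenvectors.T @ smodes.eigenvectors)
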