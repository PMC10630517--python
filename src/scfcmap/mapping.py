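"""Structure-to-function mappings and their evaluation.

The core mapping approximates FC by its K most contributing functional
modes, each expressed as a linear combination of structural eigenmodes:

    FC ~= sum_{i<=K} lambda_i^f (sum_j m_ij V_j)(sum_j m_ij V_j)^T,

with closed-form weights m_ij = V_j^T U_i. Because the expansion contains
the cross products V_{j1} V_{j2}^T for j1 != j2, it reaches interactions
between different structural modes that a diagonal eigenmode fit cannot.

Benchmarks:

* Tewarie-style eigenmode fit: FC ~= sum_j a_j V_j V_j^T, the best diagonal
  combination of structural modes (closed form a_j = V_j^T FC V_j).
* Becker-style spectral fit: FC ~= R (sum_l a_l SC^l) R^T with rotation
  R = U V^T and polynomial coefficients fitted by least squares.
* Communication model: OLS regression of the FC upper triangle on a stack
  of SC-derived communication predictors.
* Reference mapping: always predicts the group-average FC.

Performance is Pearson R between the strictly upper-triangular entries of
predicted and empirical FC (whole-brain), or between corresponding rows
excluding the diagonal (regional).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .comm_predictors import PredictorStack
from .eigenmodes import ModeSet, contribution_weights
from .matrices import ConnectomeMatrix, InvalidInputError, UndefinedResultError, upper_triangle


@dataclass
class MappingResult:
    """Predicted FC together with fitted parameters and accuracy."""

    predicted: ConnectomeMatrix
    params: dict
    method: str
    whole_brain_r: float
    regional_r: np.ndarray


@dataclass(frozen=True)
class GroupReference:
    """Entrywise mean FC over a cohort, used as the no-structure baseline."""

    mean_fc: ConnectomeMatrix
    n_subjects: int


def whole_brain_r(predicted: ConnectomeMatrix | np.ndarray, empirical: ConnectomeMatrix | np.ndarray) -> float:
    """Pearson R over the n(n-1)/2 strictly upper-triangular entries."""
    a = upper_triangle(_values(predicted))
    b = upper_triangle(_values(empirical))
    if a.shape != b.shape:
        raise InvalidInputError("matrices have different sizes")
    if a.size < 3:
        raise InvalidInputError("need n >= 3 nodes")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedResultError("zero variance in upper-triangle entries; R undefined")
    return float(stats.pearsonr(a, b).statistic)


def regional_r(predicted: ConnectomeMatrix | np.ndarray, empirical: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    """Per-region Pearson R between FC profiles (matrix rows, diagonal excluded).

    Regions with zero variance in either profile get NaN and a warning.
    """
    pred = _values(predicted)
    emp = _values(empirical)
    if pred.shape != emp.shape:
        raise InvalidInputError("matrices have different sizes")
    n = pred.shape[0]
    if n < 4:
        raise InvalidInputError("need n >= 4 nodes for regional profiles")
    out = np.empty(n)
    mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        a, b = pred[i, mask[i]], emp[i, mask[i]]
        if np.std(a) == 0 or np.std(b) == 0:
            warnings.warn(f"region {i}: zero-variance profile, regional R undefined", stacklevel=2)
            out[i] = np.nan
        else:
            out[i] = stats.pearsonr(a, b).statistic
    return out


def fraction_better(regional_r_a: np.ndarray, regional_r_b: np.ndarray) -> float:
    """Share of regions where method A explains the FC profile better than B.

    Ties count as not better.
    """
    a = np.asarray(regional_r_a, dtype=float)
    b = np.asarray(regional_r_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("regional vectors have different lengths")
    return float(np.mean(a > b))


def _values(mat) -> np.ndarray:
    return mat.values if isinstance(mat, ConnectomeMatrix) else np.asarray(mat, dtype=float)


def _result(predicted: np.ndarray, empirical: ConnectomeMatrix, params: dict, method: str) -> MappingResult:
    predicted = (predicted + predicted.T) / 2.0
    pred_cm = ConnectomeMatrix(predicted, role="functional", strict=False)
    try:
        wbr = whole_brain_r(pred_cm, empirical)
    except UndefinedResultError as exc:
        warnings.warn(f"{method}: {exc}", stacklevel=3)
        wbr = float("nan")
    return MappingResult(
        predicted=pred_cm,
        params=params,
        method=method,
        whole_brain_r=wbr,
        regional_r=regional_r(pred_cm, empirical),
    )


def fit_proposed(
    smodes: ModeSet,
    fmodes: ModeSet,
    k: int = 1,
    evaluate_against: ConnectomeMatrix | None = None,
) -> MappingResult:
    """K-mode projection mapping: rebuild FC from its top K functional modes
    expressed in the structural eigenbasis.

    With k equal to the number of positive functional eigenvalues the
    prediction reproduces the clipped empirical FC exactly. ``evaluate_against``
    switches to out-of-sample evaluation: parameters come from ``fmodes``
    (session 1) while R is computed against a second empirical FC.
    """
    if not 1 <= k <= smodes.n:
        raise InvalidInputError(f"k={k} out of range 1..{smodes.n}")
    contrib = contribution_weights(fmodes, smodes)
    m_rows = contrib.weights[:k]  # (k, n): row i holds m_ij over structural modes j
    # sum_j m_ij V_j reproduces U_i exactly (V is a complete orthonormal basis)
    rebuilt = smodes.eigenvectors @ m_rows.T  # (n, k)
    predicted = (rebuilt * fmodes.eigenvalues[:k]) @ rebuilt.T
    empirical = evaluate_against
    if empirical is None:
        empirical = ConnectomeMatrix(fmodes.reconstruct(), role="functional", strict=False)
    return _result(predicted, empirical, {"k": k, "m": m_rows, "eigenvalues": fmodes.eigenvalues[:k]}, "proposed")


def fit_tewarie(smodes: ModeSet, fc: ConnectomeMatrix) -> MappingResult:
    """Diagonal eigenmode fit FC ~= sum_j a_j V_j V_j^T.

    By orthonormality of V the Frobenius least-squares solution is the
    closed form a_j = V_j^T FC V_j.
    """
    if smodes.n != fc.n:
        raise InvalidInputError("node counts differ")
    v = smodes.eigenvectors
    a = np.einsum("ij,jk,ki->i", v.T, fc.values, v)
    predicted = (v * a) @ v.T
    return _result(predicted, fc, {"a": a}, "tewarie")


def fit_becker(smodes: ModeSet, fmodes: ModeSet, l_max: int,
               evaluate_against: ConnectomeMatrix | None = None) -> MappingResult:
    """Rotation-plus-polynomial spectral fit FC ~= R (sum_l a_l SC^l) R^T.

    The rotation R = U V^T aligns structural to functional eigenmodes, so in
    the rotated eigen-domain the fit reduces to a polynomial regression of
    functional on structural eigenvalues: p(lambda_j^s) ~= lambda_j^f. That
    diagonal least-squares problem is solved with a Vandermonde design whose
    columns are scaled by the spectral radius to keep it well conditioned;
    it is mathematically equivalent to the Frobenius matrix-domain fit.
    """
    if l_max < 0:
        raise InvalidInputError("l_max must be >= 0")
    if smodes.n != fmodes.n:
        raise InvalidInputError("node counts differ")
    lam_s = smodes.eigenvalues
    lam_f = fmodes.eigenvalues
    scale = max(np.abs(lam_s).max(), 1.0)
    design = np.vander(lam_s / scale, N=l_max + 1, increasing=True)
    coef_scaled, _, rank, _ = np.linalg.lstsq(design, lam_f, rcond=None)
    if rank < l_max + 1:
        warnings.warn("rank-deficient polynomial design; pseudoinverse solution used", stacklevel=2)
    coefs = coef_scaled / scale ** np.arange(l_max + 1)
    u = fmodes.eigenvectors
    predicted = (u * (design @ coef_scaled)) @ u.T
    empirical = evaluate_against
    if empirical is None:
        empirical = ConnectomeMatrix(fmodes.reconstruct(), role="functional", strict=False)
    rotation = u @ smodes.eigenvectors.T
    return _result(predicted, empirical, {"a": coefs, "rotation": rotation, "l_max": l_max}, "becker")


def fit_communication(fc: ConnectomeMatrix, predictors: PredictorStack) -> MappingResult:
    """OLS regression of the empirical FC upper triangle on communication
    predictors derived from SC.

    Predictor upper triangles are z-scored before the regression (their raw
    scales differ by orders of magnitude; R is invariant). Collinear stacks
    are solved by pseudoinverse with a warning. The predicted matrix is
    rebuilt symmetric with the empirical diagonal.
    """
    if predictors.q == 0:
        raise UndefinedResultError("intercept-only communication model: prediction constant, R undefined")
    y = fc.upper_triangle()
    cols = []
    for name, mat in zip(predictors.names, predictors.matrices):
        if mat.shape != fc.values.shape:
            raise InvalidInputError(f"predictor {name!r} has wrong shape")
        x = upper_triangle(mat)
        sd = np.std(x)
        if sd == 0:
            warnings.warn(f"predictor {name!r} is constant over edges", stacklevel=2)
            cols.append(np.zeros_like(x))
        else:
            cols.append((x - x.mean()) / sd)
    design = np.column_stack([np.ones_like(y)] + cols)
    coefs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("collinear predictors; pseudoinverse solution used", stacklevel=2)
    yhat = design @ coefs
    n = fc.n
    predicted = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    predicted[iu] = yhat
    predicted = predicted + predicted.T
    np.fill_diagonal(predicted, np.diag(fc.values))
    params = {"a": coefs, "names": ["intercept"] + list(predictors.names)}
    return _result(predicted, fc, params, "communication")


def group_reference(fcs: Sequence[ConnectomeMatrix]) -> GroupReference:
    """Entrywise mean FC over a cohort of subjects."""
    if len(fcs) < 2:
        raise InvalidInputError("group reference needs at least 2 subjects")
    n = fcs[0].n
    if any(fc.n != n for fc in fcs):
        raise InvalidInputError("subjects have different node counts")
    mean = np.mean([fc.values for fc in fcs], axis=0)
    return GroupReference(
        mean_fc=ConnectomeMatrix(mean, role="functional", strict=False),
        n_subjects=len(fcs),
    )


def reference_predict(group: GroupReference, empirical: ConnectomeMatrix) -> MappingResult:
    """Reference mapping: predict every subject's FC by the group mean."""
    return _result(group.mean_fc.values.copy(), empirical, {"n_subjects": group.n_subjects}, "reference")
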