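"""Functional diversity, aligned/deviated components, and age associations.

Functional diversity (FD) measures how evenly the positive functional
eigenvalues are spread: with M positive eigenvalues and shares
p_i = lambda_i / sum(lambda),

    FD = 1 - (1 / N_M) * sum_i |p_i - 1/M|,   N_M = 2 (M - 1) / M,

so FD = 0 when one mode carries everything and FD = 1 when all M modes
contribute equally.

The leading functional mode U_1 is split by spectral filtering into a
structure-aligned component (built from the first L_A structural modes,
those with the largest eigenvalues) and a structure-deviated component
(built from the last L_D modes, those most misaligned with the anatomy).
The liberality index is the energy ratio of the deviated to the aligned
component: larger values mean the dominant functional pattern is less
tethered to the anatomical wiring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .eigenmodes import CLIP_TOL, ContributionMatrix, ModeSet, contribution_weights, decompose_fc, decompose_sc
from .matrices import ConnectomeMatrix, InvalidInputError, UndefinedResultError

DEFAULT_L_ALIGNED = 10
DEFAULT_L_DEVIATED = 10


@dataclass(frozen=True)
class ComponentSplit:
    """Structure-aligned and structure-deviated parts of the leading
    functional mode, with their norms and the liberality index."""

    aligned: np.ndarray
    deviated: np.ndarray
    l_a: int
    l_d: int
    norm_aligned: float
    norm_deviated: float
    liberality: float


def functional_diversity(eigenvalues: np.ndarray, n_modes: int | None = None) -> float:
    """Evenness of the (clipped) functional eigenvalue distribution in [0, 1].

    Parameters
    ----------
    eigenvalues : clipped functional spectrum (nonnegative).
    n_modes : fix M instead of counting eigenvalues above tolerance
        (sensitivity option).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0 or lam.max() <= CLIP_TOL:
        raise InvalidInputError("spectrum has no positive eigenvalues")
    if (lam < -CLIP_TOL).any():
        raise InvalidInputError("clipped functional spectrum must be nonnegative")
    if n_modes is None:
        m = int(np.sum(lam > CLIP_TOL))
        lam = np.sort(lam)[::-1][:m]
    else:
        m = int(n_modes)
        lam = np.sort(lam)[::-1][:m]
    if m == 1:
        return 0.0
    shares = lam / lam.sum()
    n_m = 2.0 * (m - 1) / m
    return float(1.0 - np.abs(shares - 1.0 / m).sum() / n_m)


def eigenvalue_share(fmodes: ModeSet, i: int) -> float:
    """Share lambda_i^f / sum(lambda^f) of functional mode i (1-based)."""
    if not 1 <= i <= fmodes.n:
        raise InvalidInputError(f"mode index {i} out of range")
    total = fmodes.eigenvalues.sum()
    if total <= 0:
        raise InvalidInputError("spectrum has no positive eigenvalues")
    return float(fmodes.eigenvalues[i - 1] / total)


def split_components(
    contrib: ContributionMatrix,
    smodes: ModeSet,
    l_a: int = DEFAULT_L_ALIGNED,
    l_d: int = DEFAULT_L_DEVIATED,
    ratio: str = "deviated_over_aligned",
) -> ComponentSplit:
    """Split the leading functional mode into aligned and deviated parts.

    aligned  = sum_{j <= l_a} m_1j V_j         (top structural modes)
    deviated = sum_{j > n - l_d} m_1j V_j      (bottom structural modes)

    Energies (squared norms) of the two parts plus the middle band sum to 1.
    ``ratio`` selects the orientation of the liberality index; the default
    deviated/aligned makes a decline in liberality correspond to shrinking
    structure-deviated energy.
    """
    n = smodes.n
    if l_a < 1 or l_d < 1 or l_a + l_d > n:
        raise InvalidInputError(f"invalid window sizes l_a={l_a}, l_d={l_d} for n={n}")
    m1 = contrib.weights[0]
    v = smodes.eigenvectors
    aligned = v[:, :l_a] @ m1[:l_a]
    deviated = v[:, n - l_d:] @ m1[n - l_d:]
    norm_a = float(np.linalg.norm(aligned))
    norm_d = float(np.linalg.norm(deviated))
    split = ComponentSplit(
        aligned=aligned,
        deviated=deviated,
        l_a=l_a,
        l_d=l_d,
        norm_aligned=norm_a,
        norm_deviated=norm_d,
        liberality=liberality_from_norms(norm_a, norm_d, ratio=ratio),
    )
    return split


def liberality_from_norms(norm_aligned: float, norm_deviated: float,
                          ratio: str = "deviated_over_aligned") -> float:
    """Energy ratio of the two components (energies = squared norms)."""
    ea, ed = norm_aligned**2, norm_deviated**2
    if ratio == "deviated_over_aligned":
        num, den = ed, ea
    elif ratio == "aligned_over_deviated":
        num, den = ea, ed
    else:
        raise InvalidInputError(f"unknown ratio orientation {ratio!r}")
    if den == 0:
        warnings.warn("zero energy in denominator component; liberality infinite", stacklevel=2)
        return float("inf")
    return float(num / den)


def liberality_index(split: ComponentSplit) -> float:
    """Liberality of a precomputed component split (deviated/aligned energy)."""
    return liberality_from_norms(split.norm_aligned, split.norm_deviated)


def age_association(values: np.ndarray, ages: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of a per-subject quantity with age.

    Returns (r, two-sided p) from the t-distribution with n - 2 df.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape != ages.shape or values.size < 3:
        raise InvalidInputError("need matched vectors with at least 3 subjects")
    if np.std(values) == 0 or np.std(ages) == 0:
        raise UndefinedResultError("constant input; correlation undefined")
    res = stats.pearsonr(values, ages)
    return float(res.statistic), float(res.pvalue)


def subject_metrics(
    sc: ConnectomeMatrix,
    fc: ConnectomeMatrix,
    l_a: int = DEFAULT_L_ALIGNED,
    l_d: int = DEFAULT_L_DEVIATED,
) -> dict:
    """All per-subject lifespan quantities from one SC/FC pair."""
    smodes = decompose_sc(sc)
    fmodes = decompose_fc(fc)
    contrib = contribution_weights(fmodes, smodes)
    split = split_components(contrib, smodes, l_a=l_a, l_d=l_d)
    return {
        "fd": functional_diversity(fmodes.eigenvalues),
        "share1": eigenvalue_share(fmodes, 1),
        "share2": eigenvalue_share(fmodes, 2),
        "share3": eigenvalue_share(fmodes, 3),
        "norm_aligned": split.norm_aligned,
        "norm_deviated": split.norm_deviated,
        "liberality": split.liberality,
    }


def cohort_table(
    subjects: Sequence[tuple[str, float, ConnectomeMatrix, ConnectomeMatrix]],
    l_a: int = DEFAULT_L_ALIGNED,
    l_d: int = DEFAULT_L_DEVIATED,
) -> pd.DataFrame:
    """Tidy per-subject results table for a cohort.

    ``subjects`` holds (subject_id, age, sc, fc) tuples. Columns:
    subject_id, age, fd, share1..share3, norm_aligned, norm_deviated,
    liberality.
    """
    rows = []
    for subject_id, age, sc, fc in subjects:
        row = {"subject_id": subject_id, "age": age}
        row.update(subject_metrics(sc, fc, l_a=l_a, l_d=l_d))
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_age_associations(table: pd.DataFrame) -> pd.DataFrame:
    """Age correlation (r, p) for every metric column of a cohort table."""
    metrics = [c for c in table.columns if c not in ("subject_id", "age")]
    out = []
    for col in metrics:
        r, p = age_association(table[col].to_numpy(), table["age"].to_numpy())
        out.append({"metric": col, "r": r, "p": p})
    return pd.DataFrame(out)


def sensitivity_sweep(
    subjects: Sequence[tuple[str, float, ConnectomeMatrix, ConnectomeMatrix]],
    window_sizes: Sequence[int] = (5, 10, 15, 20),
) -> pd.DataFrame:
    """Liberality-age correlation across (l_a, l_d) window choices.

    Mirrors the robustness check over aligned/deviated thresholds: one row
    per (l_a, l_d) combination with the liberality-age r and p.
    """
    rows = []
    for l_a, l_d in product(window_sizes, window_sizes):
        table = cohort_table(subjects, l_a=l_a, l_d=l_d)
        r, p = age_association(table["liberality"].to_numpy(), table["age"].to_numpy())
        rows.append({"l_a": l_a, "l_d": l_d, "r": r, "p": p})
    return pd.DataFrame(rows)
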