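"""Spatially constrained permutation (spin test) nulls and basic statistics.

Brain maps are spatially autocorrelated, so naive permutation tests of
map-to-map similarity are anticonservative. The spin test builds null maps
by rigidly rotating node locations on a sphere — preserving the spatial
covariance structure while breaking the correspondence between maps — and
reassigning nodes to their nearest rotated positions. Volumetric
parcellations have no native sphere, so node centroids are projected to a
unit sphere per hemisphere (centered on the hemisphere centroid, radially
normalized); rotations are mirrored across hemispheres and the
original-to-rotated assignment is greedy nearest-neighbor without
replacement, which keeps every permutation bijective and the test statistic
exchangeable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import special_ortho_group
from statsmodels.stats.multitest import multipletests

from .matrices import InvalidInputError, UndefinedResultError

DEFAULT_N_PERM = 10_000


@dataclass(frozen=True)
class SpinEnsemble:
    """Bank of bijective node permutations from random sphere rotations."""

    permutations: np.ndarray  # (n_perm, n) int
    seed: int
    n_perm: int

    @property
    def n(self) -> int:
        return self.permutations.shape[1]


def _sphere_project(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    norms = np.linalg.norm(centered, axis=1)
    if (norms == 0).any():
        raise InvalidInputError("node at hemisphere centroid cannot be sphere-projected")
    return centered / norms[:, None]


def _greedy_assign(original: np.ndarray, rotated: np.ndarray) -> np.ndarray:
    """perm[i] = index of the rotated node assigned to original node i."""
    n = len(original)
    cost = np.linalg.norm(original[:, None, :] - rotated[None, :, :], axis=2)
    taken = np.zeros(n, dtype=bool)
    perm = np.empty(n, dtype=int)
    for i in range(n):
        row = np.where(taken, np.inf, cost[i])
        j = int(np.argmin(row))
        perm[i] = j
        taken[j] = True
    return perm


def generate_spins(
    coords: np.ndarray,
    hemisphere_labels: Sequence[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> SpinEnsemble:
    """Generate a reproducible ensemble of spatial-rotation permutations.

    Each repetition draws a uniform random 3D rotation (applied mirrored to
    the right hemisphere so left/right stay matched), rotates the
    sphere-projected node coordinates, and maps original to rotated nodes by
    greedy nearest-neighbor without replacement within each hemisphere.
    """
    coords = np.asarray(coords, dtype=float)
    if n_perm <= 0:
        raise InvalidInputError("n_perm must be positive")
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise InvalidInputError("coords must be (n, 3)")
    if len(np.unique(coords, axis=0)) != len(coords):
        raise InvalidInputError("duplicate node coordinates")
    hemi = np.asarray(hemisphere_labels)
    if hemi.shape[0] != coords.shape[0]:
        raise InvalidInputError("hemisphere labels do not match coordinates")
    rng = np.random.default_rng(seed)
    mirror = np.diag([-1.0, 1.0, 1.0])
    sphere: dict[str, np.ndarray] = {}
    idx: dict[str, np.ndarray] = {}
    for h in np.unique(hemi):
        idx[h] = np.flatnonzero(hemi == h)
        sphere[h] = _sphere_project(coords[idx[h]])
    perms = np.empty((n_perm, coords.shape[0]), dtype=int)
    for k in range(n_perm):
        rot = special_ortho_group.rvs(3, random_state=rng)
        for h, nodes in idx.items():
            r = rot if h == sorted(idx)[0] else mirror @ rot @ mirror
            rotated = sphere[h] @ r.T
            local = _greedy_assign(sphere[h], rotated)
            perms[k, nodes] = nodes[local]
    return SpinEnsemble(permutations=perms, seed=seed, n_perm=n_perm)


def spin_pvalue(
    map_a: np.ndarray,
    map_b: np.ndarray,
    spins: SpinEnsemble,
    stat: str = "absolute-correlation",
) -> tuple[float, float]:
    """Spin-test p-value for the similarity of two regional maps.

    Returns (observed statistic, p). The null distribution permutes
    ``map_a`` by each spin; p = (1 + #{null >= observed}) / (1 + n_perm),
    which never reaches exactly zero. ``stat`` is "absolute-correlation"
    (|Pearson R|, sign-invariant as eigenmode maps are defined up to sign)
    or "mean-difference" (|mean(a) - mean(b)| is not spin-sensitive, so this
    option compares mean of a over the support of b; mainly for enrichment).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.shape != (spins.n,):
        raise InvalidInputError("maps must match the spin ensemble size")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedResultError("constant map; similarity undefined")

    def statistic(x: np.ndarray) -> float:
        if stat == "absolute-correlation":
            return abs(stats.pearsonr(x, b).statistic)
        if stat == "mean-difference":
            return float(x[b > 0].mean() - x.mean())
        raise InvalidInputError(f"unknown statistic {stat!r}")

    observed = statistic(a)
    null = np.array([statistic(a[perm]) for perm in spins.permutations])
    p = (1.0 + np.sum(null >= observed)) / (1.0 + spins.n_perm)
    return float(observed), float(p)


def rsn_enrichment(
    regional_stat: np.ndarray,
    rsn_labels: Sequence[str],
    spins: SpinEnsemble,
) -> pd.DataFrame:
    """Network-level enrichment of a regional statistic against spin nulls.

    Aggregates the statistic by resting-state network, compares each
    network's mean to the spin-null distribution of means (two-sided), and
    BH-corrects the p-values. Columns: network, mean, p, q.
    """
    values = np.asarray(regional_stat, dtype=float)
    labels = np.asarray(rsn_labels)
    if values.shape[0] != spins.n or labels.shape[0] != spins.n:
        raise InvalidInputError("statistic/labels must match the spin ensemble size")
    networks = [n for n in pd.unique(labels)]
    if len(networks) < 2:
        raise InvalidInputError("need at least 2 networks")
    rows = []
    for net in networks:
        mask = labels == net
        if not mask.any():
            warnings.warn(f"network {net!r} is empty; skipped", stacklevel=2)
            continue
        obs = values[mask].mean()
        null = np.array([values[perm][mask].mean() for perm in spins.permutations])
        center = null.mean()
        p = (1.0 + np.sum(np.abs(null - center) >= abs(obs - center))) / (1.0 + spins.n_perm)
        rows.append({"network": net, "mean": float(obs), "p": float(p)})
    table = pd.DataFrame(rows)
    table["q"] = fdr_bh(table["p"].to_numpy())
    return table


def fdr_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Paired t-test between matched per-subject vectors.

    Returns (t, two-sided p) with n - 1 degrees of freedom. Identical inputs
    give (0, 1); zero-variance nonzero differences are flagged as infinite.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise InvalidInputError("need matched vectors of length >= 3")
    diff = a - b
    if np.std(diff) == 0:
        if np.all(diff == 0):
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero differences; t infinite", stacklevel=2)
        return float(np.sign(diff[0]) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
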