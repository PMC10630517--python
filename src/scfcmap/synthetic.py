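"""Synthetic connectomes with planted ground truth.

The generators emulate the statistical structure the mapping assumes, so
every statistic in the package can be validated by parameter recovery:

* ``gen_sc`` draws a distance-dependent weighted structural network on
  nodes placed in a two-hemisphere ball, with connection probability and
  weight both decaying with Euclidean distance (long-range connections are
  rarer and weaker, as in tractography-derived connectomes).
* ``gen_fc_planted`` builds an FC whose leading eigenmode has *known*
  projection weights onto the structural eigenbasis and whose eigenvalue
  spectrum is planted exactly. The FC is mode-built (trace normalized to n,
  diagonal near 1) so the ground truth is exact; an optional time-series
  route samples signals with that covariance and returns a true Pearson
  correlation matrix instead.
* ``gen_cohort`` produces an age-structured cohort in which the leading
  functional eigenvalue share rises and the structure-function liberality
  falls linearly with age, the regimes reported across the human lifespan.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .eigenmodes import ModeSet, decompose_fc, decompose_sc
from .matrices import ConnectomeMatrix, InvalidInputError

DEFAULT_DENSITY = 0.35
DEFAULT_DECAY_MM = 45.0
BRAIN_RADIUS_MM = 70.0
#: per-subject lognormal sigma for SC weight jitter in cohorts
SC_JITTER_SIGMA = 0.1


def default_spectrum(n: int, n_active: int = 12, ratio: float = 0.65) -> np.ndarray:
    """Geometrically decaying eigenvalue shares dominated by a few modes.

    Empirical FC spectra are far from uniform, with the first handful of
    modes carrying most of the energy; a geometric decay over ``n_active``
    modes (leading share ~0.36 at the defaults) reproduces that shape.
    """
    k = min(n, n_active)
    shares = ratio ** np.arange(k)
    out = np.zeros(n)
    out[:k] = shares / shares.sum()
    return out


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one synthetic FC network.

    ``planted_weights`` are the true projections m_1j of the leading
    functional mode onto the structural modes (unit norm);
    ``planted_spectrum`` holds the functional eigenvalue shares (descending,
    summing to 1); ``age_slopes`` = (leading-share slope, liberality slope)
    per year for cohort generation.
    """

    seed: int
    planted_weights: np.ndarray
    planted_spectrum: np.ndarray
    noise_sd: float = 0.0
    age_slopes: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        w = np.asarray(self.planted_weights, dtype=float)
        if abs(np.linalg.norm(w) - 1.0) > 1e-8:
            raise InvalidInputError("planted weights must have unit norm")
        s = np.asarray(self.planted_spectrum, dtype=float)
        if (s < 0).any() or abs(s.sum() - 1.0) > 1e-8:
            raise InvalidInputError("planted spectrum must be nonnegative shares summing to 1")
        if (np.diff(s) > 1e-12).any():
            raise InvalidInputError("planted spectrum shares must be non-increasing")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be nonnegative")
        object.__setattr__(self, "planted_weights", w)
        object.__setattr__(self, "planted_spectrum", s)


@dataclass(frozen=True)
class CohortSubject:
    """One synthetic subject: connectomes, age, and the planted values."""

    subject_id: str
    age: float
    sc: ConnectomeMatrix
    fc: ConnectomeMatrix
    planted_share1: float
    planted_liberality: float


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[CohortSubject, ...]
    coords: np.ndarray
    hemispheres: np.ndarray
    seed: int

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects])


def _connected(adj: np.ndarray) -> bool:
    from scipy.sparse.csgraph import connected_components

    return connected_components(adj > 0, directed=False)[0] == 1


def gen_sc(
    n: int,
    density: float = DEFAULT_DENSITY,
    decay_mm: float = DEFAULT_DECAY_MM,
    seed: int = 0,
) -> tuple[ConnectomeMatrix, np.ndarray, np.ndarray]:
    """Distance-dependent weighted structural connectome.

    Nodes are uniform in a ball of diameter 140 mm split into left/right
    hemispheres at the sagittal plane. A fixed number of edges (density x
    number of pairs) is drawn without replacement with probability
    proportional to exp(-d / decay_mm); weights are exp(-d / decay_mm) with
    lognormal jitter. Resampled until connected.

    Returns (sc, coords, hemisphere_labels).
    """
    if n < 8:
        raise InvalidInputError("need at least 8 nodes")
    if not 0 < density <= 1:
        raise InvalidInputError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    coords = np.empty((n, 3))
    filled = 0
    while filled < n:
        draw = rng.uniform(-BRAIN_RADIUS_MM, BRAIN_RADIUS_MM, size=(2 * n, 3))
        draw = draw[np.linalg.norm(draw, axis=1) <= BRAIN_RADIUS_MM]
        take = min(len(draw), n - filled)
        coords[filled:filled + take] = draw[:take]
        filled += take
    hemis = np.where(coords[:, 0] < 0, "L", "R")
    ii, jj = np.triu_indices(n, k=1)
    dists = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    n_pairs = len(ii)
    m = int(round(density * n_pairs))
    if m < n - 1:
        raise InvalidInputError(f"density {density} gives {m} edges; cannot connect {n} nodes")
    prob = np.exp(-dists / decay_mm)
    for _ in range(100):
        chosen = rng.choice(n_pairs, size=m, replace=False, p=prob / prob.sum())
        sc = np.zeros((n, n))
        weights = np.exp(-dists[chosen] / decay_mm) * rng.lognormal(0.0, 0.3, size=m)
        sc[ii[chosen], jj[chosen]] = weights
        sc = sc + sc.T
        if _connected(sc):
            return ConnectomeMatrix(sc, role="structural"), coords, hemis
    raise InvalidInputError(f"could not draw a connected graph at density {density}")


def gen_fc_planted(
    smodes: ModeSet,
    truth: SyntheticTruth,
    n_timepoints: int = 0,
) -> ConnectomeMatrix:
    """FC with planted leading-mode projections and eigenvalue spectrum.

    The leading functional mode is U_1 = sum_j w_j V_j with the planted
    weights w; secondary modes complete an orthonormal basis. Eigenvalues
    are the planted shares scaled to trace n. Symmetric Gaussian noise of
    sd ``truth.noise_sd`` is added and negative eigenvalues clipped; at zero
    noise the construction is exact. With ``n_timepoints`` > 0 the FC is
    instead the Pearson correlation of that many signal samples drawn with
    the mode-built covariance (unit diagonal, inexact ground truth).
    """
    n = smodes.n
    w = truth.planted_weights
    if w.shape != (n,):
        raise InvalidInputError(f"planted weights length {w.shape[0]} != n = {n}")
    rng = np.random.default_rng(truth.seed)
    u1 = smodes.eigenvectors @ w
    basis = np.column_stack([u1, rng.standard_normal((n, n - 1))])
    q, _ = np.linalg.qr(basis)
    q[:, 0] *= np.sign(q[:, 0] @ u1)  # keep column 0 equal to u1, not -u1
    shares = np.zeros(n)
    shares[: truth.planted_spectrum.size] = truth.planted_spectrum
    lam = shares * n
    fc = (q * lam) @ q.T
    if n_timepoints > 0:
        signals = rng.standard_normal((n_timepoints, n)) @ (q * np.sqrt(lam)).T
        fc = np.corrcoef(signals, rowvar=False)
        return ConnectomeMatrix(fc, role="functional")
    if truth.noise_sd > 0:
        noise = rng.normal(0.0, truth.noise_sd, size=(n, n))
        fc = fc + (noise + noise.T) / 2.0
        clipped = decompose_fc(ConnectomeMatrix(fc, role="functional", strict=False))
        fc = clipped.reconstruct()
    return ConnectomeMatrix(fc, role="functional", strict=False)


def gen_cohort(
    n_subjects: int,
    age_range: tuple[float, float] = (4.0, 85.0),
    truth_template: SyntheticTruth | None = None,
    seed: int = 0,
    n_nodes: int = 50,
    density: float = DEFAULT_DENSITY,
    l_a: int = 10,
    l_d: int = 10,
    base_share1: float = 0.40,
    base_liberality: float = 0.8,
    aligned_energy: float = 0.35,
) -> Cohort:
    """Age-structured cohort with planted lifespan trends.

    Subjects share one SC topology with per-subject lognormal weight jitter.
    Ages are uniform over ``age_range``. Per subject, the planted leading
    eigenvalue share follows base_share1 + share_slope * (age - midpoint)
    and the planted liberality follows base_liberality + liberality_slope *
    (age - midpoint); slopes come from ``truth_template.age_slopes``.
    Liberality is planted exactly by fixing the aligned-band energy of the
    leading mode and moving the deviated-band energy. FC-level noise is
    ``truth_template.noise_sd``.
    """
    if n_subjects < 10:
        raise InvalidInputError("need at least 10 subjects")
    if n_nodes <= l_a + l_d:
        raise InvalidInputError("n_nodes must exceed l_a + l_d")
    if truth_template is None:
        truth_template = SyntheticTruth(
            seed=seed,
            planted_weights=np.eye(n_nodes)[0],
            planted_spectrum=default_spectrum(n_nodes),
            noise_sd=0.0,
            age_slopes=(0.001, -0.006),
        )
    share_slope, lib_slope = truth_template.age_slopes
    rng = np.random.default_rng(seed)
    sc_base, coords, hemis = gen_sc(n_nodes, density=density, seed=int(rng.integers(2**31 - 1)))
    ages = rng.uniform(age_range[0], age_range[1], size=n_subjects)
    mid = (age_range[0] + age_range[1]) / 2.0
    # fixed unit directions within the aligned / middle / deviated bands
    band_rng = np.random.default_rng(truth_template.seed)
    t_a = _unit(band_rng.standard_normal(l_a))
    t_m = _unit(band_rng.standard_normal(n_nodes - l_a - l_d))
    t_d = _unit(band_rng.standard_normal(l_d))
    template_tail = truth_template.planted_spectrum[1:]
    subjects = []
    ii, jj = np.triu_indices(n_nodes, k=1)
    for s_idx, age in enumerate(ages):
        share1 = base_share1 + share_slope * (age - mid)
        lib = base_liberality + lib_slope * (age - mid)
        if not 0 < share1 < 1:
            raise InvalidInputError(f"share slope pushes leading share to {share1:.3f} at age {age:.1f}")
        dev_energy = aligned_energy * lib
        mid_energy = 1.0 - aligned_energy - dev_energy
        if lib < 0 or mid_energy < 0:
            raise InvalidInputError(f"liberality slope gives invalid energies at age {age:.1f}")
        weights = np.concatenate([
            np.sqrt(aligned_energy) * t_a,
            np.sqrt(mid_energy) * t_m,
            np.sqrt(dev_energy) * t_d,
        ])
        tail = template_tail / template_tail.sum() * (1.0 - share1)
        spectrum = np.concatenate([[share1], tail])
        if spectrum[0] <= spectrum[1]:
            raise InvalidInputError("leading share must stay dominant across the age range")
        # per-subject SC: shared topology, jittered weights
        jitter = rng.lognormal(0.0, SC_JITTER_SIGMA, size=ii.size)
        vals = np.zeros((n_nodes, n_nodes))
        vals[ii, jj] = sc_base.values[ii, jj] * jitter
        vals = vals + vals.T
        sc = ConnectomeMatrix(vals, role="structural")
        truth = replace(
            truth_template,
            seed=int(rng.integers(2**31 - 1)),
            planted_weights=weights,
            planted_spectrum=spectrum,
        )
        fc = gen_fc_planted(decompose_sc(sc), truth)
        subjects.append(
            CohortSubject(
                subject_id=f"sub-{s_idx:03d}",
                age=float(age),
                sc=sc,
                fc=fc,
                planted_share1=float(share1),
                planted_liberality=float(lib),
            )
        )
    return Cohort(subjects=tuple(subjects), coords=coords, hemispheres=hemis, seed=seed)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)
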