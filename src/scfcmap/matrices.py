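"""Connectome matrix containers and validation.

A connectome is an n x n symmetric matrix over brain regions. Structural
connectivity (SC) holds nonnegative white-matter connection weights with a
zero diagonal; functional connectivity (FC) holds Pearson correlations of
regional activity time series, with a unit diagonal when it comes straight
from data. Matrices built from eigenmode reconstructions are FC-like but
need not have an exactly unit diagonal, so functional validation has a
strict and a relaxed mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SYMMETRY_TOL = 1e-6


class InvalidInputError(ValueError):
    """Raised when a matrix violates the invariants of its role."""


class UndefinedResultError(ArithmeticError):
    """Raised when a statistic is undefined (e.g. zero-variance input)."""


@dataclass(frozen=True)
class ConnectomeMatrix:
    """Symmetric connectivity matrix with a structural or functional role.

    Parameters
    ----------
    values : (n, n) ndarray
        Connection weights (structural) or correlations (functional).
    role : {"structural", "functional"}
    strict : bool
        For the functional role, require unit diagonal and entries in
        [-1, 1] (true Pearson-correlation matrix). Relax for mode-built
        or predicted FC matrices.
    """

    values: np.ndarray
    role: str
    strict: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise InvalidInputError(f"matrix must be square, got shape {values.shape}")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise InvalidInputError(f"non-finite entry at {tuple(bad)}")
        asym = np.abs(values - values.T).max() if values.size else 0.0
        if asym > SYMMETRY_TOL:
            raise InvalidInputError(f"matrix asymmetric beyond tolerance (max |A-A.T| = {asym:.3g})")
        values = (values + values.T) / 2.0
        if self.role == "structural":
            if values.min() < 0:
                bad = np.argwhere(values < 0)[0]
                raise InvalidInputError(f"negative structural weight at {tuple(bad)}")
            diag_max = np.abs(np.diag(values)).max()
            if diag_max > SYMMETRY_TOL:
                raise InvalidInputError(f"structural diagonal must be zero (max |diag| = {diag_max:.3g})")
            np.fill_diagonal(values, 0.0)
        elif self.role == "functional":
            if self.strict:
                if np.abs(values).max() > 1.0 + SYMMETRY_TOL:
                    bad = np.argwhere(np.abs(values) > 1.0 + SYMMETRY_TOL)[0]
                    raise InvalidInputError(
                        f"functional entry outside [-1, 1] at {tuple(bad)}: {values[tuple(bad)]:.4g}"
                    )
                off = np.abs(np.diag(values) - 1.0).max()
                if off > SYMMETRY_TOL:
                    raise InvalidInputError(f"functional diagonal must be 1 (max deviation {off:.3g})")
        else:
            raise InvalidInputError(f"unknown role {self.role!r}")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Strictly upper-triangular entries as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Strictly upper-triangular entries of a square array as a flat vector."""
    matrix = np.asarray(matrix)
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]
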