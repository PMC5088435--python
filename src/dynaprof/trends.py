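"""Orthogonal polynomial trend extraction for short, unequal-length series.

Each mediator time series is summarized by its projections onto a discrete
orthogonal polynomial basis over the reading-round indices 1..n (the
classical orthogonal-contrast construction).  Because every basis column
has unit Euclidean norm regardless of the series length, a "linear trend"
coefficient from a 5-point series is directly comparable with one from an
8-point series — the property that lets trends act as fixed-dimension
predictors for cohorts with ragged sampling.

Column naming follows the level/linear/quadratic/cubic convention:
``<mediator>.T0`` (level), ``.L``, ``.Q``, ``.C``, ``.T4``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .cohort import Cohort, MediatorSeries

MAX_DEGREE = 4

DEGREE_SUFFIX = {0: "T0", 1: "L", 2: "Q", 3: "C", 4: "T4"}


@dataclass(frozen=True)
class TrendBasis:
    """Orthonormal discrete-polynomial basis over indices 1..n_points."""

    n_points: int
    degree: int
    basis: np.ndarray  # (n_points, degree + 1), orthonormal columns


@dataclass
class TrendCoefficients:
    """Projections c_0..c_d of one series onto a :class:`TrendBasis`.

    ``usable`` is False when the series is shorter than d+1 points, in
    which case no coefficients are produced.
    """

    mediator: str
    degree: int
    coefficients: np.ndarray | None
    usable: bool


@lru_cache(maxsize=512)
def _basis_matrix(n_points: int, degree: int) -> np.ndarray:
    # QR of the Vandermonde matrix over 1..n == Gram-Schmidt on 1, t, t^2, ...
    t = np.arange(1, n_points + 1, dtype=float)
    vander = np.vander(t, degree + 1, increasing=True)
    q, r = np.linalg.qr(vander)
    # Fix signs so each column correlates positively with its monomial.
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    q.setflags(write=False)
    return q


def build_basis(n_points: int, degree: int) -> TrendBasis:
    """Orthonormal basis of polynomial degrees 0..degree over 1..n_points.

    Degree-0 column is the constant 1/sqrt(n); higher columns span exactly
    polynomial degree j of the index and are mutually orthonormal.
    """
    if degree < 0:
        raise ValueError("degree must be non-negative")
    if degree > MAX_DEGREE:
        raise ValueError(f"degree capped at {MAX_DEGREE}, got {degree}")
    if n_points <= degree:
        raise ValueError(
            f"series too short: need at least {degree + 1} points, got {n_points}"
        )
    return TrendBasis(n_points, degree, _basis_matrix(n_points, degree))


def moving_average3(values: np.ndarray) -> np.ndarray:
    """Centered moving average of window 3, windows shrinking at the ends."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return v.copy()
    out = v.copy()
    out[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    out[0] = (v[0] + v[1]) / 2.0
    out[-1] = (v[-2] + v[-1]) / 2.0
    return out


def extract_trends(
    series: MediatorSeries | np.ndarray,
    degree: int,
    smooth: bool = False,
    mediator: str = "",
) -> TrendCoefficients:
    """Project a series onto the orthonormal basis, c = Bᵀ·values.

    Series shorter than ``degree + 1`` are flagged unusable instead of
    raising, so callers can sweep ragged cohorts without special-casing.
    """
    if isinstance(series, MediatorSeries):
        values = series.values
        mediator = mediator or series.mediator
    else:
        values = np.asarray(series, dtype=float)
    n = values.size
    if n < degree + 1:
        return TrendCoefficients(mediator, degree, None, usable=False)
    if smooth:
        values = moving_average3(values)
    basis = build_basis(n, degree)
    coeffs = basis.basis.T @ values
    return TrendCoefficients(mediator, degree, coeffs, usable=True)


def trend_column_names(panel: tuple[str, ...], degree: int) -> list[str]:
    return [f"{m}.{DEGREE_SUFFIX[j]}" for m in panel for j in range(degree + 1)]


def trend_matrix(
    cohort: Cohort,
    degree: int,
    up_to_round: int | None = None,
    smooth: bool = False,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-patient trend feature table with 13·(d+1) columns.

    Each mediator series is truncated at ``up_to_round`` (when given and
    rounds are assigned) before projection.  Patients with any mediator
    series shorter than d+1 points are excluded and reported in the
    returned mask ``{patient_id: reason}``.
    """
    if not 0 <= degree <= MAX_DEGREE:
        raise ValueError(f"degree must lie in [0, {MAX_DEGREE}], got {degree}")
    columns = trend_column_names(cohort.mediator_panel, degree)
    rows: dict[str, list[float]] = {}
    excluded: dict[str, str] = {}
    for p in cohort:
        feats: list[float] = []
        short = None
        for m in cohort.mediator_panel:
            values = p.series[m].values_up_to_round(up_to_round)
            tc = extract_trends(values, degree, smooth=smooth, mediator=m)
            if not tc.usable:
                short = f"{m} series has {values.size} < {degree + 1} points"
                break
            feats.extend(tc.coefficients)
        if short is not None:
            excluded[p.id] = short
        else:
            rows[p.id] = feats
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    frame.index.name = "patient_id"
    return frame, excluded


def residual_summary(
    series: MediatorSeries | np.ndarray, coeffs: TrendCoefficients
) -> tuple[np.ndarray, float]:
    """Residuals of the polynomial-trend fit and their sample variance.

    The residual vector is orthogonal to every basis column by
    construction; its variance flags series with structure beyond degree d
    (e.g. unrecorded clinical interventions).
    """
    if not coeffs.usable:
        raise ValueError("cannot compute residuals for unusable coefficients")
    values = series.values if isinstance(series, MediatorSeries) else np.asarray(series, float)
    basis = build_basis(values.size, coeffs.degree)
    residuals = values - basis.basis @ coeffs.coefficients
    variance = float(np.var(residuals, ddof=1)) if residuals.size > 1 else 0.0
    return residuals, variance
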