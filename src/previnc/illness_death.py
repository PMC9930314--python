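"""Incidence estimation from prevalence cross-sections via the illness-death model.

The illness-death model has three states -- Healthy, Diseased, Dead -- with
age- and time-dependent transition rates: the incidence ``i(t, a)`` and the
mortality rates ``m0(t, a)`` (non-diseased) and ``m1(t, a)`` (diseased).
Writing ``p(t, a)`` for the age-specific prevalence, ``m`` for the general
mortality ``(1-p)*m0 + p*m1`` and ``R = m1/m0`` for the mortality rate
ratio, the prevalence obeys the transport equation

    (d/dt + d/da) p = (1 - p) * [ i - m * p * (R - 1) / (1 + p * (R - 1)) ]

which, when diseased and non-diseased mortality are equal (``R = 1``, a good
approximation for diabetes in youth), collapses to

    (d/dt + d/da) p = (1 - p) * i .

This module provides, in the order the method runs:

1. forward machinery -- integrate the PDE along characteristics (birth
   cohorts, lines of constant ``a - t``) to evolve a prevalence curve
   between two calendar years;
2. estimation -- invert the simplified equation to recover the average
   age-specific incidence between two prevalence surveys, with percentile
   bootstrap confidence intervals, direct age-standardization and
   comparison statistics against an observed incidence panel;
3. synthetic worlds -- ground-truth scenario generator emulating a
   youth-diabetes surveillance design (two cross-sections eight years
   apart, single-year ages 0-19, 2 sexes x 4 race/ethnicity groups,
   binomial case counts) so the whole pipeline is testable end to end;
4. file I/O -- delimited-text readers/writers with validation for
   prevalence tables, incidence panels, standard-population weights and
   scenario configurations.

Internally all rates are per person-year; everything crossing the I/O
boundary is per 100,000 person-years.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import nnls

logger = logging.getLogger("previnc")

__all__ = [
    "DomainError",
    "ValidationError",
    "ConfigError",
    "NumericalError",
    "N_AGES",
    "AGES",
    "PER_100K",
    "RateSurface",
    "PrevalenceCurve",
    "characteristic_rhs",
    "solve_forward",
    "closed_form_constant_rates",
    "PrevalenceCrossSection",
    "StandardPopulation",
    "IncidenceEstimate",
    "BootstrapResult",
    "prevalence_from_counts",
    "estimate_incidence_characteristics",
    "estimate_incidence_finite_difference",
    "bootstrap_ci",
    "age_standardize",
    "relative_error",
    "observed_incidence_summary",
    "summarize_against_observed",
    "age_bands",
    "ScenarioConfig",
    "World",
    "default_scenario",
    "true_incidence",
    "incidence_grid",
    "generate_world",
    "recovery_experiment",
    "read_prevalence_table",
    "write_prevalence_table",
    "read_incidence_panel",
    "write_incidence_panel",
    "read_standard_population",
    "write_standard_population",
    "load_scenario",
    "save_scenario",
    "RunConfig",
    "run_estimate",
]

# --------------------------------------------------------------------------
# constants & errors
# --------------------------------------------------------------------------

N_AGES = 20                      #: single-year age intervals [a, a+1), a = 0..19
AGES = np.arange(N_AGES)         #: the age index
PER_100K = 1e5                   #: rate unit conversion at the I/O boundary
DEFAULT_STEP = 0.1               #: sub-annual integration step, years
DEFAULT_REPLICATES = 5000        #: bootstrap replicates
_P_TOL = 1e-9                    # tolerance for prevalence leaving [0, 1)
_RHS_TOL = 1e-12                 # tolerance before a negative constraint is flagged

SEXES = ("female", "male")
RACE_GROUPS = ("NHW", "NHB", "Hispanic", "Other")

PREVALENCE_COLUMNS = ["year", "sex", "race_ethnicity", "age", "cases", "denominator"]
PANEL_COLUMNS = ["year", "sex", "race_ethnicity", "age", "rate_per_100k"]
WEIGHT_COLUMNS = ["age", "weight"]


class DomainError(ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(ValueError):
    """Input data violate a schema or consistency constraint."""


class ConfigError(ValueError):
    """A scenario or run configuration is invalid."""


class NumericalError(RuntimeError):
    """The numerical solution left its admissible region beyond tolerance."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite values")
    return arr


# --------------------------------------------------------------------------
# 1. forward machinery: the transport PDE along characteristics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RateSurface:
    """Transition rates of the illness-death model on the age-time window.

    Each of ``incidence`` (events per person-year), ``general_mortality``
    (deaths per person-year) and ``mortality_rate_ratio`` (dimensionless,
    m1/m0) is either a length-20 array, read as piecewise-constant on the
    single-year age intervals [a, a+1) and constant in calendar time, or a
    callable ``f(t, a)`` accepting vectorized ages.  Evaluation outside
    ``time_window`` x [0, 20) is an error, not an extrapolation.
    """

    time_window: tuple[float, float]
    incidence: np.ndarray | Callable[[float, np.ndarray], np.ndarray]
    general_mortality: np.ndarray | Callable[[float, np.ndarray], np.ndarray] = (
        None  # type: ignore[assignment]
    )
    mortality_rate_ratio: np.ndarray | Callable[[float, np.ndarray], np.ndarray] = (
        None  # type: ignore[assignment]
    )

    def __post_init__(self):
        t0, t1 = self.time_window
        if not (np.isfinite(t0) and np.isfinite(t1) and t1 > t0):
            raise DomainError(f"time_window must satisfy t0 < t1, got {self.time_window}")
        for name, default in (
            ("general_mortality", 0.0),
            ("mortality_rate_ratio", 1.0),
        ):
            if getattr(self, name) is None:
                object.__setattr__(self, name, np.full(N_AGES, default))
        for name, positive in (
            ("incidence", False),
            ("general_mortality", False),
            ("mortality_rate_ratio", True),
        ):
            val = getattr(self, name)
            if callable(val):
                continue
            arr = _as_float_array(val, name)
            if arr.ndim == 0:
                arr = np.full(N_AGES, float(arr))
            if arr.shape != (N_AGES,):
                raise DomainError(
                    f"{name} table must have one value per single-year age "
                    f"(shape ({N_AGES},)), got {arr.shape}"
                )
            if positive and np.any(arr <= 0):
                raise DomainError(f"{name} must be > 0 everywhere")
            if not positive and np.any(arr < 0):
                raise DomainError(f"{name} must be >= 0 everywhere")
            object.__setattr__(self, name, arr)

    @classmethod
    def constant(
        cls,
        incidence,
        general_mortality=0.0,
        mortality_rate_ratio=1.0,
        time_window=(0.0, 100.0),
    ) -> "RateSurface":
        """Build a surface from scalars or per-age arrays, constant in time."""
        return cls(
            time_window=tuple(time_window),
            incidence=np.broadcast_to(np.asarray(incidence, float), (N_AGES,)).copy(),
            general_mortality=np.broadcast_to(
                np.asarray(general_mortality, float), (N_AGES,)
            ).copy(),
            mortality_rate_ratio=np.broadcast_to(
                np.asarray(mortality_rate_ratio, float), (N_AGES,)
            ).copy(),
        )

    def at(self, t: float, ages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Evaluate (i, m, R) at calendar time ``t`` and (possibly fractional) ages."""
        t0, t1 = self.time_window
        if not (t0 - 1e-9 <= t <= t1 + 1e-9):
            raise DomainError(f"time {t} outside rate surface window [{t0}, {t1}]")
        ages = np.asarray(ages, dtype=float)
        if np.any(ages < 0) or np.any(ages >= N_AGES):
            raise DomainError("age outside [0, 20) requested from rate surface")
        out = []
        idx = ages.astype(int)
        for val in (self.incidence, self.general_mortality, self.mortality_rate_ratio):
            out.append(val(t, ages) if callable(val) else val[idx])
        return out[0], out[1], out[2]


@dataclass(frozen=True)
class PrevalenceCurve:
    """Age-specific prevalence proportions p(a), a = 0..19, in one survey year."""

    proportions: np.ndarray
    year: float
    ages: np.ndarray = field(default_factory=lambda: AGES.copy())

    def __post_init__(self):
        p = _as_float_array(self.proportions, "proportions")
        ages = np.asarray(self.ages)
        if p.shape != ages.shape:
            raise ValidationError(
                f"proportions and ages differ in length: {p.shape} vs {ages.shape}"
            )
        if np.any(p < 0) or np.any(p >= 1):
            bad = np.flatnonzero((p < 0) | (p >= 1))
            raise DomainError(f"prevalence must lie in [0, 1); offending ages: {ages[bad]}")
        object.__setattr__(self, "proportions", p)
        object.__setattr__(self, "ages", ages)


def _rhs(p, i, m, R):
    # unvalidated vectorized right-hand side of the full transport equation
    return (1.0 - p) * (i - m * p * (R - 1.0) / (1.0 + p * (R - 1.0)))


def characteristic_rhs(p: float, i: float, m: float, R: float) -> float:
    """Rate of change of prevalence along a characteristic (birth cohort).

    Evaluates ``(1-p) * [i - m*p*(R-1)/(1+p*(R-1))]``.  With ``R = 1`` the
    mortality term vanishes identically and the value is exactly
    ``(1-p)*i`` -- the equal-mortality simplification.

    Parameters
    ----------
    p : prevalence, in [0, 1)
    i : incidence, events per person-year, >= 0
    m : general mortality, deaths per person-year, >= 0
    R : mortality rate ratio m1/m0, > 0
    """
    vals = [np.asarray(v, dtype=float) for v in (p, i, m, R)]
    for v, name in zip(vals, "pimR"):
        if not np.all(np.isfinite(v)):
            raise DomainError(f"non-finite value for {name!r}")
    p_, i_, m_, R_ = vals
    if np.any(p_ < 0) or np.any(p_ >= 1):
        raise DomainError(f"prevalence {p} outside [0, 1)")
    if np.any(i_ < 0) or np.any(m_ < 0):
        raise DomainError("rates must be non-negative")
    if np.any(R_ <= 0):
        raise DomainError("mortality rate ratio must be positive")
    out = _rhs(p_, i_, m_, R_)
    return float(out) if out.ndim == 0 else out


def _check_step(step: float) -> int:
    """Sub-steps per year; the step must divide one year."""
    if step <= 0:
        raise DomainError(f"step must be positive, got {step}")
    n = round(1.0 / step)
    if n < 1 or abs(n * step - 1.0) > 1e-9:
        raise DomainError(f"step {step} does not divide 1.0 year")
    return n


def solve_forward(
    initial: PrevalenceCurve,
    rates: RateSurface,
    t1: float,
    birth_prevalence: float = 0.0,
    step: float = DEFAULT_STEP,
) -> PrevalenceCurve:
    """Evolve a prevalence curve from its survey year to ``t1`` under the PDE.

    Integrates the characteristic ODE ``dp/dtau = characteristic_rhs`` along
    lines of constant ``a - t`` with classical 4th-order Runge-Kutta.  Rates
    are sampled once per sub-step at the sub-step age midpoint, so each step
    stays inside a single one-year age interval and piecewise-constant rate
    tables are handled without smearing across interval boundaries.

    Cohorts aging past 20 before ``t1`` leave the surveillance window and
    are dropped (logged at debug level); cohorts born after the initial
    year enter at age 0 with prevalence ``birth_prevalence``.

    Returns the prevalence curve on ages 0..19 attained at ``t1``.
    """
    t0 = float(initial.year)
    gap = t1 - t0
    if gap <= 0:
        raise DomainError(f"t1 ({t1}) must exceed the initial year ({t0})")
    if not (0 <= birth_prevalence < 1):
        raise DomainError(f"birth prevalence {birth_prevalence} outside [0, 1)")
    per_year = _check_step(step)
    h = 1.0 / per_year
    n_steps = round(gap / h)
    if abs(n_steps * h - gap) > 1e-9:
        raise DomainError(f"survey gap {gap} is not a multiple of step {step}")

    dropped = [a for a in range(N_AGES) if a + gap > N_AGES - 1 + 1e-9]
    if dropped:
        logger.debug(
            "cohorts at initial ages %s age past %d before %s and are dropped",
            dropped, N_AGES, t1,
        )

    final_ages = AGES.astype(float)
    start_age = final_ages - gap                      # may be negative: born after t0
    tau_start = np.maximum(0.0, -start_age)           # entry time of each characteristic
    p = np.where(
        start_age >= -1e-9,
        initial.proportions[np.clip(np.rint(start_age).astype(int), 0, N_AGES - 1)],
        birth_prevalence,
    ).astype(float)

    for k in range(n_steps):
        tau = k * h
        active = tau >= tau_start - 0.25 * h
        if not np.any(active):
            continue
        a_mid = final_ages[active] - gap + tau + 0.5 * h
        i, m, R = rates.at(t0 + tau + 0.5 * h, a_mid)
        q = p[active]
        k1 = _rhs(q, i, m, R)
        k2 = _rhs(q + 0.5 * h * k1, i, m, R)
        k3 = _rhs(q + 0.5 * h * k2, i, m, R)
        k4 = _rhs(q + h * k3, i, m, R)
        p[active] = q + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    if np.any(p < -_P_TOL) or np.any(p >= 1.0):
        bad = np.flatnonzero((p < -_P_TOL) | (p >= 1.0))
        raise NumericalError(
            f"prevalence left [0, 1) along characteristics ending at ages {AGES[bad]}: "
            f"{p[bad]}"
        )
    return PrevalenceCurve(proportions=np.clip(p, 0.0, None), year=t1)


def closed_form_constant_rates(i, a):
    """Prevalence of a cohort aged ``a`` under constant incidence ``i`` and R = 1.

    The characteristic ODE dp/da = (1-p) i with p(0) = 0 has the exponential
    solution ``p = 1 - exp(-i a)``; used throughout as an analytic oracle.
    """
    i_ = _as_float_array(i, "i")
    a_ = _as_float_array(a, "a")
    if np.any(i_ < 0) or np.any(a_ < 0):
        raise DomainError("closed form requires i >= 0 and a >= 0")
    out = -np.expm1(-i_ * a_)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# 2. estimation: inverting the simplified PDE between two cross-sections
# --------------------------------------------------------------------------


def prevalence_from_counts(cases, denominator):
    """Prevalence proportion cases/denominator, validated cell by cell."""
    c = np.asarray(cases)
    n = np.asarray(denominator)
    if np.any(n <= 0):
        raise DomainError("denominator must be positive")
    if np.any(c < 0) or np.any(c > n):
        bad = np.flatnonzero((np.ravel(c) < 0) | (np.ravel(c) > np.ravel(n)))
        raise ValidationError(
            f"cases outside [0, denominator] at flat cell index(es) {bad.tolist()}"
        )
    out = c / n
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class StandardPopulation:
    """Age weights for direct standardization; normalized to sum to 1."""

    weights: np.ndarray
    ages: np.ndarray = field(default_factory=lambda: AGES.copy())

    def __post_init__(self):
        w = _as_float_array(self.weights, "weights")
        ages = np.asarray(self.ages)
        if w.shape != ages.shape:
            raise ValidationError("weights and ages differ in length")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("weights must be non-negative with positive sum")
        object.__setattr__(self, "weights", w / w.sum())
        object.__setattr__(self, "ages", ages)

    @classmethod
    def uniform(cls) -> "StandardPopulation":
        return cls(weights=np.full(N_AGES, 1.0 / N_AGES))


def age_standardize(rates, weights: StandardPopulation | np.ndarray) -> float:
    """Directly age-standardized rate: the weight-averaged age-specific rate."""
    if isinstance(weights, StandardPopulation):
        w = weights.weights
    else:
        w = _as_float_array(weights, "weights")
    r = _as_float_array(rates, "rates")
    if r.shape != w.shape:
        raise ValidationError(
            f"rates and standard-population weights on different age indices: "
            f"{r.shape} vs {w.shape}"
        )
    return float(r @ w)


def relative_error(estimated: float, observed: float) -> float:
    """Signed relative error 100 * (E - O) / O, in percent; NaN when O = 0."""
    if observed == 0:
        warnings.warn("relative error undefined for observed rate 0; reporting NaN")
        return float("nan")
    return 100.0 * (estimated - observed) / observed


@dataclass
class IncidenceEstimate:
    """Age-specific incidence estimates (per person-year) with identifiability flags.

    ``identified[a]`` is False where the single-year interval [a, a+1) is
    touched by no characteristic constraint (age 19 for an 8-year survey
    gap) and the value was filled by carrying the last identified estimate
    forward.
    """

    rates: np.ndarray
    identified: np.ndarray
    ages: np.ndarray = field(default_factory=lambda: AGES.copy())
    smoothness: float = 0.0          #: roughness-penalty weight actually applied


def _constraint_system(gap: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rows of the cumulative-hazard constraint system for an integer survey gap.

    Along the characteristic ending at age a1 at the second survey, the
    simplified PDE integrates exactly to a linear constraint on the
    piecewise-constant incidence vector:

        sum_{k = max(0, a1-gap)}^{a1-1} i(k) = log[(1-p0) / (1-p1)]

    with p0 the first-survey prevalence of the same cohort (0 for cohorts
    born between the surveys).  Returns (A, final_ages, identified_columns).
    """
    rows = []
    final_ages = []
    for a1 in range(1, N_AGES):           # a1 = 0 yields an empty window
        row = np.zeros(N_AGES)
        row[max(0, a1 - gap): a1] = 1.0
        rows.append(row)
        final_ages.append(a1)
    A = np.array(rows)
    identified = A.sum(axis=0) > 0
    return A, np.array(final_ages), identified


def _cumulative_hazards(p0: np.ndarray, p1: np.ndarray, gap: int) -> np.ndarray:
    """Right-hand sides log[(1-p0)/(1-p1)] for final ages 1..19 (may be negative)."""
    q0 = -np.log1p(-p0)
    q1 = -np.log1p(-p1)
    b = np.empty(N_AGES - 1)
    for j, a1 in enumerate(range(1, N_AGES)):
        b[j] = q1[a1] - (q0[a1 - gap] if a1 >= gap else 0.0)
    return b


_PENALTY_ORDER = 3   # difference order of the roughness penalty; null space = quadratics


def _difference_matrix(n: int, order: int = _PENALTY_ORDER) -> np.ndarray:
    D = np.eye(n)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return D


def _fill_unidentified(x: np.ndarray, identified: np.ndarray) -> np.ndarray:
    """Fill intervals no constraint touches by linear extrapolation, floored at 0.

    With an 8-year gap only the boundary interval [19, 20) is unidentified;
    extrapolating from the last two identified intervals tracks both rising
    and falling shapes at the boundary (plain carry-forward systematically
    under-shoots rising ones).  Falls back to carrying the nearest value
    when fewer than two identified neighbours exist.
    """
    rates = np.empty(N_AGES)
    rates[identified] = x
    idx = np.flatnonzero(identified)
    for a in np.flatnonzero(~identified):
        left = idx[idx < a]
        if left.size >= 2:
            a1, a2 = left[-2], left[-1]
            slope = (rates[a2] - rates[a1]) / (a2 - a1)
            rates[a] = max(0.0, rates[a2] + slope * (a - a2))
        elif left.size == 1:
            rates[a] = rates[left[-1]]
        else:
            right = idx[idx > a]
            rates[a] = rates[right[0]] if right.size else 0.0
    return rates


def _solve_nnls(A_id: np.ndarray, b: np.ndarray, identified: np.ndarray,
                smoothness: float) -> np.ndarray:
    if smoothness > 0:
        n = A_id.shape[1]
        A_id = np.vstack([A_id, np.sqrt(smoothness) * _difference_matrix(n)])
        b = np.concatenate([b, np.zeros(n - _PENALTY_ORDER)])
    x, _ = nnls(A_id, b)
    return _fill_unidentified(x, identified)


def _hazard_sd(p0: np.ndarray, p1: np.ndarray, n0: np.ndarray, n1: np.ndarray,
               gap: int) -> np.ndarray:
    """Sampling standard deviation of each cumulative-hazard constraint.

    Delta method on q = -log(1-p), p-hat binomial: var(q) ~= p/((1-p) n).
    Proportions are continuity-floored (cases + 0.5) for the variance
    estimate only, so empty cells get a nonzero noise scale.
    """
    def var_q(p, n):
        pt = (p * n + 0.5) / (n + 1.0)
        return pt / ((1.0 - pt) * n)

    v0, v1 = var_q(p0, n0), var_q(p1, n1)
    var_b = np.empty(N_AGES - 1)
    for j, a1 in enumerate(range(1, N_AGES)):
        var_b[j] = v1[a1] + (v0[a1 - gap] if a1 >= gap else 0.0)
    return np.sqrt(var_b)


_W_GRID = 10.0 ** np.linspace(0.0, 16.0, 33)   # REML search grid for the weight
_LOG_W_GRID = np.log(_W_GRID)


def _reml_setup(A_w: np.ndarray):
    """One-off factorization so REML weight selection is O(grid x n) per call.

    With AtA = L L' (Cholesky) and the penalty similarity L^-1 P L^-T
    eigendecomposed as U diag(s) U', every term of the REML criterion
    becomes elementwise in the rotated coordinates, for any weight.
    """
    n = A_w.shape[1]
    D = _difference_matrix(n)
    P = D.T @ D
    L = np.linalg.cholesky(A_w.T @ A_w)
    L_inv = np.linalg.inv(L)
    s, U = np.linalg.eigh(L_inv @ P @ L_inv.T)
    return L_inv, U, np.maximum(s, 0.0), 2.0 * np.log(np.diag(L)).sum(), D.shape[0]


def _reml_weight(setup, Atb: np.ndarray, b_sq: float) -> float:
    L_inv, U, s, logdet_LL, r_pen = setup
    b_rot = U.T @ (L_inv @ Atb)
    d = 1.0 + _W_GRID[:, None] * s
    z = b_rot / d
    zz = z * z
    crit = (
        (b_sq - 2.0 * (z @ b_rot) + zz.sum(axis=1))   # residual sum of squares
        + _W_GRID * (zz @ s)                          # penalty term
        + logdet_LL + np.log(d).sum(axis=1)           # log-determinant
        - r_pen * _LOG_W_GRID                         # prior normalization
    )
    return float(_W_GRID[np.argmin(crit)])


def _select_smoothness(A_w: np.ndarray, b_w: np.ndarray) -> float:
    """REML (empirical-Bayes) choice of the roughness-penalty weight.

    On the noise-whitened constraint system (rows scaled by the binomial
    sampling standard deviation of each right-hand side, so the error
    variance is 1) the incidence vector is given the standard P-spline
    working prior: third differences i.i.d. Gaussian with variance 1/w,
    quadratic age trends unpenalized.  The restricted marginal likelihood
    is maximized over a log-spaced grid -- the same smoothing-parameter
    selection penalized-spline GAMs perform.  The nonnegativity constraint
    is ignored during selection (Gaussian working model) and enforced in
    the final solve.

    The data term scales with the denominators while the prior does not,
    so the selected smoothing becomes negligible as sampling noise goes to
    zero and near-noise-free input is recovered to solver accuracy.
    """
    return _reml_weight(_reml_setup(A_w), A_w.T @ b_w, float(b_w @ b_w))


def _validate_curves(p_t0: PrevalenceCurve, p_t1: PrevalenceCurve, gap) -> int:
    derived = p_t1.year - p_t0.year
    if gap is None:
        gap = derived
    elif abs(gap - derived) > 1e-9:
        raise ValidationError(
            f"stated gap {gap} conflicts with survey years "
            f"{p_t0.year} -> {p_t1.year}"
        )
    if abs(gap - round(gap)) > 1e-9 or gap <= 0:
        raise DomainError(f"survey gap must be a positive integer number of years, got {gap}")
    return int(round(gap))


def estimate_incidence_characteristics(
    p_t0: PrevalenceCurve,
    p_t1: PrevalenceCurve,
    gap: int | None = None,
    smoothness: float | str = "auto",
    denominators: tuple[np.ndarray, np.ndarray] | None = None,
) -> IncidenceEstimate:
    """Estimate average age-specific incidence between two prevalence surveys.

    Assumes the simplified illness-death PDE (equal mortality with and
    without disease), incidence constant in calendar time over the survey
    gap and piecewise-constant on single-year age intervals.  Each birth
    cohort contributes one exact linear constraint on the incidence vector
    (see :func:`_constraint_system`); the system is solved by nonnegativity-
    constrained least squares with an optional difference-penalty on the
    roughness of the age profile.

    The single-year system is exactly determined, so on noisy survey data
    the unpenalized solution amplifies sampling noise which the
    nonnegativity floor then rectifies into upward bias.  When the survey
    ``denominators`` (a pair of per-age arrays, first and second survey)
    are supplied, the constraints are noise-whitened and
    ``smoothness='auto'`` selects the penalty weight by restricted maximum
    likelihood (:func:`_select_smoothness`) -- the weight goes to zero with
    the noise, so noise-free inputs are still recovered exactly.  Without
    denominators there is no noise scale and ``'auto'`` means no penalty.
    A numeric ``smoothness`` forces that weight on the whitened system.

    Constraints with negative right-hand side (prevalence falling along a
    cohort, impossible under the model without excess mortality) are floored
    at zero with a warning; sampling noise makes these inevitable in
    bootstrap replicates.
    """
    gap = _validate_curves(p_t0, p_t1, gap)
    A, _, identified = _constraint_system(gap)
    b = _cumulative_hazards(p_t0.proportions, p_t1.proportions, gap)
    n_neg = int(np.sum(b < -_RHS_TOL))
    if n_neg:
        warnings.warn(
            f"{n_neg} characteristic constraint(s) imply prevalence decreasing "
            "along a cohort; floored at zero"
        )
    b = np.maximum(b, 0.0)
    if p_t1.proportions[0] > _RHS_TOL:
        warnings.warn(
            "non-zero prevalence at age 0 in the second survey cannot be "
            "attributed to any incidence interval and is ignored"
        )
    A_id = A[:, identified]
    if denominators is not None:
        n0 = np.broadcast_to(np.asarray(denominators[0], float), (N_AGES,))
        n1 = np.broadcast_to(np.asarray(denominators[1], float), (N_AGES,))
        sd_b = _hazard_sd(p_t0.proportions, p_t1.proportions, n0, n1, gap)
        A_eff = A_id / sd_b[:, None]
        b_eff = b / sd_b
        w = (
            _select_smoothness(A_eff, b_eff)
            if smoothness == "auto"
            else float(smoothness)
        )
    else:
        A_eff, b_eff = A_id, b
        w = 0.0 if smoothness == "auto" else float(smoothness)
    rates = _solve_nnls(A_eff, b_eff, identified, w)
    return IncidenceEstimate(rates=rates, identified=identified.copy(), smoothness=w)


def estimate_incidence_finite_difference(
    p_t0: PrevalenceCurve,
    p_t1: PrevalenceCurve,
    gap: int | None = None,
) -> IncidenceEstimate:
    """Midpoint finite-difference estimator along characteristics (cross-check).

    For the cohort observed at age a0 in the first survey and a1 = a0 + gap
    in the second, the directional derivative reading of the simplified PDE
    gives ``i(a_mid) ~= [p1(a1) - p0(a0)] / (gap * (1 - p_mean))`` at the
    mid-age (a0+a1)/2; cohorts born between the surveys start from p = 0
    over a window of length a1.  Mid-ages are mapped to the containing
    single-year interval (floor); intervals receiving several estimates are
    averaged, intervals receiving none are filled from the nearest assigned
    interval and flagged unidentified.  Coarser than the characteristics
    method; retained as a documented cross-check, not the default.
    """
    gap = _validate_curves(p_t0, p_t1, gap)
    p0, p1 = p_t0.proportions, p_t1.proportions
    sums = np.zeros(N_AGES)
    counts = np.zeros(N_AGES)
    n_neg = 0
    for a1 in range(1, N_AGES):
        if a1 >= gap:
            start_p, length, mid = p0[a1 - gap], gap, (a1 - gap + a1) / 2.0
        else:
            start_p, length, mid = 0.0, a1, a1 / 2.0
        p_bar = 0.5 * (start_p + p1[a1])
        est = (p1[a1] - start_p) / (length * (1.0 - p_bar))
        if est < 0:
            n_neg += 1
            est = 0.0
        k = min(int(mid), N_AGES - 1)
        sums[k] += est
        counts[k] += 1
    if n_neg:
        warnings.warn(f"{n_neg} negative finite-difference estimate(s) floored at zero")
    identified = counts > 0
    rates = np.zeros(N_AGES)
    rates[identified] = sums[identified] / counts[identified]
    assigned = np.flatnonzero(identified)
    for a in np.flatnonzero(~identified):
        rates[a] = rates[assigned[np.argmin(np.abs(assigned - a))]]
    return IncidenceEstimate(rates=rates, identified=identified)


_ESTIMATORS = {
    "characteristics": estimate_incidence_characteristics,
    "finite-difference": estimate_incidence_finite_difference,
}


# --- cross-sections -------------------------------------------------------


class PrevalenceCrossSection:
    """One survey year's age-by-stratum case counts and denominators.

    Thin wrapper over a tidy frame with columns sex, race_ethnicity, age,
    cases, denominator (plus a recomputable ``proportion``); every stratum
    must carry the complete single-year age index 0..19.
    """

    def __init__(self, year: int, data: pd.DataFrame):
        self.year = int(year)
        df = data.copy()
        missing = [c for c in PREVALENCE_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise ValidationError(f"prevalence table missing column(s) {missing}")
        problems = []
        if (df["denominator"] <= 0).any():
            problems += [
                f"row {r}: non-positive denominator"
                for r in df.index[df["denominator"] <= 0].tolist()
            ]
        bad = df["cases"].lt(0) | df["cases"].gt(df["denominator"])
        problems += [
            f"row {r}: cases={df.at[r, 'cases']} outside [0, denominator="
            f"{df.at[r, 'denominator']}] "
            f"({df.at[r, 'sex']}/{df.at[r, 'race_ethnicity']}/age {df.at[r, 'age']})"
            for r in df.index[bad].tolist()
        ]
        if problems:
            raise ValidationError(
                f"invalid prevalence cells in year {year}:\n" + "\n".join(problems)
            )
        self._strata: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        for (sex, race), grp in df.groupby(["sex", "race_ethnicity"], sort=True):
            grp = grp.sort_values("age")
            ages = grp["age"].to_numpy()
            if not np.array_equal(ages, AGES):
                raise ValidationError(
                    f"stratum ({sex}, {race}) in year {year} does not cover "
                    f"ages 0..{N_AGES - 1} exactly (got {ages.tolist()})"
                )
            cases = grp["cases"].to_numpy(float)
            denom = grp["denominator"].to_numpy(float)
            self._strata[(sex, race)] = {
                "cases": cases,
                "denominator": denom,
                "proportion": prevalence_from_counts(cases, denom),
            }
        df["proportion"] = df["cases"] / df["denominator"]
        self.data = df.reset_index(drop=True)

    @property
    def strata(self) -> list[tuple[str, str]]:
        return sorted(self._strata)

    def proportions(self, sex: str, race: str) -> np.ndarray:
        return self._strata[(sex, race)]["proportion"]

    def denominators(self, sex: str, race: str) -> np.ndarray:
        return self._strata[(sex, race)]["denominator"]

    def curve(self, sex: str, race: str) -> PrevalenceCurve:
        return PrevalenceCurve(proportions=self.proportions(sex, race), year=self.year)


# --- bootstrap ------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Point estimates with percentile-bootstrap 95% confidence intervals.

    ``table`` holds per (sex, race_ethnicity, age): rate_per_100k, ci_lower,
    ci_upper, identified.  ``standardized`` holds the directly
    age-standardized rate with its CI per stratum, standardization applied
    within each replicate before taking percentiles.  ``lower <= point <=
    upper`` is checked and violations are flagged in ``ci_flag``, not
    hidden.  ``draws`` keeps each stratum's replicate distribution of the
    standardized rate (per 100k) for downstream comparisons.
    """

    table: pd.DataFrame
    standardized: pd.DataFrame
    replicates: int
    seed: int | None
    weights: StandardPopulation
    draws: dict[tuple[str, str], np.ndarray]


def _resample_proportions(rng, phat, denom, how):
    if how == "binomial":
        return rng.binomial(denom.astype(int), phat) / denom
    if how == "normal":
        se = np.sqrt(phat * (1 - phat) / denom)
        return np.clip(rng.normal(phat, se), 0.0, 1.0 - 1e-12)
    raise ConfigError(f"unknown resampling model {how!r}")


def bootstrap_ci(
    cross0: PrevalenceCrossSection,
    cross1: PrevalenceCrossSection,
    estimator: str = "characteristics",
    replicates: int = DEFAULT_REPLICATES,
    seed: int | np.random.SeedSequence | None = None,
    weights: StandardPopulation | None = None,
    resample: str = "binomial",
    smoothness: float | str = "auto",
) -> BootstrapResult:
    """Percentile-bootstrap confidence intervals for the incidence estimates.

    For each replicate, case counts are redrawn per (stratum, age, survey)
    cell -- Binomial(denominator, p-hat) by default, a clipped normal
    approximation with ``resample='normal'`` -- proportions recomputed and
    the estimator re-run.  The 2.5th and 97.5th percentiles (linear
    interpolation convention) of the replicate distribution give the 95%
    interval; the point estimate comes from the unperturbed data.  Fully
    reproducible given ``seed``.  Replicates that degenerate (a resampled
    proportion reaching 1) are excluded and counted; more than 1% failures
    is a hard error.

    The characteristics estimator's noise whitening is fixed at the
    observed data, while its REML penalty weight is re-selected inside
    every replicate: the bootstrap resamples the complete estimation
    procedure, so the intervals carry smoothing-selection variability too.
    """
    if replicates < 2:
        raise ConfigError("at least 2 bootstrap replicates are required")
    if estimator not in _ESTIMATORS:
        raise ConfigError(
            f"unknown estimator {estimator!r}; choose from {sorted(_ESTIMATORS)}"
        )
    if cross0.strata != cross1.strata:
        raise ValidationError("the two cross-sections carry different strata")
    if weights is None:
        logger.warning(
            "no standard population supplied; falling back to UNIFORM age "
            "weights -- supply survey-appropriate weights (e.g. US 2000) for "
            "publishable standardized rates"
        )
        weights = StandardPopulation.uniform()
    gap = cross1.year - cross0.year
    gap = int(gap)
    A, _, identified = _constraint_system(gap)
    A_id = A[:, identified]
    use_chars = estimator == "characteristics"
    w = weights.weights
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(len(cross0.strata))

    rows, std_rows, draws = [], [], {}
    for (sex, race), child in zip(cross0.strata, children):
        rng = np.random.default_rng(child)
        phat0, phat1 = cross0.proportions(sex, race), cross1.proportions(sex, race)
        n0, n1 = cross0.denominators(sex, race), cross1.denominators(sex, race)
        c0, c1 = cross0.curve(sex, race), cross1.curve(sex, race)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if use_chars:
                point = estimate_incidence_characteristics(
                    c0, c1, smoothness=smoothness, denominators=(n0, n1)
                )
            else:
                point = _ESTIMATORS[estimator](c0, c1)

        p0s = _resample_proportions(rng, np.broadcast_to(phat0, (replicates, N_AGES)),
                                    np.broadcast_to(n0, (replicates, N_AGES)), resample)
        p1s = _resample_proportions(rng, np.broadcast_to(phat1, (replicates, N_AGES)),
                                    np.broadcast_to(n1, (replicates, N_AGES)), resample)
        ok = (p0s.max(axis=1) < 1.0) & (p1s.max(axis=1) < 1.0)
        n_failed = int(replicates - ok.sum())
        if n_failed > 0.01 * replicates:
            raise NumericalError(
                f"{n_failed}/{replicates} degenerate bootstrap replicates in "
                f"stratum ({sex}, {race})"
            )
        p0s, p1s = p0s[ok], p1s[ok]
        B = p0s.shape[0]
        rep_rates = np.empty((B, N_AGES))
        if use_chars:
            # whitening fixed at the observed data; the penalty weight is
            # re-selected inside every replicate so the interval reflects
            # smoothing-selection variability as well as sampling noise
            sd_b = _hazard_sd(phat0, phat1, n0, n1, gap)
            A_w = A_id / sd_b[:, None]
            auto = smoothness == "auto"
            reml = _reml_setup(A_w) if auto else None
            q0 = -np.log1p(-p0s)
            q1 = -np.log1p(-p1s)
            b_mat = np.empty((B, N_AGES - 1))
            for j, a1 in enumerate(range(1, N_AGES)):
                b_mat[:, j] = q1[:, a1] - (q0[:, a1 - gap] if a1 >= gap else 0.0)
            n_floored = int(np.sum(b_mat < -_RHS_TOL))
            np.clip(b_mat, 0.0, None, out=b_mat)
            b_mat /= sd_b
            for r in range(B):
                b_r = b_mat[r]
                w_r = (
                    _reml_weight(reml, A_w.T @ b_r, float(b_r @ b_r))
                    if auto
                    else point.smoothness
                )
                rep_rates[r] = _solve_nnls(A_w, b_r, identified, w_r)
            if n_floored:
                logger.debug(
                    "stratum (%s, %s): %d negative cohort constraints floored "
                    "across %d replicates", sex, race, n_floored, B,
                )
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for r in range(B):
                    rep_rates[r] = estimate_incidence_finite_difference(
                        PrevalenceCurve(p0s[r], cross0.year),
                        PrevalenceCurve(p1s[r], cross1.year),
                    ).rates
        lo, hi = np.percentile(rep_rates, [2.5, 97.5], axis=0, method="linear")
        std_draws = rep_rates @ w * PER_100K
        std_lo, std_hi = np.percentile(std_draws, [2.5, 97.5], method="linear")
        std_point = age_standardize(point.rates, weights) * PER_100K
        draws[(sex, race)] = std_draws
        for a in range(N_AGES):
            rows.append(
                dict(
                    sex=sex, race_ethnicity=race, age=a,
                    rate_per_100k=point.rates[a] * PER_100K,
                    ci_lower=lo[a] * PER_100K, ci_upper=hi[a] * PER_100K,
                    identified=bool(point.identified[a]),
                )
            )
        std_rows.append(
            dict(
                sex=sex, race_ethnicity=race, rate_per_100k=std_point,
                ci_lower=std_lo, ci_upper=std_hi, n_failed=n_failed,
                ci_flag=not (std_lo <= std_point + 1e-12 and std_point - 1e-12 <= std_hi),
            )
        )
    table = pd.DataFrame(rows)
    flag = ~(
        (table["ci_lower"] <= table["rate_per_100k"] + 1e-9)
        & (table["rate_per_100k"] <= table["ci_upper"] + 1e-9)
    )
    table["ci_flag"] = flag
    n_flag = int(flag.sum())
    if n_flag:
        logger.warning(
            "%d age cell(s) have the point estimate outside its percentile "
            "interval (flagged in ci_flag)", n_flag,
        )
    return BootstrapResult(
        table=table,
        standardized=pd.DataFrame(std_rows),
        replicates=replicates,
        seed=seed if isinstance(seed, int) or seed is None else None,
        weights=weights,
        draws=draws,
    )


# --- comparison with an observed incidence panel --------------------------


def observed_incidence_summary(panel: pd.DataFrame) -> pd.DataFrame:
    """Mean, min and max observed annual incidence per (stratum, age).

    The panel is tidy with columns year, sex, race_ethnicity, age,
    rate_per_100k; cells with no observation year are simply absent from
    the output (missing, not zero).
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValidationError(f"incidence panel missing column(s) {missing}")
    if (panel["rate_per_100k"] < 0).any():
        raise ValidationError("incidence panel contains negative rates")
    out = (
        panel.groupby(["sex", "race_ethnicity", "age"], sort=True)["rate_per_100k"]
        .agg(mean="mean", min="min", max="max")
        .reset_index()
    )
    return out


def summarize_against_observed(
    boot: BootstrapResult,
    panel: pd.DataFrame,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Per-stratum comparison of estimated vs observed age-standardized rates.

    The observed standardized rate is the standard-population average of the
    per-age mean annual rates.  Its uncertainty is bootstrapped
    nonparametrically by resampling calendar years with replacement within
    each (stratum, age) cell; the estimated rate's replicate draws come from
    the prevalence bootstrap, and the relative-error interval is taken over
    the paired ratio replicates (observed and estimated resampled jointly,
    independently of each other).
    """
    summary = observed_incidence_summary(panel)
    w = boot.weights.weights
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rows = []
    strata = sorted(boot.draws)
    for (sex, race), child in zip(strata, ss.spawn(len(strata))):
        cell = summary[(summary["sex"] == sex) & (summary["race_ethnicity"] == race)]
        cell = cell.set_index("age")
        if not set(AGES).issubset(cell.index):
            logger.warning(
                "observed panel incomplete for stratum (%s, %s); skipped in summary",
                sex, race,
            )
            continue
        yearly = (
            panel[(panel["sex"] == sex) & (panel["race_ethnicity"] == race)]
            .pivot_table(index="year", columns="age", values="rate_per_100k")
            .to_numpy()
        )
        n_years = yearly.shape[0]
        obs_std = float(cell.loc[AGES, "mean"].to_numpy() @ w)
        e_draws = boot.draws[(sex, race)]
        B = e_draws.shape[0]
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n_years, size=(B, n_years))
        o_draws = yearly[idx].mean(axis=1) @ w
        est = boot.standardized
        est = est[(est["sex"] == sex) & (est["race_ethnicity"] == race)].iloc[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            re_draws = 100.0 * (e_draws - o_draws) / o_draws
        o_lo, o_hi = np.percentile(o_draws, [2.5, 97.5], method="linear")
        re_lo, re_hi = np.percentile(re_draws, [2.5, 97.5], method="linear")
        rows.append(
            dict(
                sex=sex, race_ethnicity=race,
                observed=obs_std, observed_lo=o_lo, observed_hi=o_hi,
                estimated=est["rate_per_100k"],
                estimated_lo=est["ci_lower"], estimated_hi=est["ci_upper"],
                rel_err=relative_error(est["rate_per_100k"], obs_std)
                if obs_std != 0 else float("nan"),
                rel_err_lo=re_lo, rel_err_hi=re_hi,
            )
        )
    return pd.DataFrame(rows)


def age_bands(boot: BootstrapResult, panel: pd.DataFrame) -> pd.DataFrame:
    """Per-age observed min/max band beside the estimate and its CI."""
    summary = observed_incidence_summary(panel).rename(
        columns={"mean": "obs_mean", "min": "obs_min", "max": "obs_max"}
    )
    est = boot.table.rename(
        columns={"rate_per_100k": "estimated", "ci_lower": "est_lo", "ci_upper": "est_hi"}
    )[["sex", "race_ethnicity", "age", "estimated", "est_lo", "est_hi", "identified"]]
    return summary.merge(est, on=["sex", "race_ethnicity", "age"], how="outer")


# --------------------------------------------------------------------------
# 3. synthetic worlds: ground truth for validation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic ground-truth surveillance world.

    Emulates a youth-diabetes design: two prevalence cross-sections eight
    years apart, single-year ages 0-19, 2 sexes x 4 race/ethnicity groups,
    binomial case counts on denominators of order 10^4 per cell, and an
    annual observed-incidence panel in the intervening years.

    Incidence shape families (rates per 100,000 person-years):

    * ``type1-like`` -- unimodal Gaussian bump, ``peak_rate`` at
      ``peak_age`` (default 30 at age 10, width 4.5 y), the childhood-onset
      autoimmune pattern;
    * ``type2-like`` -- logistic rise, near zero before ``onset_age``
      (default 13 y) saturating at ``plateau_rate`` (default 15), the
      adolescent metabolic pattern.

    Per-stratum multipliers ``sex_scale`` x ``race_scale`` modulate the
    shared shape.  Mortality defaults to zero with rate ratio 1 (negligible
    and non-differential at these ages).  The total population, split
    equally over sexes and ages and 40/30/20/10 over NHW/Hispanic/NHB/Other,
    fixes the per-cell denominators.
    """

    family: str = "type1-like"
    peak_age: float = 10.0
    peak_rate: float = 30.0
    width: float = 4.5
    onset_age: float = 13.0
    plateau_rate: float = 15.0
    steepness: float = 1.5
    sex_scale: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.95, "male": 1.05}
    )
    race_scale: Mapping[str, float] = field(
        default_factory=lambda: {"NHW": 1.25, "NHB": 1.0, "Hispanic": 0.7, "Other": 0.55}
    )
    mortality: float = 0.0
    mortality_rate_ratio: float = 1.0
    total_population: int = 3_400_000
    race_shares: Mapping[str, float] = field(
        default_factory=lambda: {"NHW": 0.4, "Hispanic": 0.3, "NHB": 0.2, "Other": 0.1}
    )
    survey_years: tuple[int, int] = (2001, 2009)
    observation_years: tuple[int, ...] = tuple(range(2002, 2009))
    birth_prevalence: float = 0.0
    step: float = DEFAULT_STEP
    seed: int | None = None

    def __post_init__(self):
        if self.family not in ("type1-like", "type2-like"):
            raise ConfigError(f"unknown incidence shape family {self.family!r}")
        if self.survey_years[1] <= self.survey_years[0]:
            raise ConfigError("survey years must be distinct and increasing")
        for name in ("peak_rate", "plateau_rate", "mortality"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.mortality_rate_ratio <= 0:
            raise ConfigError("mortality_rate_ratio must be > 0")
        if self.total_population <= 0:
            raise ConfigError("total_population must be positive")
        if set(self.race_shares) != set(RACE_GROUPS) or set(self.race_scale) != set(
            RACE_GROUPS
        ):
            raise ConfigError(f"race maps must cover exactly {RACE_GROUPS}")
        if set(self.sex_scale) != set(SEXES):
            raise ConfigError(f"sex_scale must cover exactly {SEXES}")

    @property
    def strata(self) -> list[tuple[str, str]]:
        return [(s, r) for s in SEXES for r in RACE_GROUPS]

    def denominator(self, sex: str, race: str) -> int:
        """Population per (sex, race, single-year age) cell, identical across cells."""
        return int(round(self.total_population / (2 * N_AGES) * self.race_shares[race]))


def default_scenario(family: str = "type1-like", **overrides) -> ScenarioConfig:
    """Scenario with family-appropriate stratum multipliers.

    The type-2 pattern is more common in females and in NHB/Hispanic youth
    and rarest in NHW youth; the type-1 pattern is slightly more common in
    males and in NHW youth.
    """
    if family == "type2-like":
        base = dict(
            family=family,
            sex_scale={"female": 1.3, "male": 0.85},
            race_scale={"NHW": 0.45, "NHB": 1.6, "Hispanic": 1.25, "Other": 1.1},
        )
    else:
        base = dict(family=family)
    base.update(overrides)
    return ScenarioConfig(**base)


def true_incidence(config: ScenarioConfig, sex: str, race: str, age) -> np.ndarray | float:
    """Ground-truth incidence (per person-year) of the configured shape at ``age``."""
    a = np.asarray(age, dtype=float)
    if np.any(a < 0) or np.any(a >= N_AGES):
        raise DomainError(f"age {age} outside [0, {N_AGES})")
    if config.family == "type1-like":
        shape = config.peak_rate * np.exp(
            -((a - config.peak_age) ** 2) / (2.0 * config.width**2)
        )
    else:
        shape = config.plateau_rate / (
            1.0 + np.exp(-(a - config.onset_age) / config.steepness)
        )
    out = shape * config.sex_scale[sex] * config.race_scale[race] / PER_100K
    return float(out) if out.ndim == 0 else out


def incidence_grid(config: ScenarioConfig, sex: str, race: str) -> np.ndarray:
    """Piecewise-constant truth on single-year intervals: shape at interval midpoints."""
    return np.asarray(true_incidence(config, sex, race, AGES + 0.5))


def _stratum_surface(config: ScenarioConfig, sex: str, race: str) -> RateSurface:
    t0, t1 = config.survey_years
    return RateSurface.constant(
        incidence_grid(config, sex, race),
        general_mortality=config.mortality,
        mortality_rate_ratio=config.mortality_rate_ratio,
        time_window=(t0 - N_AGES, t1),
    )


def _steady_prevalence(config: ScenarioConfig, sex: str, race: str) -> np.ndarray:
    """True prevalence by age attained, burned in from each cohort's birth.

    With time-constant rates the surface is stationary: a cohort aged ``a``
    at either survey was born ``a`` years earlier with prevalence
    ``birth_prevalence`` and integrated forward ever since, so both
    cross-sections share this curve.
    """
    surface = _stratum_surface(config, sex, race)
    t0 = config.survey_years[0]
    seed_curve = PrevalenceCurve(
        proportions=np.full(N_AGES, config.birth_prevalence), year=t0 - (N_AGES - 1)
    )
    # after N_AGES-1 years, the cohort at final age a entered at age max(0, a-19),
    # i.e. every age 0..19 descends from a birth cohort -> fully burned in
    try:
        out = solve_forward(
            seed_curve, surface, t0,
            birth_prevalence=config.birth_prevalence, step=config.step,
        )
    except NumericalError as exc:
        raise ConfigError(
            f"configured rates are implausibly large for stratum ({sex}, {race}): {exc}"
        ) from exc
    if np.any(out.proportions >= 1 - 1e-6):
        raise ConfigError("configured rates drive prevalence to 1; implausibly large")
    return out.proportions


@dataclass
class World:
    """One realized synthetic world: the truth plus its noisy observations."""

    config: ScenarioConfig
    seed: int | None
    truth_incidence: pd.DataFrame      # sex, race_ethnicity, age, rate_per_100k
    truth_prevalence: pd.DataFrame     # sex, race_ethnicity, age, proportion
    cross_sections: tuple[PrevalenceCrossSection, PrevalenceCrossSection]
    panel: pd.DataFrame                # year, sex, race_ethnicity, age, rate_per_100k

    def standardized_truth(self, weights: StandardPopulation,
                           sex: str, race: str) -> float:
        t = self.truth_incidence
        cell = t[(t["sex"] == sex) & (t["race_ethnicity"] == race)].sort_values("age")
        return age_standardize(cell["rate_per_100k"].to_numpy(), weights)


def generate_world(
    config: ScenarioConfig,
    seed: int | np.random.SeedSequence | None = None,
    noise_free: bool = False,
) -> World:
    """Realize a synthetic surveillance dataset from a ground-truth scenario.

    True prevalence surfaces come from the forward PDE solver with burn-in
    from each cohort's birth year, so the first cross-section is internally
    consistent with the configured rates.  Case counts are
    Binomial(denominator, p) per (stratum, age, survey) cell; annual
    incident counts are Poisson(denominator x i) per observation year.
    With ``noise_free=True`` expected counts are used instead of draws
    (rounded binomial/Poisson means), for solver-tolerance checks.
    Bit-identical output for a fixed seed.
    """
    if seed is None:
        seed = config.seed
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss)
    t0, t1 = config.survey_years
    truth_i_rows, truth_p_rows, prev_rows, panel_rows = [], [], [], []
    for sex, race in config.strata:
        i_true = incidence_grid(config, sex, race)
        p_true = _steady_prevalence(config, sex, race)
        denom = config.denominator(sex, race)
        for a in AGES:
            truth_i_rows.append(
                dict(sex=sex, race_ethnicity=race, age=int(a),
                     rate_per_100k=i_true[a] * PER_100K)
            )
            truth_p_rows.append(
                dict(sex=sex, race_ethnicity=race, age=int(a), proportion=p_true[a])
            )
        for year in (t0, t1):
            if noise_free:
                cases = np.rint(denom * p_true).astype(int)
            else:
                cases = rng.binomial(denom, p_true)
            for a in AGES:
                prev_rows.append(
                    dict(year=year, sex=sex, race_ethnicity=race, age=int(a),
                         cases=int(cases[a]), denominator=denom)
                )
        for year in config.observation_years:
            mean_counts = denom * i_true
            counts = np.rint(mean_counts) if noise_free else rng.poisson(mean_counts)
            for a in AGES:
                panel_rows.append(
                    dict(year=year, sex=sex, race_ethnicity=race, age=int(a),
                         rate_per_100k=counts[a] / denom * PER_100K)
                )
    prev = pd.DataFrame(prev_rows)
    crosses = tuple(
        PrevalenceCrossSection(y, prev[prev["year"] == y].drop(columns="year"))
        for y in (t0, t1)
    )
    return World(
        config=config,
        seed=seed if isinstance(seed, int) else None,
        truth_incidence=pd.DataFrame(truth_i_rows),
        truth_prevalence=pd.DataFrame(truth_p_rows),
        cross_sections=crosses,  # type: ignore[arg-type]
        panel=pd.DataFrame(panel_rows),
    )


def recovery_experiment(
    configs: ScenarioConfig | Sequence[ScenarioConfig],
    n_worlds: int,
    estimator: str = "characteristics",
    replicates: int = 500,
    seed: int | None = None,
    weights: StandardPopulation | None = None,
    noise_free: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo validation: bias, RMSE and CI coverage of standardized rates.

    Simulates ``n_worlds`` independent worlds per scenario, estimates each
    stratum's age-standardized incidence with a ``replicates``-draw
    bootstrap, and reports per (family, sex, race_ethnicity): the mean
    signed relative error (%), the RMSE (per 100k) and the fraction of
    worlds whose 95% CI covers the true standardized rate.  With
    ``noise_free=True`` the exact proportions are fed straight to the
    estimator (no sampling, no bootstrap) to verify solver-tolerance
    recovery.
    """
    if n_worlds < 1:
        raise ConfigError("n_worlds must be >= 1")
    if isinstance(configs, ScenarioConfig):
        configs = [configs]
    if weights is None:
        weights = StandardPopulation.uniform()
    ss = np.random.SeedSequence(seed)
    acc: dict[tuple[str, str, str], dict[str, list]] = {}
    for config in configs:
        world_seeds = ss.spawn(n_worlds)
        for wseed in world_seeds:
            child_world, child_boot = wseed.spawn(2)
            world = generate_world(config, seed=child_world, noise_free=noise_free)
            if noise_free:
                # exact proportions straight into the estimator: isolates the
                # inversion from both sampling noise and count rounding
                tp = world.truth_prevalence.set_index(
                    ["sex", "race_ethnicity", "age"]
                ).sort_index()
                t0, t1 = config.survey_years
                for sex, race in config.strata:
                    truth = world.standardized_truth(weights, sex, race)
                    exact = tp.loc[(sex, race)].sort_index()["proportion"].to_numpy()
                    est = _ESTIMATORS[estimator](
                        PrevalenceCurve(exact, t0), PrevalenceCurve(exact, t1)
                    )
                    got = age_standardize(est.rates, weights) * PER_100K
                    rec = acc.setdefault(
                        (config.family, sex, race),
                        {"rel": [], "err": [], "cover": []},
                    )
                    rec["rel"].append(relative_error(got, truth))
                    rec["err"].append(got - truth)
                continue
            boot = bootstrap_ci(
                *world.cross_sections,
                estimator=estimator,
                replicates=replicates,
                seed=child_boot,
                weights=weights,
            )
            std = boot.standardized.set_index(["sex", "race_ethnicity"])
            for sex, race in config.strata:
                truth = world.standardized_truth(weights, sex, race)
                row = std.loc[(sex, race)]
                rec = acc.setdefault(
                    (config.family, sex, race), {"rel": [], "err": [], "cover": []}
                )
                rec["rel"].append(relative_error(row["rate_per_100k"], truth))
                rec["err"].append(row["rate_per_100k"] - truth)
                rec["cover"].append(row["ci_lower"] <= truth <= row["ci_upper"])
    rows = []
    for (family, sex, race), rec in sorted(acc.items()):
        rows.append(
            dict(
                family=family, sex=sex, race_ethnicity=race,
                n_worlds=len(rec["rel"]),
                mean_rel_err_pct=float(np.mean(rec["rel"])),
                rmse_per_100k=float(np.sqrt(np.mean(np.square(rec["err"])))),
                coverage=float(np.mean(rec["cover"])) if rec["cover"] else float("nan"),
            )
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# 4. file I/O: delimited text in, delimited text out
# --------------------------------------------------------------------------


def _read_csv(path, columns: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{what} file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} {path} missing column(s) {missing}")
    return df


def read_prevalence_table(path) -> dict[int, PrevalenceCrossSection]:
    """Read a prevalence table (one row per year/sex/race/age cell) by survey year."""
    df = _read_csv(path, PREVALENCE_COLUMNS, "prevalence table")
    bad_age = ~df["age"].between(0, N_AGES - 1)
    if bad_age.any():
        raise ValidationError(
            f"prevalence table {path}: ages outside 0..{N_AGES - 1} at rows "
            f"{df.index[bad_age].tolist()}"
        )
    return {
        int(year): PrevalenceCrossSection(int(year), grp.drop(columns="year"))
        for year, grp in df.groupby("year", sort=True)
    }


def write_prevalence_table(crosses: Iterable[PrevalenceCrossSection], path) -> None:
    frames = []
    for cs in crosses:
        df = cs.data[["sex", "race_ethnicity", "age", "cases", "denominator"]].copy()
        df.insert(0, "year", cs.year)
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False)


def read_incidence_panel(path) -> pd.DataFrame:
    df = _read_csv(path, PANEL_COLUMNS, "incidence panel")
    if (df["rate_per_100k"] < 0).any():
        raise ValidationError(f"incidence panel {path} contains negative rates")
    return df


def write_incidence_panel(panel: pd.DataFrame, path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, index=False)


def read_standard_population(path) -> StandardPopulation:
    df = _read_csv(path, WEIGHT_COLUMNS, "standard population").sort_values("age")
    if not np.array_equal(df["age"].to_numpy(), AGES):
        raise ValidationError(
            f"standard population {path} must cover ages 0..{N_AGES - 1} exactly"
        )
    return StandardPopulation(weights=df["weight"].to_numpy(float))


def write_standard_population(weights: StandardPopulation, path) -> None:
    pd.DataFrame({"age": weights.ages, "weight": weights.weights}).to_csv(
        path, index=False
    )


_SCENARIO_FIELDS = {f.name for f in fields(ScenarioConfig)}


def load_scenario(path) -> ScenarioConfig:
    """Load a scenario from a flat YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"scenario file {path} must be a flat key-value mapping")
    unknown = set(raw) - _SCENARIO_FIELDS
    if unknown:
        raise ConfigError(f"unknown scenario key(s) in {path}: {sorted(unknown)}")
    for key in ("survey_years", "observation_years"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ScenarioConfig(**raw)


def save_scenario(config: ScenarioConfig, path) -> None:
    data = {}
    for f in fields(ScenarioConfig):
        val = getattr(config, f.name)
        if isinstance(val, tuple):
            val = list(val)
        elif isinstance(val, Mapping):
            val = dict(val)
        data[f.name] = val
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class RunConfig:
    """Validated inputs for an estimation run; paths are checked up front."""

    prevalence_path: Path
    panel_path: Path | None = None
    weights_path: Path | None = None
    estimator: str = "characteristics"
    replicates: int = DEFAULT_REPLICATES
    seed: int | None = None
    smoothness: float | str = "auto"
    out_dir: Path = Path(".")

    def __post_init__(self):
        self.prevalence_path = Path(self.prevalence_path)
        if not self.prevalence_path.exists():
            raise ValidationError(f"prevalence table not found: {self.prevalence_path}")
        for name in ("panel_path", "weights_path"):
            val = getattr(self, name)
            if val is not None:
                val = Path(val)
                if not val.exists():
                    raise ValidationError(f"{name.replace('_path', '')} file not found: {val}")
                setattr(self, name, val)
        if self.estimator not in _ESTIMATORS:
            raise ConfigError(f"unknown estimator {self.estimator!r}")
        if self.replicates < 2:
            raise ConfigError("replicates must be >= 2")
        self.out_dir = Path(self.out_dir)


def run_estimate(config: RunConfig) -> dict[str, Path]:
    """Full estimation pipeline: read, validate, estimate, bootstrap, write.

    Writes estimates.csv and standardized.csv always; summary.csv (the
    stratified observed-vs-estimated comparison) and age_bands.csv (per-age
    observed min/max beside the estimate) when an observed incidence panel
    is supplied.  Returns the mapping of artifact names to paths.
    """
    crosses = read_prevalence_table(config.prevalence_path)
    if len(crosses) != 2:
        raise ValidationError(
            f"prevalence table must hold exactly two survey years, got "
            f"{sorted(crosses)}"
        )
    (y0, cross0), (y1, cross1) = sorted(crosses.items())
    weights = (
        read_standard_population(config.weights_path)
        if config.weights_path is not None
        else None
    )
    ss = np.random.SeedSequence(config.seed)
    boot_ss, cmp_ss = ss.spawn(2)
    boot = bootstrap_ci(
        cross0,
        cross1,
        estimator=config.estimator,
        replicates=config.replicates,
        seed=boot_ss,
        weights=weights,
        smoothness=config.smoothness,
    )
    # cross-check the two inversion methods; per-age values differ by design
    # (window smoothing vs exact deconvolution), so the aggregate level over
    # the jointly identified ages is what is compared
    other = (
        "finite-difference" if config.estimator == "characteristics" else "characteristics"
    )
    for sex, race in cross0.strata:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alt = _ESTIMATORS[other](cross0.curve(sex, race), cross1.curve(sex, race))
        main = boot.table[
            (boot.table["sex"] == sex) & (boot.table["race_ethnicity"] == race)
        ].sort_values("age")["rate_per_100k"].to_numpy() / PER_100K
        both = alt.identified & (main >= 0)
        if both.any() and main[both].mean() > 0:
            rel = alt.rates[both].mean() / main[both].mean() - 1.0
            if abs(rel) > 0.10:
                logger.warning(
                    "stratum (%s, %s): %s cross-check differs from the %s "
                    "estimate by %+.0f%% in aggregate level over identified "
                    "ages; inspect the input prevalence",
                    sex, race, other, config.estimator, 100 * rel,
                )
    config.out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    est_path = config.out_dir / "estimates.csv"
    boot.table.to_csv(est_path, index=False, float_format="%.10g")
    outputs["estimates"] = est_path
    std_path = config.out_dir / "standardized.csv"
    boot.standardized.to_csv(std_path, index=False, float_format="%.10g")
    outputs["standardized"] = std_path
    if config.panel_path is not None:
        panel = read_incidence_panel(config.panel_path)
        summary = summarize_against_observed(boot, panel, seed=cmp_ss)
        sum_path = config.out_dir / "summary.csv"
        summary.to_csv(sum_path, index=False, float_format="%.10g")
        outputs["summary"] = sum_path
        bands = age_bands(boot, panel)
        bands_path = config.out_dir / "age_bands.csv"
        bands.to_csv(bands_path, index=False, float_format="%.10g")
        outputs["age_bands"] = bands_path
    return outputs
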