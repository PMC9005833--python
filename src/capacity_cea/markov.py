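"""Three-state cohort Markov engine for oncology state-transition models.

The model tracks a cohort of patients through ``progression_free``,
``progressive_disease`` and ``dead`` states on a fixed cycle grid, accruing
discounted costs and quality-adjusted life-years (QALYs).  Survival in each
arm is parameterized by median progression-free survival (PFS) and median
overall survival (OS) under an exponential (constant-hazard) assumption:
the hazard corresponding to a median ``m`` is ``ln 2 / m``.

Transition construction
-----------------------
* The death hazard out of *both* alive states is the OS hazard, so the
  cohort's overall survival curve is exactly exponential with the stated
  OS median.
* The progression hazard is the PFS-event hazard minus the OS hazard
  (floored at zero), so time-to-first-event (progression or death) is
  exponential with the stated PFS median.
* Per-cycle probabilities are the exact continuous-time embedding (the
  matrix exponential of the hazard generator, in closed form), so the
  cohort at the cycle grid coincides with the continuous-time process:
  survival at the OS median is exactly one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

DAYS_PER_YEAR = 365.0
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0

#: Ordered health states; ``dead`` is absorbing.
STATES = ("progression_free", "progressive_disease", "dead")
PF, PD, DEAD = 0, 1, 2


class InvalidParameterError(ValueError):
    """A model parameter is outside its admissible range."""


@dataclass(frozen=True)
class ArmProfile:
    """One treatment arm: survival medians, state utilities and cycle costs.

    Parameters
    ----------
    name:
        Label for the arm (e.g. ``"crizotinib"``).
    pfs_median, os_median:
        Median progression-free and overall survival, in months.
    utility_pf, utility_pd:
        Health-state utilities (QALY weight per year alive) for the
        progression-free and progressive-disease states, in [0, 1].
    cost_pf_cycle, cost_pd_cycle:
        Cost accrued per full model cycle spent in each alive state (GBP).
    one_off_cost:
        Cost incurred once at model entry (GBP).
    """

    name: str
    pfs_median: float
    os_median: float
    utility_pf: float
    utility_pd: float
    cost_pf_cycle: float
    cost_pd_cycle: float
    one_off_cost: float = 0.0

    def __post_init__(self) -> None:
        if not (self.pfs_median > 0 and self.os_median > 0):
            raise InvalidParameterError(
                f"survival medians must be positive, got PFS={self.pfs_median}, "
                f"OS={self.os_median}"
            )
        if self.pfs_median > self.os_median:
            raise InvalidParameterError(
                f"PFS median ({self.pfs_median}) cannot exceed OS median "
                f"({self.os_median}): progression cannot follow death"
            )
        for field in ("utility_pf", "utility_pd"):
            u = getattr(self, field)
            if not (0.0 <= u <= 1.0):
                raise InvalidParameterError(f"{field}={u} outside [0, 1]")
        for field in ("cost_pf_cycle", "cost_pd_cycle", "one_off_cost"):
            c = getattr(self, field)
            if c < 0:
                raise InvalidParameterError(f"{field}={c} must be non-negative")


@dataclass(frozen=True)
class DiscountSpec:
    """Discounting and time-grid settings.

    ``annual_rate`` is applied to both costs and QALYs, compounded per cycle
    as ``(1 + rate) ** (-t_years)`` with a 365-day year.  The horizon is cut
    into ``cycle_length``-day cycles; a final partial cycle is truncated
    (accrual weighted by the fraction of the cycle inside the horizon).
    """

    annual_rate: float = 0.035
    cycle_length: float = 30.0  # days
    horizon_years: float = 15.0
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise InvalidParameterError("annual_rate must be >= 0")
        if self.cycle_length <= 0 or self.horizon_years <= 0:
            raise InvalidParameterError("cycle_length and horizon must be positive")

    @property
    def horizon_days(self) -> float:
        return self.horizon_years * DAYS_PER_YEAR

    @property
    def n_cycles(self) -> int:
        """Number of cycles covering the horizon (last one possibly partial)."""
        return math.ceil(round(self.horizon_days / self.cycle_length, 9))

    def discount_factor(self, t_years: float | np.ndarray) -> float | np.ndarray:
        return (1.0 + self.annual_rate) ** (-np.asarray(t_years, dtype=float))


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy over time plus per-cycle accruals.

    ``occupancy`` has shape ``(n_cycles + 1, 3)``: row ``k`` is the state
    distribution at the start of cycle ``k`` (row ``n_cycles`` is the end of
    the horizon).  ``cycle_costs`` and ``cycle_qalys`` are the discounted
    accruals attributed to each cycle.
    """

    occupancy: np.ndarray
    time_years: np.ndarray
    cycle_costs: np.ndarray
    cycle_qalys: np.ndarray

    def to_csv(self, path) -> None:
        """Write the trace as CSV (cycle, time_years, occupancies, accruals)."""
        import pandas as pd

        n = len(self.cycle_costs)
        frame = pd.DataFrame(
            {
                "cycle": np.arange(n),
                "time_years": self.time_years[:n],
                "progression_free": self.occupancy[:n, PF],
                "progressive_disease": self.occupancy[:n, PD],
                "dead": self.occupancy[:n, DEAD],
                "cycle_cost": self.cycle_costs,
                "cycle_qalys": self.cycle_qalys,
            }
        )
        frame.to_csv(path, index=False, encoding="utf-8")


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted per-patient totals for one arm, plus the cohort trace."""

    discounted_cost: float
    discounted_qalys: float
    trace: CohortTrace


def _hazards_per_day(arm: ArmProfile) -> tuple[float, float, float]:
    """Cause-specific daily hazards (progression, death-from-PF, death-from-PD)."""
    h_pfs = math.log(2.0) / (arm.pfs_median * DAYS_PER_MONTH)
    h_os = math.log(2.0) / (arm.os_median * DAYS_PER_MONTH)
    h_prog = max(h_pfs - h_os, 0.0)
    return h_prog, h_os, h_os


def build_arm_transitions(arm: ArmProfile, cycle_length: float = 30.0) -> np.ndarray:
    """Per-cycle 3x3 transition matrix for an arm under exponential survival.

    Rows/columns are ordered (progression_free, progressive_disease, dead);
    each row sums to one and the dead row is absorbing.  Entries are the
    closed-form matrix exponential of the constant-hazard generator over
    one cycle, so multi-step transitions (progress then die within a
    cycle) are accounted for exactly.
    """
    if cycle_length <= 0:
        raise InvalidParameterError("cycle_length must be positive")
    h_prog, h_death_pf, h_death_pd = _hazards_per_day(arm)

    c = cycle_length
    h_exit_pf = h_prog + h_death_pf  # = PFS-event hazard
    p_stay_pf = math.exp(-h_exit_pf * c)
    if h_prog == 0.0:
        p_pf_pd = 0.0
    elif abs(h_exit_pf - h_death_pd) > 1e-15:
        # exp(Qc) off-diagonal for distinct exit rates
        p_pf_pd = (
            h_prog
            * (math.exp(-h_death_pd * c) - math.exp(-h_exit_pf * c))
            / (h_exit_pf - h_death_pd)
        )
    else:  # equal-rate limit
        p_pf_pd = h_prog * c * math.exp(-h_exit_pf * c)
    p_pf_dead = 1.0 - p_stay_pf - p_pf_pd
    p_pd_dead = -math.expm1(-h_death_pd * c)

    matrix = np.array(
        [
            [p_stay_pf, p_pf_pd, p_pf_dead],
            [0.0, 1.0 - p_pd_dead, p_pd_dead],
            [0.0, 0.0, 1.0],
        ]
    )
    return matrix


def validate_transition_matrix(matrix: np.ndarray) -> None:
    """Raise if ``matrix`` is not a valid 3-state transition matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise InvalidParameterError(f"transition matrix must be 3x3, got {m.shape}")
    if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
        raise InvalidParameterError("transition probabilities outside [0, 1]")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12, rtol=0.0):
        raise InvalidParameterError("transition matrix rows must sum to 1")
    if not np.allclose(m[DEAD], [0.0, 0.0, 1.0], atol=1e-12):
        raise InvalidParameterError("dead state must be absorbing")


def run_cohort(
    matrix: np.ndarray, arm: ArmProfile, discount: DiscountSpec
) -> ArmOutcome:
    """Propagate a cohort (starting 100% progression-free) through the horizon.

    QALYs accrue as occupancy x utility x cycle-length-in-years x discount
    factor; costs accrue as occupancy x per-cycle cost x discount factor,
    scaled by the in-horizon fraction of a truncated final cycle.  By default
    occupancy at the start of each cycle is used; with
    ``discount.half_cycle_correction`` the start/end average is used instead.
    """
    validate_transition_matrix(matrix)
    m = np.asarray(matrix, dtype=float)
    n_cycles = discount.n_cycles
    cl = discount.cycle_length

    occupancy = np.zeros((n_cycles + 1, 3))
    occupancy[0] = (1.0, 0.0, 0.0)
    for k in range(n_cycles):
        occupancy[k + 1] = occupancy[k] @ m

    starts_days = np.arange(n_cycles) * cl
    time_years = np.arange(n_cycles + 1) * cl / DAYS_PER_YEAR
    # fraction of each cycle that lies inside the horizon (last may be partial)
    frac = np.clip((discount.horizon_days - starts_days) / cl, 0.0, 1.0)
    dfactors = discount.discount_factor(starts_days / DAYS_PER_YEAR)

    occ = occupancy[:-1]
    if discount.half_cycle_correction:
        occ = 0.5 * (occupancy[:-1] + occupancy[1:])

    utilities = np.array([arm.utility_pf, arm.utility_pd, 0.0])
    cycle_costs_vec = np.array([arm.cost_pf_cycle, arm.cost_pd_cycle, 0.0])

    cycle_qalys = (occ @ utilities) * (cl / DAYS_PER_YEAR) * frac * dfactors
    cycle_costs = (occ @ cycle_costs_vec) * frac * dfactors

    trace = CohortTrace(
        occupancy=occupancy,
        time_years=time_years,
        cycle_costs=cycle_costs,
        cycle_qalys=cycle_qalys,
    )
    return ArmOutcome(
        discounted_cost=arm.one_off_cost + float(cycle_costs.sum()),
        discounted_qalys=float(cycle_qalys.sum()),
        trace=trace,
    )


def evaluate_arm(arm: ArmProfile, discount: DiscountSpec) -> ArmOutcome:
    """Convenience: build transitions and run the cohort in one call."""
    return run_cohort(build_arm_transitions(arm, discount.cycle_length), arm, discount)


def apply_survival_degradation(
    arm: ArmProfile, m_pfs: float, m_os: float
) -> ArmProfile:
    """Scale an arm's survival medians by ratios in (0, 1].

    A ratio ``m`` multiplies the median (equivalently divides the
    exponential hazard by ``m``); ``m = 1`` is the identity.  Used to model
    poorer-quality testing degrading treatment benefit.
    """
    for label, m in (("m_pfs", m_pfs), ("m_os", m_os)):
        if not (0.0 < m <= 1.0):
            raise InvalidParameterError(f"{label}={m} must lie in (0, 1]")
    if m_pfs == 1.0 and m_os == 1.0:
        return arm
    return replace(
        arm,
        pfs_median=min(arm.pfs_median * m_pfs, arm.os_median * m_os),
        os_median=arm.os_median * m_os,
    )
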