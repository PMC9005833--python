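"""Cost-effectiveness and value-of-implementation calculus.

Core quantities at a willingness-to-pay threshold ``lambda`` (GBP/QALY):

* ICER = ``delta_cost / delta_qalys`` (incremental cost-effectiveness ratio);
* per-patient net monetary benefit NMB = ``lambda * delta_qalys - delta_cost``;
* total annual NMB = ``access * n * NMB`` for an annual eligible population
  of ``n`` tested patients of whom a proportion ``access`` are reached;
* value of perfect implementation
  ``n * NMB_unconstrained - access * n * NMB_constrained``, the annual NMB
  forgone because of the capacity constraints (the unconstrained benchmark
  uses full access, fully resourced laboratories, and whichever pure
  localization policy maximizes per-patient NMB).

Constraints are classified by their footprint: *access-limiting* ones
shrink the treated population but leave the ICER untouched;
*quality-limiting* ones move per-patient costs or QALYs and hence the ICER.
"""

from __future__ import annotations

from dataclasses import dataclass

from .markov import ArmProfile, DiscountSpec, InvalidParameterError
from .pathway import (
    ConstraintScenario,
    PathwayOutcome,
    TestingParameters,
    evaluate_pathway,
    resolve_pathology_beta,
)


class UndefinedICERError(ZeroDivisionError):
    """Incremental QALYs are zero; the ICER is undefined."""


@dataclass(frozen=True)
class EconOutcome:
    """Per-patient incremental cost (GBP) and incremental QALYs."""

    delta_cost: float
    delta_qalys: float

    @classmethod
    def from_pathway(cls, outcome: PathwayOutcome) -> "EconOutcome":
        return cls(outcome.delta_cost, outcome.delta_qalys)


@dataclass(frozen=True)
class PopulationContext:
    """Annual eligible tested population and willingness-to-pay threshold."""

    n: float  # patients/year eligible for testing (cohort expectation)
    threshold_lambda: float = 50_000.0  # GBP per QALY

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise InvalidParameterError("population size n must be positive")
        if self.threshold_lambda <= 0:
            raise InvalidParameterError("threshold_lambda must be positive")


@dataclass(frozen=True)
class ScenarioResult:
    """Summary economics for one constraint scenario."""

    name: str
    icer: float  # GBP/QALY
    icer_quadrant: str  # cost-effectiveness plane quadrant of (dQ, dC)
    nmb_per_patient: float  # GBP
    total_nmb: float  # GBP/year
    vopi: float  # GBP/year NMB shortfall vs perfect implementation
    qaly_gain: float  # QALYs/year (= total_nmb / lambda)
    qaly_shortfall: float  # QALYs/year (= vopi / lambda)
    shortfall_fraction: float  # vopi / (n * NMB_unconstrained)
    access_proportion: float
    delta_cost: float
    delta_qalys: float


def icer(outcome: EconOutcome) -> float:
    """Incremental cost per QALY; raises if incremental QALYs are zero."""
    if outcome.delta_qalys == 0:
        raise UndefinedICERError("delta_qalys is zero; ICER undefined")
    return outcome.delta_cost / outcome.delta_qalys


def icer_quadrant(outcome: EconOutcome) -> str:
    """Cost-effectiveness plane quadrant label for (delta_qalys, delta_cost)."""
    dq, dc = outcome.delta_qalys, outcome.delta_cost
    if dq > 0 and dc >= 0:
        return "NE (more effective, more costly)"
    if dq > 0 and dc < 0:
        return "SE (dominant)"
    if dq < 0 and dc >= 0:
        return "NW (dominated)"
    if dq < 0 and dc < 0:
        return "SW (less effective, less costly)"
    return "on the cost axis (no QALY difference)"


def nmb_per_patient(outcome: EconOutcome, threshold_lambda: float) -> float:
    """Net monetary benefit per patient at the stated threshold."""
    if threshold_lambda <= 0:
        raise InvalidParameterError("threshold_lambda must be positive")
    return threshold_lambda * outcome.delta_qalys - outcome.delta_cost


def total_nmb(outcome: EconOutcome, pop: PopulationContext, access: float) -> float:
    """Annual population NMB: access x n x per-patient NMB."""
    if not (0.0 <= access <= 1.0):
        raise InvalidParameterError("access must lie in [0, 1]")
    return access * pop.n * nmb_per_patient(outcome, pop.threshold_lambda)


def value_of_perfect_implementation(
    unconstrained: EconOutcome,
    constrained: EconOutcome,
    pop: PopulationContext,
    access: float,
) -> float:
    """Annual NMB forgone due to the constraints.

    ``n * NMB_unconstrained - access * n * NMB_constrained``: the first term
    is the population NMB with every patient reached at unconstrained
    quality, the second is what the constrained system actually delivers.
    """
    return pop.n * nmb_per_patient(
        unconstrained, pop.threshold_lambda
    ) - total_nmb(constrained, pop, access)


def unconstrained_benchmark(
    test: TestingParameters,
    crizotinib: ArmProfile,
    docetaxel: ArmProfile,
    discount: DiscountSpec | None = None,
    threshold: float = 50_000.0,
) -> EconOutcome:
    """Per-patient outcome of the no-constraint benchmark.

    Full access and fully resourced laboratories, with the localization
    endpoint (all-central vs all-local) chosen to maximize per-patient NMB;
    resolved computationally each run rather than assuming centralization.
    """
    best = None
    for beta in (0.0, 1.0):
        out = evaluate_pathway(
            ConstraintScenario(name="benchmark", alpha=1.0, beta=beta, gamma=1),
            test,
            crizotinib,
            docetaxel,
            discount,
        )
        econ = EconOutcome.from_pathway(out)
        if best is None or nmb_per_patient(econ, threshold) > nmb_per_patient(
            best, threshold
        ):
            best = econ
    return best


def evaluate_scenario(
    scenario: ConstraintScenario,
    test: TestingParameters,
    crizotinib: ArmProfile,
    docetaxel: ArmProfile,
    pop: PopulationContext,
    discount: DiscountSpec | None = None,
    benchmark: EconOutcome | None = None,
) -> ScenarioResult:
    """Full economic summary of one scenario against the perfect-implementation
    benchmark (computed on the fly unless supplied)."""
    if benchmark is None:
        benchmark = unconstrained_benchmark(
            test, crizotinib, docetaxel, discount, pop.threshold_lambda
        )
    out = evaluate_pathway(scenario, test, crizotinib, docetaxel, discount)
    econ = EconOutcome.from_pathway(out)

    lam = pop.threshold_lambda
    tot = total_nmb(econ, pop, out.access_proportion)
    vopi = value_of_perfect_implementation(benchmark, econ, pop, out.access_proportion)
    perfect_total = pop.n * nmb_per_patient(benchmark, lam)
    return ScenarioResult(
        name=scenario.name,
        icer=icer(econ),
        icer_quadrant=icer_quadrant(econ),
        nmb_per_patient=nmb_per_patient(econ, lam),
        total_nmb=tot,
        vopi=vopi,
        qaly_gain=tot / lam,
        qaly_shortfall=vopi / lam,
        shortfall_fraction=vopi / perfect_total if perfect_total != 0 else float("nan"),
        access_proportion=out.access_proportion,
        delta_cost=econ.delta_cost,
        delta_qalys=econ.delta_qalys,
    )


def classify_constraint(
    baseline: ScenarioResult, constrained: ScenarioResult, tol: float = 0.5
) -> str:
    """Label a constraint's footprint on the economics.

    ``access_limiting``: ICER unchanged (within ``tol`` GBP/QALY) but total
    NMB reduced; ``quality_limiting``: ICER moved at full access; ``mixed``:
    ICER moved *and* access reduced; ``none``: neither.
    """
    icer_moved = abs(constrained.icer - baseline.icer) > tol
    nmb_reduced = constrained.total_nmb < baseline.total_nmb - 1e-9
    access_reduced = constrained.access_proportion < baseline.access_proportion - 1e-12
    if icer_moved and access_reduced:
        return "mixed"
    if icer_moved:
        return "quality_limiting"
    if nmb_reduced:
        return "access_limiting"
    return "none"
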