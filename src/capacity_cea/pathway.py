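"""Test-and-treat decision tree with health-system capacity constraints.

The pathway screens tested patients for *ALK* rearrangement with
immunohistochemistry (IHC), confirms IHC-positives with fluorescence in
situ hybridization (FISH, treated as a perfect confirmatory test), and
treats confirmed positives with crizotinib; everyone else receives
docetaxel.  The comparator strategy is no testing and universal docetaxel.

Three capacity constraints enter as branch parameters:

``alpha``
    Proportion of patients with access to commissioned testing (awareness
    of commissioning arrangements).  The ``1 - alpha`` mass is never tested,
    receives docetaxel under both strategies and contributes no incremental
    cost or benefit; outcomes here are therefore *per tested patient* and
    ``alpha`` is carried as the access proportion for population totals.
``beta``
    Proportion of tests processed in localized (in-house) rather than
    centralized laboratories.  Localized IHC costs more (a fixed percentage
    uplift on the centralized price).
``gamma``
    Pathology-laboratory staffing flag.  ``gamma = 1`` means laboratories
    are fully resourced and the localization/centralization mix has no
    quality or turnaround consequences.  ``gamma = 0`` activates them:
    centralized testing incurs a treatment-start delay (an extra
    oncologist appointment cost and a short anxiety disutility) and
    localized testing degrades crizotinib survival via median ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .markov import (
    ArmProfile,
    DiscountSpec,
    InvalidParameterError,
    DAYS_PER_YEAR,
    apply_survival_degradation,
    evaluate_arm,
)


@dataclass(frozen=True)
class TestingParameters:
    """Test costs, accuracy and delay penalties for the screening pathway."""

    ihc_cost_central: float = 25.0  # GBP per IHC test in a centralized lab
    ihc_local_uplift: float = 0.17  # localized labs cost 17% more
    fish_cost: float = 150.0  # GBP per confirmatory FISH test
    ihc_sensitivity: float = 0.95
    ihc_specificity: float = 0.98
    alk_prevalence: float = 0.04  # ALK-rearrangement prevalence among tested
    delay_cost: float = 101.0  # extra oncologist appointment (GBP)
    delay_disutility: float = 0.03  # utility decrement while waiting
    delay_days: float = 9.0  # duration of the wait

    def __post_init__(self) -> None:
        for field in ("ihc_sensitivity", "ihc_specificity", "alk_prevalence"):
            v = getattr(self, field)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{field}={v} outside [0, 1]")
        for field in (
            "ihc_cost_central",
            "ihc_local_uplift",
            "fish_cost",
            "delay_cost",
            "delay_disutility",
            "delay_days",
        ):
            v = getattr(self, field)
            if v < 0:
                raise InvalidParameterError(f"{field}={v} must be non-negative")

    @property
    def ihc_cost_local(self) -> float:
        """Localized IHC price: centralized price plus the percentage uplift."""
        return self.ihc_cost_central * (1.0 + self.ihc_local_uplift)

    @property
    def delay_qaly_loss(self) -> float:
        """QALY decrement of the treatment-start delay (365-day year)."""
        return self.delay_disutility * self.delay_days / DAYS_PER_YEAR


@dataclass(frozen=True)
class ConstraintScenario:
    """One (alpha, beta, gamma) configuration plus quality-degradation ratios.

    ``m_pfs`` and ``m_os`` are the localized-to-centralized median survival
    ratios applied to the crizotinib arm when ``gamma = 0``; with
    ``gamma = 1`` they are inert.
    """

    name: str
    alpha: float = 1.0
    beta: float = 0.0
    gamma: int = 1
    m_pfs: float = 0.822
    m_os: float = 0.775

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise InvalidParameterError("alpha and beta must lie in [0, 1]")
        if self.gamma not in (0, 1):
            raise InvalidParameterError("gamma must be 0 or 1")
        for label, m in (("m_pfs", self.m_pfs), ("m_os", self.m_os)):
            if not (0.0 < m <= 1.0):
                raise InvalidParameterError(f"{label}={m} must lie in (0, 1]")


@dataclass(frozen=True)
class PathwayOutcome:
    """Per-tested-patient incremental outcome of test-treat vs no-test."""

    delta_cost: float  # GBP per tested patient
    delta_qalys: float  # QALYs per tested patient
    access_proportion: float  # alpha: fraction of the population tested
    treated_fraction: float  # fraction of tested patients on crizotinib


def pathway_weights(
    scenario: ConstraintScenario, test: TestingParameters
) -> dict[tuple[str, str, str], float]:
    """Terminal branch probabilities among tested patients.

    Keys are ``(site, alk_status, ihc_result)`` with site in
    ``{"localized", "centralized"}``, *ALK* status in ``{"positive",
    "negative"}`` and IHC result in ``{"positive", "negative"}``.  The
    eight weights form a probability distribution.
    """
    theta = test.alk_prevalence
    sens, spec = test.ihc_sensitivity, test.ihc_specificity
    weights: dict[tuple[str, str, str], float] = {}
    for site, p_site in (("localized", scenario.beta), ("centralized", 1 - scenario.beta)):
        weights[(site, "positive", "positive")] = p_site * theta * sens
        weights[(site, "positive", "negative")] = p_site * theta * (1 - sens)
        weights[(site, "negative", "positive")] = p_site * (1 - theta) * (1 - spec)
        weights[(site, "negative", "negative")] = p_site * (1 - theta) * spec
    return weights


def evaluate_pathway(
    scenario: ConstraintScenario,
    test: TestingParameters,
    crizotinib: ArmProfile,
    docetaxel: ArmProfile,
    discount: DiscountSpec | None = None,
    delay_applies_to: str = "treated",
) -> PathwayOutcome:
    """Incremental cost and QALYs per tested patient for one scenario.

    Every tested patient pays for IHC (centralized or uplifted localized
    price by branch); IHC-positives additionally pay for FISH.  Confirmed
    true positives receive crizotinib, everyone else docetaxel, so against
    the universal-docetaxel comparator only test costs and the treated
    fraction's arm contrast are incremental.

    With ``gamma = 0``, centrally tested patients who proceed to crizotinib
    incur the delay cost and QALY loss (set ``delay_applies_to="all_tested"``
    to charge every centrally tested patient instead), and locally tested
    crizotinib recipients use the survival-degraded arm.
    """
    if delay_applies_to not in ("treated", "all_tested"):
        raise InvalidParameterError(
            f"delay_applies_to must be 'treated' or 'all_tested', got {delay_applies_to!r}"
        )
    if discount is None:
        discount = DiscountSpec()

    doc = evaluate_arm(docetaxel, discount)
    criz = evaluate_arm(crizotinib, discount)
    if criz.discounted_qalys < doc.discounted_qalys:
        warnings.warn(
            "crizotinib arm yields fewer QALYs than docetaxel arm; "
            "check the arm profiles",
            stacklevel=2,
        )

    theta = test.alk_prevalence
    treated = theta * test.ihc_sensitivity  # confirmed true positives
    p_ihc_pos = treated + (1 - theta) * (1 - test.ihc_specificity)
    beta = scenario.beta

    # Test costs apply under every scenario.
    delta_cost = (
        beta * test.ihc_cost_local
        + (1 - beta) * test.ihc_cost_central
        + p_ihc_pos * test.fish_cost
    )

    d_arm_cost = criz.discounted_cost - doc.discounted_cost
    d_arm_qalys = criz.discounted_qalys - doc.discounted_qalys

    if scenario.gamma == 1:
        delta_cost += treated * d_arm_cost
        delta_qalys = treated * d_arm_qalys
    else:
        degraded = evaluate_arm(
            apply_survival_degradation(crizotinib, scenario.m_pfs, scenario.m_os),
            discount,
        )
        d_deg_cost = degraded.discounted_cost - doc.discounted_cost
        d_deg_qalys = degraded.discounted_qalys - doc.discounted_qalys

        delta_cost += (1 - beta) * treated * d_arm_cost + beta * treated * d_deg_cost
        delta_qalys = (1 - beta) * treated * d_arm_qalys + beta * treated * d_deg_qalys

        if delay_applies_to == "treated":
            delayed = (1 - beta) * treated
        else:
            delayed = 1 - beta
        delta_cost += delayed * test.delay_cost
        delta_qalys -= delayed * test.delay_qaly_loss

    return PathwayOutcome(
        delta_cost=float(delta_cost),
        delta_qalys=float(delta_qalys),
        access_proportion=scenario.alpha,
        treated_fraction=float(treated),
    )


#: Base-case constraint values: 23% awareness, 11% localized testing.
AWARENESS_BASE = 0.23
LOCALIZED_BASE = 0.11


def resolve_pathology_beta(
    test: TestingParameters,
    crizotinib: ArmProfile,
    docetaxel: ArmProfile,
    discount: DiscountSpec | None = None,
    threshold: float = 50_000.0,
) -> int:
    """Pick the localization endpoint (fully local vs fully central) that
    maximizes per-patient net monetary benefit when pathology capacity is
    constrained (``gamma = 0``).

    The under-resourced scenario is defined relative to the *better* of the
    two pure policies; which one is better is an empirical question answered
    by evaluating both.
    """
    nmb = {}
    for beta in (0, 1):
        out = evaluate_pathway(
            ConstraintScenario(name=f"pathology-beta{beta}", beta=float(beta), gamma=0),
            test,
            crizotinib,
            docetaxel,
            discount,
        )
        nmb[beta] = threshold * out.delta_qalys - out.delta_cost
    return 0 if nmb[0] >= nmb[1] else 1


def scenario_presets(
    test: TestingParameters | None = None,
    crizotinib: ArmProfile | None = None,
    docetaxel: ArmProfile | None = None,
    discount: DiscountSpec | None = None,
    threshold: float = 50_000.0,
) -> list[ConstraintScenario]:
    """The five study scenarios: baseline, each constraint alone, and all three.

    The pathology-only scenario needs a localization endpoint (all-central
    or all-local); when arm profiles are supplied it is resolved by
    evaluating both endpoints and keeping the one with the higher net
    monetary benefit, otherwise full centralization is assumed.
    """
    if crizotinib is not None and docetaxel is not None and test is not None:
        pathology_beta = resolve_pathology_beta(
            test, crizotinib, docetaxel, discount, threshold
        )
    else:
        pathology_beta = 0
    return [
        ConstraintScenario(name="baseline", alpha=1.0, beta=0.0, gamma=1),
        ConstraintScenario(name="awareness", alpha=AWARENESS_BASE, beta=0.0, gamma=1),
        ConstraintScenario(name="localization", alpha=1.0, beta=LOCALIZED_BASE, gamma=1),
        ConstraintScenario(name="pathology", alpha=1.0, beta=float(pathology_beta), gamma=0),
        ConstraintScenario(name="combined", alpha=AWARENESS_BASE, beta=LOCALIZED_BASE, gamma=0),
    ]
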