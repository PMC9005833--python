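"""Probabilistic sensitivity analysis over the capacity-constraint parameters.

Each iteration draws a fresh constraint parameter set, re-evaluates the
decision tree + Markov pipeline for the requested scenario, and records the
per-tested-patient incremental cost and QALYs.  The distributions are:

======================  ==========================================
awareness (alpha)       Beta(498, 1660)
localized proportion    Beta(19, 158)
PFS median ratio        Uniform(0.697, 1)
OS median ratio         Uniform(0.633, 1)
delay disutility        Triangular(min 0, mode 0.03, max 0.1)
localized IHC cost      25 x (1 + Uniform(0.10, 0.25)) GBP
delay cost              fixed at 101 GBP
======================  ==========================================

A draw only replaces a parameter where the scenario activates the
corresponding constraint (e.g. the survival-degradation ratios vary only
when pathology capacity is constrained, ``gamma = 0``), so the
unconstrained baseline is untouched by the sampling and its cloud
collapses to the deterministic point.

Common random numbers: iteration ``i`` uses an RNG keyed on
``(seed, i)``, so different scenarios run at the same seed see identical
parameter draws and their cost-effectiveness clouds are directly
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import BaselineFixture
from .markov import DiscountSpec, InvalidParameterError
from .pathway import ConstraintScenario, evaluate_pathway


@dataclass(frozen=True)
class ParameterDistributions:
    """Sampling distributions for the constraint parameters."""

    awareness_beta: tuple[float, float] = (498.0, 1660.0)
    localized_beta: tuple[float, float] = (19.0, 158.0)
    m_pfs_uniform: tuple[float, float] = (0.697, 1.0)
    m_os_uniform: tuple[float, float] = (0.633, 1.0)
    delay_disutility_triangular: tuple[float, float, float] = (0.0, 0.03, 0.1)  # min, mode, max
    ihc_central_cost: float = 25.0
    ihc_uplift_uniform: tuple[float, float] = (0.10, 0.25)
    delay_cost: float = 101.0  # fixed


def sample_parameters(
    dists: ParameterDistributions, seed: int, index: int
) -> dict[str, float]:
    """One independent draw of every constraint parameter.

    Reproducible: the draw depends only on ``(seed, index)``, giving common
    random numbers across scenarios evaluated at the same seed.
    """
    rng = np.random.default_rng((int(seed), int(index)))
    lo, mode, hi = dists.delay_disutility_triangular
    return {
        "awareness": float(rng.beta(*dists.awareness_beta)),
        "localized_proportion": float(rng.beta(*dists.localized_beta)),
        "m_pfs": float(rng.uniform(*dists.m_pfs_uniform)),
        "m_os": float(rng.uniform(*dists.m_os_uniform)),
        "delay_disutility": float(rng.triangular(lo, mode, hi)),
        "ihc_local_uplift": float(rng.uniform(*dists.ihc_uplift_uniform)),
        "delay_cost": float(dists.delay_cost),
    }


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo sample of incremental outcomes for one scenario."""

    scenario: str
    iterations: int
    delta_costs: np.ndarray  # GBP per tested patient, one per iteration
    delta_qalys: np.ndarray  # QALYs per tested patient
    access: np.ndarray  # access proportion per iteration
    prob_cost_effective: float  # fraction of iterations with positive NMB

    @property
    def ce_pairs(self) -> np.ndarray:
        """(iterations, 2) array of (delta_cost, delta_qalys)."""
        return np.column_stack([self.delta_costs, self.delta_qalys])


def _apply_draw(
    scenario: ConstraintScenario, fixture: BaselineFixture, draw: dict[str, float]
):
    """Overlay a parameter draw on the scenario/test parameters.

    Only constraints the scenario activates are varied: alpha when access
    is limited (alpha < 1), beta when the mix is genuinely partial
    (0 < beta < 1), and the quality/delay parameters when gamma = 0.  The
    localized IHC price uplift varies whenever any testing is localized.
    """
    scn_kwargs = {}
    if scenario.alpha < 1.0:
        scn_kwargs["alpha"] = draw["awareness"]
    if 0.0 < scenario.beta < 1.0:
        scn_kwargs["beta"] = draw["localized_proportion"]
    if scenario.gamma == 0:
        scn_kwargs["m_pfs"] = draw["m_pfs"]
        scn_kwargs["m_os"] = draw["m_os"]
    scn = replace(scenario, **scn_kwargs) if scn_kwargs else scenario

    test_kwargs = {}
    if scn.beta > 0.0:
        test_kwargs["ihc_local_uplift"] = draw["ihc_local_uplift"]
    if scenario.gamma == 0:
        test_kwargs["delay_disutility"] = draw["delay_disutility"]
        test_kwargs["delay_cost"] = draw["delay_cost"]
    test = replace(fixture.test, **test_kwargs) if test_kwargs else fixture.test
    return scn, test


def run_psa(
    fixture: BaselineFixture,
    scenario: ConstraintScenario,
    dists: ParameterDistributions | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    discount: DiscountSpec | None = None,
    threshold: float = 50_000.0,
) -> PSAResult:
    """Monte-Carlo re-evaluation of one scenario under parameter uncertainty."""
    if n_iter < 1:
        raise InvalidParameterError("n_iter must be at least 1")
    dists = dists or ParameterDistributions()
    discount = discount or DiscountSpec()

    d_costs = np.empty(n_iter)
    d_qalys = np.empty(n_iter)
    access = np.empty(n_iter)
    for i in range(n_iter):
        draw = sample_parameters(dists, seed, i)
        scn, test = _apply_draw(scenario, fixture, draw)
        out = evaluate_pathway(scn, test, fixture.crizotinib, fixture.docetaxel, discount)
        d_costs[i] = out.delta_cost
        d_qalys[i] = out.delta_qalys
        access[i] = out.access_proportion

    nmb = threshold * d_qalys - d_costs
    # access scales but never flips the sign of the population NMB
    prob = float(np.mean(nmb > 0.0))
    return PSAResult(
        scenario=scenario.name,
        iterations=n_iter,
        delta_costs=d_costs,
        delta_qalys=d_qalys,
        access=access,
        prob_cost_effective=prob,
    )


def ce_plane_export(results: list[PSAResult], path) -> pd.DataFrame:
    """Write the cost-effectiveness-plane sample to CSV.

    One row per (scenario, iteration) with the incremental cost and QALYs;
    suitable for external plotting.  Returns the written frame.
    """
    if not results:
        raise ValueError("no PSA results to export")
    frames = [
        pd.DataFrame(
            {
                "scenario": res.scenario,
                "iteration": np.arange(res.iterations),
                "delta_cost": res.delta_costs,
                "delta_qalys": res.delta_qalys,
            }
        )
        for res in results
    ]
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(Path(path), index=False)
    return table


def psa_summary(results: list[PSAResult], threshold: float = 50_000.0) -> pd.DataFrame:
    """Per-scenario summary: mean incrementals and probability cost-effective."""
    if not results:
        raise ValueError("no PSA results to summarize")
    return pd.DataFrame(
        {
            "scenario": [r.scenario for r in results],
            "iterations": [r.iterations for r in results],
            "mean_delta_cost": [float(r.delta_costs.mean()) for r in results],
            "mean_delta_qalys": [float(r.delta_qalys.mean()) for r in results],
            "prob_cost_effective": [r.prob_cost_effective for r in results],
        }
    )
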