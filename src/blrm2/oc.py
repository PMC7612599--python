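"""Operating characteristics and prior calibration.

The design's accuracy is judged by its *predictive* performance for the
patients of the subsequent proof-of-concept study: for 112 future patients
with methadone doses drawn from the population distribution, the share
recommended a dose whose true risk lies in the target band (correct) and
the share recommended a dose whose true risk does not exceed the band's
upper edge (safe).  Conventional metrics (DLT burden, sample size, stop
probabilities) are aggregated alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np

from .design import DesignConfig, dosing_intervals
from .inference import PosteriorDraws, PriorHyperparameters
from .scenarios import Scenario, classify_scenario, scenario_risk
from .simulate import MethadoneDistribution, TrialRecord, draw_methadone

__all__ = [
    "OCRow",
    "target_dose_truth",
    "predictive_accuracy",
    "summarize",
    "binned_summary",
    "calibrate_priors",
]

logger = logging.getLogger("blrm2")


@dataclass(frozen=True)
class OCRow:
    """One row of an operating-characteristics table (percent scale)."""

    pct_correct: float | None
    pct_safe: float | None
    pct_dlt: float
    avg_n: float
    pct_stop_unsafe: float
    pct_stop_safe: float

    def as_dict(self) -> dict:
        return {
            "% of correct selections": self.pct_correct,
            "% of safe selections": self.pct_safe,
            "Proportion of DLTs": self.pct_dlt,
            "Average sample size": self.avg_n,
            "Stopped unsafe": self.pct_stop_unsafe,
            "Stopped safe": self.pct_stop_safe,
        }


def target_dose_truth(
    scenario: Scenario, m: float, config: DesignConfig
) -> float | None:
    """True target baclofen dose(s) for methadone dose ``m``.

    Returns the highest dose whose true risk lies in the target band; if
    no dose reaches the band, the highest dose with risk below it (the
    best safe dose); ``None`` if even the lowest dose is too toxic.
    """
    risks = [float(scenario_risk(scenario, m, b)) for b in config.b_doses]
    in_band = [
        b
        for b, r in zip(config.b_doses, risks)
        if config.target_lo <= r <= config.target_hi
    ]
    if in_band:
        return in_band[-1]
    below = [b for b, r in zip(config.b_doses, risks) if r < config.target_lo]
    return below[-1] if below else None


def predictive_accuracy(
    final_draws: PosteriorDraws,
    scenario: Scenario,
    future_dist: MethadoneDistribution,
    config: DesignConfig,
    seed: int,
    n_future: int = 112,
) -> tuple[float, float]:
    """(pct_correct, pct_safe) for ``n_future`` patients of the next phase.

    Recommendations come from the end-of-trial dosing function (no
    intra-trial escalation restrictions).  A recommendation is correct if
    the recommended dose's true risk lies in the target band, or — when no
    dose reaches the band for that methadone dose — if it is the best safe
    dose; it is safe if the true risk does not exceed the band's upper
    edge.  A patient for whom no dose is recommended scores neither.
    """
    rng = np.random.default_rng(seed)
    doses_m = draw_methadone(future_dist, n_future, rng)
    fn = dosing_intervals(final_draws, config)
    n_correct = n_safe = 0
    for m in doses_m:
        b = fn.recommend(float(m))
        if np.isnan(b):
            continue
        r = float(scenario_risk(scenario, float(m), b))
        if r <= config.target_hi:
            n_safe += 1
        if config.target_lo <= r <= config.target_hi:
            n_correct += 1
        else:
            tgt = target_dose_truth(scenario, float(m), config)
            if tgt is not None and b == tgt and r < config.target_lo:
                n_correct += 1
    return 100.0 * n_correct / n_future, 100.0 * n_safe / n_future


def summarize(
    records: list[TrialRecord],
    scenario: Scenario,
    future_dist: MethadoneDistribution,
    config: DesignConfig,
    seed: int,
    n_future: int = 112,
) -> OCRow:
    """Aggregate operating characteristics over replicate trials.

    Predictive accuracy is averaged over trials *not* stopped for safety
    (a stopped-unsafe trial recommends no combination); DLT and sample-size
    metrics cover all trials.  With every trial stopped unsafe the accuracy
    entries are missing, mirroring the "-" entries of printed tables.
    """
    if not records:
        raise ValueError("no trial records to summarise")
    ss = np.random.SeedSequence(seed)
    correct, safe = [], []
    for rec, child in zip(records, ss.spawn(len(records))):
        if rec.status == "stopped_unsafe":
            continue
        pc, psafe = predictive_accuracy(
            rec.final_draws,
            scenario,
            future_dist,
            config,
            seed=int(child.generate_state(1)[0] % (2**31)),
            n_future=n_future,
        )
        correct.append(pc)
        safe.append(psafe)
    n_pat = sum(r.n_patients for r in records)
    n_dlt = sum(r.n_dlt for r in records)
    return OCRow(
        pct_correct=float(np.mean(correct)) if correct else None,
        pct_safe=float(np.mean(safe)) if safe else None,
        pct_dlt=100.0 * n_dlt / n_pat,
        avg_n=n_pat / len(records),
        pct_stop_unsafe=100.0
        * sum(r.status == "stopped_unsafe" for r in records)
        / len(records),
        pct_stop_safe=100.0
        * sum(r.status == "stopped_safe" for r in records)
        / len(records),
    )


def binned_summary(tagged_results, thresholds, mode: str) -> list[dict]:
    """Cumulative random-scenario curves.

    ``tagged_results`` pairs each scenario's safety-check risk with its
    per-scenario metric (accuracy in percent for ``mode='accuracy'``,
    early-termination proportion in percent for ``mode='termination'``).
    For each threshold x the accuracy curve averages scenarios with risk
    below x and the termination curve scenarios with risk above x; empty
    bins yield missing values.
    """
    if mode not in ("accuracy", "termination"):
        raise ValueError("mode must be 'accuracy' or 'termination'")
    out = []
    for x in thresholds:
        if mode == "accuracy":
            vals = [v for risk, v in tagged_results if risk < x]
        else:
            vals = [v for risk, v in tagged_results if risk >= x]
        out.append(
            {
                "threshold": float(x),
                "value": float(np.mean(vals)) if vals else None,
                "n_scenarios": len(vals),
            }
        )
    return out


def calibrate_priors(
    grid: dict,
    scenarios: list[Scenario],
    config: DesignConfig,
    run_scenario,
    seed: int,
) -> tuple[PriorHyperparameters, list[dict]]:
    """Grid search for the prior maximising the geometric mean of accuracy.

    ``grid`` maps hyper-parameter names (``mu01``, ``mu02``, ``mu11``,
    ``mu12``, ``sigma0``, ``sigma1``, ``sigma01``, ``sigma_eta``) to value
    lists; unlisted names keep the default.  ``run_scenario(hyper,
    scenario, seed)`` must return that scenario's accuracy in percent —
    injected so that callers control the simulation budget.  Cells with a
    zero accuracy have geometric mean zero and are eliminated (logged).
    Returns the winning hyper-parameters and the full results table.
    """
    if not scenarios:
        raise ValueError("at least one calibration scenario is required")
    names = list(grid)
    if not names:
        raise ValueError("empty hyper-parameter grid")
    base = PriorHyperparameters()
    results = []
    best = None
    ss = np.random.SeedSequence(seed)
    for cell_idx, values in enumerate(product(*(grid[n] for n in names))):
        cell = dict(zip(names, values))
        kwargs = {}
        pair_map = {
            "mu01": ("mu0", 0),
            "mu02": ("mu0", 1),
            "mu11": ("slope_median", 0),
            "mu12": ("slope_median", 1),
        }
        mu0 = list(base.mu0)
        med = list(base.slope_median)
        for key, val in cell.items():
            if key in pair_map:
                attr, idx = pair_map[key]
                (mu0 if attr == "mu0" else med)[idx] = val
            elif key in ("sigma0", "sigma1", "sigma01"):
                kwargs[key] = (val, val)
            elif key == "sigma_eta":
                kwargs[key] = val
            else:
                raise ValueError(f"unknown hyper-parameter {key!r}")
        hyper = PriorHyperparameters(
            mu0=tuple(mu0), slope_median=tuple(med), **kwargs
        )
        accs = []
        for scen, child in zip(scenarios, ss.spawn(len(scenarios))):
            accs.append(
                run_scenario(hyper, scen, int(child.generate_state(1)[0] % (2**31)))
            )
        if min(accs) <= 0:
            geo = 0.0
            logger.info("calibration cell %s eliminated (zero accuracy)", cell)
        else:
            geo = float(np.exp(np.mean(np.log(accs))))
        results.append({**cell, "accuracies": accs, "geometric_mean": geo})
        if best is None or geo > best[0]:
            best = (geo, hyper)
    return best[1], results
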