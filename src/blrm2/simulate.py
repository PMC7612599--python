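"""Sequential trial simulation and replay of recorded escalation paths.

A simulated trial draws each patient's methadone dose from the study
population's dose distribution (truncated normal, mean 51.4 mg, SD 23.3 mg
on [10, 150] for the motivating trial), assigns baclofen by the design's
rules, generates DLT outcomes from a true scenario, and updates the
posterior after every cohort until the maximum sample size or an early
stop.  Replay mode instead feeds recorded cohorts (doses and outcomes)
through the model to recompute the decision quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import (
    DesignConfig,
    DosingFunction,
    TrialState,
    admissible_doses,
    check_stop_safe,
    check_stop_unsafe,
    dosing_intervals,
    recommend_dose,
)
from .inference import (
    PosteriorDraws,
    PriorHyperparameters,
    SamplerSettings,
    TrialData,
    prob_exceeds,
    sample_posterior,
)
from .scenarios import Scenario, scenario_risk

__all__ = [
    "MethadoneDistribution",
    "CohortSnapshot",
    "TrialRecord",
    "draw_methadone",
    "simulate_dlt",
    "run_trial",
    "replay_trial",
    "run_many",
]

logger = logging.getLogger("blrm2")


@dataclass(frozen=True)
class MethadoneDistribution:
    """Distribution of externally prescribed methadone doses (mg).

    ``truncated_normal`` reflects the motivating study population;
    ``truncated_student_t`` (default 10 degrees of freedom) and ``uniform``
    are the heavier-tailed robustness variants for future patients.
    """

    family: str = "truncated_normal"
    location: float = 51.4
    scale: float = 23.3
    dof: float = 10.0
    bounds: tuple[float, float] = (10.0, 150.0)

    def __post_init__(self) -> None:
        if self.family not in ("truncated_normal", "truncated_student_t", "uniform"):
            raise ValueError(f"unknown dose distribution family {self.family!r}")
        lo, hi = self.bounds
        if not (1.0 <= lo < hi <= 150.0):
            raise ValueError("bounds must satisfy 1 <= lo < hi <= 150")

    def _frozen(self):
        lo, hi = self.bounds
        if self.family == "truncated_normal":
            a, b = (lo - self.location) / self.scale, (hi - self.location) / self.scale
            return stats.truncnorm(a, b, loc=self.location, scale=self.scale)
        if self.family == "truncated_student_t":
            base = stats.t(df=self.dof, loc=self.location, scale=self.scale)
            return _TruncatedFrozen(base, lo, hi)
        return stats.uniform(loc=lo, scale=hi - lo)

    def mean(self) -> float:
        frozen = self._frozen()
        if hasattr(frozen, "mean_numeric"):
            return frozen.mean_numeric()
        return float(frozen.mean())


class _TruncatedFrozen:
    """Truncation of an arbitrary continuous scipy distribution via its CDF."""

    def __init__(self, base, lo, hi):
        self.base = base
        self.lo, self.hi = lo, hi
        self.plo, self.phi = base.cdf(lo), base.cdf(hi)

    def rvs(self, size, random_state):
        u = random_state.uniform(self.plo, self.phi, size=size)
        return self.base.ppf(u)

    def mean_numeric(self) -> float:
        from scipy.integrate import quad

        z = self.phi - self.plo
        val, _ = quad(lambda x: x * self.base.pdf(x) / z, self.lo, self.hi)
        return val


def draw_methadone(
    dist: MethadoneDistribution, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` integer-mg methadone doses inside the distribution bounds."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    frozen = dist._frozen()
    if isinstance(frozen, _TruncatedFrozen):
        raw = frozen.rvs(n, rng)
    else:
        raw = frozen.rvs(size=n, random_state=rng)
    lo, hi = dist.bounds
    return np.clip(np.rint(raw), np.ceil(lo), np.floor(hi)).astype(int)


def simulate_dlt(scenario: Scenario, m, b, rng: np.random.Generator):
    """Bernoulli DLT outcome(s) at the scenario's true risk."""
    p = scenario_risk(scenario, m, b)
    return (rng.random(np.shape(p)) < p).astype(int)


@dataclass(frozen=True)
class CohortSnapshot:
    """Decision quantities recorded after each cohort's posterior update."""

    cohort: int
    p_unsafe: float
    p_safe: float
    intervals: dict | None = None


@dataclass(frozen=True)
class TrialRecord:
    """Complete record of one simulated or replayed trial."""

    patients: tuple[tuple[float, float, int, int], ...]  # (m, b, y, cohort)
    snapshots: tuple[CohortSnapshot, ...]
    status: str
    final_draws: PosteriorDraws
    seed: int | None = None

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_dlt(self) -> int:
        return sum(p[2] for p in self.patients)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.patients, columns=["m_dose", "b_dose", "dlt", "cohort"]
        )

    def dosing_function(self, config: DesignConfig) -> DosingFunction:
        return dosing_intervals(self.final_draws, config)


def _update(hyper, data, settings, seed):
    return sample_posterior(hyper, TrialData.from_records(data), settings, seed)


def _snapshot(draws, config, cohort, with_intervals):
    m_s, b_s = config.safety_check_combo
    m_h, b_h = config.high_combo
    return CohortSnapshot(
        cohort=cohort,
        p_unsafe=prob_exceeds(draws, m_s, b_s, config.target_hi),
        p_safe=1.0 - prob_exceeds(draws, m_h, b_h, config.target_hi),
        intervals=(
            dosing_intervals(draws, config).intervals if with_intervals else None
        ),
    )


def run_trial(
    scenario: Scenario,
    config: DesignConfig,
    hyper: PriorHyperparameters,
    dist: MethadoneDistribution,
    seed: int,
    settings: SamplerSettings = SamplerSettings(),
    snapshots_with_intervals: bool = False,
) -> TrialRecord:
    """Run one sequential trial under a true toxicity scenario.

    The first cohort receives the lowest baclofen dose; thereafter each
    patient is dosed by the design's recommendation under the cohort-level
    posterior, stopping rules are checked once per cohort, and the loop
    ends at ``config.max_n`` patients or an early stop.
    """
    rng = np.random.default_rng(seed)
    n_cohorts = config.max_n // config.cohort_size
    m_doses = draw_methadone(dist, config.max_n, rng)
    state = TrialState()
    patients: list[tuple[float, float, int, int]] = []
    snaps: list[CohortSnapshot] = []
    draws = None
    for cohort in range(n_cohorts):
        ms = m_doses[cohort * config.cohort_size : (cohort + 1) * config.cohort_size]
        records = []
        for m in ms:
            if cohort == 0:
                b = config.b_doses[0]
            else:
                b = recommend_dose(draws, float(m), state, config)
            y = int(simulate_dlt(scenario, float(m), b, rng))
            records.append((float(m), float(b), y))
            patients.append((float(m), float(b), y, cohort + 1))
        state = state.with_cohort(records, config)
        draws = _update(hyper, state.data.records, settings, int(rng.integers(2**31)))
        snaps.append(_snapshot(draws, config, cohort + 1, snapshots_with_intervals))
        if check_stop_unsafe(draws, config):
            state = state.with_status("stopped_unsafe")
            break
        if check_stop_safe(draws, config):
            state = state.with_status("stopped_safe")
            break
    if state.status == "ongoing":
        state = state.with_status("completed")
    return TrialRecord(
        patients=tuple(patients),
        snapshots=tuple(snaps),
        status=state.status,
        final_draws=draws,
        seed=seed,
    )


def replay_trial(
    cohorts,
    config: DesignConfig,
    hyper: PriorHyperparameters,
    settings: SamplerSettings = SamplerSettings(),
    seed: int = 0,
    with_intervals: bool = True,
) -> TrialRecord:
    """Recompute the decision quantities for recorded cohorts.

    ``cohorts`` is a sequence of (m_doses, b_doses, dlts) triples as printed
    in escalation-path tables.  Doses and outcomes are taken as given; the
    posterior, stopping probabilities and dosing intervals are recomputed
    after each cohort.
    """
    rng = np.random.default_rng(seed)
    state = TrialState()
    patients: list[tuple[float, float, int, int]] = []
    snaps: list[CohortSnapshot] = []
    draws = None
    for cohort, (ms, bs, ys) in enumerate(cohorts, start=1):
        if not (len(ms) == len(bs) == len(ys)):
            raise ValueError(f"cohort {cohort}: inconsistent lengths")
        records = [(float(m), float(b), int(y)) for m, b, y in zip(ms, bs, ys)]
        for m, b, y in records:
            patients.append((m, b, y, cohort))
        state = state.with_cohort(records, config)
        draws = _update(hyper, state.data.records, settings, int(rng.integers(2**31)))
        snaps.append(_snapshot(draws, config, cohort, with_intervals))
    status = "completed"
    if draws is not None:
        if check_stop_unsafe(draws, config):
            status = "stopped_unsafe"
        elif check_stop_safe(draws, config):
            status = "stopped_safe"
    return TrialRecord(
        patients=tuple(patients),
        snapshots=tuple(snaps),
        status=status,
        final_draws=draws,
        seed=seed,
    )


def run_many(
    scenario: Scenario,
    config: DesignConfig,
    hyper: PriorHyperparameters,
    dist: MethadoneDistribution,
    n_sims: int,
    seed: int,
    settings: SamplerSettings = SamplerSettings(),
) -> list[TrialRecord]:
    """Independent replicate trials with counter-based per-trial seeds."""
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_sims)):
        trial_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(
            run_trial(scenario, config, hyper, dist, trial_seed, settings)
        )
        if (i + 1) % 50 == 0:
            logger.info("completed %d/%d simulated trials", i + 1, n_sims)
    return out
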