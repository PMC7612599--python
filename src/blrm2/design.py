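"""Escalation decisions: admissibility, overdose control, stopping, dosing.

The decision layer sits on top of the posterior draws.  For each enrolled
patient with externally prescribed methadone dose ``m`` the design

1. restricts baclofen to *admissible* doses (no skipping of untried levels
   and coherency after a DLT cohort),
2. keeps the *safe* admissible doses, those with posterior probability of
   overdose ``P(risk > gamma+delta) < c_overdose``,
3. assigns the safe admissible dose maximising the posterior probability
   that the risk lies in the target band ``(gamma-delta, gamma+delta)``.

Two trial-level stopping rules are checked once per cohort: stop-unsafe if
the safety-check combination (60, 30) is too likely to be toxic and
stop-safe if the high combination (120, 90) is safe with high confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .inference import PosteriorDraws, TrialData, prob_exceeds, prob_in_interval

__all__ = [
    "DesignConfig",
    "TrialState",
    "DosingFunction",
    "admissible_doses",
    "safe_doses",
    "recommend_dose",
    "check_stop_unsafe",
    "check_stop_safe",
    "dosing_intervals",
]

logger = logging.getLogger("blrm2")


@dataclass(frozen=True)
class DesignConfig:
    """Design parameters of the motivating trial (defaults as calibrated)."""

    gamma: float = 0.20
    delta: float = 0.05
    c_overdose: float = 0.25
    cohort_size: int = 3
    max_n: int = 48
    b_doses: tuple[float, ...] = (10.0, 30.0, 60.0, 90.0)
    m_range: tuple[float, float] = (10.0, 150.0)
    safety_check_combo: tuple[float, float] = (60.0, 30.0)
    high_combo: tuple[float, float] = (120.0, 90.0)
    stop_unsafe_threshold: float = 0.25
    stop_safe_threshold: float = 0.925

    def __post_init__(self) -> None:
        if not 0 < self.gamma - self.delta < self.gamma + self.delta < 1:
            raise ValueError("target band must lie strictly inside (0, 1)")
        if list(self.b_doses) != sorted(set(self.b_doses)):
            raise ValueError("b_doses must be strictly ascending")
        for t in (self.c_overdose, self.stop_unsafe_threshold, self.stop_safe_threshold):
            if not 0 < t < 1:
                raise ValueError("probability thresholds must lie in (0, 1)")

    @property
    def target_lo(self) -> float:
        return self.gamma - self.delta

    @property
    def target_hi(self) -> float:
        return self.gamma + self.delta


@dataclass(frozen=True)
class TrialState:
    """Mutable-by-replacement record of the trial's progress."""

    data: TrialData = field(default_factory=TrialData)
    highest_tried_index: int = -1
    last_cohort: tuple[tuple[float, float, int], ...] = ()
    status: str = "ongoing"

    _STATUSES = ("ongoing", "stopped_unsafe", "stopped_safe", "completed")

    def __post_init__(self) -> None:
        if self.status not in self._STATUSES:
            raise ValueError(f"unknown status {self.status!r}")

    def with_cohort(self, cohort, config: DesignConfig) -> "TrialState":
        """Fold a finished cohort of (m, b, y) records into the state."""
        if self.status != "ongoing":
            raise ValueError("cannot enrol into a stopped trial")
        idx = max(
            [config.b_doses.index(b) for _, b, _ in cohort],
            default=-1,
        )
        return replace(
            self,
            data=self.data.extend(cohort),
            highest_tried_index=max(self.highest_tried_index, idx),
            last_cohort=tuple((float(m), float(b), int(y)) for m, b, y in cohort),
        )

    def with_status(self, status: str) -> "TrialState":
        if self.status != "ongoing" and status != self.status:
            raise ValueError("status transitions are one-way")
        return replace(self, status=status)


@dataclass(frozen=True)
class DosingFunction:
    """Baclofen recommendation per integer methadone dose.

    ``grid`` is the integer methadone grid, ``recommendation`` the baclofen
    dose per grid point (``nan`` where no dose is safe) and ``intervals``
    the maximal contiguous methadone runs per baclofen dose, as printed in
    escalation-path tables.
    """

    grid: np.ndarray
    recommendation: np.ndarray
    intervals: dict[float, list[tuple[int, int]]]

    def recommend(self, m: float) -> float:
        """Recommended baclofen dose for methadone dose ``m`` (nearest grid)."""
        i = int(np.argmin(np.abs(self.grid - m)))
        return float(self.recommendation[i])


def admissible_doses(state: TrialState, config: DesignConfig) -> tuple[float, ...]:
    """Baclofen doses that may be assigned to the next cohort.

    No skipping: at most one level above the highest level tried so far.
    Coherency: if the most recent cohort contained a DLT, the cap is the
    lowest baclofen dose at which a DLT occurred in that cohort.
    """
    if state.status != "ongoing":
        raise ValueError("trial is not ongoing")
    if state.highest_tried_index < 0:
        return (config.b_doses[0],)
    cap = min(state.highest_tried_index + 1, len(config.b_doses) - 1)
    dlt_doses = [b for _, b, y in state.last_cohort if y]
    if dlt_doses:
        coherency_cap = config.b_doses.index(min(dlt_doses))
        cap = min(cap, coherency_cap)
    return tuple(config.b_doses[: cap + 1])


def safe_doses(
    draws: PosteriorDraws,
    m: float,
    admissible: tuple[float, ...],
    config: DesignConfig,
) -> tuple[float, ...]:
    """Admissible doses passing the overdose-control criterion at ``m``."""
    if not admissible:
        raise ValueError("admissible set must be nonempty")
    return tuple(
        b
        for b in admissible
        if prob_exceeds(draws, m, b, config.target_hi) < config.c_overdose
    )


def recommend_dose(
    draws: PosteriorDraws,
    m: float,
    state: TrialState,
    config: DesignConfig,
) -> float:
    """Baclofen dose for a patient with methadone dose ``m``.

    Among safe admissible doses, the maximiser of the posterior probability
    of the target band; ties break to the lowest dose.  If no admissible
    dose is safe the lowest dose is assigned (trial-level safety is
    delegated to the stop-unsafe rule).
    """
    adm = admissible_doses(state, config)
    safe = safe_doses(draws, m, adm, config)
    if not safe:
        logger.info("no safe admissible dose at m=%.0f; assigning lowest", m)
        return config.b_doses[0]
    probs = [
        prob_in_interval(draws, m, b, config.target_lo, config.target_hi)
        for b in safe
    ]
    return safe[int(np.argmax(probs))]


def check_stop_unsafe(draws: PosteriorDraws, config: DesignConfig) -> bool:
    """True if the safety-check combination is too likely to be toxic."""
    m, b = config.safety_check_combo
    return (
        prob_exceeds(draws, m, b, config.target_hi) > config.stop_unsafe_threshold
    )


def check_stop_safe(draws: PosteriorDraws, config: DesignConfig) -> bool:
    """True if the high combination is safe with high confidence."""
    m, b = config.high_combo
    p_safe = 1.0 - prob_exceeds(draws, m, b, config.target_hi)
    return p_safe > config.stop_safe_threshold


def _runs(ms: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous integer runs of a sorted array."""
    out: list[tuple[int, int]] = []
    for m in ms:
        if out and m == out[-1][1] + 1:
            out[-1] = (out[-1][0], int(m))
        else:
            out.append((int(m), int(m)))
    return out


def dosing_intervals(
    draws: PosteriorDraws,
    config: DesignConfig,
    admissible: tuple[float, ...] | None = None,
) -> DosingFunction:
    """Dosing function on the 1 mg methadone grid.

    By default every baclofen dose is eligible (the end-of-trial dosing
    function carries no intra-trial escalation restrictions); pass
    ``admissible`` to restrict, e.g. when printing the per-cohort tables
    used to assign the next group.
    """
    doses = tuple(admissible) if admissible is not None else config.b_doses
    lo, hi = config.m_range
    grid = np.arange(int(lo), int(hi) + 1, dtype=float)
    # vectorised over the grid: risk matrix per dose
    over = np.empty((len(doses), len(grid)))
    inband = np.empty((len(doses), len(grid)))
    for i, b in enumerate(doses):
        risks = draws.risk(grid[:, None], b)  # (grid, draws)
        over[i] = np.mean(risks > config.target_hi, axis=1)
        inband[i] = np.mean(
            (risks > config.target_lo) & (risks < config.target_hi), axis=1
        )
    eligible = over < config.c_overdose
    masked = np.where(eligible, inband, -np.inf)
    best = masked.argmax(axis=0)
    any_safe = eligible.any(axis=0)
    rec = np.where(any_safe, np.asarray(doses)[best], np.nan)
    intervals: dict[float, list[tuple[int, int]]] = {}
    for b in doses:
        ms = grid[rec == b].astype(int)
        runs = _runs(ms)
        if len(runs) > 1:
            logger.warning("non-contiguous recommendation runs for B=%g mg", b)
        intervals[b] = runs
    return DosingFunction(grid=grid, recommendation=rec, intervals=intervals)
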