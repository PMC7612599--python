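"""True combination-toxicity scenarios for simulation studies.

A scenario is a parametric toxicity surface from one of three families:
the five-parameter logistic working model (``logistic5``), the Bailey
binary-covariate model (``bailey``) or the seven-parameter Bliss surface
(``bliss7``).  Random scenario generators draw the family parameters from
the uniform supports of the robustness studies; the eight named fixed
scenarios (Safe, Low/Medium/High Toxicity 1-2, Unsafe) are user-supplied
through a scenario file, since their exact parameter vectors live in
supplementary material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .models import (
    BaileyParams,
    BlissParams,
    ReferenceDoses,
    ThetaVector,
    bailey_risk,
    bliss_risk,
    combination_risk,
)

__all__ = [
    "Scenario",
    "scenario_risk",
    "random_logistic_scenario",
    "random_bliss_scenario",
    "classify_scenario",
    "load_fixed_scenarios",
    "scenario_contours",
    "LOGISTIC_SUPPORTS",
    "BLISS_SUPPORTS",
]

FAMILIES = ("logistic5", "bailey", "bliss7")

#: uniform supports of the random logistic scenario generator
LOGISTIC_SUPPORTS = {
    "alpha01": (-5.00, -0.75),
    "alpha02": (-6.00, -0.75),
    "alpha11": (0.40, 3.00),
    "alpha12": (0.10, 2.00),
    "eta": (0.0, 1.1),
}

#: uniform supports of the random Bliss scenario generator
BLISS_SUPPORTS = {
    "beta1": (0.0, 0.4),
    "beta2": (0.0, 0.25),
    "beta3": (0.5, 1.5),
    "beta4": (0.5, 1.5),
    "beta5": (0.5, 1.5),
    "beta6": (0.5, 1.5),
    "beta7": (0.75, 1.5),
}


@dataclass(frozen=True)
class Scenario:
    """A true toxicity surface: family tag plus its parameter object."""

    family: str
    params: object
    refs: ReferenceDoses = field(default_factory=ReferenceDoses)
    label: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown scenario family {self.family!r}")
        expected = {
            "logistic5": ThetaVector,
            "bailey": BaileyParams,
            "bliss7": BlissParams,
        }[self.family]
        if not isinstance(self.params, expected):
            raise TypeError(
                f"family {self.family!r} requires {expected.__name__} parameters"
            )


def scenario_risk(scenario: Scenario, m, b):
    """True DLT probability of the scenario at dose pair(s) (m, b)."""
    if scenario.family == "logistic5":
        return combination_risk(scenario.params, m, b, scenario.refs)
    if scenario.family == "bailey":
        return bailey_risk(scenario.params, m, b, scenario.refs.m_star)
    return bliss_risk(scenario.params, m, b, scenario.refs)


def random_logistic_scenario(
    rng: np.random.Generator, refs: ReferenceDoses = ReferenceDoses()
) -> Scenario:
    """Draw a random five-parameter logistic scenario (synergistic eta)."""
    s = LOGISTIC_SUPPORTS
    theta = ThetaVector(
        alpha01=rng.uniform(*s["alpha01"]),
        alpha11=rng.uniform(*s["alpha11"]),
        alpha02=rng.uniform(*s["alpha02"]),
        alpha12=rng.uniform(*s["alpha12"]),
        eta=rng.uniform(*s["eta"]),
    )
    return Scenario("logistic5", theta, refs, label="random-logistic")


def random_bliss_scenario(
    rng: np.random.Generator, refs: ReferenceDoses = ReferenceDoses()
) -> Scenario:
    """Draw a random Bliss-surface scenario.

    Draws with ``beta1 <= beta2`` (risk decreasing in dose) are retained;
    the generator's supports guarantee probabilities inside [0, 1].
    """
    s = BLISS_SUPPORTS

    def positive(lo, hi):
        # dataclass validation requires strictly positive beta1/beta2
        v = rng.uniform(lo, hi)
        while v <= 0:
            v = rng.uniform(lo, hi)
        return v

    params = BlissParams(
        beta1=positive(*s["beta1"]),
        beta2=positive(*s["beta2"]),
        beta3=rng.uniform(*s["beta3"]),
        beta4=rng.uniform(*s["beta4"]),
        beta5=rng.uniform(*s["beta5"]),
        beta6=rng.uniform(*s["beta6"]),
        beta7=rng.uniform(*s["beta7"]),
    )
    return Scenario("bliss7", params, refs, label="random-bliss")


def classify_scenario(scenario: Scenario, safety_check=(60.0, 30.0)) -> float:
    """The scenario's true risk at the safety-check combination."""
    return float(scenario_risk(scenario, *safety_check))


def scenario_contours(scenario: Scenario, m_grid, b_grid) -> np.ndarray:
    """Matrix of true risks with methadone on rows and baclofen on columns."""
    m_grid = np.asarray(m_grid, dtype=float)
    b_grid = np.asarray(b_grid, dtype=float)
    if not len(m_grid) or not len(b_grid):
        raise ValueError("grids must be nonempty")
    out = np.empty((len(m_grid), len(b_grid)))
    for j, b in enumerate(b_grid):
        out[:, j] = scenario_risk(scenario, m_grid, float(b))
    return out


_PARAM_CLASSES = {
    "logistic5": (ThetaVector, ["alpha01", "alpha11", "alpha02", "alpha12", "eta"]),
    "bailey": (BaileyParams, ["alpha01", "alpha11", "beta1", "beta2", "beta3"]),
    "bliss7": (
        BlissParams,
        ["beta1", "beta2", "beta3", "beta4", "beta5", "beta6", "beta7"],
    ),
}


def load_fixed_scenarios(path) -> list[Scenario]:
    """Load named scenarios from a YAML scenario file.

    The file maps ``scenarios`` to a list of entries with ``name``,
    ``family`` and ``params``.  Placeholder entries (null parameters) are
    rejected with a descriptive error so that template files cannot be used
    accidentally.  When a scenario named like ``Medium Toxicity 2`` is
    supplied, its near-zero interaction (0.10) is validated.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    entries = raw.get("scenarios") if isinstance(raw, dict) else None
    if not entries:
        raise ValueError(f"{path}: no scenarios found")
    refs = ReferenceDoses(
        **raw.get("reference_doses", {"m_star": 60.0, "b_star": 30.0})
    )
    out, names = [], set()
    for entry in entries:
        name = entry.get("name", "<unnamed>")
        if name in names:
            raise ValueError(f"{path}: duplicate scenario name {name!r}")
        names.add(name)
        family = entry.get("family")
        if family not in _PARAM_CLASSES:
            raise ValueError(f"{path}: scenario {name!r} has unknown family {family!r}")
        cls, fields = _PARAM_CLASSES[family]
        params = entry.get("params") or {}
        missing = [f for f in fields if params.get(f) is None]
        if missing:
            raise ValueError(
                f"{path}: scenario {name!r} is missing parameter values for "
                f"{', '.join(missing)} (template placeholders must be filled in)"
            )
        obj = cls(**{f: float(params[f]) for f in fields})
        if family == "logistic5" and name.lower().replace(" ", "") in (
            "mediumtoxicity2",
            "medtoxicity2",
        ):
            if abs(obj.eta - 0.10) > 1e-9:
                raise ValueError(
                    f"{path}: {name!r} must have interaction eta = 0.10"
                )
        out.append(Scenario(family, obj, refs, label=name))
    return out
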