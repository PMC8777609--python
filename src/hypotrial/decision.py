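"""Hemodynamic-management rule engine.

Two policies are modelled, mirroring the two arms of an early-warning-system
(EWS) trial:

* **proactive** — fires when the Hypotension Prediction Index (HPI) alert
  exceeds its threshold (default: HPI > 85%), after an artifact check, and
  then branches on advanced hemodynamic parameters: stroke volume variation
  (SVV, preload responsiveness), dynamic arterial elastance (Eadyn, arterial
  tone) and dP/dt\\ :sub:`max` (contractility) to select fluid, vasopressor or
  inotrope therapy;
* **reactive** — standard care: the same branch logic, but triggered only
  once MAP has already fallen below the hypotension threshold (< 65 mmHg).

The branch thresholds (SVV > 13% => fluid-responsive; Eadyn < 0.8 =>
vasopressor; dP/dt_max < 480 mmHg/s => inotrope; otherwise observe) follow
common hemodynamic practice; they are package conventions, configurable in
:class:`RuleConfig`, not values taken from any particular monitor.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import yaml

# actions
NONE = "none"
OBSERVE = "observe"
FLUID = "fluid"
VASOPRESSOR = "vasopressor"
INOTROPE = "inotrope"
COMBINATION = "combination"
ACTIONS = (NONE, OBSERVE, FLUID, VASOPRESSOR, INOTROPE, COMBINATION)

# triggers
PROACTIVE_ALERT = "proactive_alert"
REACTIVE_HYPOTENSION = "reactive_hypotension"


class RuleConfigError(ValueError):
    """Malformed rule configuration."""


@dataclass(frozen=True)
class HemodynamicState:
    """Monitor snapshot consumed by the policies.

    ``map`` mmHg; ``hpi`` percent in [0, 100]; ``svv`` percent;
    ``eadyn`` dimensionless; ``dpdt_max`` mmHg/s; ``artifact_flag`` marks a
    suspect arterial-line signal.
    """

    map: float
    hpi: float
    svv: float
    eadyn: float
    dpdt_max: float
    artifact_flag: bool = False

    def __post_init__(self) -> None:
        import math
        for name in ("map", "hpi", "svv", "eadyn", "dpdt_max"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.hpi <= 100.0:
            raise ValueError("hpi must be in [0, 100]")
        if self.svv < 0:
            raise ValueError("svv must be >= 0")


@dataclass(frozen=True)
class Recommendation:
    """Policy output: one action and the trigger that caused it."""

    action: str
    trigger: Optional[str] = None
    reason: str = ""

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if (self.action == NONE) != (self.trigger is None):
            raise ValueError("action 'none' must coincide with no trigger")


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds of the rule table; every value is a tunable convention."""

    hpi_alert_threshold: float = 85.0   # percent, alert when HPI > this
    map_threshold: float = 65.0         # mmHg, reactive trigger when MAP < this
    svv_fluid_threshold: float = 13.0   # percent, SVV > this -> fluid
    eadyn_vasopressor_threshold: float = 0.8  # Eadyn < this -> vasopressor
    dpdt_inotrope_threshold: float = 480.0    # mmHg/s, dP/dt_max < this -> inotrope

    def __post_init__(self) -> None:
        import math
        for name, value in asdict(self).items():
            if not math.isfinite(value):
                raise RuleConfigError(f"{name} must be finite")
        if not 0 <= self.hpi_alert_threshold <= 100:
            raise RuleConfigError("hpi_alert_threshold must be in [0, 100]")
        if self.map_threshold <= 0:
            raise RuleConfigError("map_threshold must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise RuleConfigError(f"{path}: expected a mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise RuleConfigError(f"{path}: {exc}") from exc


DEFAULT_RULES = RuleConfig()


def _branch(state: HemodynamicState, rules: RuleConfig, trigger: str,
            ) -> Recommendation:
    """Treatment selection shared by both policies (mutually exclusive)."""
    if state.svv > rules.svv_fluid_threshold:
        return Recommendation(FLUID, trigger, "preload-responsive (high SVV)")
    if state.eadyn < rules.eadyn_vasopressor_threshold:
        return Recommendation(VASOPRESSOR, trigger, "low arterial tone (Eadyn)")
    if state.dpdt_max < rules.dpdt_inotrope_threshold:
        return Recommendation(INOTROPE, trigger, "low contractility (dP/dt_max)")
    return Recommendation(OBSERVE, trigger, "no actionable branch")


def proactive_policy(state: HemodynamicState,
                     rules: RuleConfig = DEFAULT_RULES) -> Recommendation:
    """EWS-gated policy: fires only on an HPI alert (strictly above threshold).

    An alert with a flagged artifact yields ``observe`` (re-check the signal
    before treating).
    """
    if state.hpi <= rules.hpi_alert_threshold:
        return Recommendation(NONE)
    if state.artifact_flag:
        return Recommendation(OBSERVE, PROACTIVE_ALERT, "artifact check failed")
    return _branch(state, rules, PROACTIVE_ALERT)


def reactive_policy(state: HemodynamicState,
                    rules: RuleConfig = DEFAULT_RULES) -> Recommendation:
    """Standard care: treat once MAP is strictly below the threshold."""
    if state.map >= rules.map_threshold:
        return Recommendation(NONE)
    return _branch(state, rules, REACTIVE_HYPOTENSION)
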