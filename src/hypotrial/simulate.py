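"""Synthetic two-arm trial generator and trial power computation.

The generator produces complete in-silico trials with the statistical
structure the analysis modules assume:

* **randomization** — permuted blocks of sizes 4 and 6, 1:1 allocation;
* **MAP trajectories** — a mean-reverting (AR(1)/Ornstein-Uhlenbeck) baseline
  around a normotensive level, sampled every 20 s, on which hypotension-
  inducing events arrive as a patient-frailty-mixed Poisson process; each
  event is a trapezoidal dip (ramp down, hold near a drawn nadir, ramp up);
* **arm protocols** — in the intervention arm an impending event is alerted
  with probability ``alert_sensitivity`` ahead of its nadir, a proactive
  policy call is recorded, and with probability ``treatment_efficacy`` the
  event is averted (the dip stays above the hypotension threshold) or else
  merely truncated; in the control arm treatment is reactive — it shortens an
  episode once MAP is below threshold but never prevents it;
* **biomarkers** — T0 panels drawn from log-normal baselines, T2 panels equal
  to T0 plus an analyte-specific slope times a compressed burden metric plus
  noise, so burden-biomarker rank correlations are injected by construction
  (S100B keyed to episode count, NGAL and glutathione to the time-weighted
  average, NSE to absolute hypotension time).

Event-rate and efficacy defaults are the output of a documented root-finding
calibration (:func:`calibrate_event_rate`, :func:`calibrate_treatment_efficacy`)
against the design incidences: 80% of control patients and 38% of
intervention patients experience at least one hypotensive episode.  The
frailty-mixed Poisson count makes the expected incidence available in closed
form up to a one-dimensional quadrature over the surgery-duration
distribution, which is what the calibration inverts.

:func:`power_simulation` reproduces the design's power computation by
Monte-Carlo: two-sided two-proportion comparison of binary hypotension
incidence (pooled-variance z-test by default) at n per arm.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.stats import norm as _norm
from scipy.stats import t as _t_dist
from scipy.signal import lfilter

from .biomarkers import ANALYTES, BiomarkerPanel, attach_panels
from .decision import (
    DEFAULT_RULES,
    HemodynamicState,
    Recommendation,
    RuleConfig,
    proactive_policy,
    reactive_policy,
)
from .metrics import MetricsConfig, summarize
from .series import ARMS, MAPSeries, Patient, TrialDataset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiomarkerSpec:
    """Generator model for one analyte.

    T0 values are log-normal (``baseline_median``, log-scale
    ``baseline_sigma``).  The T2 - T0 delta is
    ``slope * asinh(metric / scale) + noise_sd * eps`` where ``metric`` is the
    burden outcome named by ``key`` (``None`` -> pure noise) — the asinh
    compresses the heavy right tail of burden metrics so a single slope can
    span zero-burden and high-burden patients.
    """

    baseline_median: float
    baseline_sigma: float
    slope: float = 0.0
    noise_sd: float = 1.0
    key: Optional[str] = None
    scale: float = 1.0


def _default_biomarkers() -> Dict[str, BiomarkerSpec]:
    return {
        # injured-organ markers keyed to burden; slopes/noise calibrated so the
        # pooled Spearman correlations land near the design targets
        # (S100B~episodes 0.584, NGAL~TWA 0.316) at trial scale
        "s100b": BiomarkerSpec(0.34, 0.70, slope=0.85, noise_sd=0.84,
                               key="n_episodes", scale=2.0),
        "ngal": BiomarkerSpec(2.1, 0.50, slope=0.45, noise_sd=1.06,
                              key="twa", scale=0.2),
        "nse": BiomarkerSpec(2.0, 0.55, slope=0.80, noise_sd=0.70,
                             key="total_time", scale=5.0),
        "gsh": BiomarkerSpec(7.2, 0.50, slope=-2.6, noise_sd=2.2,
                             key="twa", scale=0.2),
        # markers with no injected burden dependence
        "hif1a": BiomarkerSpec(0.17, 0.50, noise_sd=0.03),
        "acetyl_coa": BiomarkerSpec(0.15, 1.00, noise_sd=0.30),
        "hs_troponin": BiomarkerSpec(37.0, 0.60, noise_sd=12.0),
        "looh": BiomarkerSpec(5.0, 0.70, noise_sd=2.0),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; defaults are the study conditions.

    Durations are log-normal with arm-specific medians (minutes) and
    log-sigmas backed out of the reported interquartile ranges.  Event-rate /
    efficacy defaults come from the calibration pass (see module docstring).
    """

    n_per_arm: int = 20
    block_sizes: Tuple[int, ...] = (4, 6)
    duration_median: Tuple[float, float] = (207.0, 237.0)  # (intervention, control) min
    duration_sigma: Tuple[float, float] = (0.228, 0.374)   # log-scale
    sampling_step: float = 20.0      # s
    baseline_map: float = 78.0       # mmHg
    reversion_time: float = 300.0    # OU time constant, s
    noise_sd: float = 2.0            # stationary SD of the baseline, mmHg
    threshold: float = 65.0          # mmHg, hypotension definition
    # event process
    event_rate: float = 1.1096       # events / exposed hour (calibrated)
    frailty_shape: float = 1.0       # gamma shape of the patient multiplier
    event_margin: float = 300.0      # s excluded at both ends of surgery
    nadir_low: float = 52.0          # untreated event nadir target, mmHg
    nadir_high: float = 62.0
    ramp_s: float = 90.0             # dip ramp time, s
    hold_median: float = 120.0       # s at full depth (log-normal)
    hold_sigma: float = 0.6
    hold_min: float = 60.0           # floor so dips are well-sampled at 20 s
    # arm protocols
    control_incidence: float = 0.80
    intervention_incidence: float = 0.38
    alert_sensitivity: float = 0.85
    alert_lead: float = 300.0        # s before full depth
    treatment_efficacy: float = 0.9796  # P(averted | alerted) (calibrated)
    avert_margin: float = 8.0        # averted nadir sits this far above threshold
    mitigation_hold: float = 0.6     # hold scale for alerted-but-not-averted
    reactive_cap: float = 180.0      # max hold (s) once reactive treatment fires
    # biomarkers
    biomarkers: Dict[str, BiomarkerSpec] = field(default_factory=_default_biomarkers)
    rules: RuleConfig = field(default_factory=RuleConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ConfigError("n_per_arm must be >= 1")
        for b in self.block_sizes:
            if b <= 0 or b % 2:
                raise ConfigError("block sizes must be positive and even (1:1 balance)")
        for p, name in (
            (self.control_incidence, "control_incidence"),
            (self.intervention_incidence, "intervention_incidence"),
            (self.alert_sensitivity, "alert_sensitivity"),
            (self.treatment_efficacy, "treatment_efficacy"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.event_rate <= 0 or self.frailty_shape <= 0:
            raise ConfigError("rates must be positive")
        if self.sampling_step <= 0 or self.ramp_s <= 0:
            raise ConfigError("time steps must be positive")
        if not self.nadir_low < self.nadir_high < self.threshold:
            raise ConfigError("need nadir_low < nadir_high < threshold")
        if self.baseline_map <= self.threshold:
            raise ConfigError("baseline_map must sit above the threshold")
        missing = set(ANALYTES) - set(self.biomarkers)
        if missing:
            raise ConfigError(f"biomarker model missing analytes: {sorted(missing)}")

    # -- duration model helpers ------------------------------------------
    def duration_params(self, arm: str) -> Tuple[float, float]:
        idx = ARMS.index(arm)
        return self.duration_median[idx], self.duration_sigma[idx]

    def episode_probability(self, arm: str) -> float:
        """Per-event probability that the event yields a hypotensive episode."""
        if arm == "control":
            return 1.0
        return 1.0 - self.alert_sensitivity * self.treatment_efficacy

    # -- YAML round trip --------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["block_sizes"] = list(self.block_sizes)
        data["duration_median"] = list(self.duration_median)
        data["duration_sigma"] = list(self.duration_sigma)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping")
        if "biomarkers" in data:
            data["biomarkers"] = {
                k: BiomarkerSpec(**v) for k, v in data["biomarkers"].items()
            }
        if "rules" in data:
            data["rules"] = RuleConfig(**data["rules"])
        for key in ("block_sizes", "duration_median", "duration_sigma"):
            if key in data:
                data[key] = tuple(data[key])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream: patient i is reproducible in isolation."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


# ---------------------------------------------------------------------------
# randomization
# ---------------------------------------------------------------------------

def _reachable(n_total: int, sizes: Sequence[int]) -> np.ndarray:
    """reachable[r]: some sequence of block sizes sums exactly to r."""
    reach = np.zeros(n_total + 1, dtype=bool)
    reach[0] = True
    for r in range(1, n_total + 1):
        reach[r] = any(r >= b and reach[r - b] for b in sizes)
    return reach


def randomize_blocks(
    n_total: int,
    block_sizes: Sequence[int] = (4, 6),
    seed: int = 0,
) -> List[str]:
    """Permuted-block 1:1 randomization over the two arms.

    The block-size sequence is drawn uniformly at each step among the sizes
    that keep the remaining total reachable; each block contains exactly half
    of each arm in random order.  Deterministic given ``seed``.
    """
    sizes = sorted(set(int(b) for b in block_sizes))
    if any(b <= 0 or b % 2 for b in sizes):
        raise ConfigError("block sizes must be positive and even")
    reach = _reachable(n_total, sizes)
    if not reach[n_total]:
        raise ConfigError(
            f"no sequence of blocks {sizes} sums to {n_total}"
        )
    rng = _rng(seed, 0xB10C)
    assignments: List[str] = []
    remaining = n_total
    while remaining:
        feasible = [b for b in sizes if b <= remaining and reach[remaining - b]]
        b = int(rng.choice(feasible))
        block = ["intervention"] * (b // 2) + ["control"] * (b // 2)
        rng.shuffle(block)
        assignments.extend(block)
        remaining -= b
    return assignments


# ---------------------------------------------------------------------------
# analytic incidence and calibration
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def expected_incidence(config: SimulationConfig, arm: str,
                       event_rate: Optional[float] = None,
                       episode_probability: Optional[float] = None) -> float:
    """P(at least one hypotensive episode) under the generator's model.

    Episode-producing events are a gamma-frailty-mixed Poisson process over
    the exposed window, so conditional on surgery duration T (minutes) the
    probability of none is ``(1 + rate*q*W(T)/k)**(-k)`` with W(T) the exposed
    hours and k the frailty shape; the duration integral uses Gauss-Hermite
    quadrature over the log-normal.
    """
    lam = config.event_rate if event_rate is None else event_rate
    q = (config.episode_probability(arm) if episode_probability is None
         else episode_probability)
    med, sig = config.duration_params(arm)
    k = config.frailty_shape
    z = np.sqrt(2.0) * _GH_NODES
    t_min = med * np.exp(sig * z)
    w_h = np.maximum(t_min - 2.0 * config.event_margin / 60.0, 0.0) / 60.0
    none = (1.0 + lam * q * w_h / k) ** (-k)
    return float(1.0 - (_GH_WEIGHTS * none).sum() / np.sqrt(np.pi))


def calibrate_event_rate(config: SimulationConfig,
                         target: Optional[float] = None) -> float:
    """Event rate making the control-arm incidence hit its target."""
    target = config.control_incidence if target is None else target
    f = lambda lam: expected_incidence(config, "control", event_rate=lam) - target
    return float(brentq(f, 1e-3, 50.0, xtol=1e-10))


def calibrate_treatment_efficacy(config: SimulationConfig,
                                 target: Optional[float] = None) -> float:
    """Efficacy making the intervention-arm incidence hit its target,
    given the configured event rate and alert sensitivity."""
    target = config.intervention_incidence if target is None else target

    def f(eff: float) -> float:
        q = 1.0 - config.alert_sensitivity * eff
        return expected_incidence(config, "intervention",
                                  episode_probability=q) - target

    if f(1.0) > 0:
        raise ConfigError(
            "intervention incidence target unreachable at this alert sensitivity"
        )
    return float(brentq(f, 0.0, 1.0, xtol=1e-10))


# ---------------------------------------------------------------------------
# surgery simulation
# ---------------------------------------------------------------------------

def _trapezoid_pulse(t: np.ndarray, start: float, ramp: float, hold: float,
                     depth: float) -> np.ndarray:
    """Dip profile: 0 -> depth over ``ramp``, hold, back to 0 over ``ramp``."""
    knots = np.array([start, start + ramp, start + ramp + hold,
                      start + 2 * ramp + hold])
    vals = np.array([0.0, depth, depth, 0.0])
    return np.interp(t, knots, vals, left=0.0, right=0.0)


def simulate_surgery(
    arm: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "sim",
) -> Tuple[MAPSeries, List[dict]]:
    """One surgery: MAP series plus an auditable event log.

    The log records every hypotension-inducing event with its alert status,
    the policy recommendation (proactive on alert, reactive at threshold
    crossing) and whether the event was averted or truncated.
    """
    if arm not in ARMS:
        raise ConfigError(f"unknown arm {arm!r}")
    med, sig = config.duration_params(arm)
    duration_min = float(med * np.exp(sig * rng.standard_normal()))
    duration_min = float(np.clip(duration_min, 45.0, 720.0))
    dur_s = duration_min * 60.0
    step = config.sampling_step
    t = step * np.arange(int(np.floor(dur_s / step)) + 1)

    # mean-reverting baseline noise (AR(1) = sampled Ornstein-Uhlenbeck)
    phi = np.exp(-step / config.reversion_time)
    innov_sd = config.noise_sd * np.sqrt(1.0 - phi ** 2)
    eps = rng.normal(0.0, innov_sd, size=t.size)
    eps[0] = rng.normal(0.0, config.noise_sd)
    noise = lfilter([1.0], [1.0, -phi], eps)

    # frailty-mixed Poisson events over the exposed window
    lo = config.event_margin
    hi = max(dur_s - config.event_margin, lo)
    window_h = (hi - lo) / 3600.0
    frailty = rng.gamma(config.frailty_shape, 1.0 / config.frailty_shape)
    n_events = rng.poisson(config.event_rate * frailty * window_h)
    starts = np.sort(rng.uniform(lo, hi, size=n_events))

    deficit = np.zeros_like(t)
    events: List[dict] = []
    for s in starts:
        nadir_target = rng.uniform(config.nadir_low, config.nadir_high)
        depth = config.baseline_map - nadir_target
        hold = float(config.hold_median * np.exp(config.hold_sigma
                                                 * rng.standard_normal()))
        hold = max(hold, config.hold_min)
        record: dict = {"time_s": float(s), "arm": arm, "type": "event",
                        "nadir_target": float(nadir_target)}
        averted = False
        if arm == "intervention":
            alerted = rng.random() < config.alert_sensitivity
            if alerted:
                alert_time = max(0.0, s + config.ramp_s - config.alert_lead)
                state = HemodynamicState(
                    map=float(config.baseline_map + noise[min(len(t) - 1,
                             int(alert_time // step))]),
                    hpi=float(rng.uniform(86.0, 99.0)),
                    svv=float(rng.uniform(5.0, 20.0)),
                    eadyn=float(rng.uniform(0.4, 1.2)),
                    dpdt_max=float(rng.uniform(300.0, 1200.0)),
                )
                rec = proactive_policy(state, config.rules)
                record.update(alert_time_s=alert_time, alerted=True,
                              action=rec.action, trigger=rec.trigger)
                averted = rng.random() < config.treatment_efficacy
            else:
                record.update(alerted=False)
        if averted:
            depth = max(0.0, config.baseline_map
                        - (config.threshold + config.avert_margin))
            hold *= 0.5
            record.update(outcome="averted")
        elif arm == "intervention" and record.get("alerted"):
            hold = min(hold, config.reactive_cap) * config.mitigation_hold
            record.update(outcome="truncated")
        else:
            # reactive standard care once MAP crosses the threshold
            cross_frac = (config.baseline_map - config.threshold) / depth
            cross_time = s + config.ramp_s * min(1.0, cross_frac)
            state = HemodynamicState(
                map=config.threshold - 1.0,
                hpi=0.0, svv=float(rng.uniform(5.0, 20.0)),
                eadyn=float(rng.uniform(0.4, 1.2)),
                dpdt_max=float(rng.uniform(300.0, 1200.0)),
            )
            rec = reactive_policy(state, config.rules)
            hold = min(hold, config.reactive_cap)
            record.update(reactive_time_s=float(cross_time),
                          action=rec.action, trigger=rec.trigger,
                          outcome="treated")
        deficit += _trapezoid_pulse(t, s, config.ramp_s, hold, depth)
        events.append(record)

    values = np.maximum(config.baseline_map + noise - deficit, 30.0)
    series = MAPSeries(patient_id=patient_id, times=t, values=values,
                       surgery_duration=duration_min,
                       nominal_step=step)
    return series, events


def simulate_biomarkers(
    summary,
    arm: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "sim",
) -> Tuple[BiomarkerPanel, BiomarkerPanel]:
    """T0/T2 panels for one patient given their burden summary."""
    pre_vals: Dict[str, float] = {}
    post_vals: Dict[str, float] = {}
    for analyte in ANALYTES:
        spec = config.biomarkers[analyte]
        pre = spec.baseline_median * np.exp(spec.baseline_sigma
                                            * rng.standard_normal())
        drive = 0.0
        if spec.key is not None:
            metric = summary.outcome(spec.key)
            drive = spec.slope * np.arcsinh(metric / spec.scale)
        delta = drive + spec.noise_sd * rng.standard_normal()
        post = pre + delta
        if post < 0:
            logger.debug("truncated negative %s at 0 for %s", analyte, patient_id)
            post = 0.0
        pre_vals[analyte] = float(pre)
        post_vals[analyte] = float(post)
    return (
        BiomarkerPanel(patient_id=patient_id, timepoint="T0", **pre_vals),
        BiomarkerPanel(patient_id=patient_id, timepoint="T2", **post_vals),
    )


def simulate_trial(
    config: SimulationConfig,
    seed: Optional[int] = None,
    return_events: bool = False,
):
    """A full two-arm trial, reproducible from (config, seed).

    Randomizes arms in permuted blocks, simulates every surgery and biomarker
    pair, and returns a :class:`~hypotrial.series.TrialDataset` with burden
    summaries attached (``return_events=True`` additionally returns the
    per-patient event logs).
    """
    seed = config.seed if seed is None else seed
    n_total = 2 * config.n_per_arm
    try:
        arms = randomize_blocks(n_total, config.block_sizes, seed=seed)
    except ConfigError:
        # tiny trials that the configured blocks cannot compose: one balanced
        # block keeps the 1:1 allocation contract
        logger.warning(
            "block sizes %s cannot compose %d patients; using a single "
            "balanced block", config.block_sizes, n_total)
        arms = randomize_blocks(n_total, (n_total,), seed=seed)
    patients: List[Patient] = []
    logs: Dict[str, List[dict]] = {}
    mcfg = MetricsConfig()
    for i, arm in enumerate(arms):
        pid = f"P{i + 1:03d}"
        rng = _rng(seed, 1, i)
        series, events = simulate_surgery(arm, config, rng, patient_id=pid)
        summary = summarize(series, threshold=config.threshold, config=mcfg)
        pre, post = simulate_biomarkers(summary, arm, config, _rng(seed, 2, i),
                                        patient_id=pid)
        patients.append(Patient(patient_id=pid, arm=arm, series=series,
                                pre_panel=pre, post_panel=post,
                                summary=summary))
        logs[pid] = events
    trial = TrialDataset(patients=patients)
    if return_events:
        return trial, logs
    return trial


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

POWER_TESTS = ("pooled_z", "unpooled_z", "t")


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo power estimate with its binomial standard error."""

    power: float
    se: float
    reps: int
    test: str
    n_per_arm: int
    alpha: float


def power_simulation(
    p1: float,
    p2: float,
    n_per_arm: int = 20,
    alpha: float = 0.05,
    reps: int = 20000,
    seed: int = 0,
    test: str = "pooled_z",
) -> PowerResult:
    """Monte-Carlo power of a two-sided two-group comparison of incidences.

    Each replicate draws ``n_per_arm`` Bernoulli outcomes per arm and applies
    the chosen test at level ``alpha``:

    * ``pooled_z`` (default) — score z-test with pooled variance, the test
      underlying the classical two-proportion sample-size formula;
    * ``unpooled_z`` — Wald z-test;
    * ``t`` — Welch two-sample t-test on the 0/1 encodings.
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ConfigError("incidences must lie strictly in (0, 1)")
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    if test not in POWER_TESTS:
        raise ConfigError(f"unknown test {test!r}; choose from {POWER_TESTS}")
    rng = _rng(seed, 0xA11)
    n = n_per_arm
    x = rng.binomial(n, p1, size=reps)
    y = rng.binomial(n, p2, size=reps)
    ph1 = x / n
    ph2 = y / n
    d = ph1 - ph2
    if test == "pooled_z":
        pbar = (x + y) / (2.0 * n)
        se = np.sqrt(2.0 * pbar * (1.0 - pbar) / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, np.abs(d) / se, 0.0)
        reject = z > _norm.ppf(1.0 - alpha / 2.0)
    elif test == "unpooled_z":
        se = np.sqrt(ph1 * (1 - ph1) / n + ph2 * (1 - ph2) / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, np.abs(d) / se,
                         np.where(d != 0, np.inf, 0.0))
        reject = z > _norm.ppf(1.0 - alpha / 2.0)
    else:  # Welch t on 0/1 encodings
        v1 = ph1 * (1 - ph1) * n / (n - 1)
        v2 = ph2 * (1 - ph2) * n / (n - 1)
        se = np.sqrt(v1 / n + v2 / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, np.abs(d) / se,
                             np.where(d != 0, np.inf, 0.0))
            df = np.where(se > 0,
                          (v1 / n + v2 / n) ** 2
                          / ((v1 / n) ** 2 / (n - 1) + (v2 / n) ** 2 / (n - 1)),
                          1.0)
            df = np.where(np.isfinite(df) & (df >= 1), df, 1.0)
        reject = tstat > _t_dist.ppf(1.0 - alpha / 2.0, df)
    power = float(reject.mean())
    se_est = float(np.sqrt(power * (1.0 - power) / reps))
    return PowerResult(power=power, se=se_est, reps=reps, test=test,
                       n_per_arm=n_per_arm, alpha=alpha)
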