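"""Biomarker panels and their association with hypotension burden.

Eight serum analytes are tracked at two draws — T0 (pre-induction) and T2
(end of surgery):

====================  =========  ==========================================
field                 unit       marker of
====================  =========  ==========================================
``ngal``              ng/mL      kidney injury (neutrophil gelatinase-
                                 associated lipocalin)
``nse``               ng/mL      brain injury (neuron-specific enolase)
``hif1a``             ng/mL      hypoxia signalling (HIF-1 alpha)
``s100b``             pg/mL      brain injury (S100B protein)
``acetyl_coa``        pmol/uL    metabolic rewiring
``hs_troponin``       pg/mL      myocardial injury (high-sensitivity
                                 cardiac troponin)
``looh``              nmol/uL    lipid peroxidation (lipid hydroperoxides)
``gsh``               nmol/uL    antioxidant reserve (reduced glutathione)
====================  =========  ==========================================

The analysis works on post-minus-pre deltas by default (``value_mode=
"delta"``): the intraoperative change is what hypotension burden can
plausibly drive, and any assay offset common to both draws cancels.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .series import ARMS, TrialDataset
from .stats import (
    CorrelationResult,
    GroupComparison,
    InsufficientDataError,
    compare_groups,
    spearman,
)

TIMEPOINTS = ("T0", "T2")

ANALYTES: Tuple[str, ...] = (
    "ngal", "nse", "hif1a", "s100b", "acetyl_coa", "hs_troponin", "looh", "gsh",
)

ANALYTE_UNITS: Dict[str, str] = {
    "ngal": "ng/mL", "nse": "ng/mL", "hif1a": "ng/mL", "s100b": "pg/mL",
    "acetyl_coa": "pmol/uL", "hs_troponin": "pg/mL", "looh": "nmol/uL",
    "gsh": "nmol/uL",
}

BURDEN_OUTCOMES: Tuple[str, ...] = (
    "n_episodes", "total_time", "relative_time", "twa",
)


class PairingError(ValueError):
    """Panels do not form a valid T0/T2 pair for one patient."""


@dataclass(frozen=True)
class BiomarkerPanel:
    """One patient's analyte concentrations at a single timepoint."""

    patient_id: str
    timepoint: str
    ngal: float
    nse: float
    hif1a: float
    s100b: float
    acetyl_coa: float
    hs_troponin: float
    looh: float
    gsh: float

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        for name in ANALYTES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0 (got {v!r})")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, a) for a in ANALYTES], dtype=float)


@dataclass(frozen=True)
class BiomarkerDelta:
    """Elementwise T2 - T0 change for one patient (same units as the panel)."""

    patient_id: str
    ngal: float
    nse: float
    hif1a: float
    s100b: float
    acetyl_coa: float
    hs_troponin: float
    looh: float
    gsh: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, a) for a in ANALYTES], dtype=float)


def compute_deltas(pre: BiomarkerPanel, post: BiomarkerPanel) -> BiomarkerDelta:
    """Post-minus-pre change; both panels must belong to the same patient."""
    if pre.patient_id != post.patient_id:
        raise PairingError(
            f"panels belong to different patients: {pre.patient_id!r} vs "
            f"{post.patient_id!r}"
        )
    if pre.timepoint != "T0" or post.timepoint != "T2":
        raise PairingError(
            f"expected (T0, T2) pair, got ({pre.timepoint}, {post.timepoint})"
        )
    values = {a: getattr(post, a) - getattr(pre, a) for a in ANALYTES}
    return BiomarkerDelta(patient_id=pre.patient_id, **values)


def _patient_values(patient, value_mode: str) -> Optional[np.ndarray]:
    if value_mode == "delta":
        if patient.pre_panel is None or patient.post_panel is None:
            return None
        return compute_deltas(patient.pre_panel, patient.post_panel).as_array()
    if value_mode == "post":
        if patient.post_panel is None:
            return None
        return patient.post_panel.as_array()
    raise ValueError(f"unknown value_mode {value_mode!r}")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Spearman rho and p over analytes + burden outcomes.

    ``rho`` and ``p`` are square DataFrames over ``labels``; cells with fewer
    than 3 complete pairs (or a constant vector) are NaN — unavailable, never
    imputed.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    @property
    def labels(self) -> List[str]:
        return list(self.rho.index)


def burden_correlations(
    trial: TrialDataset,
    value_mode: str = "delta",
) -> CorrelationMatrix:
    """Full Spearman matrix over the 8 analytes and the 4 burden outcomes.

    Analyte values are post-surgery levels (``value_mode='post'``) or
    post-minus-pre deltas (default).  Every patient contributing a cell needs
    the relevant panel(s) and a burden summary.
    """
    labels = list(ANALYTES) + list(BURDEN_OUTCOMES)
    columns: Dict[str, List[float]] = {lab: [] for lab in labels}
    for patient in trial:
        panel = _patient_values(patient, value_mode)
        if panel is None or patient.summary is None:
            vals = {lab: np.nan for lab in labels}
        else:
            vals = dict(zip(ANALYTES, panel))
            vals.update({o: patient.summary.outcome(o) for o in BURDEN_OUTCOMES})
        for lab in labels:
            columns[lab].append(vals[lab])
    data = pd.DataFrame(columns)
    k = len(labels)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    npairs = np.zeros((k, k), dtype=int)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pval, 0.0)
    for i, j in itertools.combinations(range(k), 2):
        x = data[labels[i]].to_numpy()
        y = data[labels[j]].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        npairs[i, j] = npairs[j, i] = int(ok.sum())
        if ok.sum() < 3:
            continue
        try:
            res = spearman(x[ok], y[ok])
        except (InsufficientDataError, ValueError):
            continue
        rho[i, j] = rho[j, i] = res.rho
        pval[i, j] = pval[j, i] = res.p_value
    np.fill_diagonal(npairs, [int(np.isfinite(data[l]).sum()) for l in labels])
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=labels, columns=labels),
        p=pd.DataFrame(pval, index=labels, columns=labels),
        n=pd.DataFrame(npairs, index=labels, columns=labels),
    )


def group_biomarker_differences(
    trial: TrialDataset,
    conf: float = 0.95,
    alpha: float = 0.05,
) -> Dict[str, GroupComparison]:
    """Per-analyte Hodges-Lehmann difference of deltas, intervention - control."""
    deltas = {arm: [] for arm in ARMS}
    for patient in trial:
        if patient.pre_panel is None or patient.post_panel is None:
            raise PairingError(
                f"patient {patient.patient_id!r} lacks a paired T0/T2 panel"
            )
        deltas[patient.arm].append(
            compute_deltas(patient.pre_panel, patient.post_panel).as_array()
        )
    for arm in ARMS:
        if not deltas[arm]:
            raise InsufficientDataError(f"arm {arm!r} has no paired panels")
    out: Dict[str, GroupComparison] = {}
    arrays = {arm: np.vstack(deltas[arm]) for arm in ARMS}
    for idx, analyte in enumerate(ANALYTES):
        out[analyte] = compare_groups(
            arrays["intervention"][:, idx], arrays["control"][:, idx],
            outcome_name=analyte, conf=conf, alpha=alpha,
        )
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_panels(path: str | Path) -> List[BiomarkerPanel]:
    """Read panels from a wide CSV: patient_id, timepoint, one column per
    analyte (units as documented on :class:`BiomarkerPanel`)."""
    df = pd.read_csv(path)
    required = {"patient_id", "timepoint", *ANALYTES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    panels = []
    for row in df.itertuples(index=False):
        panels.append(BiomarkerPanel(
            patient_id=str(row.patient_id), timepoint=str(row.timepoint),
            **{a: float(getattr(row, a)) for a in ANALYTES},
        ))
    return panels


def write_panels(panels: Iterable[BiomarkerPanel], path: str | Path) -> None:
    rows = []
    for p in panels:
        row = {"patient_id": p.patient_id, "timepoint": p.timepoint}
        row.update({a: getattr(p, a) for a in ANALYTES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def attach_panels(trial: TrialDataset, panels: Iterable[BiomarkerPanel]) -> None:
    """Attach T0/T2 panels to the matching patients in place."""
    by_patient = {p.patient_id: p for p in trial}
    for panel in panels:
        patient = by_patient.get(panel.patient_id)
        if patient is None:
            raise PairingError(f"panel for unknown patient {panel.patient_id!r}")
        if panel.timepoint == "T0":
            patient.pre_panel = panel
        else:
            patient.post_panel = panel
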