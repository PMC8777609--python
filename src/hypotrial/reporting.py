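"""Table-shaped report output and run manifests.

Three report shapes mirror how hypotension trials are usually presented:

* per-patient burden summaries (one row per surgery, four outcomes);
* arm comparisons: median (IQR) per arm, Hodges-Lehmann difference with CI
  and Mann-Whitney p per outcome (and per biomarker delta);
* the analyte-by-outcome Spearman correlation matrix with significance flags.

Every output directory receives exactly one ``manifest.json`` capturing the
command, configuration snapshot, seeds, inputs and outputs so a run can be
reproduced from the manifest alone.
"""
from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import CorrelationMatrix
from .stats import GroupComparison


def summaries_frame(trial) -> pd.DataFrame:
    """One row per patient: arm plus the four burden outcomes."""
    rows = []
    for p in trial:
        s = p.summary
        rows.append({
            "patient_id": p.patient_id,
            "arm": p.arm,
            "surgery_duration_min": s.surgery_duration if s else np.nan,
            "n_episodes": s.n_episodes if s else np.nan,
            "total_time_min": s.total_time if s else np.nan,
            "relative_time_pct": s.relative_time if s else np.nan,
            "area_under_threshold_mmhg_min": s.area_under_threshold if s else np.nan,
            "twa_mmhg": s.twa if s else np.nan,
        })
    return pd.DataFrame(rows)


def comparisons_frame(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    """Arm-comparison table: one outcome per row, intervention vs control."""
    rows = []
    for c in comparisons:
        rows.append({
            "outcome": c.outcome_name,
            "intervention_median": c.median_a,
            "intervention_iqr": c.iqr_a,
            "control_median": c.median_b,
            "control_iqr": c.iqr_b,
            "median_difference": c.hl_difference,
            "ci_low": c.ci_low,
            "ci_high": c.ci_high,
            "p_value": c.p_value,
            "significant": c.significant,
        })
    return pd.DataFrame(rows)


def correlation_frames(matrix: CorrelationMatrix) -> Dict[str, pd.DataFrame]:
    """rho / p / flags views of a correlation matrix (flags: * p<0.05,
    ** p<0.001, blank otherwise, '.' unavailable)."""
    flags = matrix.p.copy().astype(object)
    for i in flags.index:
        for j in flags.columns:
            p = matrix.p.loc[i, j]
            if not np.isfinite(p):
                flags.loc[i, j] = "."
            elif p < 0.001:
                flags.loc[i, j] = "**"
            elif p < 0.05:
                flags.loc[i, j] = "*"
            else:
                flags.loc[i, j] = ""
    return {"rho": matrix.rho, "p": matrix.p, "flags": flags}


def write_reports(
    out_dir: str | Path,
    *,
    summaries: Optional[pd.DataFrame] = None,
    comparisons: Optional[pd.DataFrame] = None,
    biomarker_comparisons: Optional[pd.DataFrame] = None,
    correlations: Optional[CorrelationMatrix] = None,
) -> List[Path]:
    """Write the available reports as CSV + one JSON bundle; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    bundle: Dict[str, object] = {}

    def _csv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=index, float_format="%.10g")
        written.append(path)

    if summaries is not None:
        _csv(summaries, "patient_summaries")
        bundle["patient_summaries"] = summaries.to_dict(orient="records")
    if comparisons is not None:
        _csv(comparisons, "arm_comparisons")
        bundle["arm_comparisons"] = comparisons.to_dict(orient="records")
    if biomarker_comparisons is not None:
        _csv(biomarker_comparisons, "biomarker_comparisons")
        bundle["biomarker_comparisons"] = biomarker_comparisons.to_dict(orient="records")
    if correlations is not None:
        frames = correlation_frames(correlations)
        _csv(frames["rho"], "correlations_rho", index=True)
        _csv(frames["p"], "correlations_p", index=True)
        _csv(frames["flags"], "correlations_flags", index=True)
        bundle["correlations"] = {
            "rho": frames["rho"].where(np.isfinite(frames["rho"]), None).to_dict(),
            "p": frames["p"].where(np.isfinite(frames["p"]), None).to_dict(),
        }
    path = out_dir / "report.json"
    path.write_text(json.dumps(bundle, indent=2, sort_keys=True, default=float))
    written.append(path)
    return written


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record for one CLI run."""

    command: str
    seed: Optional[int]
    config: Dict[str, object]
    inputs: List[str]
    outputs: List[str]
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True, default=str))
        return path
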