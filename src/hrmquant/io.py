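"""File formats for melt exports, cohort tables, and JSON reports.

Melt exports use a long-format CSV dialect (one row per temperature
reading): columns ``well, sample, role, known_fraction, temperature, rfu``;
UTF-8, '.' decimal separator, comma delimiter.  Cohort tables use the
:data:`~hrmquant.cohort_analysis.COHORT_COLUMNS` schema.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort_analysis import COHORT_COLUMNS, CoxResult, CutoffScanResult
from .errors import CohortFormatError
from .hrm_quantification import CalibrationModel, CalibrationStandard, MethylationCall
from .melt_simulator import MeltCurve

MELT_COLUMNS = ["well", "sample", "role", "known_fraction", "temperature", "rfu"]


def write_melt_csv(curves: Iterable[MeltCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, f in zip(c.temperatures, c.rfu):
            rows.append(
                {
                    "well": c.well_id,
                    "sample": c.sample_id,
                    "role": c.role,
                    "known_fraction": "" if c.known_fraction is None else repr(float(c.known_fraction)),
                    "temperature": repr(float(t)),
                    "rfu": repr(float(f)),
                }
            )
    pd.DataFrame(rows, columns=MELT_COLUMNS).to_csv(path, index=False)


def read_melt_csv(path: str | Path) -> list[MeltCurve]:
    """Read a long-format melt export, grouping rows by well.

    Rows may arrive in any order; each well's readings are sorted by
    temperature.  Malformed rows are reported with their line numbers.
    """
    try:
        df = pd.read_csv(path, dtype={"well": str, "sample": str, "role": str},
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise CohortFormatError(f"{path}: empty file; expected header {MELT_COLUMNS}")
    missing = [c for c in MELT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing columns {missing}")
    bad_lines = []
    for col in ("temperature", "rfu"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        bad_lines.extend(int(i) + 2 for i in bad)  # +2: header + 1-based
        df[col] = vals
    if bad_lines:
        raise CohortFormatError(f"{path}: non-numeric values at lines {sorted(set(bad_lines))}")
    if df[["temperature", "rfu"]].isna().any().any():
        rows = df.index[df[["temperature", "rfu"]].isna().any(axis=1)]
        raise CohortFormatError(f"{path}: missing values at lines {[int(i) + 2 for i in rows]}")

    curves: list[MeltCurve] = []
    for well, g in df.groupby("well", sort=True):
        g = g.sort_values("temperature")
        temps = g["temperature"].to_numpy(float)
        if np.any(np.diff(temps) <= 0):
            raise CohortFormatError(f"{path}: duplicate temperatures in well {well}")
        kf = g["known_fraction"].iloc[0]
        curves.append(
            MeltCurve(
                well_id=str(well),
                sample_id=str(g["sample"].iloc[0]),
                replicate_index=0,
                temperatures=temps,
                rfu=g["rfu"].to_numpy(float),
                role=str(g["role"].iloc[0]),
                known_fraction=None if pd.isna(kf) else float(kf),
            )
        )
    return curves


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CohortFormatError(f"{path}: empty file; expected header {COHORT_COLUMNS}")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing columns {missing}")
    return df


def write_calls_csv(calls: Sequence[MethylationCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "assay": c.assay,
                "percent_methylation": c.percent_methylation,
                "status": c.status,
                "cutoff": c.cutoff_used,
                "extrapolation_flag": c.extrapolated,
                "replicate_range": c.replicate_range,
            }
            for c in calls
        ]
    ).to_csv(path, index=False)


def write_calibration_report(
    model: CalibrationModel,
    standards: Sequence[CalibrationStandard],
    path: str | Path,
) -> None:
    report = {
        "slope": model.slope,
        "intercept": model.intercept,
        "r_squared": model.r_squared,
        "auc_range": list(model.auc_range),
        "standards": [
            {
                "known_methylation": s.known_methylation,
                "mean_auc": s.auc,
                "replicate_aucs": list(s.replicate_aucs),
            }
            for s in standards
        ],
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def write_cox_report(results: Sequence[CoxResult], path: str | Path) -> None:
    report = [
        {
            "covariate": r.covariate,
            "hazard_ratio": r.hazard_ratio,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_value": r.p_value,
        }
        for r in results
    ]
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def write_cutoff_scan_report(result: CutoffScanResult, path: str | Path) -> None:
    report = {
        "cutoffs": list(result.cutoffs),
        "auc_pfs": list(result.auc_pfs),
        "auc_os": list(result.auc_os),
        "best_cutoff": result.best_cutoff,
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
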