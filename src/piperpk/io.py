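"""Dataset and report I/O.

Observation datasets use the pharmacometric long format (NONMEM dialect):
one row per dose or observation with columns

    ID, OCC, TIME, AMT, RATE, DUR, DV, MDV, EVID, CRCL, ARM, BLQ

plus optional covariate columns (AGE, WT, SEX, ALB).  Times are decimal
hours; a pre-dose sample drawn 10 min before a dose appears at
``dose_time - 0.1667``.  Dose rows carry EVID=1, AMT (mg) and DUR (h);
observation rows carry EVID=0 and DV (mg/L).  MDV=1 marks records whose
DV is to be ignored by estimation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ObservationDataset

__all__ = [
    "read_dataset",
    "write_dataset",
    "render_pta_grid",
    "annotate_pta_grid",
    "DatasetValidationError",
]

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "MDV", "EVID")


class DatasetValidationError(ValueError):
    """A malformed observation dataset (message names the offending rows)."""


def write_dataset(dataset: ObservationDataset, path: str | Path, truth_path=None) -> None:
    """Write records (and optionally the truth sidecar) as CSV."""
    dataset.records.to_csv(path, index=False)
    if truth_path is not None:
        if dataset.truth is None:
            raise ValueError("dataset has no truth sidecar")
        dataset.truth.to_csv(truth_path, index=False)


def read_dataset(path: str | Path) -> ObservationDataset:
    """Read and validate a long-format CSV dataset."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise DatasetValidationError(f"{path}: file contains no records")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"{path}: missing required columns {missing}")
    if "OCC" not in df.columns:
        df["OCC"] = 1
    if "BLQ" not in df.columns:
        df["BLQ"] = 0

    bad = df.index[df["TIME"] < 0].tolist()
    if bad:
        raise DatasetValidationError(f"{path}: negative TIME in rows {_fmt(bad)}")
    doses = df[df["EVID"] == 1]
    bad = doses.index[doses["AMT"].isna() | (doses["AMT"] <= 0)].tolist()
    if bad:
        raise DatasetValidationError(f"{path}: dose rows without positive AMT: {_fmt(bad)}")
    if "DUR" in df.columns:
        bad = doses.index[doses["DUR"].isna() | (doses["DUR"] <= 0)].tolist()
    elif "RATE" in df.columns:
        df.loc[df["EVID"] == 1, "DUR"] = doses["AMT"] / doses["RATE"]
        bad = []
    else:
        raise DatasetValidationError(f"{path}: need a DUR or RATE column for infusions")
    if bad:
        raise DatasetValidationError(f"{path}: dose rows without positive DUR: {_fmt(bad)}")

    # every observation must be preceded by a dose for that subject
    obs = df[df["EVID"] == 0]
    first_dose = doses.groupby("ID")["TIME"].min()
    bad = []
    for idx, row in obs.iterrows():
        t0 = first_dose.get(row["ID"], np.inf)
        if row["TIME"] < t0:
            bad.append(idx)
    if bad:
        raise DatasetValidationError(
            f"{path}: observations before any dose in rows {_fmt(bad)}"
        )
    return ObservationDataset(records=df)


def _fmt(rows: list, limit: int = 10) -> str:
    shown = ", ".join(str(r + 2) for r in rows[:limit])  # 1-based + header line
    return shown + (", ..." if len(rows) > limit else "")


def render_pta_grid(results: pd.DataFrame, pta_threshold: float = 90.0) -> str:
    """Format a tidy PTA grid as per-regimen panels.

    Cells attaining ``pta_threshold`` are marked with ``*`` (the published
    table shades them); the tidy frame gains an ``attains_90`` column via
    :func:`annotate_pta_grid`.  Missing cells render as ``--``.
    """
    targets = sorted(results["target"].unique())
    crcls = sorted(results["crcl"].unique())
    lines = []
    header = "CrCL    " + "".join(f"{t:>8g}" for t in targets)
    for regimen, grp in results.groupby("regimen", sort=False):
        lines.append(f"--- {regimen} (target fCmin or fCss, mg/L)")
        lines.append(header)
        cell = grp.set_index(["crcl", "target"])["pta"]
        for c in crcls:
            row = [f"{c:<8g}"]
            for t in targets:
                try:
                    v = cell.loc[(c, t)]
                    row.append(f"{v:>7.1f}" + ("*" if v >= pta_threshold else " "))
                except KeyError:
                    row.append(f"{'--':>8}")
            lines.append("".join(row))
    lines.append(f"(* = PTA >= {pta_threshold:g}%)")
    return "\n".join(lines)


def annotate_pta_grid(results: pd.DataFrame, pta_threshold: float = 90.0) -> pd.DataFrame:
    """Tidy PTA frame with a boolean ``attains_90`` column added."""
    out = results.copy()
    out["attains_90"] = out["pta"] >= pta_threshold
    return out
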