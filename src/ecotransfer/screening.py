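"""Threshold screening of stable-element levels against literature limits.

Each threshold entry carries a single value (toxic-effect level) or a band
(adequate range) in mg/kg dry mass; thresholds published on a wet-mass basis
are recalculated to dry mass by multiplying with the entry's dry-mass factor
(wet-to-dry mass ratio of the tissue) before comparison. Measured ranges are
compared per analyte x tissue and flagged:

    below     observed max below the threshold (or below an adequate band)
    within    observed range inside an adequate band
    spans     observed range straddles a band bound
    exceeds   observed min above the threshold / band

A packaged table of literature thresholds ships with the module; it is a
plain CSV users can edit, because thresholds are literature constants, not
code.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CohortDataset, ValidationError

__all__ = ["ThresholdEntry", "load_thresholds", "screen_thresholds"]

THRESHOLD_KINDS = ("toxic", "adequate", "high")

_MASS_IN_MG_PER_KG = {"ug/kg": 1e-3, "mg/kg": 1.0, "g/kg": 1e3}


@dataclass(frozen=True)
class ThresholdEntry:
    analyte: str
    tissue: str
    threshold_value: float  # mg/kg on the published basis (lower bound for bands)
    threshold_kind: str
    threshold_high: float | None = None  # upper bound for adequate bands
    source: str = ""
    dry_mass_factor_applied: float | None = None

    def __post_init__(self) -> None:
        if self.threshold_value <= 0:
            raise ValidationError("threshold_value must be > 0")
        if self.threshold_kind not in THRESHOLD_KINDS:
            raise ValidationError(f"unknown threshold kind {self.threshold_kind!r}")
        if self.threshold_high is not None and self.threshold_high < self.threshold_value:
            raise ValidationError("threshold_high must be >= threshold_value")


def load_thresholds(path=None) -> list[ThresholdEntry]:
    """Load threshold entries from a CSV (default: the packaged table)."""
    if path is None:
        path = importlib.resources.files("ecotransfer.data") / "toxicity_thresholds.csv"
    df = pd.read_csv(path, comment="#")
    out = []
    for _, row in df.iterrows():
        high = row.get("threshold_high")
        factor = row.get("dry_mass_factor_applied")
        out.append(
            ThresholdEntry(
                analyte=str(row["analyte"]),
                tissue=str(row["tissue"]),
                threshold_value=float(row["threshold_value"]),
                threshold_kind=str(row["threshold_kind"]),
                threshold_high=float(high) if pd.notna(high) else None,
                source=str(row.get("source", "")),
                dry_mass_factor_applied=float(factor) if pd.notna(factor) else None,
            )
        )
    return out


def _observed_range_mg_kg(df: pd.DataFrame, analyte: str, tissue: str):
    g = df[(df["analyte"] == analyte) & (df["tissue"] == tissue) & (~df["censored"])]
    if g.empty:
        return None
    units = g["unit"].unique()
    if len(units) != 1:
        raise ValidationError(f"mixed units for {analyte}/{tissue}")
    unit = units[0]
    if unit not in _MASS_IN_MG_PER_KG:
        raise ValidationError(
            f"threshold screening needs a mass unit, got {unit!r} for {analyte}"
        )
    scale = _MASS_IN_MG_PER_KG[unit]
    values = g["value"].to_numpy() * scale
    if (g["basis"] != "dry").any():
        raise ValidationError("threshold screening expects dry-basis measurements")
    return float(values.min()), float(values.max())


def _flag(lo: float, hi: float, entry: ThresholdEntry) -> str:
    t_lo = entry.threshold_value
    t_hi = entry.threshold_high
    if t_hi is not None:
        if hi < t_lo:
            return "below"
        if lo > t_hi:
            return "exceeds"
        if lo >= t_lo and hi <= t_hi:
            return "within"
        return "spans"
    # single toxic / high / adequate-floor threshold
    if hi <= t_lo:
        return "within" if entry.threshold_kind == "toxic" else "below"
    if lo > t_lo:
        return "exceeds"
    return "spans"


def screen_thresholds(dataset: CohortDataset, thresholds=None) -> pd.DataFrame:
    """Compare observed detected ranges with literature thresholds.

    Returns one row per matching threshold entry with the observed min-max
    (mg/kg dm), the dry-mass threshold used (wet-mass entries multiplied by
    their dry-mass factor), and the flag. Entries whose analyte x tissue has
    no detected measurement are skipped.
    """
    if thresholds is None:
        thresholds = load_thresholds()
    df = dataset.measurements_frame()
    rows = []
    for e in thresholds:
        rng = _observed_range_mg_kg(df, e.analyte, e.tissue)
        if rng is None:
            continue
        lo, hi = rng
        f = e.dry_mass_factor_applied
        t_lo = e.threshold_value * (f if f else 1.0)
        t_hi = e.threshold_high * (f if f else 1.0) if e.threshold_high is not None else None
        adjusted = ThresholdEntry(
            e.analyte, e.tissue, t_lo, e.threshold_kind, t_hi, e.source, None
        )
        rows.append(
            {
                "analyte": e.analyte,
                "tissue": e.tissue,
                "observed_min": lo,
                "observed_max": hi,
                "threshold_value": t_lo,
                "threshold_high": t_hi if t_hi is not None else np.nan,
                "threshold_kind": e.threshold_kind,
                "flag": _flag(lo, hi, adjusted),
                "source": e.source,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "analyte",
            "tissue",
            "observed_min",
            "observed_max",
            "threshold_value",
            "threshold_high",
            "threshold_kind",
            "flag",
            "source",
        ],
    )
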