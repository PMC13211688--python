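"""Whole-organism concentrations and soil-to-organism concentration ratios.

CR_wo-soil = c_wo / c_soil, with c_wo the wet-mass whole-organism
concentration and c_soil the dry-mass soil concentration of the same analyte.
The whole organism is represented by one proxy tissue per analyte (muscle for
Cs-137, Ca, Cd and Cu; bone for Mn and Pb; liver for Zn), converted from its
dry-mass value with the tissue factor; Pb measured in bone uses the dedicated
bone-to-whole-organism factor 0.16, which already embeds the 0.8 dry/wet bone
mass ratio. Radionuclide soil entries are decay-corrected from their own
reference date to each animal's sampling date before averaging, so per-animal
CRs are computed first and only then summarised (AM +/- SD, GM, range).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CohortDataset,
    RadionuclideSpec,
    SoilReference,
    TransferConfig,
    ValidationError,
    DEFAULT_NUCLIDES,
)
from .physics import decay_factor, elapsed_years, to_wet_basis

__all__ = [
    "CRResult",
    "whole_organism_concentration",
    "concentration_ratio",
    "soil_reference_for",
    "cr_table",
    "cr_frame",
]

logger = logging.getLogger(__name__)

_UNIT_FAMILY = {"Bq/kg": "Bq/kg", "ug/kg": "mass", "mg/kg": "mass", "g/kg": "mass"}
_MASS_IN_MG_PER_KG = {"ug/kg": 1e-3, "mg/kg": 1.0, "g/kg": 1e3}


@dataclass(frozen=True)
class CRResult:
    """Per-animal concentration ratios and their summary for one analyte."""

    analyte: str
    animal_ids: tuple[str, ...]
    per_animal_cr: tuple[float, ...]
    am: float
    sd: float
    gm: float
    min: float
    max: float
    proxy_tissue: str
    soil_value_used: float  # at the mean sampling date, for reporting


def whole_organism_concentration(
    dataset: CohortDataset,
    analyte: str,
    config: TransferConfig,
    animal_id: str,
) -> float | None:
    """Wet-mass whole-organism concentration for one animal, or None if the
    animal has no detected proxy-tissue measurement (skipped with a warning).
    """
    try:
        proxy = config.proxy_tissue[analyte]
    except KeyError:
        raise ValidationError(f"no proxy tissue configured for analyte {analyte!r}")
    factor = config.factor_for(analyte, proxy)
    for m in dataset.measurements:
        if m.animal_id == animal_id and m.analyte == analyte and m.tissue == proxy:
            if m.censored:
                continue
            if m.basis == "wet":
                return m.value
            return to_wet_basis(m.value, factor)
    logger.warning(
        "animal %s has no detected %s in proxy tissue %s; skipped", animal_id, analyte, proxy
    )
    return None


def concentration_ratio(c_wo_wet: float, c_soil_dry: float) -> float:
    """Dimensionless CR = c_wo / c_soil; numerator and denominator must share
    units (checked by the callers that know the units)."""
    if c_soil_dry <= 0:
        raise ValidationError("soil concentration must be > 0")
    if c_wo_wet < 0:
        raise ValidationError("whole-organism concentration must be >= 0")
    return c_wo_wet / c_soil_dry


def _convert_soil_value(entry: SoilReference, target_unit: str) -> float:
    """Align a soil entry's unit with the tissue unit (mass units only)."""
    if entry.unit == target_unit:
        return entry.value
    fam_e = _UNIT_FAMILY.get(entry.unit)
    fam_t = _UNIT_FAMILY.get(target_unit)
    if fam_e != "mass" or fam_t != "mass":
        raise ValidationError(
            f"unit mismatch for {entry.analyte}: soil {entry.unit} vs tissue {target_unit}"
        )
    return entry.value * _MASS_IN_MG_PER_KG[entry.unit] / _MASS_IN_MG_PER_KG[target_unit]


def soil_reference_for(
    analyte: str,
    sampling_date: date,
    soil_table: Sequence[SoilReference],
    nuclide_specs: Mapping[str, RadionuclideSpec] = DEFAULT_NUCLIDES,
    target_unit: str | None = None,
) -> float:
    """Soil concentration for one analyte at one sampling date.

    Stable elements return the (mean of the) tabulated value(s) unchanged.
    Radionuclides decay-correct every entry from its own reference date to
    the sampling date, then average — correction before averaging, because
    entries may refer to different dates.
    """
    entries = [e for e in soil_table if e.analyte == analyte]
    if not entries:
        raise ValidationError(f"analyte {analyte!r} not present in the soil table")
    spec = nuclide_specs.get(analyte)
    values = []
    for e in entries:
        v = e.value if target_unit is None else _convert_soil_value(e, target_unit)
        if spec is not None:
            if e.reference_date is None:
                raise ValidationError(
                    f"radionuclide soil entry for {analyte!r} lacks a reference_date"
                )
            dt = elapsed_years(e.reference_date, sampling_date)
            v *= decay_factor(spec.half_life_years, dt)
        values.append(v)
    return float(np.mean(values))


def cr_table(
    dataset: CohortDataset,
    analytes: Sequence[str],
    config: TransferConfig,
    soil_table: Sequence[SoilReference],
    nuclide_specs: Mapping[str, RadionuclideSpec] = DEFAULT_NUCLIDES,
) -> list[CRResult]:
    """Per-animal CRs and their summaries; analytes with no eligible animal
    are omitted with a warning. Radionuclide and stable rows of the same
    element are separate entries (e.g. Pb-210 and stable Pb).
    """
    unit_by_analyte = {m.analyte: m.unit for m in dataset.measurements}
    results = []
    for analyte in analytes:
        ids, crs = [], []
        for animal in dataset.animals:
            c_wo = whole_organism_concentration(dataset, analyte, config, animal.animal_id)
            if c_wo is None:
                continue
            c_soil = soil_reference_for(
                analyte,
                animal.sampling_date,
                soil_table,
                nuclide_specs,
                target_unit=unit_by_analyte.get(analyte),
            )
            ids.append(animal.animal_id)
            crs.append(concentration_ratio(c_wo, c_soil))
        if not crs:
            logger.warning("no eligible animals for analyte %s; CR row omitted", analyte)
            continue
        arr = np.asarray(crs)
        mean_date = dataset.animals[len(dataset.animals) // 2].sampling_date
        results.append(
            CRResult(
                analyte=analyte,
                animal_ids=tuple(ids),
                per_animal_cr=tuple(float(c) for c in crs),
                am=float(arr.mean()),
                sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                gm=float(np.exp(np.mean(np.log(arr)))) if np.all(arr > 0) else 0.0,
                min=float(arr.min()),
                max=float(arr.max()),
                proxy_tissue=config.proxy_tissue[analyte],
                soil_value_used=soil_reference_for(
                    analyte,
                    mean_date,
                    soil_table,
                    nuclide_specs,
                    target_unit=unit_by_analyte.get(analyte),
                ),
            )
        )
    return results


def cr_frame(results: Sequence[CRResult]) -> pd.DataFrame:
    """Tidy CR table: one row per analyte."""
    rows = [
        {
            "analyte": r.analyte,
            "proxy_tissue": r.proxy_tissue,
            "n": len(r.per_animal_cr),
            "am": r.am,
            "sd": r.sd,
            "gm": r.gm,
            "min": r.min,
            "max": r.max,
            "soil_value_used": r.soil_value_used,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "analyte",
            "proxy_tissue",
            "n",
            "am",
            "sd",
            "gm",
            "min",
            "max",
            "soil_value_used",
        ],
    )
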