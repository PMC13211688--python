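"""Domain types and CSV I/O for tissue-distribution cohort data.

A cohort couples one table of sampled animals (biometrics, sampling date,
location) with one long-format table of per-tissue analyte measurements
(radionuclide massic activities in Bq/kg, stable-element levels in ug/kg or
mg/kg, on a stated dry or wet mass basis). Values reported only as "below the
decision threshold" are stored as the threshold itself with ``censored=True``
so that the censoring policy stays an explicit downstream choice rather than
an artefact of blank cells.

CSV conventions: comma-separated UTF-8, ISO-8601 dates, "." decimal mark.
Non-numeric tokens (e.g. "/") in optional biometric columns are read as
missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TISSUES",
    "REGIONS",
    "SEXES",
    "SchemaError",
    "ReferentialError",
    "ValidationError",
    "AnimalRecord",
    "Measurement",
    "RadionuclideSpec",
    "SoilReference",
    "TransferConfig",
    "CohortDataset",
    "DEFAULT_NUCLIDES",
    "default_transfer_config",
    "read_cohort",
    "write_cohort",
    "read_soil",
    "write_soil",
]

#: Closed vocabulary of sampled tissues.
TISSUES = ("muscle", "heart", "spleen", "lungs", "liver", "kidney", "bone")

REGIONS = ("North", "Central", "South")
SEXES = ("female", "male")

ANIMAL_COLUMNS = [
    "animal_id",
    "sampling_date",
    "latitude",
    "longitude",
    "region",
    "age_years",
    "sex",
    "body_mass_kg",
    "body_length_cm",
]

MEASUREMENT_COLUMNS = [
    "animal_id",
    "tissue",
    "analyte",
    "value",
    "unit",
    "basis",
    "censored",
    "rel_uncertainty",
]

SOIL_COLUMNS = ["analyte", "value", "unit", "basis", "reference_date", "source"]


class SchemaError(ValueError):
    """A CSV file does not have the documented columns."""


class ReferentialError(ValueError):
    """A measurement references an animal_id absent from the animal table."""


class ValidationError(ValueError):
    """A field violates a domain invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class AnimalRecord:
    """One sampled individual with biometrics and derived body condition.

    ``bci`` is the residual of body mass from an ordinary least squares fit of
    mass on body length over a reference population; it is derived, not read.
    """

    animal_id: str
    sampling_date: date
    latitude: float
    longitude: float
    region: str
    age_years: float
    sex: str
    body_mass_kg: float | None = None
    body_length_cm: float | None = None
    bci: float | None = None

    def __post_init__(self) -> None:
        _require(bool(self.animal_id), "animal_id must be non-empty")
        _require(isinstance(self.sampling_date, date), "sampling_date must be a date")
        _require(-90.0 <= self.latitude <= 90.0, f"latitude out of range: {self.latitude}")
        _require(-180.0 <= self.longitude <= 180.0, f"longitude out of range: {self.longitude}")
        _require(self.region in REGIONS, f"unknown region {self.region!r}")
        _require(self.age_years >= 0.0, f"age_years must be >= 0, got {self.age_years}")
        _require(self.sex in SEXES, f"unknown sex {self.sex!r}")
        for name in ("body_mass_kg", "body_length_cm"):
            v = getattr(self, name)
            if v is not None:
                _require(v > 0, f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class Measurement:
    """One analyte value in one tissue of one animal.

    ``censored=True`` means ``value`` stores the reporting threshold of a
    below-threshold result, not a detection.
    """

    animal_id: str
    tissue: str
    analyte: str
    value: float
    unit: str
    basis: str
    censored: bool = False
    rel_uncertainty: float | None = None

    def __post_init__(self) -> None:
        _require(self.tissue in TISSUES, f"unknown tissue {self.tissue!r}")
        _require(bool(self.analyte), "analyte must be non-empty")
        _require(self.value >= 0, f"value must be >= 0, got {self.value}")
        _require(self.basis in ("dry", "wet"), f"basis must be dry|wet, got {self.basis!r}")
        if self.rel_uncertainty is not None:
            _require(self.rel_uncertainty >= 0, "rel_uncertainty must be >= 0")


@dataclass(frozen=True)
class RadionuclideSpec:
    """Half-life and stable-analogue pairing of a radionuclide.

    The decay constant is always derived as ln(2)/half_life and never stored.
    """

    name: str
    half_life_years: float
    stable_analogue: str | None = None

    def __post_init__(self) -> None:
        _require(self.half_life_years > 0, "half_life_years must be > 0")

    @property
    def decay_constant(self) -> float:
        """Decay constant in 1/years."""
        return math.log(2.0) / self.half_life_years


#: Physical half-lives: Cs-137 30.0 y, Pb-210 22.2 y; K-40 is effectively
#: stable on sampling timescales (1.25e9 y) and is paired with K.
DEFAULT_NUCLIDES: dict[str, RadionuclideSpec] = {
    "Cs137": RadionuclideSpec("Cs137", 30.0, "Cs"),
    "Pb210": RadionuclideSpec("Pb210", 22.2, "Pb"),
    "K40": RadionuclideSpec("K40", 1.25e9, "K"),
}


@dataclass(frozen=True)
class SoilReference:
    """One soil concentration used as the denominator of a concentration ratio.

    Soil values are always on a dry-mass basis; radionuclide entries carry the
    reference date their activity refers to so they can be decay-corrected to
    each animal's sampling date.
    """

    analyte: str
    value: float
    unit: str
    basis: str = "dry"
    reference_date: date | None = None
    source: str = ""

    def __post_init__(self) -> None:
        _require(self.value > 0, "soil value must be > 0")
        _require(self.basis == "dry", "soil reference basis must be dry")


@dataclass(frozen=True)
class TransferConfig:
    """Constants of the whole-organism / soil concentration-ratio model.

    proxy_tissue
        Which single tissue stands in for the whole organism per analyte
        (muscle for Cs-137, Ca, Cd, Cu; bone for Mn and Pb; liver for Zn).
    tissue_factor
        Dry-to-wet conversion factor f = 1 - moisture for soft tissues.
    bone_dry_wet_ratio
        Ratio of dry bone mass to wet mass (0.8) used in place of a measured
        bone moisture.
    pb_bone_to_wo
        Bone-to-whole-organism conversion for Pb and Pb-210 (0.16); this
        factor already embeds the 0.8 bone dry/wet ratio.
    """

    proxy_tissue: Mapping[str, str]
    tissue_factor: Mapping[str, float]
    bone_dry_wet_ratio: float = 0.8
    pb_bone_to_wo: float = 0.16

    def __post_init__(self) -> None:
        for t, f in self.tissue_factor.items():
            _require(0 < f <= 1, f"tissue factor for {t} must be in (0, 1], got {f}")
        _require(0 < self.bone_dry_wet_ratio <= 1, "bone_dry_wet_ratio must be in (0, 1]")
        _require(0 < self.pb_bone_to_wo <= 1, "pb_bone_to_wo must be in (0, 1]")

    def factor_for(self, analyte: str, tissue: str) -> float:
        """Dry -> whole-organism-wet factor for a proxy tissue value."""
        if tissue == "bone":
            if analyte in ("Pb", "Pb210"):
                return self.pb_bone_to_wo
            return self.bone_dry_wet_ratio
        try:
            return self.tissue_factor[tissue]
        except KeyError:
            raise ValidationError(f"no dry-to-wet factor configured for tissue {tissue!r}")


def default_transfer_config() -> TransferConfig:
    """Default proxy tissues and conversion factors.

    Soft-tissue factors come from measured moisture (muscle 75%, heart 76%,
    lungs 77%, liver 70%); the spleen and kidney factors are configuration
    placeholders, not measured values.
    """
    return TransferConfig(
        proxy_tissue={
            "Cs137": "muscle",
            "Cs": "muscle",
            "Ca": "muscle",
            "Cd": "muscle",
            "Cu": "muscle",
            "Mn": "bone",
            "Zn": "liver",
            "Pb": "bone",
            "Pb210": "bone",
        },
        tissue_factor={
            "muscle": 0.25,
            "heart": 0.24,
            "lungs": 0.23,
            "liver": 0.30,
            "spleen": 0.23,  # placeholder, no measured moisture available
            "kidney": 0.25,  # placeholder
        },
    )


@dataclass
class CohortDataset:
    """Validated container coupling animals with their measurements."""

    animals: list[AnimalRecord]
    measurements: list[Measurement]
    tissue_moisture: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [a.animal_id for a in self.animals]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate animal_id in animal table")
        known = set(ids)
        for m in self.measurements:
            if m.animal_id not in known:
                raise ReferentialError(
                    f"measurement references unknown animal_id {m.animal_id!r}"
                )
        # unit/basis must be consistent within an analyte: the analysis never
        # mixes units inside one analyte and does not convert automatically
        seen: dict[str, tuple[str, str]] = {}
        for m in self.measurements:
            key = m.analyte
            ub = (m.unit, m.basis)
            if key in seen and seen[key] != ub:
                raise ValidationError(
                    f"inconsistent unit/basis for analyte {key!r}: {seen[key]} vs {ub}"
                )
            seen.setdefault(key, ub)
        for t, mois in self.tissue_moisture.items():
            _require(t in TISSUES, f"unknown tissue {t!r} in tissue_moisture")
            _require(0 <= mois < 1, f"moisture for {t} must be in [0, 1)")

    # -- frame views -------------------------------------------------------

    def animals_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.animals:
            rows.append(
                {
                    "animal_id": a.animal_id,
                    "sampling_date": a.sampling_date.isoformat(),
                    "latitude": a.latitude,
                    "longitude": a.longitude,
                    "region": a.region,
                    "age_years": a.age_years,
                    "sex": a.sex,
                    "body_mass_kg": a.body_mass_kg,
                    "body_length_cm": a.body_length_cm,
                }
            )
        return pd.DataFrame(rows, columns=ANIMAL_COLUMNS)

    def measurements_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.measurements:
            rows.append(
                {
                    "animal_id": m.animal_id,
                    "tissue": m.tissue,
                    "analyte": m.analyte,
                    "value": m.value,
                    "unit": m.unit,
                    "basis": m.basis,
                    "censored": m.censored,
                    "rel_uncertainty": m.rel_uncertainty,
                }
            )
        return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)

    def animal(self, animal_id: str) -> AnimalRecord:
        for a in self.animals:
            if a.animal_id == animal_id:
                return a
        raise KeyError(animal_id)

    def with_measurements(self, measurements: Sequence[Measurement]) -> "CohortDataset":
        return CohortDataset(list(self.animals), list(measurements), dict(self.tissue_moisture))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _check_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")


def _opt_float(token: object) -> float | None:
    """Parse an optional numeric cell; any non-numeric token means missing."""
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    try:
        return float(token)
    except (TypeError, ValueError):
        return None


def _parse_bool(token: object) -> bool:
    if isinstance(token, bool):
        return token
    s = str(token).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", "", "nan"):
        return False
    raise ValidationError(f"cannot parse boolean token {token!r}")


def read_cohort(animal_csv_path, measurement_csv_path) -> CohortDataset:
    """Read and validate a cohort from its two CSV tables.

    Raises :class:`SchemaError` for a missing column, :class:`ReferentialError`
    for a measurement whose animal_id is not in the animal table, and
    :class:`ValidationError` for any field violating an invariant. Row order
    is preserved.
    """
    adf = pd.read_csv(animal_csv_path, dtype=str, comment="#")
    _check_columns(adf, ANIMAL_COLUMNS, str(animal_csv_path))
    animals = []
    for _, row in adf.iterrows():
        animals.append(
            AnimalRecord(
                animal_id=str(row["animal_id"]),
                sampling_date=date.fromisoformat(str(row["sampling_date"])),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                region=str(row["region"]),
                age_years=float(row["age_years"]),
                sex=str(row["sex"]),
                body_mass_kg=_opt_float(row["body_mass_kg"]),
                body_length_cm=_opt_float(row["body_length_cm"]),
            )
        )
    mdf = pd.read_csv(measurement_csv_path, dtype=str, comment="#")
    _check_columns(mdf, MEASUREMENT_COLUMNS, str(measurement_csv_path))
    measurements = []
    for _, row in mdf.iterrows():
        measurements.append(
            Measurement(
                animal_id=str(row["animal_id"]),
                tissue=str(row["tissue"]),
                analyte=str(row["analyte"]),
                value=float(row["value"]),
                unit=str(row["unit"]),
                basis=str(row["basis"]),
                censored=_parse_bool(row["censored"]),
                rel_uncertainty=_opt_float(row["rel_uncertainty"]),
            )
        )
    return CohortDataset(animals, measurements)


def write_cohort(dataset: CohortDataset, animal_csv_path, measurement_csv_path) -> None:
    """Write the two cohort CSVs; ``read_cohort`` re-reads them to equality."""
    dataset.animals_frame().to_csv(animal_csv_path, index=False)
    dataset.measurements_frame().to_csv(measurement_csv_path, index=False)


def read_soil(soil_csv_path) -> list[SoilReference]:
    """Read a soil-reference table (dry-mass concentrations)."""
    df = pd.read_csv(soil_csv_path, dtype=str, comment="#")
    _check_columns(df, SOIL_COLUMNS, str(soil_csv_path))
    out = []
    for _, row in df.iterrows():
        ref = row["reference_date"]
        ref_date = None
        if isinstance(ref, str) and ref.strip():
            ref_date = date.fromisoformat(ref.strip())
        out.append(
            SoilReference(
                analyte=str(row["analyte"]),
                value=float(row["value"]),
                unit=str(row["unit"]),
                basis=str(row["basis"]),
                reference_date=ref_date,
                source=str(row["source"]) if isinstance(row["source"], str) else "",
            )
        )
    return out


def write_soil(entries: Sequence[SoilReference], soil_csv_path) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "analyte": e.analyte,
                "value": e.value,
                "unit": e.unit,
                "basis": e.basis,
                "reference_date": e.reference_date.isoformat() if e.reference_date else "",
                "source": e.source,
            }
        )
    pd.DataFrame(rows, columns=SOIL_COLUMNS).to_csv(soil_csv_path, index=False)
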