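"""Whole-organism conversion, soil referencing with decay, and CR summaries."""

from datetime import date

import numpy as np
import pytest

from ecotransfer.datamodel import (
    CohortDataset,
    Measurement,
    SoilReference,
    ValidationError,
    default_transfer_config,
)
from ecotransfer.transfer import (
    concentration_ratio,
    cr_table,
    soil_reference_for,
    whole_organism_concentration,
)

from conftest import make_animal

CFG = default_transfer_config()


def _cohort(values, analyte="Cs137", tissue="muscle", unit="Bq/kg", dates=None):
    animals = []
    ms = []
    for i, v in enumerate(values):
        kw = {"sampling_date": dates[i]} if dates else {}
        a = make_animal(f"W{i}", **kw)
        animals.append(a)
        ms.append(Measurement(a.animal_id, tissue, analyte, v, unit, "dry"))
    return CohortDataset(animals, ms)


class TestWholeOrganism:
    def test_muscle_proxy_uses_tissue_factor(self):
        ds = _cohort([40.0])
        assert whole_organism_concentration(ds, "Cs137", CFG, "W0") == pytest.approx(10.0)

    def test_bone_lead_uses_dedicated_factor(self):
        ds = _cohort([1000.0], analyte="Pb", tissue="bone", unit="ug/kg")
        assert whole_organism_concentration(ds, "Pb", CFG, "W0") == pytest.approx(160.0)

    def test_bone_nonlead_uses_dry_wet_ratio(self):
        ds = _cohort([100.0], analyte="Mn", tissue="bone", unit="ug/kg")
        assert whole_organism_concentration(ds, "Mn", CFG, "W0") == pytest.approx(80.0)

    def test_censored_only_proxy_returns_none(self):
        a = make_animal("W0")
        ds = CohortDataset(
            [a], [Measurement("W0", "muscle", "Cs137", 1.0, "Bq/kg", "dry", censored=True)]
        )
        assert whole_organism_concentration(ds, "Cs137", CFG, "W0") is None

    def test_unconfigured_proxy_raises(self):
        ds = _cohort([1.0])
        with pytest.raises(ValidationError):
            whole_organism_concentration(ds, "Hg", CFG, "W0")


class TestConcentrationRatio:
    def test_equal_concentrations_give_unity(self):
        assert concentration_ratio(5.0, 5.0) == 1.0

    def test_zero_numerator(self):
        assert concentration_ratio(0.0, 3.0) == 0.0

    def test_hand_example(self):
        assert concentration_ratio(10.1, 125.0) == pytest.approx(0.0808)

    def test_zero_soil_rejected(self):
        with pytest.raises(ValidationError):
            concentration_ratio(1.0, 0.0)


class TestSoilReference:
    SOIL = [
        SoilReference("Cs137", 109.0, "Bq/kg", "dry", date(2016, 6, 1), "A"),
        SoilReference("Cs137", 141.0, "Bq/kg", "dry", date(2016, 6, 1), "B"),
        SoilReference("Cd", 0.9, "mg/kg", "dry", None, "atlas"),
    ]

    def test_stable_element_value_unchanged_by_date(self):
        for d in (date(2014, 1, 1), date(2030, 1, 1)):
            assert soil_reference_for("Cd", d, self.SOIL) == 0.9

    def test_mean_of_two_entries_at_zero_elapsed_time(self):
        got = soil_reference_for("Cs137", date(2016, 6, 1), self.SOIL)
        assert got == pytest.approx(125.0)

    def test_single_entry_halves_after_one_half_life(self):
        soil = [SoilReference("Cs137", 100.0, "Bq/kg", "dry", date(2000, 1, 1), "A")]
        # 30 y * 365.25 d/y = 10957.5 d; use 10958 days ~ half-life
        target = date.fromordinal(date(2000, 1, 1).toordinal() + 10957)
        got = soil_reference_for("Cs137", target, soil)
        assert got == pytest.approx(50.0, rel=1e-4)

    def test_radionuclide_without_reference_date_rejected(self):
        soil = [SoilReference("Cs137", 100.0, "Bq/kg", "dry", None, "A")]
        with pytest.raises(ValidationError):
            soil_reference_for("Cs137", date(2020, 1, 1), soil)

    def test_missing_analyte_rejected(self):
        with pytest.raises(ValidationError):
            soil_reference_for("Zn", date(2020, 1, 1), self.SOIL)

    def test_mass_unit_alignment(self):
        # soil in mg/kg compared against tissue ug/kg
        got = soil_reference_for("Cd", date(2020, 1, 1), self.SOIL, target_unit="ug/kg")
        assert got == pytest.approx(900.0)


class TestCrTable:
    def test_constant_values_give_zero_sd(self):
        sampling = [date(2016, 6, 1)] * 3
        ds = _cohort([40.0, 40.0, 40.0], dates=sampling)
        soil = [SoilReference("Cs137", 125.0, "Bq/kg", "dry", date(2016, 6, 1), "A")]
        (res,) = cr_table(ds, ["Cs137"], CFG, soil)
        assert res.sd == 0.0
        assert res.am == pytest.approx(10.0 / 125.0)
        assert res.gm == pytest.approx(10.0 / 125.0)

    def test_three_animal_fixture_matches_hand_arithmetic(self):
        sampling = [date(2016, 6, 1)] * 3
        ds = _cohort([40.0, 20.0, 80.0], dates=sampling)
        soil = [SoilReference("Cs137", 125.0, "Bq/kg", "dry", date(2016, 6, 1), "A")]
        (res,) = cr_table(ds, ["Cs137"], CFG, soil)
        expect = np.array([10.0, 5.0, 20.0]) / 125.0
        assert res.per_animal_cr == pytest.approx(tuple(expect))
        assert res.am == pytest.approx(expect.mean())
        assert res.gm == pytest.approx(np.exp(np.mean(np.log(expect))))
        assert (res.min, res.max) == (pytest.approx(expect.min()), pytest.approx(expect.max()))

    def test_later_sampling_inflates_radionuclide_cr(self):
        # soil decays while tissue activities are held fixed -> CR rises by 2^(t/T)
        soil = [SoilReference("Cs137", 125.0, "Bq/kg", "dry", date(2016, 6, 1), "A")]
        early = _cohort([40.0], dates=[date(2016, 6, 1)])
        late = _cohort([40.0], dates=[date.fromordinal(date(2016, 6, 1).toordinal() + 10957)])
        (r_early,) = cr_table(early, ["Cs137"], CFG, soil)
        (r_late,) = cr_table(late, ["Cs137"], CFG, soil)
        assert r_late.per_animal_cr[0] / r_early.per_animal_cr[0] == pytest.approx(2.0, rel=1e-4)

    def test_unit_rescaling_invariance(self):
        # multiplying tissue values and soil value by the same constant
        # leaves every CR unchanged
        sampling = [date(2016, 6, 1)] * 2
        ds1 = _cohort([40.0, 20.0], dates=sampling)
        ds2 = _cohort([4000.0, 2000.0], dates=sampling)
        soil1 = [SoilReference("Cs137", 125.0, "Bq/kg", "dry", date(2016, 6, 1), "A")]
        soil2 = [SoilReference("Cs137", 12500.0, "Bq/kg", "dry", date(2016, 6, 1), "A")]
        (r1,) = cr_table(ds1, ["Cs137"], CFG, soil1)
        (r2,) = cr_table(ds2, ["Cs137"], CFG, soil2)
        assert r1.per_animal_cr == pytest.approx(r2.per_animal_cr)

    def test_analyte_without_eligible_animals_is_omitted(self):
        ds = _cohort([40.0], dates=[date(2016, 6, 1)])
        soil = [
            SoilReference("Cs137", 125.0, "Bq/kg", "dry", date(2016, 6, 1), "A"),
            SoilReference("Cd", 0.9, "mg/kg", "dry", None, "atlas"),
        ]
        results = cr_table(ds, ["Cs137", "Cd"], CFG, soil)
        assert [r.analyte for r in results] == ["Cs137"]
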