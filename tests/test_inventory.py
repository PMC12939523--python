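"""Inventory data model and linear characterization engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phycolca.inventory import (CharacterizationFactorTable, InventoryEntry,
                                InventoryTable, characterize,
                                combine_stage_intensities, read_inventory,
                                stage_totals)


def entry(flow="CO_2", amount=1.0, unit="kg", compartment="elementary",
          sign=1, stage=""):
    return InventoryEntry(flow, amount, unit, compartment, sign, stage)


class TestReadInventory:
    def test_shipped_fixture_has_26_flows_with_signed_removals(self, fixture_dir):
        table = read_inventory(fixture_dir / "inventory_cu.csv")
        assert len(table) == 26
        seq = [e for e in table
               if e.flow_name == "CO_2" and e.unit == "t"]
        assert len(seq) == 1
        assert seq[0].amount == pytest.approx(1.60248)
        assert seq[0].compartment == "elementary"
        assert seq[0].direction_sign == -1
        # both elementary CO2 rows are removals
        co2 = [e for e in table if e.flow_name == "CO_2"]
        assert {e.direction_sign for e in co2} == {-1}

    def test_empty_file_with_header_gives_empty_table(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("flow_name,amount,unit,compartment,direction_sign\n")
        assert len(read_inventory(p)) == 0

    def test_unknown_unit_error_names_row_and_unit(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("flow_name,amount,unit,compartment,direction_sign\n"
                     "Steel,1.0,lbs,technosphere,1\n")
        with pytest.raises(ValueError, match=r"row 1.*lbs"):
            read_inventory(p)

    def test_negative_amount_is_rejected(self, tmp_path):
        p = tmp_path / "neg.csv"
        p.write_text("flow_name,amount,unit,compartment,direction_sign\n"
                     "CO_2,-2.0,kg,elementary,1\n")
        with pytest.raises(ValueError, match="non-negative"):
            read_inventory(p)


class TestCharacterize:
    def test_unit_factor_single_entry(self):
        inv = InventoryTable([entry(amount=2.0)])
        res = characterize(inv, CharacterizationFactorTable.unit_co2())
        assert res.climate == pytest.approx(2.0)

    def test_tonne_removal_converts_to_negative_kg(self):
        inv = InventoryTable([entry(amount=1.60248, unit="t", sign=-1)])
        res = characterize(inv, CharacterizationFactorTable.unit_co2())
        assert res.climate == pytest.approx(-1602.48)

    def test_doubling_amounts_doubles_totals(self):
        inv = InventoryTable([entry(amount=0.4), entry(amount=1.6, unit="t", sign=-1)])
        cf = CharacterizationFactorTable.unit_co2()
        assert characterize(inv.scaled(2.0), cf).climate == pytest.approx(
            2.0 * characterize(inv, cf).climate)

    def test_unmatched_elementary_flow_is_hard_error(self):
        inv = InventoryTable([entry(flow="CH_4")])
        with pytest.raises(ValueError, match="CH_4"):
            characterize(inv, CharacterizationFactorTable.unit_co2())

    def test_ignore_set_permits_uncharacterized_elementary_flow(self):
        inv = InventoryTable([entry(), entry(flow="Land occupation", unit="m2·a")])
        res = characterize(inv, CharacterizationFactorTable.unit_co2(),
                           ignore={"Land occupation"})
        assert res.climate == pytest.approx(1.0)

    def test_technosphere_without_factor_is_reported_not_zeroed(self):
        inv = InventoryTable([entry(), entry(flow="Steel", compartment="technosphere")])
        res = characterize(inv, CharacterizationFactorTable.unit_co2())
        assert "Steel (climate_GWP100)" in res.not_characterized

    def test_missing_factor_lookup_is_explicit_error(self):
        cf = CharacterizationFactorTable.unit_co2()
        with pytest.raises(KeyError, match="never treated as zero"):
            cf.factor("CO_2", "water_AWARE")

    def test_net_biogenic_balance_from_signed_fixture_flows(self, fixture_dir):
        """Direction-signed CO2 flows with a unit factor give the net
        biogenic balance: -(0.40179 + 1602.48) kg CO2-eq per CU."""
        table = read_inventory(fixture_dir / "inventory_cu.csv")
        elementary_co2 = InventoryTable([e for e in table if e.flow_name == "CO_2"])
        res = characterize(elementary_co2, CharacterizationFactorTable.unit_co2())
        assert res.climate == pytest.approx(-(0.40179 + 1602.48))


@st.composite
def small_inventories(draw):
    n = draw(st.integers(1, 6))
    entries = [
        entry(
            flow="CO_2",
            amount=draw(st.floats(0, 1e3, allow_nan=False, allow_infinity=False)),
            unit=draw(st.sampled_from(["kg", "t", "g"])),
            sign=draw(st.sampled_from([1, -1])),
        )
        for _ in range(n)
    ]
    return InventoryTable(entries)


class TestLinearity:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(inv=small_inventories(), k=st.floats(0, 50, allow_nan=False))
    def test_characterize_is_homogeneous(self, inv, k):
        cf = CharacterizationFactorTable.unit_co2()
        assert characterize(inv.scaled(k), cf).climate == pytest.approx(
            k * characterize(inv, cf).climate, abs=1e-6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=small_inventories(), b=small_inventories())
    def test_characterize_is_additive(self, a, b):
        cf = CharacterizationFactorTable.unit_co2()
        assert characterize(a + b, cf).climate == pytest.approx(
            characterize(a, cf).climate + characterize(b, cf).climate, abs=1e-6)


class TestStageTotals:
    def test_breakdown_matches_unpartitioned_characterization(self):
        rng = np.random.default_rng(42)
        entries = [
            entry(amount=float(rng.uniform(0, 10)), sign=int(rng.choice([1, -1])),
                  stage=f"stage{i % 3}")
            for i in range(9)
        ]
        inv = InventoryTable(entries)
        cf = CharacterizationFactorTable.unit_co2()
        res = stage_totals(inv, cf)
        assert set(res.breakdown) == {"stage0", "stage1", "stage2"}
        total_from_stages = sum(v["climate_GWP100"] for v in res.breakdown.values())
        assert total_from_stages == pytest.approx(characterize(inv, cf).climate,
                                                  rel=1e-12)
        assert res.climate == pytest.approx(total_from_stages, rel=1e-9)

    def test_single_stage_breakdown_equals_total(self):
        inv = InventoryTable([entry(amount=3.0, stage="cultivation")])
        res = stage_totals(inv, CharacterizationFactorTable.unit_co2())
        assert res.breakdown["cultivation"]["climate_GWP100"] == pytest.approx(res.climate)

    def test_unmapped_flow_is_hard_error(self):
        inv = InventoryTable([entry(stage="")])
        with pytest.raises(ValueError, match="not mapped"):
            stage_totals(inv, CharacterizationFactorTable.unit_co2())

    def test_stage_labels_override(self):
        inv = InventoryTable([entry(stage="")])
        res = stage_totals(inv, CharacterizationFactorTable.unit_co2(),
                           stage_labels={"CO_2": "cultivation"})
        assert "cultivation" in res.breakdown


class TestStageIntensities:
    def test_emission_stage_subtotal(self):
        res = combine_stage_intensities({"cultivation": 0.15, "extraction": 4.83})
        assert res.climate == pytest.approx(4.98)

    def test_removal_sign_gives_net_balance(self):
        res = combine_stage_intensities(
            {"cultivation": 0.15, "extraction": 4.83, "sequestration": 1602.48},
            signs={"sequestration": -1})
        assert res.climate == pytest.approx(-1597.50)
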