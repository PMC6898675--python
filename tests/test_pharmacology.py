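"""Hill pore-block arithmetic, drug application, and library I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardioprofile.engine import PacingProtocol, pace
from cardioprofile.pharmacology import (
    CHANNEL_PANEL,
    ChannelBlock,
    DrugLibraryError,
    DrugSpec,
    apply_drug,
    block_fraction,
    load_drug_library,
    save_drug_library,
    shipped_library,
)
from cardioprofile.synthetic_fixtures import TOY_MODEL, make_toy_cell

CIPA_NAMES = {
    "quinidine", "bepridil", "dofetilide", "sotalol", "chlorpromazine",
    "cisapride", "terfenadine", "ondansetron", "diltiazem", "mexiletine",
    "ranolazine", "verapamil",
}


class TestBlockFraction:
    def test_zero_concentration_is_unity(self):
        assert block_fraction(0.0, 1.0, 2.0) == 1.0

    @pytest.mark.parametrize("hill", [0.5, 1.0, 2.0, 4.0])
    def test_ic50_gives_half_block(self, hill):
        assert block_fraction(3.7, 3.7, hill) == pytest.approx(0.5)

    def test_tenfold_ic50_hill_one(self):
        assert block_fraction(10.0, 1.0, 1.0) == pytest.approx(1.0 / 11.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            block_fraction(-1.0, 1.0)

    @given(st.floats(0.0, 1e3), st.floats(1e-3, 1e3), st.floats(0.1, 4.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_and_monotone(self, conc, ic50, hill):
        s = block_fraction(conc, ic50, hill)
        assert 0.0 < s <= 1.0
        assert block_fraction(conc * 2 + 1e-6, ic50, hill) <= s + 1e-12


class TestApplyDrug:
    def test_zero_concentration_is_identity(self, toy_cell):
        params, _ = toy_cell
        drug = DrugSpec("h", eftpc=1.0, blocks={"hERG": ChannelBlock(1.0)})
        assert apply_drug(params, drug, 0.0)["g_out"] == params["g_out"]

    def test_pure_herg_at_ic50_halves_only_that_conductance(self, toy_cell):
        params, _ = toy_cell
        drug = DrugSpec("h", eftpc=1.0, blocks={"hERG": ChannelBlock(2.0)})
        out = apply_drug(params, drug, 2.0)
        assert out["g_out"] == pytest.approx(params["g_out"] * 0.5)
        assert out["g_in"] == params["g_in"]
        assert out["g_leak"] == params["g_leak"]

    def test_original_params_untouched(self, toy_cell):
        params, _ = toy_cell
        before = params["g_out"]
        drug = DrugSpec("h", eftpc=1.0, blocks={"hERG": ChannelBlock(0.1)})
        apply_drug(params, drug)
        assert params["g_out"] == before

    def test_absent_channel_rejected_by_name(self, toy_cell):
        params, _ = toy_cell
        drug = DrugSpec("k", eftpc=1.0, blocks={"Kv4.3": ChannelBlock(1.0)})
        with pytest.raises(ValueError, match="Kv4.3"):
            apply_drug(params, drug)

    def test_disjoint_channel_drugs_commute(self, toy_cell):
        params, _ = toy_cell
        d1 = DrugSpec("a", eftpc=1.0, blocks={"hERG": ChannelBlock(0.5)})
        d2 = DrugSpec("b", eftpc=1.0, blocks={"Cav1.2": ChannelBlock(0.8)})
        ab = apply_drug(apply_drug(params, d1), d2)
        ba = apply_drug(apply_drug(params, d2), d1)
        assert ab == ba

    def test_double_application_is_not_double_concentration(self, toy_cell):
        # block composes as conductance scaling, not concentration addition
        params, _ = toy_cell
        drug = DrugSpec("h", eftpc=1.0, blocks={"hERG": ChannelBlock(1.0)})
        twice = apply_drug(apply_drug(params, drug, 1.0), drug, 1.0)
        double = apply_drug(params, drug, 2.0)
        assert twice["g_out"] == pytest.approx(params["g_out"] * 0.25)
        assert double["g_out"] == pytest.approx(params["g_out"] / 3.0)

    def test_apd_monotone_in_concentration(self):
        """Pure outward-current block: steady-state APD90 never shortens as
        the concentration rises (toy model)."""
        params, state = make_toy_cell("normal")
        drug = DrugSpec("h", eftpc=1.0, blocks={"hERG": ChannelBlock(1.0)})
        apds = []
        for conc in (0.0, 0.3, 0.8):
            p = apply_drug(params, drug, conc)
            p.initial_state = state
            res = pace(TOY_MODEL, p,
                       PacingProtocol(cl=1000.0, max_beats=40, ss_window=6),
                       keep_beats=2)
            apds.append(res.apd90)
        assert apds == sorted(apds)


class TestLibraryIO:
    def test_shipped_library_is_the_cipa_training_set(self):
        lib = shipped_library()
        assert len(lib) == 12
        assert {d.name for d in lib} == CIPA_NAMES

    def test_round_trip(self, tmp_path):
        lib = shipped_library()
        path = tmp_path / "lib.yaml"
        save_drug_library(lib, path)
        assert load_drug_library(path) == lib

    def test_empty_file_gives_empty_library(self, tmp_path, caplog):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        with caplog.at_level("WARNING"):
            assert load_drug_library(path) == []
        assert "empty" in caplog.text

    @pytest.mark.parametrize("doc,field", [
        ("drugs:\n- name: x\n  channels: {hERG: {ic50_uM: 1}}\n", "eftpc"),
        ("drugs:\n- name: x\n  eftpc_uM: 1\n  channels: {hERG: {ic50_uM: -1}}\n",
         "ic50"),
        ("drugs:\n- name: x\n  eftpc_uM: 1\n  channels: {hERG2: {ic50_uM: 1}}\n",
         "hERG2"),
        ("drugs:\n- name: x\n  eftpc_uM: 1\n", "channels"),
    ])
    def test_schema_errors_name_the_field(self, tmp_path, doc, field):
        path = tmp_path / "bad.yaml"
        path.write_text(doc)
        with pytest.raises(DrugLibraryError, match=field):
            load_drug_library(path)

    def test_missing_hill_defaults_to_one(self, tmp_path):
        path = tmp_path / "nohill.yaml"
        path.write_text(
            "drugs:\n- name: x\n  eftpc_uM: 1.0\n"
            "  channels: {hERG: {ic50_uM: 2.0}}\n")
        (drug,) = load_drug_library(path)
        assert drug.blocks["hERG"].hill == 1.0

    def test_every_panel_label_is_mapped_uniquely(self):
        from cardioprofile._family import CHANNEL_MAP
        assert set(CHANNEL_MAP) == set(CHANNEL_PANEL)
        assert len(set(CHANNEL_MAP.values())) == len(CHANNEL_PANEL)
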