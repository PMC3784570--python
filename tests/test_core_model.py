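import json
import math

import numpy as np
import pytest

from mtow import (
    Dg0Estimate,
    Metabolite,
    NetworkModel,
    Reaction,
    ThermoParams,
    load_model,
    reaction_gibbs,
    split_reversible,
    validate_model,
    write_model,
)
from mtow.core_model import fixed_ln_conc, load_medium, net_flux_rows, write_medium
from mtow.errors import ModelFormatError, ModelValidationError


def toy_json_doc():
    return {
        "metabolites": [{"id": m} for m in "ABC"],
        "reactions": [
            {"id": "EX_A", "stoichiometry": {"A": 1.0}, "is_exchange": True},
            {"id": "R1", "stoichiometry": {"A": -1.0, "B": 1.0}, "dg0": {"value": -10.0}},
            {"id": "R2", "stoichiometry": {"B": -1.0, "C": 1.0}, "dg0": {"value": -5.0, "stderr": 1.0}},
            {"id": "EX_C", "stoichiometry": {"C": -1.0}, "is_exchange": True},
        ],
    }


class TestJsonDialect:
    def test_linear_fixture_loads(self, tmp_path):
        p = tmp_path / "m.json"
        p.write_text(json.dumps(toy_json_doc()))
        model = load_model(p, format="json")
        assert len(model.metabolites) == 3
        assert len(model.reactions) == 4
        assert sum(r.is_exchange for r in model.reactions) == 2
        assert model.rg_reactions == ["R1", "R2"]

    def test_unknown_metabolite_rejected(self, tmp_path):
        doc = toy_json_doc()
        doc["reactions"][1]["stoichiometry"]["X"] = 1.0
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError, match="unknown metabolite X"):
            load_model(p, format="json")

    def test_malformed_record_names_format_error(self, tmp_path):
        p = tmp_path / "broken.json"
        p.write_text("{not json")
        with pytest.raises(ModelFormatError):
            load_model(p, format="json")

    def test_round_trip_preserves_everything(self, tmp_path, linear_toy):
        model, _ = linear_toy
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_model(model, p1)
        reread = load_model(p1, format="json")
        write_model(reread, p2)
        assert p1.read_text() == p2.read_text()
        assert np.array_equal(
            model.stoichiometric_matrix(sparse=False),
            reread.stoichiometric_matrix(sparse=False),
        )
        for a, b in zip(model.reactions, reread.reactions):
            assert (a.flux_lower, a.flux_upper, a.is_exchange, a.in_rg) == (
                b.flux_lower,
                b.flux_upper,
                b.is_exchange,
                b.in_rg,
            )
            if a.dg0 is not None:
                assert (a.dg0.value, a.dg0.stderr) == (b.dg0.value, b.dg0.stderr)


class TestTsvAndSbml:
    def test_tsv_stoichiometry_with_companion(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "reaction_id\tmetabolite_id\tcoefficient\n"
            "R1\tA\t-1\nR1\tB\t1\nEX_A\tA\t1\nEX_B\tB\t-1\n"
        )
        (tmp_path / "m.reactions.tsv").write_text(
            "reaction_id\treversible\tflux_lower\tflux_upper\tis_exchange\tdg0\tdg0_stderr\n"
            "R1\tFalse\t0\t50\tFalse\t-3.5\t0.7\nEX_A\tFalse\t0\t10\tTrue\t\t\n"
            "EX_B\tFalse\t0\t10\tTrue\t\t\n"
        )
        model = load_model(tmp_path / "m.tsv", format="tsv")
        r1 = model.get_reaction("R1")
        assert r1.dg0.value == -3.5 and r1.dg0.stderr == 0.7
        assert r1.flux_upper == 50
        assert model.get_reaction("EX_A").is_exchange

    def test_sbml_read_matches_source_model(self, tmp_path, linear_toy):
        cobra = pytest.importorskip("cobra")
        model, _ = linear_toy
        cm = cobra.Model("toy")
        mets = {m.id: cobra.Metabolite(m.id, compartment="c") for m in model.metabolites}
        for r in model.reactions:
            cr = cobra.Reaction(r.id)
            cr.lower_bound, cr.upper_bound = r.flux_lower, r.flux_upper
            cm.add_reactions([cr])
            cr.add_metabolites({mets[mid]: c for mid, c in r.stoichiometry.items()})
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(cm, str(path))
        loaded = load_model(path, format="sbml")
        assert {r.id for r in loaded.reactions} == {r.id for r in model.reactions}
        for r in model.reactions:
            assert loaded.get_reaction(r.id).stoichiometry == r.stoichiometry
            assert loaded.get_reaction(r.id).flux_upper == r.flux_upper


class TestValidation:
    def test_valid_fixture_has_no_diagnostics(self, linear_toy):
        assert validate_model(linear_toy[0]) == []

    @pytest.mark.parametrize(
        "mutate, fragment",
        [
            (lambda m: setattr(m.metabolites[0], "conc_lower", 200.0), "conc_lower"),
            (lambda m: setattr(m.metabolites[0], "fixed_conc", 1e-9), "fixed_conc"),
            (lambda m: setattr(m.reactions[1], "in_rg", True), "in_rg"),
            (lambda m: setattr(m.reactions[0], "stoichiometry", {}), "empty stoichiometry"),
        ],
    )
    def test_single_violation_yields_one_diagnostic(self, mutate, fragment):
        spec_model = NetworkModel(
            metabolites=[Metabolite(id="A"), Metabolite(id="B")],
            reactions=[
                Reaction(id="EX_A", stoichiometry={"A": 1.0}, is_exchange=True),
                Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0}),
                Reaction(id="EX_B", stoichiometry={"B": -1.0}, is_exchange=True),
            ],
        )
        mutate(spec_model)
        diags = validate_model(spec_model)
        assert len(diags) == 1
        assert fragment in diags[0]


class TestSplitReversible:
    def make_model(self):
        return NetworkModel(
            metabolites=[Metabolite(id="A"), Metabolite(id="B")],
            reactions=[
                Reaction(
                    id="R1",
                    stoichiometry={"A": -1.0, "B": 1.0},
                    reversible=True,
                    flux_lower=-5.0,
                    flux_upper=8.0,
                    dg0=Dg0Estimate(value=-3.0, stderr=0.4),
                ),
                Reaction(id="R2", stoichiometry={"B": -1.0, "A": 1.0}),
            ],
        )

    def test_counts_and_bounds(self):
        split = split_reversible(self.make_model())
        assert len(split.reactions) == 3
        fwd, rev = split.get_reaction("R1__fwd"), split.get_reaction("R1__rev")
        assert (fwd.flux_lower, fwd.flux_upper) == (0.0, 8.0)
        assert (rev.flux_lower, rev.flux_upper) == (0.0, 5.0)
        assert all(r.flux_lower >= 0 for r in split.reactions)
        assert split.split_map == {"R1__fwd": "R1", "R1__rev": "R1"}

    def test_dg0_antisymmetry(self):
        split = split_reversible(self.make_model())
        fwd, rev = split.get_reaction("R1__fwd"), split.get_reaction("R1__rev")
        assert rev.dg0.value == -fwd.dg0.value
        assert rev.dg0.stderr == fwd.dg0.stderr

    def test_gibbs_antisymmetric_at_random_concentrations(self):
        split = split_reversible(self.make_model())
        params = ThermoParams()
        rng = np.random.default_rng(7)
        for _ in range(20):
            ln_c = {"A": rng.uniform(-11, 4), "B": rng.uniform(-11, 4)}
            gf = reaction_gibbs(split.get_reaction("R1__fwd"), ln_c, params)
            gr = reaction_gibbs(split.get_reaction("R1__rev"), ln_c, params)
            assert gf.dg_prime == pytest.approx(-gr.dg_prime, abs=1e-9)
            assert gf.driving_force == pytest.approx(-gr.driving_force, abs=1e-12)

    def test_idempotent_on_irreversible_models(self, linear_toy):
        model, _ = linear_toy
        once = split_reversible(model)
        twice = split_reversible(once)
        assert [r.id for r in once.reactions] == [r.id for r in twice.reactions]
        assert np.array_equal(
            once.stoichiometric_matrix(sparse=False),
            twice.stoichiometric_matrix(sparse=False),
        )

    def test_net_flux_rows_for_split_and_plain(self):
        split = split_reversible(self.make_model())
        assert net_flux_rows(split, "R1") == {"R1__fwd": 1.0, "R1__rev": -1.0}
        assert net_flux_rows(split, "R2") == {"R2": 1.0}


class TestMedium:
    def test_medium_round_trip(self, tmp_path):
        from mtow import MediumSpec

        med = MediumSpec(
            exchange_bounds={"EX_A": (0.0, 10.0)},
            currency_concs={"atp": 3.0},
            measured_fluxes={"R1": (2.0, 0.2)},
            growth_rate=(0.5, 0.05),
        )
        p = tmp_path / "medium.json"
        write_medium(med, p)
        back = load_medium(p)
        assert back == med

    def test_fixed_ln_conc_priority(self):
        from mtow import MediumSpec, ToySpec, make_toy_model

        model, _ = make_toy_model(ToySpec(n_steps=2, dg0s=[-1.0], boundary_concs=(2.0, 0.5)))
        med = MediumSpec(currency_concs={"M1": 5.0})
        pins = fixed_ln_conc(model, med)
        assert pins["M1"] == pytest.approx(math.log(5.0))
        assert pins["M2"] == pytest.approx(math.log(0.5))
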