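import math

import numpy as np
import pytest

from mtow import (
    ComponentContribution,
    GroupDecomposition,
    MeasuredReactionSet,
    PseudoisomerSet,
    ThermoParams,
    legendre_transform,
    loo_crossvalidate,
    make_synthetic_ccm_data,
)
from mtow.errors import EstimationError
from mtow.gibbs_ccm import transformed_formation_energy
from mtow.synthetic import make_category_iii_example

PARAMS = ThermoParams()


@pytest.fixture(scope="module")
def cc(ccm_noise_free):
    train, groups, _ = ccm_noise_free
    return ComponentContribution(train, groups)


class TestCategorize:
    def test_training_column_is_category_i(self, ccm_noise_free, cc):
        train, _, _ = ccm_noise_free
        for j in (0, 7, 19):
            assert cc.categorize(train.S_train[:, j]) == "I"

    def test_linear_combination_of_training_is_category_i(self, ccm_noise_free, cc):
        train, _, _ = ccm_noise_free
        combo = 2.0 * train.S_train[:, 1] - train.S_train[:, 5] + train.S_train[:, 9]
        assert cc.categorize(combo) == "I"

    def test_untrained_decomposable_compounds_are_category_ii(self):
        train, groups, _, _ = make_category_iii_example(-10.0, 5.0)
        r = np.array([0.0, 0.0, -1.0, 1.0])  # only untrained compounds
        assert ComponentContribution(train, groups).categorize(r) == "II"

    def test_mixed_reaction_is_category_iii(self):
        train, groups, ge, target = make_category_iii_example(-10.0, 5.0)
        assert ComponentContribution(train, groups, ge).categorize(target) == "III"

    def test_non_decomposable_remainder_is_undetermined(self):
        train, groups, ge, target = make_category_iii_example(-10.0, 5.0)
        groups.decomposable[3] = False  # C4 cannot be split into groups
        model = ComponentContribution(train, groups, ge)
        assert model.categorize(target) == "undetermined"
        with pytest.raises(EstimationError):
            model.estimate(target)

    def test_dimension_mismatch_rejected(self, cc):
        with pytest.raises(ValueError):
            cc.categorize(np.zeros(3))


class TestEstimate:
    def test_category_i_recovers_observed_value(self, ccm_noise_free, cc):
        train, _, _ = ccm_noise_free
        est = cc.estimate(train.S_train[:, 4])
        assert est.category == "I"
        assert est.value == pytest.approx(train.dg0_obs[4], abs=1e-8)
        assert est.stderr == pytest.approx(0.0, abs=1e-6)

    def test_half_reaction_combination(self):
        # two half-reactions of −164.0 (measured span) and 204.9 (groups)
        # must combine to 40.9 kJ/mol
        train, groups, ge, target = make_category_iii_example(-164.0, 204.9)
        model = ComponentContribution(train, groups, ge)
        span_half, group_half = model.half_reaction_values(target)
        assert span_half == pytest.approx(-164.0, abs=1e-9)
        assert group_half == pytest.approx(204.9, abs=1e-9)
        est = model.estimate(target)
        assert est.category == "III"
        assert est.value == pytest.approx(40.9, abs=1e-9)

    def test_noise_free_recovery_of_truth(self, ccm_noise_free, cc):
        train, groups, truth = ccm_noise_free
        rng = np.random.default_rng(3)
        for _ in range(20):
            r = np.zeros(len(train.compound_ids))
            members = rng.choice(len(r), size=4, replace=False)
            r[members] = rng.choice([-1.0, 1.0, 2.0], size=4)
            expected = float(r @ truth["formation_energies"])
            assert cc.estimate(r).value == pytest.approx(expected, abs=1e-6)

    def test_first_law_additivity(self, ccm_noise_free, cc):
        train, _, _ = ccm_noise_free
        rng = np.random.default_rng(11)
        for _ in range(100):
            i, j = rng.integers(0, train.S_train.shape[1], size=2)
            r12 = train.S_train[:, i] + train.S_train[:, j]
            if not r12.any():
                continue
            total = cc.estimate(train.S_train[:, i]).value + cc.estimate(train.S_train[:, j]).value
            assert cc.estimate(r12).value == pytest.approx(total, abs=1e-8)

    def test_antisymmetry(self, ccm_noise_free, cc):
        train, _, _ = ccm_noise_free
        r = train.S_train[:, 2] + 0.5 * train.S_train[:, 8]
        assert cc.estimate(-r).value == pytest.approx(-cc.estimate(r).value, abs=1e-9)

    def test_category_i_invariant_to_group_model(self, ccm_noise_free):
        train, groups, _ = ccm_noise_free
        r = train.S_train[:, 6]
        base = ComponentContribution(train, groups).estimate(r).value
        perturbed = ComponentContribution(
            train, groups, group_energies=np.full(len(groups.group_ids), 1234.5)
        ).estimate(r).value
        assert perturbed == pytest.approx(base, abs=1e-6)

    def test_span_augmented_beats_group_only_on_inconsistent_data(self):
        # violate group independence for span-covered reactions: the measured
        # energies get a shift the group model cannot represent
        train, groups, truth = make_synthetic_ccm_data(20, 5, 12, 0.0, seed=5)
        y = train.dg0_obs + 25.0 * np.sign(np.arange(len(train.dg0_obs)) % 3 - 1)
        shifted = MeasuredReactionSet(
            train.S_train, y, train.reaction_ids, train.compound_ids
        )
        cc = ComponentContribution(shifted, groups)
        errs_cc, errs_gcm = [], []
        for j in range(train.S_train.shape[1]):
            r = train.S_train[:, j]
            errs_cc.append(abs(cc.estimate(r).value - y[j]))
            errs_gcm.append(abs(float(r @ (groups.G @ cc.group_energies)) - y[j]))
        assert np.sqrt(np.mean(np.square(errs_cc))) <= np.sqrt(np.mean(np.square(errs_gcm)))


class TestLegendreTransform:
    def test_single_species_zero_corrections_identity(self):
        # species energies consistent with the raw value; pH 0, I = 0
        a = PseudoisomerSet("A", [(-50.0, 0, 0)])
        b = PseudoisomerSet("B", [(-20.0, 0, 0)])
        raw = (-20.0) - (-50.0)
        out = legendre_transform(raw, [(-1.0, a), (1.0, b)], pH=0.0, ionic_strength=0.0, params=PARAMS)
        assert out == pytest.approx(raw)

    def test_two_species_equal_contribution_closed_form(self):
        # species differ by one proton; choose pH so both corrected energies
        # coincide, then pooling lowers the energy by exactly RT ln 2
        RT = PARAMS.RT
        g0, g1 = -100.0, -110.0  # n_H = 0 and 1, charges 0
        pH = (g0 - g1) / (RT * math.log(10.0))
        ps = PseudoisomerSet("A", [(g0, 0, 0), (g1, 1, 0)])
        out = transformed_formation_energy(ps, pH=pH, ionic_strength=0.0, params=PARAMS)
        assert out == pytest.approx(g0 - RT * math.log(2.0))

    def test_shift_of_one_compound_scales_with_coefficient(self):
        a = PseudoisomerSet("A", [(-50.0, 0, 0), (-48.0, 1, -1)])
        b = PseudoisomerSet("B", [(-20.0, 0, 0)])
        args = dict(pH=7.0, ionic_strength=0.1, params=PARAMS)
        base = legendre_transform(0.0, [(-2.0, a), (1.0, b)], **args)
        shifted_a = PseudoisomerSet("A", [(-50.0 + 3.0, 0, 0), (-48.0 + 3.0, 1, -1)])
        shifted = legendre_transform(0.0, [(-2.0, shifted_a), (1.0, b)], **args)
        assert shifted - base == pytest.approx(-2.0 * 3.0, abs=1e-9)

    def test_missing_pseudoisomers_pass_through_with_warning(self):
        a = PseudoisomerSet("A", [(-50.0, 0, 0)])
        with pytest.warns(UserWarning, match="missing"):
            out = legendre_transform(17.5, [(-1.0, a), (1.0, None)], 7.0, 0.1, PARAMS)
        assert out == 17.5

    def test_empty_species_rejected(self):
        with pytest.raises(ValueError):
            PseudoisomerSet("A", [])


class TestLeaveOneOut:
    def test_noise_free_medians_near_zero(self, ccm_noise_free):
        train, groups, _ = ccm_noise_free
        res = loo_crossvalidate(train, groups)
        assert res.median_cc == pytest.approx(0.0, abs=1e-8)
        assert res.median_gcm == pytest.approx(0.0, abs=1e-8)

    def test_undetermined_heldout_excluded(self):
        # compound C4 appears in exactly one training reaction and is not
        # decomposable: held out, that reaction becomes undetermined
        train, groups, ge, target = make_category_iii_example(-10.0, 5.0)
        S = np.hstack([train.S_train, target[:, None], np.array([[0.0], [-1.0], [1.0], [0.0]])])
        bigger = MeasuredReactionSet(
            S, np.array([-10.0, -5.0, 4.0]), ["T1", "T2", "T3"], train.compound_ids
        )
        groups.decomposable[3] = False
        res = loo_crossvalidate(bigger, groups)
        row = res.table.set_index("reaction_id").loc["T2"]
        assert not row["included"]
        assert row["category"] == "undetermined"

    def test_table_covers_every_training_reaction(self, ccm_noise_free):
        train, groups, _ = ccm_noise_free
        res = loo_crossvalidate(train, groups)
        assert list(res.table["reaction_id"]) == train.reaction_ids


class TestTabularIO:
    def test_training_tables_round_trip(self, tmp_path):
        from mtow.gibbs_ccm import load_group_decomposition, load_measured_reactions

        (tmp_path / "stoich.tsv").write_text(
            "reaction_id\tcompound_id\tcoefficient\n"
            "T1\tc_a\t-1\nT1\tc_b\t1\nT2\tc_b\t-1\nT2\tc_c\t1\n"
        )
        (tmp_path / "dg0.tsv").write_text("reaction_id\tdg0_obs\nT1\t-4.2\nT2\t7.5\n")
        (tmp_path / "groups.tsv").write_text(
            "compound_id\tgroup_id\tcount\nc_a\tg1\t2\nc_b\tg1\t1\nc_c\tg2\t1\n"
        )
        train = load_measured_reactions(tmp_path / "stoich.tsv", tmp_path / "dg0.tsv")
        assert train.S_train.shape == (3, 2)
        assert list(train.dg0_obs) == [-4.2, 7.5]
        groups = load_group_decomposition(
            tmp_path / "groups.tsv", train.compound_ids, non_decomposable=["c_c"]
        )
        assert groups.G[train.compound_ids.index("c_a"), groups.group_ids.index("g1")] == 2
        assert not groups.decomposable[train.compound_ids.index("c_c")]
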