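"""Subclass fold changes, structure profiles, PLS-DA and VIP."""

import numpy as np
import pandas as pd
import pytest

from conftest import PATHWAY_COUNTS, make_table
from lipidaxis import (
    LipidomeSimConfig,
    discriminating_species,
    generate_lipidome,
    plsda_fit,
    structure_profile,
    subclass_abundance,
    subclass_test,
)
from lipidaxis.differential import two_sample_t
from lipidaxis.nomenclature import LipidParseError
from lipidaxis.preprocess import normalize_total_area


class TestSubclassAbundance:
    def test_additivity(self):
        table = make_table(
            [[1.5, 1.0], [2.5, 2.0], [4.0, 5.0]],
            features=["DG(34:2/0:0)", "DG(36:4)", "PC(34:2)"],
        )
        mat = subclass_abundance(table)
        assert mat.loc["DG"].tolist() == [4.0, 3.0]
        assert mat.loc["PC"].tolist() == [4.0, 5.0]

    def test_partition_conserves_column_totals(self, pfc_normalized):
        mat = subclass_abundance(pfc_normalized)
        assert np.allclose(mat.sum(axis=0), 100.0, atol=1e-9)

    def test_feature_order_invariance(self, pfc_normalized):
        shuffled = pfc_normalized.with_values(
            pfc_normalized.values.sample(frac=1, random_state=1)
        )
        a = subclass_abundance(pfc_normalized)
        b = subclass_abundance(shuffled)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_unparseable_policy(self):
        table = make_table([[1.0, 1.0]], features=["not a lipid"])
        with pytest.raises(LipidParseError):
            subclass_abundance(table)
        assert subclass_abundance(table, on_unparseable="skip").empty


class TestSubclassTest:
    def test_identical_groups(self):
        mat = pd.DataFrame([[2.0, 3.0, 4.0, 2.0, 3.0, 4.0]], index=["DG"])
        mat.columns = [f"s{i}" for i in range(6)]
        groups = pd.Series(["DL"] * 3 + ["HC"] * 3, index=mat.columns)
        res = subclass_test(mat, groups)
        assert res.loc[0, "fold_change"] == pytest.approx(1.0)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_fold_change_limit(self):
        rng = np.random.default_rng(0)
        dl = 2.0 + rng.normal(0, 1e-9, 3)
        hc = 1.0 + rng.normal(0, 1e-9, 3)
        mat = pd.DataFrame([np.concatenate([dl, hc])], index=["DG"],
                           columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["DL"] * 3 + ["HC"] * 3, index=mat.columns)
        res = subclass_test(mat, groups)
        assert res.loc[0, "fold_change"] == pytest.approx(2.0, rel=1e-6)

    def test_zero_hc_mean_flagged(self):
        mat = pd.DataFrame([[1.0, 2.0, 1.0, 0.0, 0.0, 0.0]], index=["DG"],
                           columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["DL"] * 3 + ["HC"] * 3, index=mat.columns)
        res = subclass_test(mat, groups)
        assert res.loc[0, "flagged"]
        assert np.isnan(res.loc[0, "fold_change"])

    def test_planted_fold_change_recovered_across_replicates(self):
        """Planted DG fold change 1.38 at n=6: the median recovered FC over
        50 replicates stays within [1.30, 1.46]."""
        fcs = []
        for rep in range(50):
            cfg = LipidomeSimConfig(
                tissues=("PFC",),
                n_species_per_subclass=PATHWAY_COUNTS,
                subclass_effects=(("PFC", "DG", 1.38),),
                seed=1000 + rep,
            )
            table = generate_lipidome(cfg).tissues["PFC"].table
            mat = subclass_abundance(normalize_total_area(table))
            res = subclass_test(mat, table.groups).set_index("subclass")
            fcs.append(res.loc["DG", "fold_change"])
        assert 1.30 <= np.median(fcs) <= 1.46


class TestStructureProfile:
    def test_equal_totals_share_a_bin(self):
        table = make_table(
            np.ones((3, 4)),
            features=["DG(16:0/18:1)", "DG(16:1/18:0)", "DG(18:2/18:2)"],
        )
        prof = structure_profile(table, None, "DG", "total_carbons")
        assert prof["bin"].tolist() == [34, 36]
        assert prof.loc[prof["bin"] == 34, "dl_mean"].iloc[0] == pytest.approx(2.0)

    def test_bins_partition_subclass_abundance(self, pfc_normalized):
        prof = structure_profile(pfc_normalized, None, "DG", "double_bonds")
        total = subclass_abundance(pfc_normalized).loc["DG"]
        assert (prof["dl_mean"].sum() + prof["hc_mean"].sum()) == pytest.approx(
            total.mean() * 2, rel=1e-9
        )

    def test_empty_subclass_warns_and_returns_empty(self, caplog):
        table = make_table([[1.0, 1.0]], features=["PC(34:2)"])
        prof = structure_profile(table, None, "DG", "total_carbons")
        assert prof.empty

    def test_planted_chain_bin_flagged(self):
        """A 2x enrichment of 36-carbon DG species is detected (p < 0.05)
        in at least 90% of 50 replicates."""
        hits = 0
        for rep in range(50):
            cfg = LipidomeSimConfig(
                tissues=("PFC",),
                n_species_per_subclass={"DG": 12, "PC": 20},
                chain_effects=(("PFC", "DG", 36, 2.0),),
                seed=2000 + rep,
            )
            table = generate_lipidome(cfg).tissues["PFC"].table
            prof = structure_profile(
                normalize_total_area(table), None, "DG", "total_carbons"
            ).set_index("bin")
            if 36 in prof.index and prof.loc[36, "p_value"] < 0.05:
                hits += 1
        assert hits >= 45


class TestPlsda:
    def test_vip_mean_square_is_one(self, pfc_normalized):
        model = plsda_fit(pfc_normalized)
        assert (model.vip ** 2).mean() == pytest.approx(1.0, abs=1e-6)

    def test_duplicated_feature_gets_equal_vip(self):
        rng = np.random.default_rng(8)
        base = rng.lognormal(0, 0.5, (20, 12))
        base[0, :6] *= 3.0
        values = np.vstack([base, base[0]])  # duplicate the informative row
        features = [f"f{i}" for i in range(20)] + ["f0_copy"]
        model = plsda_fit(make_table(values, features=features))
        assert model.vip["f0"] == pytest.approx(model.vip["f0_copy"], rel=1e-9)

    def test_single_separating_feature_attains_max_vip(self):
        rng = np.random.default_rng(9)
        values = rng.lognormal(0, 0.1, (15, 12))
        values[4, :6] *= 10.0  # a cleanly separating feature
        model = plsda_fit(make_table(values))
        assert model.vip.idxmax() == "f4"
        assert model.vip["f4"] > 1.0

    def test_noise_vip_centered_near_one_with_planted_above(self):
        """Pure noise keeps the VIP distribution centered near 1 (the
        mean-square-1 constraint); modestly planted discriminators rise
        above 1 while leaving the noise bulk near 1."""
        rng = np.random.default_rng(10)
        noise = rng.lognormal(0, 0.3, (200, 40))
        null_model = plsda_fit(make_table(noise.copy()))
        # VIP is right-skewed with mean square pinned at 1; "centered near
        # 1" means the interquartile range straddles 1
        assert (null_model.vip ** 2).mean() == pytest.approx(1.0, abs=1e-6)
        assert null_model.vip.quantile(0.25) < 1.0 < null_model.vip.quantile(0.75)
        planted = [0, 1, 2]
        values = noise.copy()
        for i in planted:
            values[i, :20] *= 1.5
        model = plsda_fit(make_table(values))
        assert all(model.vip[f"f{i}"] > 1.0 for i in planted)

    def test_constant_features_dropped(self):
        values = np.vstack([np.ones((1, 8)), np.random.default_rng(1).lognormal(0, 1, (5, 8))])
        model = plsda_fit(make_table(values))
        assert model.dropped_features == ["f0"]
        assert "f0" not in model.vip.index

    def test_too_many_components_raises(self):
        values = np.random.default_rng(2).lognormal(0, 1, (5, 6))
        with pytest.raises(ValueError, match="n_components"):
            plsda_fit(make_table(values), n_components=6)


class TestDiscriminatingSpecies:
    def test_double_cutoff_matches_brute_force(self, pfc_normalized):
        """The reported set equals an explicit recomputation of
        VIP > 1 AND t-test p < 0.05 over all features."""
        model = plsda_fit(pfc_normalized)
        out = discriminating_species(pfc_normalized, model=model)
        groups = pfc_normalized.groups
        dl = groups.index[groups == "DL"]
        hc = groups.index[groups == "HC"]
        expected = set()
        for f in model.features:
            _, p = two_sample_t(
                pfc_normalized.values.loc[f, dl], pfc_normalized.values.loc[f, hc]
            )
            if model.vip[f] > 1.0 and p < 0.05:
                expected.add(f)
        assert set(out["species"]) == expected
        assert (out["vip"] > 1.0).all()
        assert (out["p_value"] < 0.05).all()

    def test_direction_matches_mean_difference(self, pfc_normalized):
        out = discriminating_species(pfc_normalized)
        groups = pfc_normalized.groups
        for _, row in out.iterrows():
            dl = pfc_normalized.values.loc[row["species"], groups == "DL"].mean()
            hc = pfc_normalized.values.loc[row["species"], groups == "HC"].mean()
            assert row["direction"] == ("up_in_DL" if dl > hc else "down_in_DL")

    def test_planted_effect_recall(self):
        """Ten species planted at multiplier 3 with n=6/group are recovered
        with recall >= 0.8 averaged over 50 replicates."""
        recalls = []
        for rep in range(50):
            cfg = LipidomeSimConfig(
                tissues=("PFC",),
                n_species_per_subclass={"PC": 60, "PE": 30, "DG": 10},
                subclass_effects=(("PFC", "DG", 3.0),),
                seed=3000 + rep,
            )
            tl = generate_lipidome(cfg).tissues["PFC"]
            table = normalize_total_area(tl.table)
            planted = {n for n, a in tl.annotations.items() if a.subclass == "DG"}
            out = discriminating_species(table)
            recalls.append(len(planted & set(out["species"])) / len(planted))
        assert np.mean(recalls) >= 0.8
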