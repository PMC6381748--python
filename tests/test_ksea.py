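"""KSEA: score formula, permutation null, matching, temporal classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphoflux import ksea as ks
from phosphoflux import synthetic as syn
from phosphoflux.io_formats import KinaseSubstrateDB

from conftest import make_table


def _db(rows):
    return KinaseSubstrateDB(pd.DataFrame(
        rows, columns=["enzyme", "class", "substrate_gene", "substrate_acc",
                       "site", "window"]))


class TestZScore:
    def test_zero_when_group_mean_equals_background(self):
        allv = np.array([1.0, 0.0, 0.0, 0.0, -1.0])
        s = ks.ksea_zscore(np.array([0.0, 0.0]), allv)
        assert s.z == 0.0 and s.p_value == pytest.approx(1.0)

    def test_direct_formula_evaluation(self):
        rng = np.random.default_rng(2)
        allv = rng.normal(0, 0.5, 200)
        group = allv[:10] + 0.8
        allv = np.concatenate([group, allv[10:]])
        s = ks.ksea_zscore(group, allv)
        expected = (group.mean() - allv.mean()) * np.sqrt(10) / allv.std(ddof=1)
        assert s.z == pytest.approx(expected, rel=1e-12)

    def test_full_background_group_is_zero(self):
        rng = np.random.default_rng(3)
        allv = rng.normal(size=50)
        assert ks.ksea_zscore(allv, allv).z == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_background_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            ks.ksea_zscore(np.array([1.0]), np.full(10, 1.0))

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            ks.ksea_zscore(np.array([]), np.arange(5.0))

    @settings(derandomize=True, max_examples=30)
    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    def test_affine_invariance(self, shift, scale):
        """Adding a constant to every FC or rescaling by lambda > 0 leaves z
        unchanged (both the centered mean difference and delta scale)."""
        rng = np.random.default_rng(7)
        allv = rng.normal(0, 1, 100)
        group = allv[:8]
        z0 = ks.ksea_zscore(group, allv).z
        z_shift = ks.ksea_zscore(group + shift, allv + shift).z
        z_scale = ks.ksea_zscore(group * scale, allv * scale).z
        assert z_shift == pytest.approx(z0, abs=1e-9)
        assert z_scale == pytest.approx(z0, rel=1e-9, abs=1e-9)

    def test_background_stability(self):
        """Removing one non-member site moves z only O(1/n)."""
        rng = np.random.default_rng(11)
        allv = rng.normal(0, 1, 500)
        group = allv[:10]
        z0 = ks.ksea_zscore(group, allv).z
        z1 = ks.ksea_zscore(group, allv[:-1]).z
        assert abs(z1 - z0) < 10.0 / len(allv)


class TestPermutationP:
    def test_normal_p_agrees_with_permutation(self):
        """For m >= 10 the two-sided normal p matches a permutation p
        within 3 Monte-Carlo SEs on a dataset-sized background (the
        quantified background in this kind of study is thousands of
        sites, so the without-replacement correction is negligible)."""
        rng = np.random.default_rng(5)
        allv = rng.normal(0, 0.5, 2000)
        group = allv[:10] + 0.35
        allv = np.concatenate([group, allv[10:]])
        s = ks.ksea_zscore(group, allv)
        n_perm = 100000
        p_perm = ks.ksea_permutation_p(group, allv, n_perm=n_perm, seed=1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(s.p_value - p_perm) <= 3 * se + 1e-6

    def test_null_group_p_near_one(self):
        rng = np.random.default_rng(6)
        allv = rng.normal(0, 1, 100)
        group = allv[np.argsort(np.abs(allv - allv.mean()))[:10]]
        p = ks.ksea_permutation_p(group, allv, n_perm=2000, seed=2)
        assert p > 0.5

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        allv = rng.normal(size=60)
        a = ks.ksea_permutation_p(allv[:5], allv, n_perm=1000, seed=3)
        b = ks.ksea_permutation_p(allv[:5], allv, n_perm=1000, seed=3)
        assert a == b

    def test_group_size_and_nperm_validation(self):
        allv = np.arange(10.0)
        with pytest.raises(ValueError):
            ks.ksea_permutation_p(allv, allv, n_perm=1000)
        with pytest.raises(ValueError):
            ks.ksea_permutation_p(allv[:2], allv, n_perm=10)


class TestMatching:
    def _table(self):
        vals = {"P49841_S9": np.full(30, 20.0),
                "P16220_S133": np.full(30, 20.0),
                "SP1_S10/S14": np.full(30, 20.0)}
        return make_table(vals, genes={"P49841_S9": "GSK3B",
                                       "P16220_S133": "CREB1",
                                       "SP1_S10/S14": "DUAL"},
                          peptides={"P49841_S9": "AAAARWRGDSAAAAA"})

    def test_exact_gene_site_join(self):
        db = _db([("AKT1", "kinase", "GSK3B", "P49841", "S9", "")])
        (g,) = ks.match_substrates(self._table(), db)
        assert g.enzyme_name == "AKT1" and g.members == ["P49841_S9"]
        assert g.match_modes["P49841_S9"] == "db-site"

    def test_accession_mode(self):
        db = _db([("AKT1", "kinase", "", "P49841", "S9", "")])
        (g,) = ks.match_substrates(self._table(), db, match_on="accession")
        assert g.members == ["P49841_S9"]

    def test_motif_match_at_phospho_residue(self):
        db = KinaseSubstrateDB(
            pd.DataFrame(columns=["enzyme", "class", "substrate_gene",
                                  "substrate_acc", "site", "window"]),
            motif_groups={"basophilic": r"R.R..[ST]"})
        groups = ks.match_substrates(self._table(), db)
        (g,) = [g for g in groups if g.enzyme_name == "basophilic"]
        assert g.members == ["P49841_S9"]
        assert g.match_modes["P49841_S9"] == "motif"

    def test_multisite_feature_joins_once_per_group(self):
        db = _db([("CK2", "kinase", "DUAL", "SP1", "S10", ""),
                  ("CK2", "kinase", "DUAL", "SP1", "S14", "")])
        (g,) = ks.match_substrates(self._table(), db)
        assert g.members == ["SP1_S10/S14"]   # no double counting

    def test_empty_db_errors(self):
        empty = KinaseSubstrateDB(pd.DataFrame(
            columns=["enzyme", "class", "substrate_gene", "substrate_acc",
                     "site", "window"]))
        with pytest.raises(ValueError):
            ks.match_substrates(self._table(), empty)

    def test_coverage_report(self, small_table, small_truth):
        db = syn.truth_to_ksdb(small_truth)
        groups = ks.match_substrates(small_table, db)
        cov = ks.match_coverage(groups, small_table)
        planted = sum(len(m) for m in small_truth.enzyme_members.values())
        assert cov["matched_sites"] == planted
        assert cov["total_sites"] == len(small_table)


class TestOverTime:
    def test_mean_equals_hand_average(self, small_table, small_truth):
        db = syn.truth_to_ksdb(small_truth)
        groups = ks.match_substrates(small_table, db)
        mat = ks.ksea_over_time(small_table, groups)
        enz = groups[0].enzyme_name
        for t in small_table.times:
            reps = mat.per_replicate.loc[enz].xs(t, level="time")
            assert mat.mean.loc[enz, t] == pytest.approx(reps.mean(),
                                                         rel=1e-12)

    def test_single_replicate_mean_equals_per_replicate(self, small_truth):
        cfg = syn.PhosphoSimConfig(n_sites=200, n_proteins=100,
                                   n_regulated=150, replicates=1)
        table, _, truth = syn.generate_phospho_dataset(cfg, seed=13)
        groups = ks.match_substrates(table, syn.truth_to_ksdb(truth))
        mat = ks.ksea_over_time(table, groups)
        for t in table.times:
            np.testing.assert_allclose(
                mat.mean[t].to_numpy(),
                mat.per_replicate.xs(t, axis=1, level="time").iloc[:, 0]
                .to_numpy())

    def test_min_m_exclusion_listed(self, small_table, small_truth):
        db = syn.truth_to_ksdb(small_truth)
        groups = ks.match_substrates(small_table, db)
        groups[0].members[:] = groups[0].members[:1]
        mat = ks.ksea_over_time(small_table, groups, min_m=2)
        assert groups[0].enzyme_name in mat.excluded_low_m
        assert groups[0].enzyme_name not in mat.mean.index

    def test_highlight_convention(self, small_table, small_truth):
        db = syn.truth_to_ksdb(small_truth)
        mat = ks.ksea_over_time(small_table,
                                ks.match_substrates(small_table, db))
        assert mat.highlighted().equals(mat.mean.abs() > 2.0)


class TestClassification:
    def _matrix(self, rows, classes=None):
        mean = pd.DataFrame(rows).T
        mean.columns = [5, 30, 60]
        return ks.KseaMatrix(mean, mean, mean, mean,
                             {e: 5 for e in mean.index},
                             classes or {e: "kinase" for e in mean.index},
                             list(mean.index), [])

    def test_sustained_positive_is_early(self):
        cls = ks.classify_activity_trajectories(
            self._matrix({"K1": [3.0, 3.0, 3.0]}))
        assert cls.loc["K1", "direction"] == "positive"
        assert cls.loc["K1", "timing"] == "early"
        assert cls.loc["K1", "interpreted_activity"] == "activated"

    def test_late_negative(self):
        cls = ks.classify_activity_trajectories(
            self._matrix({"K1": [0.0, -0.2, -3.0]}))
        assert cls.loc["K1", "direction"] == "negative"
        assert cls.loc["K1", "timing"] == "late"

    def test_flat_profile_unchanged(self):
        cls = ks.classify_activity_trajectories(
            self._matrix({"K1": [0.0, 0.0, 0.0]}))
        assert cls.loc["K1", "direction"] == "unchanged"

    def test_phosphatase_negative_scores_mean_activation(self):
        cls = ks.classify_activity_trajectories(self._matrix(
            {"P1": [-3.0, -3.0, -3.0]}, classes={"P1": "phosphatase"}))
        assert cls.loc["P1", "interpreted_activity"] == "activated"

    def test_phosphatase_score_interpretation_inverts(self):
        s = ks.KseaScore("P1", z=2.5, p_value=0.01, m=5,
                         enzyme_class="phosphatase")
        assert s.interpreted_activity == "inhibited"
        k = ks.KseaScore("K1", z=2.5, p_value=0.01, m=5)
        assert k.interpreted_activity == "activated"


def test_planted_sign_recovery_over_seeds():
    """Replicate-mean z signs match planted enzyme directions for >= 95%
    of enzymes over 20 seeds (effect 0.8, noise 0.2, m = 10, 5 reps)."""
    hits = total = 0
    for seed in range(20):
        cfg = syn.PhosphoSimConfig(n_sites=300, n_proteins=150,
                                   n_regulated=150)
        table, _, truth = syn.generate_phospho_dataset(cfg, seed=100 + seed)
        groups = ks.match_substrates(table, syn.truth_to_ksdb(truth))
        mat = ks.ksea_over_time(table, groups)
        for enz, info in truth.enzyme_effects.items():
            # judge at a time point where the archetype is active
            active_t = {"early-sustained": 5, "early-transient": 5,
                        "intermediate": 30, "late": 60}[info["archetype"]]
            z = mat.mean.loc[enz, active_t]
            expected = 1.0 if info["direction"] == "up" else -1.0
            hits += int(np.sign(z) == expected)
            total += 1
    assert hits / total >= 0.95
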