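"""Generator contracts: determinism, planted effects, scenarios, SNP structure."""

import numpy as np
import pytest

from connaudit import (
    SyntheticSpec,
    correlate_features,
    generate_cohort,
    generate_timeseries,
    overlap_count,
    plant_snp_overlap,
    resolve_structure,
    top_k,
)
from connaudit.exceptions import SpecError


class TestDeterminism:
    def test_identical_spec_gives_identical_cohort(self):
        spec = SyntheticSpec(n=60, seed=13)
        a, b = generate_cohort(spec), generate_cohort(spec)
        assert a.phenotypes.data.equals(b.phenotypes.data)
        np.testing.assert_array_equal(
            a.connectivity["rest"].values, b.connectivity["rest"].values
        )
        np.testing.assert_array_equal(
            np.nan_to_num(a.snps.values), np.nan_to_num(b.snps.values)
        )

    def test_different_seeds_differ(self):
        a = generate_cohort(SyntheticSpec(n=60, seed=1))
        b = generate_cohort(SyntheticSpec(n=60, seed=2))
        assert not np.array_equal(
            a.connectivity["rest"].values, b.connectivity["rest"].values
        )

    def test_structure_matches_generation(self):
        spec = SyntheticSpec(n=40, seed=5)
        s1, s2 = resolve_structure(spec), resolve_structure(spec)
        np.testing.assert_array_equal(s1.race_edges, s2.race_edges)
        np.testing.assert_array_equal(s1.q_group_a, s2.q_group_a)


class TestPlantedEffects:
    def test_edge_effect_calibration(self):
        """Mean Fisher-z group difference on race edges ~ delta within 3 SEs."""
        spec = SyntheticSpec(n=2000, seed=3)
        cohort = generate_cohort(spec)
        structure = resolve_structure(spec)
        z = np.arctanh(cohort.connectivity["rest"].values)
        grp = cohort.phenotypes.data["race_code"].to_numpy().astype(bool)
        diff = (
            z[grp][:, structure.race_edges].mean()
            - z[~grp][:, structure.race_edges].mean()
        )
        tol = 3 * spec.sigma_z / np.sqrt(spec.n * spec.prop_b * (1 - spec.prop_b))
        assert diff == pytest.approx(spec.edge_effect, abs=tol)

    def test_confound_scenario_conditional_independence(self):
        """Given group, score is uncorrelated with every race edge."""
        spec = SyntheticSpec(n=2000, scenario="confound", seed=4)
        cohort = generate_cohort(spec)
        structure = resolve_structure(spec)
        grp = cohort.phenotypes.data["race_code"].to_numpy().astype(bool)
        X = cohort.connectivity["rest"].values
        y = cohort.phenotypes.data["wrat"].to_numpy()
        for sel in (grp, ~grp):
            amap = correlate_features(X[sel][:, structure.race_edges], y[sel])
            # no within-group association beyond sampling noise
            assert np.abs(amap.r).max() < 4 / np.sqrt(sel.sum())

    def test_direct_scenario_score_tracks_direct_edges(self):
        spec = SyntheticSpec(n=2000, scenario="direct", seed=5)
        cohort = generate_cohort(spec)
        structure = resolve_structure(spec)
        grp = cohort.phenotypes.data["race_code"].to_numpy().astype(bool)
        X = cohort.connectivity["rest"].values
        y = cohort.phenotypes.data["wrat"].to_numpy()
        amap = correlate_features(X[grp][:, structure.direct_edges], y[grp])
        assert np.abs(amap.r).mean() > 0.1

    def test_age_and_sex_independent_of_score(self):
        cohort = generate_cohort(SyntheticSpec(n=2000, seed=6))
        df = cohort.phenotypes.data
        assert abs(np.corrcoef(df["age_months"], df["wrat"])[0, 1]) < 0.07
        assert abs(np.corrcoef(df["sex"], df["wrat"])[0, 1]) < 0.07


class TestScenarioConstraints:
    def test_null_forces_no_effects(self):
        spec = SyntheticSpec(scenario="null", edge_effect=0.5,
                             score_mean_a=100.0, score_mean_b=90.0)
        assert spec.edge_effect == 0.0
        assert spec.score_mean_b == spec.score_mean_a

    def test_confound_rejects_explicit_score_effect(self):
        with pytest.raises(SpecError):
            SyntheticSpec(scenario="confound", score_effect=5.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"scenario": "bogus"},
            {"prop_b": 0.0},
            {"sigma_z": -1.0},
            {"fst": 1.0},
            {"n_race_edges": 1000, "p": 10},
            {"race_edges": (500,), "p": 10},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(SpecError):
            SyntheticSpec(**kwargs)

    def test_direct_auto_beta_matches_calibration(self):
        spec = SyntheticSpec(scenario="direct")
        expected = spec.score_sd / (spec.sigma_z * np.sqrt(spec.n_direct_edges))
        assert spec.effective_score_effect() == pytest.approx(expected)


class TestSNPs:
    def test_zero_fst_no_divergence(self):
        spec = SyntheticSpec(n=1500, fst=0.0, seed=7)
        cohort = generate_cohort(spec)
        structure = resolve_structure(spec)
        np.testing.assert_array_equal(structure.q_group_a, structure.q_group_b)
        d = cohort.snps.filled()
        grp = cohort.phenotypes.data["race_code"].to_numpy()
        amap = correlate_features(d, grp)
        # no SNP survives Bonferroni when frequencies are identical
        assert (amap.p_adj < 0.05).sum() == 0

    def test_dosages_valid_and_missingness_planted(self):
        cohort = generate_cohort(SyntheticSpec(n=300, seed=8))
        values = cohort.snps.values
        finite = values[np.isfinite(values)]
        assert set(np.unique(finite)) <= {0.0, 1.0, 2.0}
        miss_rate = np.isnan(values).mean()
        assert miss_rate == pytest.approx(0.1, abs=0.02)

    def test_planted_overlap_recovered(self):
        """Top-20-by-|r| race and score SNP lists share ~6 planted SNPs."""
        overlaps = []
        for seed in range(5):
            spec = plant_snp_overlap(
                SyntheticSpec(n=800, scenario="confound", fst=0.05, seed=seed),
                k=20, shared=6,
            )
            cohort = generate_cohort(spec)
            d = cohort.snps.filled()
            ids = np.array(cohort.snps.snp_ids)
            race = correlate_features(d, cohort.phenotypes.data["race_code"], feature_ids=ids)
            wrat = correlate_features(d, cohort.phenotypes.data["wrat"], feature_ids=ids)
            overlaps.append(overlap_count(top_k(race, 20), top_k(wrat, 20)))
        assert all(abs(o - 6) <= 2 for o in overlaps)
        assert abs(np.mean(overlaps) - 6) <= 1

    def test_shared_equals_k_limit(self):
        spec = plant_snp_overlap(
            SyntheticSpec(n=1200, scenario="confound", fst=0.05, seed=1), k=10, shared=10
        )
        cohort = generate_cohort(spec)
        d = cohort.snps.filled()
        ids = np.array(cohort.snps.snp_ids)
        race = correlate_features(d, cohort.phenotypes.data["race_code"], feature_ids=ids)
        wrat = correlate_features(d, cohort.phenotypes.data["wrat"], feature_ids=ids)
        assert overlap_count(top_k(race, 10), top_k(wrat, 10)) >= 9

    def test_no_planting_gives_chance_overlap(self):
        spec = plant_snp_overlap(
            SyntheticSpec(n=800, scenario="confound", fst=0.05, seed=2), k=20, shared=0
        )
        cohort = generate_cohort(spec)
        d = cohort.snps.filled()
        ids = np.array(cohort.snps.snp_ids)
        race = correlate_features(d, cohort.phenotypes.data["race_code"], feature_ids=ids)
        wrat = correlate_features(d, cohort.phenotypes.data["wrat"], feature_ids=ids)
        assert overlap_count(top_k(race, 20), top_k(wrat, 20)) <= 4

    def test_infeasible_plant_rejected(self):
        with pytest.raises(SpecError):
            plant_snp_overlap(SyntheticSpec(n_snps=30), k=20, shared=5)
        with pytest.raises(SpecError):
            plant_snp_overlap(SyntheticSpec(), k=5, shared=6)


class TestTimeseries:
    def test_identity_covariance_near_zero_correlations(self):
        from connaudit import pearson_fc

        ts = generate_timeseries(np.eye(5), T=2000, seed=9)
        fc = pearson_fc(ts)
        assert np.abs(fc.to_vector()).max() < 0.1

    def test_pairwise_correlation_consistency(self):
        from connaudit import pearson_fc

        cov = np.array([[1.0, 0.7], [0.7, 1.0]])
        ts = generate_timeseries(cov, T=5000, seed=10)
        fc = pearson_fc(ts)
        assert fc.matrix[0, 1] == pytest.approx(0.7, abs=0.05)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(SpecError):
            generate_timeseries(np.array([[1.0, 2.0], [2.0, 1.0]]), T=100, seed=0)
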