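"""Discovery scan: transform, per-CpG fit, permutation null, FWER estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylaging import ewas
from methylaging.ewas import (
    BETA_CLAMP_EPS,
    PermutationNull,
    beta_to_m,
    estimate_fwer,
    filter_autosomal,
    fit_cpg_ols,
    m_to_beta,
    permutation_null,
    run_scan,
    significant_set,
)
from methylaging.synthetic_data import (
    CohortDesign,
    SimulationConfig,
    simulate_cohort,
    simulate_manifest,
)

from conftest import make_study


class TestBetaToM:
    @pytest.mark.parametrize(
        "beta, m",
        [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)],
    )
    def test_closed_form_values(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m, abs=1e-12)

    def test_boundaries_clamped_finite(self):
        eps = BETA_CLAMP_EPS
        assert beta_to_m(1.0) == pytest.approx(np.log2((1 - eps) / eps))
        assert beta_to_m(0.0) == pytest.approx(np.log2(eps / (1 - eps)))

    @pytest.mark.parametrize("bad", [-0.1, 1.1, np.nan])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            beta_to_m(bad)

    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    @settings(deadline=None)
    def test_inverse_recovers_beta_away_from_clamp(self, beta):
        assert m_to_beta(beta_to_m(beta)) == pytest.approx(beta, abs=1e-9)

    def test_strictly_increasing(self):
        grid = np.linspace(0.001, 0.999, 500)
        assert (np.diff(beta_to_m(grid)) > 0).all()


class TestFilterAutosomal:
    def test_sex_chromosome_cpgs_dropped(self, manifest10, make_study_fn):
        beta = pd.DataFrame(
            np.full((3, 10), 0.5),
            index=pd.Index(["a", "b", "c"], name="sample_id"),
            columns=manifest10.cpg_ids,
        )
        study = make_study_fn(beta, ages=[60, 70, 80])
        man2, study2 = filter_autosomal(manifest10, study)
        assert len(man2) == 7 and study2.beta.shape[1] == 7
        assert not set(man2.table["chromosome"]) & {"X", "Y"}
        # order preserved
        assert list(study2.cpg_ids) == [c for c in manifest10.cpg_ids if c not in
                                        {"cg008", "cg009", "cg010"}]

    def test_identity_without_sex_chromosomes(self, manifest10, make_study_fn):
        keep = [c for c in manifest10.cpg_ids
                if manifest10.table.loc[c, "chromosome"] not in {"X", "Y"}]
        man = manifest10.subset(keep)
        beta = pd.DataFrame(
            np.full((3, len(keep)), 0.4),
            index=pd.Index(["a", "b", "c"], name="sample_id"), columns=keep,
        )
        study = make_study_fn(beta, ages=[60, 70, 80])
        man2, study2 = filter_autosomal(man, study)
        pd.testing.assert_frame_equal(man2.table, man.table)
        pd.testing.assert_frame_equal(study2.beta, study.beta)

    def test_all_sex_chromosomes_warns_and_empties(self, manifest10, make_study_fn, caplog):
        ids = ["cg008", "cg009", "cg010"]
        man = manifest10.subset(ids)
        beta = pd.DataFrame(
            np.full((3, 3), 0.4), index=pd.Index(["a", "b", "c"], name="sample_id"),
            columns=ids,
        )
        study = make_study_fn(beta, ages=[60, 70, 80])
        with caplog.at_level("WARNING"):
            man2, study2 = filter_autosomal(man, study)
        assert len(man2) == 0 and study2.beta.shape[1] == 0
        assert any("no autosomal" in r.message for r in caplog.records)


def noise_free_study(n=20, slope=0.02, intercept=1.0, seed=0):
    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(50, 90, n))
    m = intercept + slope * ages
    beta = pd.DataFrame(
        {"cg1": m_to_beta(m)}, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    )
    study = make_study(beta, ages=ages)
    # constant cells so the fit is exactly univariate in age
    study.cells.iloc[:, :] = np.tile(study.cells.iloc[0].to_numpy(), (n, 1))
    return study


class TestFitCpgOls:
    def test_exact_noise_free_fit(self):
        study = noise_free_study(slope=0.02)
        m = beta_to_m(study.beta["cg1"].to_numpy())
        slope, se, p = fit_cpg_ols(m, study.sheet["age"].to_numpy(), study.cells)
        assert slope == pytest.approx(0.02, abs=1e-10)
        assert p < 1e-12

    def test_negative_slope_direction(self):
        study = noise_free_study(slope=-0.02)
        scan = run_scan(study)
        assert scan.loc["cg1", "direction"] == "loss"

    def test_permuted_age_attenuates_slope(self):
        # brute-force permutation distribution: shuffling age destroys the signal
        study = noise_free_study(n=20, slope=0.02)
        m = beta_to_m(study.beta["cg1"].to_numpy())
        age = study.sheet["age"].to_numpy()
        rng = np.random.default_rng(42)
        hits = sum(
            abs(fit_cpg_ols(m, age[rng.permutation(20)], study.cells)[0]) < 0.02
            for _ in range(200)
        )
        assert hits >= 190

    def test_rank_deficient_design_names_columns(self):
        study = noise_free_study()
        m = beta_to_m(study.beta["cg1"].to_numpy())
        age = np.full(len(m), 70.0)  # constant age collinear with intercept
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            fit_cpg_ols(m, age, study.cells)


class TestRunScan:
    def test_single_cpg_scan_matches_ols_fit(self):
        cfg = SimulationConfig(n_cpgs=1, seed=3, frac_affected=1.0)
        man = simulate_manifest(cfg)
        study, _ = simulate_cohort(
            man, CohortDesign(name="one", n_subjects=40, age_ranges=[(50, 90)]), cfg
        )
        scan = run_scan(study)
        m = beta_to_m(study.beta.iloc[:, 0].to_numpy())
        slope, se, p = fit_cpg_ols(m, study.sheet["age"].to_numpy(), study.cells)
        assert scan.iloc[0]["slope"] == pytest.approx(slope, rel=1e-9)
        assert scan.iloc[0]["se"] == pytest.approx(se, rel=1e-9)
        assert scan.iloc[0]["p_obs"] == pytest.approx(p, rel=1e-6)

    def test_vectorised_scan_agrees_with_per_cpg_refits(self):
        # dual route: closed-form matrix OLS vs statsmodels, every CpG
        cfg = SimulationConfig(n_cpgs=12, seed=9, frac_affected=0.5)
        man = simulate_manifest(cfg)
        study, _ = simulate_cohort(
            man, CohortDesign(name="dual", n_subjects=35, age_ranges=[(55, 85)]), cfg
        )
        scan = run_scan(study)
        age = study.sheet["age"].to_numpy()
        for cpg in study.cpg_ids:
            m = beta_to_m(study.beta[cpg].to_numpy())
            slope, se, p = fit_cpg_ols(m, age, study.cells)
            assert scan.loc[cpg, "slope"] == pytest.approx(slope, rel=1e-8)
            assert scan.loc[cpg, "p_obs"] == pytest.approx(p, rel=1e-6)

    def test_planted_large_effect_ranks_first(self):
        cfg = SimulationConfig(n_cpgs=50, seed=21, frac_affected=0.0)
        man = simulate_manifest(cfg)
        study, _ = simulate_cohort(
            man, CohortDesign(name="plant", n_subjects=60, age_ranges=[(50, 90)]), cfg
        )
        beta = study.beta.copy()
        age = study.sheet["age"].to_numpy()
        big = beta_to_m(beta["cg0000010"].to_numpy()) + 0.05 * (age - age.mean())
        beta["cg0000010"] = m_to_beta(big)
        study2 = type(study)(beta, study.sheet, study.cells)
        scan = run_scan(study2)
        assert scan["p_obs"].idxmin() == "cg0000010"
        assert (scan["p_obs"] > 0).all()


class TestPermutationNull:
    def small_null_study(self, n_cpgs=10, n_subjects=30, seed=5):
        cfg = SimulationConfig(n_cpgs=n_cpgs, seed=seed, frac_affected=0.0)
        man = simulate_manifest(cfg)
        study, _ = simulate_cohort(
            man, CohortDesign(name="null", n_subjects=n_subjects, age_ranges=[(50, 90)]), cfg
        )
        return study

    def test_fixed_seed_reproducible(self):
        study = self.small_null_study()
        n1 = permutation_null(study, k=3, seed=11)
        n2 = permutation_null(study, k=3, seed=11)
        np.testing.assert_array_equal(n1.min_p, n2.min_p)

    def test_single_cpg_min_p_is_that_cpgs_p(self):
        study = self.small_null_study(n_cpgs=1)
        null = permutation_null(study, k=5, seed=2)
        # recompute each permuted fit by replaying the same generator
        age = study.sheet["age"].to_numpy()
        m = beta_to_m(study.beta.iloc[:, 0].to_numpy())
        rng = np.random.default_rng(2)
        for i in range(5):
            perm = rng.permutation(len(age))
            _, _, p = fit_cpg_ols(m, age[perm], study.cells)
            assert null.min_p[i] == pytest.approx(p, rel=1e-6)

    def test_min_p_small_against_observed_distribution(self):
        study = self.small_null_study(n_cpgs=100, n_subjects=40)
        null = permutation_null(study, k=50, seed=8)
        observed = run_scan(study)["p_obs"]
        assert (null.min_p <= observed.median()).all()

    def test_low_k_warns_and_zero_k_rejected(self, caplog):
        study = self.small_null_study(n_cpgs=2)
        with pytest.raises(ValueError):
            permutation_null(study, k=0)
        with caplog.at_level("WARNING"):
            permutation_null(study, k=5, seed=1)
        assert any("resolution" in r.message for r in caplog.records)


class TestEstimateFwer:
    def test_counting_example(self):
        null = PermutationNull(min_p=np.array([0.001, 0.01, 0.02, 0.05]), k=4, seed=0)
        assert estimate_fwer(np.array([0.015]), null)[0] == 0.5

    def test_extremes(self):
        null = PermutationNull(min_p=np.array([0.01, 0.02, 0.2, 0.9]), k=4, seed=0)
        fwer = estimate_fwer(np.array([0.001, 1.0]), null)
        assert fwer[0] == 0.0
        assert fwer[1] == 1.0

    @given(
        p_obs=st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=2, max_size=30),
        min_p=st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=25),
    )
    @settings(deadline=None, max_examples=60)
    def test_monotone_in_p_obs_and_on_fwer_grid(self, p_obs, min_p):
        null = PermutationNull(min_p=np.array(min_p), k=len(min_p), seed=0)
        p_arr = np.array(p_obs)
        fwer = estimate_fwer(p_arr, null)
        order = np.argsort(p_arr)
        assert (np.diff(fwer[order]) >= 0).all()
        grid = np.round(fwer * len(min_p))
        np.testing.assert_allclose(fwer, grid / len(min_p))


class TestSignificantSet:
    def frame(self, fwer, direction):
        return pd.DataFrame(
            {
                "slope": [1.0 if d == "gain" else -1.0 for d in direction],
                "direction": direction,
                "fwer": fwer,
            },
            index=pd.Index([f"c{i}" for i in range(len(fwer))], name="cpg_id"),
        )

    def test_none_pass_at_high_fwer(self):
        gains, losses = significant_set(self.frame([0.2, 0.2], ["gain", "loss"]), 0.05)
        assert len(gains) == len(losses) == 0

    def test_boundary_is_strict(self):
        gains, losses = significant_set(
            self.frame([0.05, 0.049], ["gain", "loss"]), 0.05
        )
        assert list(gains) == []
        assert list(losses) == ["c1"]
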