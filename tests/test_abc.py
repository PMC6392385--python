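"""ABC engine: rejection, model choice, parameter posteriors, time scale."""

import numpy as np
import pandas as pd
import pytest

from miteabc import abc as A
from miteabc import sumstats
from miteabc.abc import (
    ReferenceTable,
    Retained,
    SampleConfig,
    build_reference_table,
    choose_model,
    estimate_parameters,
    generations_to_years,
    model_check,
    reject,
)
from miteabc.scenarios import PARAM_NAMES, Prior, PriorSet


def small_table(rng, n_per=60, ids=(1, 2, 9), seed=11):
    priors = PriorSet().replace(
        N_LW=Prior(500.0, 5000.0), N_ML=Prior(500.0, 5000.0), N_HG=Prior(500.0, 5000.0),
        t1=Prior(10.0, 2000.0), t2=Prior(10.0, 4000.0), mu=Prior(1e-6, 5e-6),
    )
    cfg = SampleConfig(sample_sizes={"LW": 4, "ML": 4, "HG": 4}, length=200)
    return build_reference_table(ids, priors, n_per, cfg, seed=seed)


class TestReferenceTable:
    def test_single_row_table_is_finite(self, rng):
        table = small_table(rng, n_per=1, ids=(2,))
        assert table.n_rows == 1
        assert np.isfinite(table.stats).all()

    def test_same_seed_reproduces_table(self, rng):
        t1 = small_table(rng, n_per=5, seed=3)
        t2 = small_table(rng, n_per=5, seed=3)
        assert np.array_equal(t1.stats, t2.stats)
        assert np.array_equal(t1.params, t2.params)

    def test_prior_passthrough_for_unconstrained_scenario(self):
        # scenario 9 has no t1<t2 constraint: every marginal matches its prior
        from scipy.stats import kstest

        priors = PriorSet()
        cfg = SampleConfig(sample_sizes={"LW": 2, "ML": 2, "HG": 2}, length=50)
        table = build_reference_table([9], priors, 1000, cfg, seed=5)
        for j, name in enumerate(PARAM_NAMES):
            lo, hi = priors[name].low, priors[name].high
            p = kstest(table.params[:, j], "uniform", args=(lo, hi - lo)).pvalue
            assert p > 1e-3, name

    def test_roundtrip_through_file(self, rng, tmp_path):
        table = small_table(rng, n_per=4)
        path = tmp_path / "ref.tsv"
        table.write(path)
        back = ReferenceTable.read(path)
        assert np.allclose(back.stats, table.stats)
        assert np.array_equal(back.scenario, table.scenario)
        assert path.read_text().startswith("# miteabc reference table")


class TestReject:
    def test_delta_one_retains_everything(self, rng):
        table = small_table(rng)
        ret = reject(table, table.stats[0], 1.0)
        assert len(ret.indices) == table.n_rows

    def test_exact_match_has_zero_distance_and_max_weight(self, rng):
        table = small_table(rng)
        ret = reject(table, table.stats[7], 0.2)
        assert ret.indices[0] == 7
        assert ret.distances[0] == 0.0
        assert ret.weights[0] == ret.weights.max()

    def test_retained_set_matches_brute_force_sort(self, rng):
        table = small_table(rng, n_per=34, ids=(1, 2, 9))  # ~100 rows
        obs = table.stats.mean(axis=0)
        ret = reject(table, obs, 0.25)
        center = np.median(table.stats, axis=0)
        mad = np.median(np.abs(table.stats - center), axis=0)
        mad[mad == 0] = table.stats[:, mad == 0].std(axis=0)
        use = mad > 0
        z = (table.stats[:, use] - center[use]) / mad[use]
        zo = (obs[use] - center[use]) / mad[use]
        d = np.sqrt(((z - zo) ** 2).sum(axis=1))
        expected = set(np.argsort(d, kind="stable")[: len(ret.indices)])
        assert set(ret.indices) == expected

    def test_underpowered_retention_rejected(self, rng):
        table = small_table(rng, n_per=30)
        with pytest.raises(ValueError, match="retains"):
            reject(table, table.stats[0], 1e-5)

    def test_column_rescaling_leaves_retained_set_unchanged(self, rng):
        table = small_table(rng)
        obs = table.stats[3]
        ret1 = reject(table, obs, 0.1)
        scaled = table.stats.copy()
        scaled[:, 5] *= 100.0
        obs2 = obs.copy()
        obs2[5] *= 100.0
        table2 = ReferenceTable(
            table.scenario, table.params, scaled, table.priors, table.sample_config
        )
        ret2 = reject(table2, obs2, 0.1)
        assert np.array_equal(np.sort(ret1.indices), np.sort(ret2.indices))


def synthetic_retained(rng, n=300, sep=4.0, k=3, d=5):
    """Hand-built retained set with k scenario clouds separated by ``sep``."""
    scen = np.repeat(np.arange(1, k + 1), n // k)
    dev = rng.normal(size=(n, d))
    for i in range(k):
        dev[scen == i + 1, 0] += sep * i
    return Retained(
        indices=np.arange(n),
        distances=np.linspace(0, 1, n),
        weights=np.ones(n),
        scenario=scen,
        params=np.abs(rng.normal(size=(n, len(PARAM_NAMES)))) + 1.0,
        deviations=dev,
        scale=np.ones(33),
        center=np.zeros(33),
        tolerance=0.1,
    )


class TestChooseModel:
    def test_probabilities_sum_to_one_with_valid_cis(self, rng):
        ret = synthetic_retained(rng, sep=1.0)
        mc = choose_model(ret)
        assert mc.table["prob"].sum() == pytest.approx(1.0, abs=1e-6)
        assert ((mc.table["lower"] <= mc.table["prob"]) & (mc.table["prob"] <= mc.table["upper"])).all()
        assert (mc.table["lower"] >= 0).all() and (mc.table["upper"] <= 1).all()

    def test_forced_separation_gives_confident_winner(self, rng):
        # scenario-1 rows coincide with the observed point; others are far
        ret = synthetic_retained(rng, sep=0.0)
        ret.deviations[ret.scenario == 1] = rng.normal(scale=0.05, size=(100, 5))
        ret.deviations[ret.scenario == 2] += 8.0
        ret.deviations[ret.scenario == 3] -= 8.0
        mc = choose_model(ret)
        assert mc.best_scenario == 1
        assert mc.table.loc[1, "prob"] > 0.99

    def test_identical_distributions_split_evenly(self, rng):
        ret = synthetic_retained(rng, sep=0.0, k=2, n=400)
        mc = choose_model(ret)
        assert mc.table["prob"].max() < 0.65  # ~(0.5, 0.5) within MC error

    def test_ranking_agrees_with_rejection_frequencies(self, rng):
        # well-separated clouds: logistic and kernel-weighted retained
        # proportions must rank scenarios identically
        ret = synthetic_retained(rng, sep=0.0)
        ret.deviations[ret.scenario == 1, 0] -= 3.0
        ret.deviations[ret.scenario == 3, 0] += 3.0
        ret.deviations[ret.scenario == 2] *= 0.3  # scenario 2 tight at origin
        d = np.linalg.norm(ret.deviations, axis=1)
        ret.distances[:] = d
        ret.weights[:] = 1.0 - (d / d.max()) ** 2
        mc = choose_model(ret)
        freq = pd.Series(ret.weights).groupby(ret.scenario).sum()
        assert mc.best_scenario == freq.idxmax() == 2

    def test_single_scenario_rejected(self, rng):
        ret = synthetic_retained(rng, k=3)
        only = ret.scenario == 1
        ret1 = Retained(
            ret.indices[only], ret.distances[only], ret.weights[only],
            ret.scenario[only], ret.params[only], ret.deviations[only],
            ret.scale, ret.center, ret.tolerance,
        )
        with pytest.raises(ValueError, match=">= 2 scenarios"):
            choose_model(ret1)

    def test_invariant_to_table_duplication(self, rng):
        ret = synthetic_retained(rng, sep=2.0)
        mc1 = choose_model(ret)
        dup = Retained(
            np.r_[ret.indices, ret.indices], np.r_[ret.distances, ret.distances],
            np.r_[ret.weights, ret.weights], np.r_[ret.scenario, ret.scenario],
            np.vstack([ret.params, ret.params]), np.vstack([ret.deviations, ret.deviations]),
            ret.scale, ret.center, ret.tolerance,
        )
        mc2 = choose_model(dup)
        assert np.allclose(mc1.table["prob"], mc2.table["prob"], atol=1e-3)


def retained_for_estimation(rng, n=400, scenario=2):
    priors = PriorSet()
    params = np.column_stack(
        [PriorSet()[p].sample(rng, n) for p in PARAM_NAMES]
    )
    # stats deviations correlated with t2 so the regression has signal
    dev = rng.normal(size=(n, 6))
    dev[:, 0] = (params[:, 4] - params[:, 4].mean()) / params[:, 4].std() + rng.normal(
        scale=0.3, size=n
    )
    return (
        Retained(
            indices=np.arange(n),
            distances=np.linspace(0, 1, n),
            weights=1.0 - np.linspace(0, 1, n) ** 2,
            scenario=np.full(n, scenario),
            params=params,
            deviations=dev,
            scale=np.ones(33),
            center=np.zeros(33),
            tolerance=0.05,
        ),
        priors,
    )


class TestEstimateParameters:
    def test_quantiles_monotone_and_mode_in_bounds(self, rng):
        ret, priors = retained_for_estimation(rng)
        post = estimate_parameters(ret, 2, priors)
        for p, row in post.table.iterrows():
            assert row["q2.5"] <= row["q5"] <= row["median"] <= row["q95"] <= row["q97.5"]
            assert priors[p].low <= row["mode"] <= priors[p].high

    def test_zero_slope_leaves_draws_unadjusted(self, rng):
        ret, priors = retained_for_estimation(rng)
        ret.deviations[:] = 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            post = estimate_parameters(ret, 2, priors)
        t2 = post.samples["t2"].to_numpy()
        assert np.allclose(np.sort(t2), np.sort(ret.params[:, 4]), rtol=1e-6)

    def test_too_few_rows_rejected(self, rng):
        ret, priors = retained_for_estimation(rng, n=30)
        with pytest.raises(ValueError, match="need >="):
            estimate_parameters(ret, 2, priors)

    def test_scenario9_reports_no_t1_scenario7_reports_r(self, rng):
        ret, priors = retained_for_estimation(rng, scenario=9)
        post = estimate_parameters(ret, 9, priors)
        assert "t1" not in post.table.index and "r" not in post.table.index
        ret7, _ = retained_for_estimation(rng, scenario=7)
        post7 = estimate_parameters(ret7, 7, priors)
        assert "r" in post7.table.index

    def test_adjustment_shrinks_error_toward_truth(self, rng):
        # with a strong linear stat-parameter relationship, the adjusted
        # posterior concentrates near the value implied by zero deviation
        ret, priors = retained_for_estimation(rng, n=2000)
        post = estimate_parameters(ret, 2, priors)
        raw_sd = ret.params[:, 4].std()
        adj_sd = post.samples["t2"].std()
        assert adj_sd < raw_sd


class TestModelCheck:
    def test_observed_from_generator_is_not_flagged_everywhere(self, rng):
        table = small_table(rng, n_per=80, ids=(2,))
        obs = table.stats[40]
        ret = reject(table, obs, 0.9)
        priors = table.priors
        post = estimate_parameters(ret, 2, priors)
        report = model_check(
            post, obs, n_sims=120, sample_config=table.sample_config, seed=8
        )
        assert len(report.flagged) < 10
        assert report.stat_table["tail_prob"].between(0, 1).all()

    def test_far_outlier_statistic_flagged(self, rng):
        table = small_table(rng, n_per=80, ids=(2,))
        obs = table.stats[40].copy()
        ret = reject(table, table.stats[40], 0.9)
        post = estimate_parameters(ret, 2, table.priors)
        obs[2] = 1e6  # LW mean pairwise differences, absurdly large
        report = model_check(
            post, obs, n_sims=120, sample_config=table.sample_config, seed=8
        )
        assert sumstats.STAT_NAMES[2] in report.flagged

    def test_pca_cloud_is_centred(self, rng):
        table = small_table(rng, n_per=60, ids=(2,))
        obs = table.stats[10]
        ret = reject(table, obs, 0.9)
        post = estimate_parameters(ret, 2, table.priors)
        report = model_check(
            post, obs, n_sims=100, sample_config=table.sample_config, seed=9
        )
        assert np.allclose(report.pc_scores.mean(axis=0), 0.0, atol=1e-8)


class TestGenerationsToYears:
    @pytest.mark.parametrize(
        "gens,rate,years",
        [
            (87_900, 16, 5_494),
            (87_900, 8, 10_988),
            (320_000, 16, 20_000),
            (320_000, 8, 40_000),
            (168_000, 16, 10_500),
            (395_000, 8, 49_375),
            (0, 8, 0),
        ],
    )
    def test_printed_conversions(self, gens, rate, years):
        assert generations_to_years(gens, rate) == years

    def test_half_up_rounding(self):
        assert generations_to_years(197_500, 8) == 24_688  # 24687.5 rounds up
        assert generations_to_years(43_950, 8) == 5_494  # 5493.75 rounds up

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            generations_to_years(100, 0)
        with pytest.raises(ValueError):
            generations_to_years(-1, 8)
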