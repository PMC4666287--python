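import numpy as np
import pandas as pd
import pytest

from covsel.data_io import design_matrix
from covsel.simulate import (CovariateConfig, EffectScheme, ReplicateMetrics,
                             SimulationTruth, center_within_groups, evaluate,
                             make_covariates, make_parameters, run_scenario,
                             scenario_config, simulate_counts)


class TestCenterWithinGroups:
    def test_hand_example(self):
        out = center_within_groups([1, 2, 3, 4], ["A", "A", "B", "B"])
        np.testing.assert_allclose(out, [-0.5, 0.5, -0.5, 0.5])

    def test_already_centered_unchanged(self):
        x = np.array([-1.0, 1.0, -2.0, 2.0])
        np.testing.assert_allclose(
            center_within_groups(x, ["A", "A", "B", "B"]), x)

    def test_orthogonal_to_group_indicators(self, rng):
        for _ in range(100):
            n = rng.integers(4, 30)
            x = rng.standard_normal(n)
            g = rng.choice(["A", "B", "C"], n)
            out = center_within_groups(x, g)
            for lev in np.unique(g):
                assert abs(out[g == lev].sum()) < 1e-9


class TestMakeCovariates:
    def test_group_sizes_as_even_as_possible(self):
        ct = make_covariates(31, CovariateConfig(), seed=0)
        counts = ct.data["line"].value_counts()
        assert sorted(counts) == [15, 16]

    def test_orthogonalized_mode_centers_within_groups(self):
        ct = make_covariates(
            config=CovariateConfig(confounded="orthogonalized"), seed=3)
        trait = ct.data["trait"].to_numpy()
        line = ct.data["line"].to_numpy()
        for lev in ("L1", "L2"):
            assert abs(trait[line == lev].mean()) < 1e-12

    def test_confounded_mode_shifts_groups(self):
        ct = make_covariates(
            config=CovariateConfig(confounded="confounded", delta=2.0), seed=3)
        trait = ct.data["trait"].to_numpy()
        line = ct.data["line"].to_numpy()
        assert trait[line == "L1"].mean() > trait[line == "L2"].mean() + 0.5

    def test_delta_zero_independent_of_line(self):
        # two-sample t-test rejection rate near its nominal level
        from scipy import stats
        rejections = 0
        n_sim = 400
        for s in range(n_sim):
            ct = make_covariates(
                config=CovariateConfig(confounded="confounded", delta=0.0),
                seed=10_000 + s)
            trait = ct.data["trait"].to_numpy()
            line = ct.data["line"].to_numpy()
            t, p = stats.ttest_ind(trait[line == "L1"], trait[line == "L2"])
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sim <= 0.09

    def test_impossible_level_allocation_errors(self):
        with pytest.raises(ValueError, match="levels"):
            make_covariates(4, CovariateConfig(categorical_levels=(6,)), seed=0)


class TestMakeParameters:
    def test_exact_ee_count(self):
        ct = make_covariates(config=CovariateConfig(), seed=1)
        truth = make_parameters(5000, 0.8, ct, seed=2)
        assert int((~truth.is_DE).sum()) == 4000

    def test_nested_chain_partition(self):
        cfg = scenario_config(2, m=5000)
        ct = make_covariates(config=cfg.covariates, seed=1)
        truth = make_parameters(5000, 0.8, ct, seed=2,
                                relevant_sets=cfg.relevant_sets)
        sizes = pd.Series([tuple(sorted(s)) for s in truth.relevant_set]
                          ).value_counts()
        assert set(sizes) == {1250}

    def test_ee_genes_have_zero_primary_block(self):
        ct = make_covariates(config=CovariateConfig(), seed=1)
        truth = make_parameters(300, 0.7, ct, seed=4)
        X = design_matrix(ct, range(1, ct.k + 1))
        blk = X.column_blocks[1]
        assert (truth.beta[~truth.is_DE][:, blk] == 0).all()
        assert (np.abs(truth.beta[truth.is_DE][:, blk]) >= 0.1).all()

    def test_effects_restricted_to_relevant_set(self):
        ct = make_covariates(config=CovariateConfig(), seed=1)
        truth = make_parameters(200, 0.8, ct, seed=4,
                                relevant_sets=(frozenset({1, 2}),))
        X = design_matrix(ct, range(1, ct.k + 1))
        for j in (3, 4, 5, 6):
            assert (truth.beta[:, X.column_blocks[j]] == 0).all()

    def test_non_integer_pi0m_warns(self):
        ct = make_covariates(config=CovariateConfig(), seed=1)
        with pytest.warns(UserWarning, match="rounding"):
            make_parameters(10, 0.65, ct, seed=0)


class TestSimulateCounts:
    def test_fixed_seed_reproducible(self):
        ct = make_covariates(config=CovariateConfig(), seed=1)
        truth = make_parameters(100, 0.8, ct, seed=9)
        np.testing.assert_array_equal(simulate_counts(truth).counts,
                                      simulate_counts(truth).counts)

    def test_poisson_limit_dispersion_index(self):
        ct = make_covariates(2, CovariateConfig(n=2, n_continuous=0,
                                                categorical_levels=()), seed=0)
        # one gene, omega=0, constant mean 50 across 10000 draws
        truth = SimulationTruth(
            beta=np.array([[np.log(50.0), 0.0]]),
            omega=np.array([0.0]),
            relevant_set=[frozenset({1})],
            is_DE=np.array([False]),
            pi0=1.0,
            covariates=ct,
            offsets=np.zeros(2),
            gene_ids=np.array(["g0"], dtype=object),
            seed=3,
        )
        draws = np.concatenate([
            simulate_counts(SimulationTruth(**{**truth.__dict__, "seed": s})
                            ).counts.ravel()
            for s in range(5000)
        ])
        index = draws.var() / draws.mean()
        assert 0.95 <= index <= 1.05

    def test_doubling_offsets_doubles_means(self):
        ct = make_covariates(config=CovariateConfig(), seed=1)
        truth = make_parameters(400, 0.8, ct, seed=9)
        base = simulate_counts(truth).counts.mean()
        shifted = SimulationTruth(**{**truth.__dict__,
                                     "offsets": truth.offsets + np.log(2)})
        ratio = simulate_counts(shifted).counts.mean() / base
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_overflow_names_gene(self):
        ct = make_covariates(config=CovariateConfig(), seed=1)
        truth = make_parameters(5, 0.8, ct, seed=9)
        truth.beta[2, 0] = 40.0
        with pytest.raises(OverflowError, match="gene3"):
            simulate_counts(truth)


class TestEvaluate:
    def _truth(self, is_de):
        ct = make_covariates(config=CovariateConfig(), seed=1)
        m = len(is_de)
        return SimulationTruth(
            beta=np.zeros((m, 1)), omega=np.zeros(m),
            relevant_set=[frozenset({1})] * m, is_DE=np.asarray(is_de),
            pi0=float(np.mean(~np.asarray(is_de))), covariates=ct,
            offsets=np.zeros(ct.n),
            gene_ids=np.array([f"gene{i + 1}" for i in range(m)], dtype=object),
            seed=0)

    def _table(self, truth, p, q):
        return pd.DataFrame({"gene_id": truth.gene_ids, "p": p, "q": q})

    def test_no_rejections(self):
        truth = self._truth([True, False, True, False])
        met = evaluate(self._table(truth, [0.5] * 4, [0.9] * 4), truth)
        assert met.FDP == 0 and met.NTP == 0

    def test_perfect_separation_pauc(self):
        is_de = [True] * 50 + [False] * 50
        truth = self._truth(is_de)
        p = np.where(is_de, 1e-6, 0.9)
        met = evaluate(self._table(truth, p, p), truth)
        assert met.PAUC == pytest.approx(0.05, abs=1e-9)
        assert met.NTP == 50 and met.FDP == 0

    def test_counts_false_discoveries(self):
        truth = self._truth([True, False, False, False])
        met = evaluate(self._table(truth, [0.001] * 2 + [0.9] * 2,
                                   [0.01, 0.01, 0.9, 0.9]), truth)
        assert met.R == 2 and met.NTP == 1 and met.FDP == 0.5

    def test_random_scores_null_pauc(self, rng):
        # closed form for a useless classifier: PAUC = 0.05^2 / 2
        paucs = []
        for _ in range(200):
            is_de = np.zeros(2000, dtype=bool)
            is_de[:1000] = True
            truth = self._truth(is_de)
            p = rng.uniform(0, 1, 2000)
            paucs.append(evaluate(self._table(truth, p, np.ones(2000)),
                                  truth).PAUC)
        se = np.std(paucs, ddof=1) / np.sqrt(len(paucs))
        assert abs(np.mean(paucs) - 0.00125) < 3 * se + 1e-5

    def test_misaligned_genes_error(self):
        truth = self._truth([True, False])
        tab = pd.DataFrame({"gene_id": ["nope"], "p": [0.1], "q": [0.1]})
        with pytest.raises(ValueError, match="absent"):
            evaluate(tab, truth)


class TestRunScenario:
    def test_smoke_two_replicates_well_formed(self):
        cfg = scenario_config(1, m=100, pi0_values=(0.8,), n_replicates=2,
                              base_seed=4, strategies=("primary_only", "oracle"))
        res = run_scenario(cfg)
        assert len(res.per_replicate) == 4
        assert {"FDP", "NTP", "PAUC", "strategy"} <= set(res.per_replicate.columns)
        assert ((res.per_replicate["FDP"] >= 0)
                & (res.per_replicate["FDP"] <= 1)).all()
        assert len(res.aggregates) == 2

    def test_unknown_strategy_rejected(self):
        cfg = scenario_config(1, strategies=("magic",))
        with pytest.raises(ValueError, match="magic"):
            run_scenario(cfg)

    def test_paired_scenarios_share_truth(self):
        c2 = scenario_config(2, m=50, pi0_values=(0.8,), n_replicates=1,
                             base_seed=6)
        c3 = scenario_config(3, m=50, pi0_values=(0.8,), n_replicates=1,
                             base_seed=6)
        ct2 = make_covariates(config=c2.covariates, seed=6)
        ct3 = make_covariates(config=c3.covariates, seed=6)
        t2 = make_parameters(50, 0.8, ct2, seed=1, relevant_sets=c2.relevant_sets)
        t3 = make_parameters(50, 0.8, ct3, seed=1, relevant_sets=c3.relevant_sets)
        np.testing.assert_array_equal(t2.beta, t3.beta)
        np.testing.assert_array_equal(t2.is_DE, t3.is_DE)
        # covariates identical except the centering of the confounded one
        for col in ct2.data.columns:
            if col == "trait":
                continue
            assert (ct2.data[col] == ct3.data[col]).all()
        line = ct2.data["line"].to_numpy()
        np.testing.assert_allclose(
            center_within_groups(ct2.data["trait"].to_numpy(), line),
            ct3.data["trait"].to_numpy(), atol=1e-12)
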