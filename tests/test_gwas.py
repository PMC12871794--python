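import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gxescale import (
    ClumpParams,
    LdLookup,
    PrsModel,
    build_prs,
    clump,
    evaluate_prs,
    ld_from_panel,
    naive_genetic_correlation,
    relative_r2,
    run_gwas,
    score_prs,
    shared_hits,
    simulate_genotype_cohort,
)
from conftest import greedy_clump_oracle, identity_ld


def make_gwas(snps, ps, bps=None, chroms=None, betas=None):
    n = len(snps)
    return pd.DataFrame(
        {
            "snp": snps,
            "chr": chroms if chroms is not None else [1] * n,
            "bp": bps if bps is not None else (np.arange(n) + 1) * 10_000,
            "a1": ["A"] * n,
            "beta": betas if betas is not None else np.zeros(n),
            "se": np.ones(n),
            "p": ps,
            "n": 1000,
        }
    )


class TestRunGwas:
    def test_noiseless_effect_recovered(self, tiny_panel):
        y = 2.0 * tiny_panel.dosages[:, 0]
        res = run_gwas(tiny_panel, y)
        assert res.loc[0, "beta"] == pytest.approx(2.0, abs=1e-10)
        assert res.loc[0, "p"] < 1e-100

    def test_matches_statsmodels_per_snp(self, tiny_panel, rng):
        n = tiny_panel.n_samples
        C = rng.standard_normal((n, 2))
        y = tiny_panel.dosages[:, 3] * 0.4 + C @ [0.5, -0.2] + rng.standard_normal(n)
        res = run_gwas(tiny_panel, y, covariates=C)
        for j in range(tiny_panel.n_snps):
            X = sm.add_constant(np.column_stack([tiny_panel.dosages[:, j], C]))
            ref = sm.OLS(y, X).fit()
            assert res.loc[j, "beta"] == pytest.approx(ref.params[1], rel=1e-9)
            assert res.loc[j, "se"] == pytest.approx(ref.bse[1], rel=1e-9)
            assert res.loc[j, "p"] == pytest.approx(ref.pvalues[1], rel=1e-6, abs=1e-300)

    def test_null_calibration(self, rng):
        panel, _ = simulate_genotype_cohort(800, 1_000, seed=17)
        y = rng.standard_normal(800)
        res = run_gwas(panel, y)
        frac = (res["p"] < 0.05).mean()
        # binomial 99.9% interval around 0.05 with 1000 SNPs
        assert 0.028 < frac < 0.075

    def test_zero_variance_snp_warns_not_crashes(self, rng):
        panel, _ = simulate_genotype_cohort(60, 3, seed=1)
        panel.dosages[:, 1] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = run_gwas(panel, rng.standard_normal(60))
        assert np.isnan(res.loc[1, "beta"]) and np.isfinite(res.loc[0, "beta"])


class TestClump:
    def test_single_clump_tight_ld(self, clump_params):
        g = make_gwas(["a", "b", "c"], [1e-10, 1e-9, 1e-8], bps=[100, 200, 300])
        ld = LdLookup({("a", "b"): 0.9, ("a", "c"): 0.9, ("b", "c"): 0.9})
        res = clump(g, ld, clump_params)
        assert len(res) == 1
        assert res.loc[0, "lead"] == "a" and res.loc[0, "n_members"] == 3

    def test_outside_window_two_leads(self, clump_params):
        g = make_gwas(["a", "b"], [1e-10, 1e-9], bps=[1, 300_002])
        ld = LdLookup({("a", "b"): 0.9})
        res = clump(g, ld, clump_params)
        assert list(res["lead"]) == ["a", "b"]
        assert res["significant"].all()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed, clump_params):
        rng = np.random.default_rng(seed)
        p = 20
        snps = [f"s{i}" for i in range(p)]
        bps = np.sort(rng.choice(np.arange(1, 2_000_000), p, replace=False))
        ps = rng.uniform(size=p)
        ps[rng.integers(0, p)] = ps[rng.integers(0, p)]  # occasional tie
        r2 = rng.uniform(size=(p, p))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        frame = pd.DataFrame(r2, index=snps, columns=snps)
        g = make_gwas(snps, ps, bps=bps)
        res = clump(g, LdLookup(frame), clump_params)
        oracle = greedy_clump_oracle(
            list(zip(snps, [1] * p, bps, ps)),
            lambda a, b: frame.at[a, b],
            clump_params.r2_threshold,
            clump_params.window_bp,
        )
        assert list(res["lead"]) == [lead for lead, _ in oracle]
        for (_, row), (_, members) in zip(res.iterrows(), oracle):
            assert set(row["members"]) == members

    def test_invariant_to_row_order(self, clump_params, rng):
        p = 15
        snps = [f"s{i}" for i in range(p)]
        g = make_gwas(snps, rng.uniform(size=p), bps=np.arange(1, p + 1) * 40_000)
        r2 = rng.uniform(size=(p, p)); r2 = (r2 + r2.T) / 2; np.fill_diagonal(r2, 1)
        ld = LdLookup(pd.DataFrame(r2, index=snps, columns=snps))
        a = clump(g, ld, clump_params)
        b = clump(g.sample(frac=1, random_state=1), ld, clump_params)
        pd.testing.assert_frame_equal(a, b)

    def test_lead_p_is_clump_minimum(self, clump_params, rng):
        p = 15
        snps = [f"s{i}" for i in range(p)]
        g = make_gwas(snps, rng.uniform(size=p), bps=np.arange(1, p + 1) * 40_000)
        r2 = rng.uniform(size=(p, p)); r2 = (r2 + r2.T) / 2; np.fill_diagonal(r2, 1)
        ld = LdLookup(pd.DataFrame(r2, index=snps, columns=snps))
        res = clump(g, ld, clump_params)
        pmap = dict(zip(g["snp"], g["p"]))
        for _, row in res.iterrows():
            assert all(pmap[row["lead"]] <= pmap[m] for m in row["members"])

    def test_missing_ld_pair_treated_as_independent(self, clump_params):
        g = make_gwas(["a", "b"], [1e-10, 1e-9], bps=[100, 200])
        with pytest.warns(UserWarning, match="no LD entry"):
            res = clump(g, LdLookup({}), clump_params)
        assert len(res) == 2


class TestSharedHits:
    def toy_tables(self):
        snps = [f"s{i}" for i in range(10)]
        bps = np.arange(1, 11) * 1_000_000  # all independent (outside window)
        p_a = np.array([1e-9, 1e-9, 0.13, 0.5, 1e-10, 0.9, 1e-12, 0.2, 1e-8 / 2, 0.7])
        p_b = np.array([1e-10, 0.13, 4.29e-9, 0.5, 1e-9, 0.8, 0.9, 0.1, 0.3, 0.6])
        a = make_gwas(snps, p_a, bps=bps)
        b = make_gwas(snps, p_b, bps=bps)
        return a, b

    def test_labels_match_hand_enumeration(self, clump_params):
        a, b = self.toy_tables()
        leads, summary = shared_hits(a, b, identity_ld(list(a["snp"])), clump_params)
        lab = leads.set_index("lead")["label"]
        assert lab["s0"] == "shared"  # both below 5e-8
        assert lab["s1"] == "a_only"
        assert lab["s2"] == "b_only"  # log-scale-only discovery pattern
        assert lab["s4"] == "shared"
        assert lab["s6"] == "a_only"
        assert lab["s8"] == "a_only"
        assert set(lab.index) == {"s0", "s1", "s2", "s4", "s6", "s8"}
        assert summary["n_leads"] == 6 and summary["shared"] == 2
        assert summary["percent_shared"] == pytest.approx(100 * 2 / 6)

    def test_symmetric_with_swapped_labels(self, clump_params):
        a, b = self.toy_tables()
        ld = identity_ld(list(a["snp"]))
        ab, _ = shared_hits(a, b, ld, clump_params)
        ba, _ = shared_hits(b, a, ld, clump_params)
        assert list(ab["lead"]) == list(ba["lead"])
        swap = {"a_only": "b_only", "b_only": "a_only", "shared": "shared"}
        assert [swap[l] for l in ab["label"]] == list(ba["label"])

    def test_differing_snp_universe_rejected(self, clump_params):
        a, b = self.toy_tables()
        with pytest.raises(ValueError, match="symmetric difference"):
            shared_hits(a, b.iloc[:-1], identity_ld(list(a["snp"])), clump_params)


class TestPrs:
    def test_huge_effect_snp_always_selected(self, clump_params):
        panel, cohort = simulate_genotype_cohort(
            400, 5, effects=np.array([2.0, 0, 0, 0, 0]), noise_sd=0.5, seed=3
        )
        gwas = run_gwas(panel, cohort.y_observed)
        panel2, cohort2 = simulate_genotype_cohort(
            400, 5, effects=np.array([2.0, 0, 0, 0, 0]), noise_sd=0.5, seed=4,
            freqs=panel.snp_map["freq"].to_numpy(),
        )
        model = build_prs(
            gwas, ld_from_panel(panel), clump_params, [5e-8, 0.5], panel2, cohort2.y_observed
        )
        assert "snp1" in set(model.weights["snp"])

    def test_single_threshold_grid_is_selected(self, clump_params):
        panel, cohort = simulate_genotype_cohort(300, 4, effects=np.full(4, 1.0), seed=5)
        gwas = run_gwas(panel, cohort.y_observed)
        model = build_prs(gwas, ld_from_panel(panel), clump_params, [0.5], panel, cohort.y_observed)
        assert model.p_threshold_used == 0.5

    def test_null_phenotype_still_returns_model(self, clump_params, rng):
        panel, _ = simulate_genotype_cohort(300, 20, seed=6)
        y = rng.standard_normal(300)
        gwas = run_gwas(panel, y)
        model = build_prs(gwas, ld_from_panel(panel), clump_params, [0.9, 1.0], panel, y)
        assert len(model.weights) > 0

    def test_score_is_weighted_dosage_sum(self, tiny_panel):
        w = pd.DataFrame({"snp": ["snp1", "snp3"], "a1": ["A", "A"], "weight": [0.5, -1.0]})
        model = PrsModel(weights=w, train_scale="default", p_threshold_used=0.5)
        expected = 0.5 * tiny_panel.dosages[:, 0] - 1.0 * tiny_panel.dosages[:, 2]
        np.testing.assert_allclose(score_prs(model, tiny_panel), expected)


class TestEvaluatePrs:
    def test_relative_r2_formula(self):
        assert relative_r2(0.02, 0.01) == pytest.approx(1.0)
        assert relative_r2(0.015, 0.015) == 0.0
        with pytest.raises(ValueError):
            relative_r2(0.1, 0.0)

    def test_spearman_r2_invariant_to_increasing_transform(self, tiny_panel, rng):
        w = pd.DataFrame({"snp": tiny_panel.snp_ids, "a1": "A",
                          "weight": rng.standard_normal(tiny_panel.n_snps)})
        model = PrsModel(weights=w)
        score = score_prs(model, tiny_panel)
        y = np.exp(0.5 * (score - score.mean()) / score.std() + 0.3 * rng.standard_normal(len(score)))
        r2_raw = evaluate_prs(model, tiny_panel, y, metric="spearman_r2").loc[0, "r2"]
        r2_cub = evaluate_prs(model, tiny_panel, y**3, metric="spearman_r2").loc[0, "r2"]
        assert r2_raw == pytest.approx(r2_cub, rel=1e-12)

    def test_two_group_variance_domination_mechanism(self, rng):
        # multiplicative two-group trait: the wide group's variance dominates
        # default-scale Pearson R2; log-scale evaluation restores both groups
        n, p = 4_000, 60
        b = rng.standard_normal(p) * 0.15
        panel, cohort = simulate_genotype_cohort(
            n, p, effects={"F": b, "M": b}, noise_sd=0.0, seed=33
        )
        lat = (cohort.y_latent - cohort.y_latent.mean()) / cohort.y_latent.std()
        lat = 0.8 * lat + 0.6 * rng.standard_normal(n)
        scale = np.where(cohort.groups == "M", 2.5, 0.5)
        offset = np.where(cohort.groups == "M", 3.0, 0.0)
        y = np.exp(offset + scale * lat)
        model = PrsModel(weights=pd.DataFrame({"snp": panel.snp_ids, "a1": "A", "weight": b}))
        res_def = evaluate_prs(model, panel, y, groups=cohort.groups).set_index("group")["r2"]
        res_log = evaluate_prs(model, panel, y, groups=cohort.groups, eval_scale="log").set_index("group")["r2"]
        # overall default-scale R2 tracks the dominant group
        assert abs(res_def["overall"] - res_def["M"]) < abs(res_def["overall"] - res_def["F"])
        # on the log scale both groups retain signal
        assert res_log["F"] > 0.1 and res_log["M"] > 0.1

    def test_log_scale_requires_positive_phenotype(self, tiny_panel):
        w = pd.DataFrame({"snp": ["snp1"], "a1": ["A"], "weight": [1.0]})
        model = PrsModel(weights=w)
        with pytest.raises(ValueError, match="positive"):
            evaluate_prs(model, tiny_panel, np.linspace(-1, 1, tiny_panel.n_samples), eval_scale="log")


class TestNaiveGeneticCorrelation:
    def test_identical_tables_give_one(self, rng):
        g = make_gwas([f"s{i}" for i in range(20)], rng.uniform(size=20),
                      betas=rng.standard_normal(20))
        assert naive_genetic_correlation(g, g) == pytest.approx(1.0)

    def test_negated_betas_give_minus_one(self, rng):
        betas = rng.standard_normal(15)
        a = make_gwas([f"s{i}" for i in range(15)], rng.uniform(size=15), betas=betas)
        b = a.copy(); b["beta"] = -betas
        assert naive_genetic_correlation(a, b) == pytest.approx(-1.0)

    def test_uncorrelated_architectures_near_zero(self):
        rng = np.random.default_rng(5)
        n, p = 6_000, 300
        freqs = rng.uniform(0.2, 0.8, p)
        b1, b2 = rng.standard_normal(p), rng.standard_normal(p)  # independent effects
        panel1, c1 = simulate_genotype_cohort(n, p, effects=b1, freqs=freqs, noise_sd=1.0, seed=1)
        panel2, c2 = simulate_genotype_cohort(n, p, effects=b2, freqs=freqs, noise_sd=1.0, seed=2)
        rg = naive_genetic_correlation(run_gwas(panel1, c1.y_observed), run_gwas(panel2, c2.y_observed))
        assert abs(rg) < 0.1

    def test_too_few_snps_rejected(self, rng):
        g = make_gwas([f"s{i}" for i in range(5)], rng.uniform(size=5))
        with pytest.raises(ValueError, match="at least 10"):
            naive_genetic_correlation(g, g)
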