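import numpy as np
import pandas as pd
import pytest

from mwas.simulate import SimConfig, simulate_study
from mwas.train import (ClumpConfig, cross_validate_and_select, default_grid,
                        fit_penalized_model, fit_polygenic_score, ld_clump,
                        predict, prepare_training_genotypes)
from mwas.gwas import compute_principal_components
from .conftest import make_genotypes


def brute_force_clump(pvals, r2, chrom, bp, cfg):
    """Independent re-implementation of greedy clumping with explicit loops."""
    alive = [j for j in range(len(pvals)) if np.isfinite(pvals[j])
             and pvals[j] < cfg.p_max]
    chosen = []
    while alive:
        best = min(alive, key=lambda j: (pvals[j], j))
        chosen.append(best)
        nxt = []
        for j in alive:
            if j == best:
                continue
            near = (chrom[j] == chrom[best]
                    and abs(bp[j] - bp[best]) <= cfg.window_kb * 1000)
            if near and r2[j, best] >= cfg.r2_max:
                continue
            nxt.append(j)
        alive = nxt
    return chosen


def random_instance(rng, n_snps):
    n = 400
    # random block structure gives a spread of pairwise r^2 values
    block = rng.integers(1, max(2, n_snps // 2))
    base = rng.standard_normal((n, 1))
    dos = np.empty((n, n_snps))
    for j in range(n_snps):
        mix = rng.uniform(0, 1) if j % block else 0.0
        z = mix * base[:, 0] + np.sqrt(1 - mix**2) * rng.standard_normal(n)
        dos[:, j] = (z > rng.uniform(-0.8, 0.2)).astype(float) + (z > 1.0)
    g = make_genotypes(dos)
    # squeeze some SNPs into one window, scatter others
    g.snp_meta["bp"] = rng.choice(
        np.arange(1, 4_000_000, 5000), size=n_snps, replace=False)
    g.snp_meta["chr"] = rng.integers(1, 3, size=n_snps)
    pvals = 10.0 ** rng.uniform(-14, 0, size=n_snps)
    gwas = pd.DataFrame({"snp": g.snp_meta["snp"], "chr": g.snp_meta["chr"],
                         "bp": g.snp_meta["bp"], "p": pvals})
    return g, gwas


class TestClumping:
    def test_matches_brute_force_enumeration(self, rng):
        cfg = ClumpConfig(p_max=0.5)
        for _ in range(100):
            n_snps = int(rng.integers(3, 13))
            g, gwas = random_instance(rng, n_snps)
            got = ld_clump(gwas, g, cfg)
            xc = g.dosages - g.dosages.mean(axis=0)
            r = np.corrcoef(xc.T)
            expected = brute_force_clump(
                gwas["p"].to_numpy(), r**2,
                g.snp_meta["chr"].to_numpy(), g.snp_meta["bp"].to_numpy(), cfg)
            assert got == [g.snp_meta.at[j, "snp"] for j in expected]

    def test_correlated_trio_keeps_best_p(self, rng):
        # three SNPs in strong mutual LD: only the smallest p survives
        base = rng.standard_normal(2000)
        dos = np.column_stack([
            (0.95 * base + 0.31 * rng.standard_normal(2000) > 0).astype(float)
            + (0.95 * base + 0.31 * rng.standard_normal(2000) > 1.0)
            for _ in range(3)])
        g = make_genotypes(dos)
        gwas = pd.DataFrame({"snp": g.snp_meta["snp"], "chr": 1,
                             "bp": [1, 1001, 2001],
                             "p": [1e-12, 1e-6, 1e-3]})
        xc = dos - dos.mean(axis=0)
        r2 = np.corrcoef(xc.T) ** 2
        assert (r2[np.triu_indices(3, 1)] > 0.1).all()
        assert ld_clump(gwas, g, ClumpConfig()) == [g.snp_meta.at[0, "snp"]]

    def test_uncorrelated_all_retained(self, rng):
        dos = rng.integers(0, 3, (500, 5)).astype(float)
        g = make_genotypes(dos)
        gwas = pd.DataFrame({"snp": g.snp_meta["snp"], "chr": 1,
                             "bp": g.snp_meta["bp"],
                             "p": [1e-5, 1e-4, 1e-3, 5e-3, 9e-3]})
        assert len(ld_clump(gwas, g, ClumpConfig())) == 5

    def test_p_threshold_excludes(self, rng):
        dos = rng.integers(0, 3, (100, 2)).astype(float)
        g = make_genotypes(dos)
        gwas = pd.DataFrame({"snp": g.snp_meta["snp"], "chr": 1,
                             "bp": [1, 2_000_000], "p": [0.02, 0.005]})
        assert ld_clump(gwas, g, ClumpConfig()) == [g.snp_meta.at[1, "snp"]]

    def test_no_candidates_empty(self, rng):
        dos = rng.integers(0, 3, (50, 2)).astype(float)
        g = make_genotypes(dos)
        gwas = pd.DataFrame({"snp": g.snp_meta["snp"], "chr": 1,
                             "bp": [1, 2], "p": [0.5, 0.9]})
        assert ld_clump(gwas, g, ClumpConfig()) == []


class TestPenalizedFit:
    def test_lambda_zero_matches_ols(self, rng):
        n, m = 150, 6
        dos = rng.integers(0, 3, (n, m)).astype(float)
        g = make_genotypes(dos)
        cov = pd.DataFrame({"a": rng.normal(size=n)}, index=g.sample_ids)
        y = pd.Series(0.4 * dos[:, 0] + rng.normal(size=n),
                      index=g.sample_ids)
        model = fit_penalized_model(y, g, cov, alpha=0.5, lam=0.0)
        X = np.column_stack([np.ones(n), dos, cov["a"]])
        ols = np.linalg.lstsq(X, y.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(model.weights["weight"], ols[1:m + 1],
                                   rtol=1e-6, atol=1e-9)

    def test_lasso_null_point(self, rng):
        n, m = 120, 5
        dos = rng.integers(0, 3, (n, m)).astype(float)
        g = make_genotypes(dos)
        y = pd.Series(rng.normal(size=n), index=g.sample_ids)
        yc = y.to_numpy() - y.to_numpy().mean()
        xs = (dos - dos.mean(0)) / dos.std(0)
        lam_max = np.max(np.abs(xs.T @ yc)) / n
        model = fit_penalized_model(y, g, None, alpha=1.0, lam=lam_max * 1.001)
        assert (model.weights["weight"] == 0).all()

    def test_matches_sklearn_elastic_net(self, rng):
        from sklearn.linear_model import ElasticNet

        n, m = 200, 8
        dos = rng.integers(0, 3, (n, m)).astype(float)
        g = make_genotypes(dos)
        y = pd.Series(0.5 * dos[:, 0] - 0.3 * dos[:, 3]
                      + rng.normal(size=n), index=g.sample_ids)
        for alpha, lam in [(1.0, 0.02), (0.5, 0.05), (0.0, 0.1)]:
            mine = fit_penalized_model(y, g, None, alpha, lam)
            sd = dos.std(0)
            xs = (dos - dos.mean(0)) / sd
            yc = y.to_numpy() - y.to_numpy().mean()
            sk = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                            tol=1e-12, max_iter=200_000).fit(xs, yc)
            np.testing.assert_allclose(mine.weights["weight"], sk.coef_ / sd,
                                       rtol=1e-5, atol=1e-8)

    def test_family_classification(self, rng):
        dos = rng.integers(0, 3, (60, 3)).astype(float)
        g = make_genotypes(dos)
        y = pd.Series(rng.normal(size=60), index=g.sample_ids)
        assert fit_penalized_model(y, g, None, 1.0, 0.1).family == "lasso"
        assert fit_penalized_model(y, g, None, 0.0, 0.1).family == "ridge"
        assert fit_penalized_model(y, g, None, 0.3, 0.1).family == "elastic_net"

    def test_lasso_path_monotone_in_lambda(self, rng):
        dos = rng.integers(0, 3, (150, 10)).astype(float)
        g = make_genotypes(dos)
        y = pd.Series(dos @ rng.normal(0, 0.3, 10) + rng.normal(size=150),
                      index=g.sample_ids)
        lambdas, _ = default_grid()
        counts = [fit_penalized_model(y, g, None, 1.0, lam).n_snps
                  for lam in lambdas]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_grid_is_11_by_11(self):
        lambdas, alphas = default_grid()
        assert len(lambdas) == 11 and len(alphas) == 11
        assert lambdas[0] == pytest.approx(1e-5) and lambdas[-1] == pytest.approx(1.0)
        assert alphas[0] == 0.0 and alphas[-1] == 1.0


class TestPolygenicScore:
    def test_single_snp_scores(self, rng):
        dos = np.array([[0.0], [1.0], [2.0]])
        g = make_genotypes(dos)
        gwas = pd.DataFrame({"snp": ["s0"], "chr": [1], "bp": [1],
                             "beta": [0.5], "p": [1e-5]})
        model = fit_polygenic_score(gwas, ["s0"], g, 1e-2)
        np.testing.assert_allclose(predict(model, g), [0.0, 0.5, 1.0])

    def test_thresholds_nested(self, rng):
        k = 20
        dos = rng.integers(0, 3, (50, k)).astype(float)
        g = make_genotypes(dos)
        gwas = pd.DataFrame({"snp": g.snp_meta["snp"], "chr": 1,
                             "bp": g.snp_meta["bp"],
                             "beta": rng.normal(size=k),
                             "p": 10.0 ** rng.uniform(-6, -1, k)})
        clumped = list(g.snp_meta["snp"])
        sets = [set(fit_polygenic_score(gwas, clumped, g, t).weights["snp"])
                for t in (1e-4, 1e-3, 1e-2)]
        assert sets[0] <= sets[1] <= sets[2]

    def test_no_passing_snp_constant_score(self, rng):
        dos = rng.integers(0, 3, (30, 2)).astype(float)
        g = make_genotypes(dos)
        gwas = pd.DataFrame({"snp": g.snp_meta["snp"], "chr": 1,
                             "bp": [1, 2], "beta": [0.1, 0.2],
                             "p": [0.5, 0.9]})
        model = fit_polygenic_score(gwas, list(g.snp_meta["snp"]), g, 1e-2)
        assert model.n_snps == 0
        assert np.all(predict(model, g) == 0.0)


class TestTrainingGenotypePrep:
    def test_ambiguous_and_rare_removed(self, rng):
        dos = rng.integers(0, 3, (200, 3)).astype(float)
        dos[:, 1] = (rng.random(200) < 0.01).astype(float)  # rare
        g = make_genotypes(dos)
        g.snp_meta.loc[2, ["effect_allele", "other_allele"]] = ["A", "T"]
        out = prepare_training_genotypes(g, maf_min=0.05)
        assert list(out.snp_meta["snp"]) == ["s0"]


def _cv_setup(seed=21):
    cfg = SimConfig(n_samples_per_cohort=100, n_snps=60, n_metabolites=1,
                    h2_per_metabolite=0.4, xenobiotic_fraction=0.0,
                    missingness_rates={"nonxeno": 0.0, "xeno": 0.0},
                    seed=seed)
    study = simulate_study(cfg)
    g = prepare_training_genotypes(study.genotypes)
    pcs, _ = compute_principal_components(g, 2)
    cov = study.covariates.join(pcs)
    y = np.log10(study.metabolites.values["met0001"])
    return study, g, cov, y


class TestCrossValidation:
    def test_deterministic_selection(self):
        study, g, cov, y = _cv_setup()
        a = cross_validate_and_select(y, g, cov, study.cohort, seed=5)
        b = cross_validate_and_select(y, g, cov, study.cohort, seed=5)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        pd.testing.assert_frame_equal(a.table, b.table)
        pd.testing.assert_frame_equal(a.best_model.weights,
                                      b.best_model.weights)

    def test_selected_model_has_max_mean_r(self):
        study, g, cov, y = _cv_setup()
        sel = cross_validate_and_select(y, g, cov, study.cohort, seed=5)
        assert sel.best_model.cv_mean_r == pytest.approx(
            sel.table["cv_mean_r"].max())

    def test_grid_has_124_configurations(self):
        study, g, cov, y = _cv_setup()
        sel = cross_validate_and_select(y, g, cov, study.cohort, seed=5)
        assert len(sel.table) == 121 + 3
        assert (sel.table["kind"] == "penalized").sum() == 121

    def test_causal_snp_in_winning_model(self):
        hits = 0
        for seed in range(10):
            study, g, cov, y = _cv_setup(seed=100 + seed)
            sel = cross_validate_and_select(y, g, cov, study.cohort,
                                            seed=seed)
            causal, _ = study.truth.causal_snps_per_metabolite["met0001"][0]
            w = sel.best_model.weights
            model_snps = set(w.loc[w["weight"] != 0, "snp"])
            # accept a block mate in strong LD with the causal SNP
            j = study.genotypes.snp_ids.get_loc(causal)
            block = study.genotypes.snp_meta["block"]
            mates = set(study.genotypes.snp_meta.loc[
                block == block[j], "snp"])
            if model_snps & mates:
                hits += 1
        assert hits >= 9

    def test_no_leakage_from_held_out_samples(self):
        # permuting the held-out fold's y must leave that fold's models
        # bit-identical: no stage of fold fitting may touch held-out y
        study, g, cov, y = _cv_setup()
        sel = cross_validate_and_select(y, g, cov, study.cohort, seed=3)
        fold0 = sel.fold_assignment == 0
        held_ids = g.sample_ids[fold0]
        y2 = y.copy()
        rng = np.random.default_rng(1)
        y2.loc[held_ids] = rng.permutation(y2.loc[held_ids].to_numpy())
        sel2 = cross_validate_and_select(y2, g, cov, study.cohort, seed=3)
        assert np.array_equal(sel.fold_assignment, sel2.fold_assignment)
        for key, models in sel.fold_models.items():
            w1 = models[0].weights["weight"].to_numpy()
            w2 = sel2.fold_models[key][0].weights["weight"].to_numpy()
            assert np.array_equal(w1, w2)

    def test_null_metabolite_rarely_passes_inclusion(self):
        passed = 0
        for seed in range(12):
            cfg = SimConfig(n_samples_per_cohort=100, n_snps=60,
                            n_metabolites=1, h2_per_metabolite=0.0,
                            xenobiotic_fraction=0.0,
                            missingness_rates={"nonxeno": 0.0, "xeno": 0.0},
                            seed=300 + seed)
            study = simulate_study(cfg, affected_metabolite=None)
            g = prepare_training_genotypes(study.genotypes)
            y = np.log10(study.metabolites.values["met0001"])
            sel = cross_validate_and_select(y, g, study.covariates,
                                            study.cohort, seed=seed)
            if sel.best_model is not None and \
                    sel.best_model.passes_inclusion_filter():
                passed += 1
        assert passed <= 1
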