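import numpy as np
import pandas as pd
import pytest

from mwas.associate import (badgers_association, compute_qvalues,
                            harmonize_sumstats, impute_missing_zscores)
from mwas.types import PredictionModel, complement_allele
from .conftest import make_genotypes


def model_of(weights, snps=None, ea="A", oa="G", cv_mean_r=0.5):
    snps = snps or [f"s{j}" for j in range(len(weights))]
    w = pd.DataFrame({"snp": snps,
                      "effect_allele": [ea] * len(snps),
                      "other_allele": [oa] * len(snps),
                      "weight": weights})
    m = PredictionModel("met", "elastic_net", w, alpha=0.5, lam=0.1)
    m.cv_mean_r = cv_mean_r
    return m


def stats_of(snps, z=None, beta=None, se=None, ea="A", oa="G", n=10_000,
             **extra):
    k = len(snps)
    df = pd.DataFrame({"snp": snps, "chr": 1, "bp": np.arange(k) + 1,
                       "effect_allele": [ea] * k, "other_allele": [oa] * k,
                       "n": n})
    if beta is not None:
        df["beta"] = beta
    if se is not None:
        df["se"] = se
    if z is not None:
        df["z"] = z
    for key, val in extra.items():
        df[key] = val
    return df


class TestHarmonization:
    def test_or_one_gives_zero_beta(self):
        st = stats_of(["s0"], se=[0.1], **{"or": [1.0]})
        h = harmonize_sumstats(model_of([1.0]), st)
        assert h.table.at[0, "beta"] == 0.0
        assert h.table.at[0, "z"] == 0.0

    def test_swapped_alleles_flip_sign(self):
        st = stats_of(["s0"], beta=[0.25], se=[0.1], ea="G", oa="A")
        h = harmonize_sumstats(model_of([1.0]), st)
        assert h.table.at[0, "z"] == pytest.approx(-2.5)
        assert h.table.at[0, "provenance"] == "sign_flipped"

    def test_strand_complement_resolved(self):
        st = stats_of(["s0"], beta=[0.25], se=[0.1], ea="T", oa="C")
        h = harmonize_sumstats(model_of([1.0]), st)
        assert h.table.at[0, "z"] == pytest.approx(2.5)
        assert h.table.at[0, "provenance"] == "strand_complemented"

    def test_ambiguous_snp_dropped(self):
        st = stats_of(["s0"], beta=[0.25], se=[0.1], ea="A", oa="T")
        h_model = model_of([1.0], ea="A", oa="T")
        st2 = stats_of(["s0", "s1"], beta=[0.2, 0.3], se=[0.1, 0.1])
        h = harmonize_sumstats(model_of([1.0, 1.0], snps=["s0", "s1"]),
                               pd.concat([st2]))
        assert len(h.table) == 2
        with pytest.raises(ValueError):
            harmonize_sumstats(h_model, st)

    def test_z_only_conversion_self_consistent(self):
        st = stats_of(["s0"], z=[2.5], eaf=[0.3], n=[50_000])
        h = harmonize_sumstats(model_of([1.0]), st)
        row = h.table.iloc[0]
        assert row["beta"] / row["se"] == pytest.approx(2.5, rel=1e-6)

    def test_no_overlap_raises(self):
        st = stats_of(["other"], beta=[0.1], se=[0.1])
        with pytest.raises(ValueError, match="untestable"):
            harmonize_sumstats(model_of([1.0]), st)

    def test_missing_model_snp_flagged(self):
        st = stats_of(["s0"], beta=[0.1], se=[0.1])
        h = harmonize_sumstats(model_of([1.0, 2.0], snps=["s0", "s1"]), st)
        assert list(h.table["provenance"]) == ["as_is", "missing"]


class TestImputation:
    def test_observed_returned_unchanged(self, rng):
        dos = rng.integers(0, 3, (300, 2)).astype(float)
        g = make_genotypes(dos)
        st = stats_of(["s0", "s1"], beta=[0.2, 0.1], se=[0.1, 0.1])
        h = harmonize_sumstats(model_of([1.0, 1.0], snps=["s0", "s1"]), st)
        out = impute_missing_zscores(h, g)
        pd.testing.assert_frame_equal(out.table, h.table)

    def test_perfect_proxy_copies_z(self, rng):
        base = rng.integers(0, 3, 500).astype(float)
        dos = np.column_stack([base, base])  # r = 1 between the pair
        g = make_genotypes(dos)
        st = stats_of(["s0"], beta=[0.3], se=[0.1])
        h = harmonize_sumstats(model_of([1.0, 1.0], snps=["s0", "s1"]), st)
        out = impute_missing_zscores(h, g, ridge_eps=0.0)
        assert out.table.at[1, "z"] == pytest.approx(3.0, rel=1e-9)
        assert out.table.at[1, "provenance"] == "imputed"
        assert out.table.at[1, "impute_r2"] == pytest.approx(1.0, rel=1e-9)

    def test_uncorrelated_target_imputes_zero(self, rng):
        dos = rng.integers(0, 3, (20_000, 2)).astype(float)
        g = make_genotypes(dos)
        st = stats_of(["s0"], beta=[0.3], se=[0.1])
        h = harmonize_sumstats(model_of([1.0, 1.0], snps=["s0", "s1"]), st)
        out = impute_missing_zscores(h, g, ridge_eps=0.0)
        assert abs(out.table.at[1, "z"]) < 0.1

    def test_target_absent_from_panel_left_missing(self, rng):
        dos = rng.integers(0, 3, (100, 1)).astype(float)
        g = make_genotypes(dos)
        st = stats_of(["s0"], beta=[0.3], se=[0.1])
        h = harmonize_sumstats(model_of([1.0, 1.0], snps=["s0", "sX"]), st)
        out = impute_missing_zscores(h, g)
        assert np.isnan(out.table.at[1, "z"])
        assert ("sX", "absent_from_panel") in out.dropped


class TestBadgers:
    def test_single_snp_reduces_to_that_z(self, rng):
        dos = rng.integers(0, 3, (400, 1)).astype(float)
        g = make_genotypes(dos)
        st = stats_of(["s0"], beta=[0.2], se=[0.1])
        model = model_of([0.7])
        h = harmonize_sumstats(model, st)
        res = badgers_association(model, h, g)
        assert res.z_score == pytest.approx(2.0, rel=1e-12)

    def test_two_uncorrelated_equal_weights(self, rng):
        # Z = (2 + 2) / sqrt(2) with identity LD; built from orthogonal
        # dosage columns so the panel correlation really is the identity
        dos = np.column_stack([np.tile([0.0, 2.0], 150),
                               np.tile([0.0, 0.0, 2.0, 2.0], 75)])
        assert abs(np.corrcoef(dos.T)[0, 1]) < 1e-12
        g = make_genotypes(dos)
        st = stats_of(["s0", "s1"], beta=[0.2, 0.2], se=[0.1, 0.1])
        # equal standardized weights: same dosage sd, same raw weight
        model = model_of([1.0, 1.0], snps=["s0", "s1"])
        h = harmonize_sumstats(model, st)
        res = badgers_association(model, h, g, ridge_eps=0.0)
        assert res.z_score == pytest.approx(4 / np.sqrt(2), rel=1e-9)

    def test_weight_scale_invariance(self, rng):
        dos = rng.integers(0, 3, (300, 3)).astype(float)
        g = make_genotypes(dos)
        st = stats_of(["s0", "s1", "s2"], beta=[0.2, -0.1, 0.05],
                      se=[0.1, 0.1, 0.1])
        m1 = model_of([0.5, -0.2, 0.1], snps=["s0", "s1", "s2"])
        m2 = model_of([5.0, -2.0, 1.0], snps=["s0", "s1", "s2"])
        z1 = badgers_association(m1, harmonize_sumstats(m1, st), g).z_score
        z2 = badgers_association(m2, harmonize_sumstats(m2, st), g).z_score
        assert z1 == pytest.approx(z2, rel=1e-12)

    def test_harmonization_invariance_under_complement_and_flip(self, rng):
        dos = rng.integers(0, 3, (300, 3)).astype(float)
        g = make_genotypes(dos)
        model = model_of([0.5, -0.2, 0.1], snps=["s0", "s1", "s2"])
        st = stats_of(["s0", "s1", "s2"], beta=[0.2, -0.1, 0.05],
                      se=[0.1, 0.1, 0.1])
        # complement all phenotype alleles AND swap effect/other with
        # negated betas: harmonization must undo both
        st2 = st.copy()
        st2["effect_allele"] = [complement_allele("G")] * 3  # -> C
        st2["other_allele"] = [complement_allele("A")] * 3   # -> T
        st2["beta"] = -st2["beta"]
        z1 = badgers_association(model, harmonize_sumstats(model, st),
                                 g).z_score
        z2 = badgers_association(model, harmonize_sumstats(model, st2),
                                 g).z_score
        assert z1 == z2

    def test_degenerate_weight_variance_raises(self, rng):
        dos = rng.integers(0, 3, (100, 1)).astype(float)
        g = make_genotypes(dos)
        st = stats_of(["s0"], beta=[0.2], se=[0.1])
        model = model_of([0.0])
        h = harmonize_sumstats(model, st)
        with pytest.raises(ValueError, match="no harmonized SNP"):
            badgers_association(model, h, g)


class TestQValues:
    def test_all_ones(self):
        q, sig = compute_qvalues([1.0, 1.0, 1.0], method="bh")
        assert np.all(q == 1.0) and not sig.any()

    def test_bh_hand_computed_stepup(self):
        q, _ = compute_qvalues([0.01, 0.02, 0.03, 0.04], method="bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_storey_pi0_scales_bh(self):
        p = np.concatenate([np.full(5, 1e-4), np.linspace(0.55, 0.95, 5)])
        q_bh, _ = compute_qvalues(p, method="bh")
        q_st, _ = compute_qvalues(p, method="storey")
        # pi0 = (#p > 0.5) / (m * 0.5) = 5 / 5 = 1 -> equal here
        np.testing.assert_allclose(q_st, q_bh)
        p2 = np.concatenate([np.full(8, 1e-4), [0.6, 0.7]])
        q_bh2, _ = compute_qvalues(p2, method="bh")
        q_st2, _ = compute_qvalues(p2, method="storey")
        assert np.all(q_st2 <= q_bh2 + 1e-15)

    def test_qvalues_monotone_in_p(self, rng):
        p = rng.uniform(size=50)
        q, _ = compute_qvalues(p, method="storey")
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            compute_qvalues([0.5, 0.0])

    def test_empty_input(self):
        q, sig = compute_qvalues([])
        assert q.size == 0 and sig.size == 0

    def test_bonferroni_flag_paper_instance(self):
        from mwas.gwas import bonferroni_threshold
        assert bonferroni_threshold(0.05, 106 * 27) == pytest.approx(1.7e-5,
                                                                     rel=3e-2)
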