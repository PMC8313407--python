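"""Normalization, filtering, moderated DE, factorial interaction, decoupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecrscan.core import PipelineParams, ValidationError
from ecrscan.diffexp import (
    differential_expression,
    expressed_features,
    filter_features,
    interaction_test,
    intron_gene_decoupling,
    library_sizes,
    log2_cpm,
    normalization_factors,
    rpkm,
    select_regulated_introns,
)
from ecrscan.simulate import (
    negative_binomial,
    simulate_de_counts,
    simulate_factorial_counts,
)


class TestNormalizationFactors:
    def test_identical_samples(self):
        rng = np.random.default_rng(0)
        c = rng.poisson(100, 500)
        counts = pd.DataFrame({"a": c, "b": c})
        nf = normalization_factors(counts)
        assert nf.to_numpy() == pytest.approx([1.0, 1.0])

    def test_pure_depth_invariance(self):
        rng = np.random.default_rng(0)
        c = rng.poisson(100, 500) + 1
        counts = pd.DataFrame({"a": c, "b": 2 * c})
        nf = normalization_factors(counts)
        assert nf.to_numpy() == pytest.approx([1.0, 1.0])

    def test_geometric_mean_one(self):
        counts, _, _ = simulate_de_counts(3, n_features=400, n_planted=50, log2fc=3.0)
        nf = normalization_factors(counts)
        assert np.exp(np.mean(np.log(nf))) == pytest.approx(1.0)

    def test_composition_bias_recovered(self):
        """10% of genes 8-fold up in B: factor matches the analytic trimmed
        value within 5%."""
        rng = np.random.default_rng(4)
        n = 2000
        base = rng.poisson(200, n).astype(float) + 1
        b = base.copy()
        b[:200] *= 8
        counts = pd.DataFrame({"A": base, "B": b})
        nf = normalization_factors(counts)
        # analytic: trimming removes the shifted genes; unchanged genes all
        # share M = -log2(libB/libA); after geometric-mean rescaling the
        # factors are (sqrt(r), 1/sqrt(r)) with r = libB/libA
        r = b.sum() / base.sum()
        expected = np.array([np.sqrt(r), 1 / np.sqrt(r)])
        assert nf.to_numpy() == pytest.approx(expected, rel=0.05)

    def test_disjoint_sample_rejected(self):
        counts = pd.DataFrame({"a": [10, 0, 5], "b": [0, 7, 0]})
        with pytest.raises(ValidationError):
            normalization_factors(counts)


class TestFilterFeatures:
    def test_boundary_inclusive(self, params):
        lib = pd.Series({"s1": 1e6, "s2": 1e6})
        nf = pd.Series({"s1": 1.0, "s2": 1.0})
        at_cutoff = 2**0.5 - 0.5  # mean log2-cpm exactly 0.5
        counts = pd.DataFrame(
            {"s1": [at_cutoff, at_cutoff - 0.01], "s2": [at_cutoff, at_cutoff - 0.01]},
            index=["kept", "dropped"],
        )
        out = filter_features(counts, "gene", params, lib, nf)
        assert list(out.index) == ["kept"]

    def test_ecr_cutoff_is_stricter(self, params):
        lib = pd.Series({"s1": 1e6})
        nf = pd.Series({"s1": 1.0})
        counts = pd.DataFrame({"s1": [10.0]}, index=["f"])  # log2cpm ~3.39
        assert len(filter_features(counts, "gene", params, lib, nf)) == 1
        assert len(filter_features(counts, "ECR", params, lib, nf)) == 0

    def test_all_zero_dropped(self, params):
        lib = pd.Series({"s1": 1e6, "s2": 1e6})
        nf = pd.Series({"s1": 1.0, "s2": 1.0})
        counts = pd.DataFrame({"s1": [0.0], "s2": [0.0]}, index=["z"])
        assert len(filter_features(counts, "intron", params, lib, nf)) == 0

    def test_unknown_class(self, params):
        with pytest.raises(ValidationError):
            filter_features(pd.DataFrame(), "exon", params, None, None)


class TestDifferentialExpression:
    def test_contrast_antisymmetry(self, params):
        counts, design, _ = simulate_de_counts(5, n_features=200, n_planted=40,
                                               log2fc=1.5)
        ab = differential_expression(counts, design, ("A", "B"), params)
        ba = differential_expression(counts, design, ("B", "A"), params)
        assert np.allclose(ab["log2fc"], -ba["log2fc"])

    def test_null_calibration(self, params):
        """Null p-values uniform; no false 'regulated' calls beyond the
        FDR level."""
        counts, design, _ = simulate_de_counts(0, n_features=2000)
        nf = normalization_factors(counts)
        res = differential_expression(counts, design, ("A", "B"), params,
                                      norm_factor=nf)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01
        assert res["regulated"].mean() <= 0.05

    def test_planted_recovery(self, params):
        counts, design, planted = simulate_de_counts(
            1, n_features=2000, n_planted=200, log2fc=2.0
        )
        nf = normalization_factors(counts)
        res = differential_expression(counts, design, ("A", "B"), params,
                                      norm_factor=nf)
        sub = res.loc[planted]
        assert sub["regulated"].mean() >= 0.8
        assert abs(sub["log2fc"].mean() - 2.0) <= 0.2
        false = res.drop(planted)["regulated"].sum()
        assert false / max(1, res["regulated"].sum()) <= 0.07

    def test_small_group_rejected(self, params):
        counts, design, _ = simulate_de_counts(0, n_features=10, n_per_group=1)
        with pytest.raises(ValidationError):
            differential_expression(counts, design, ("A", "B"), params)

    def test_single_sample_rescaling_leaves_log2fc_invariant(self, params):
        counts, design, _ = simulate_de_counts(6, n_features=400, n_planted=50,
                                               log2fc=2.0)
        nf = normalization_factors(counts)
        res = differential_expression(counts, design, ("A", "B"), params,
                                      norm_factor=nf)
        scaled = counts.copy()
        scaled["s0"] = scaled["s0"] * 2
        nf2 = normalization_factors(scaled)
        res2 = differential_expression(scaled, design, ("A", "B"), params,
                                       norm_factor=nf2)
        assert np.allclose(res["log2fc"], res2["log2fc"], atol=0.02)


class TestInteraction:
    def test_coefficient_identity_on_noiseless_input(self, params):
        """Interaction estimate equals (DKO-ADAR)-(hnRNPC-CTRL) computed by
        direct group-mean arithmetic."""
        counts, design, isgs, _ = simulate_factorial_counts(
            2, n_isg=100, n_synergistic=30, n_background=0, interaction=2.0
        )
        res = interaction_test(counts, design, list(isgs), params)
        lib = library_sizes(counts)
        logcpm = log2_cpm(counts, lib, pd.Series(1.0, index=counts.columns))
        by_cond = {
            c: logcpm[design.loc[design["condition"] == c, "sample_id"]].mean(axis=1)
            for c in ("CTRL", "hnRNPC", "ADAR", "DKO")
        }
        direct = (by_cond["DKO"] - by_cond["ADAR"]) - (
            by_cond["hnRNPC"] - by_cond["CTRL"]
        )
        assert np.allclose(res["interaction"], direct.loc[res.index])

    def test_planted_synergy_recovered(self, params):
        counts, design, isgs, synergistic = simulate_factorial_counts(
            1, n_isg=500, n_synergistic=100, interaction=2.0
        )
        nf = normalization_factors(counts)
        res = interaction_test(counts, design, list(isgs), params,
                               norm_factor=nf)
        syn = res.loc[synergistic]
        additive = res.drop(synergistic)
        assert abs(syn["interaction"].mean() - 2.0) <= 0.3
        assert syn["significant"].mean() >= 0.8
        assert abs(additive["interaction"].mean()) <= 0.1

    def test_missing_genotype_rejected(self, params):
        counts, design, isgs, _ = simulate_factorial_counts(
            3, n_isg=20, n_background=0
        )
        sub = design[design["condition"] != "DKO"]
        with pytest.raises(ValidationError, match="DKO"):
            interaction_test(counts, sub, list(isgs), params)

    def test_bh_runs_across_isg_set_only(self, params):
        counts, design, isgs, _ = simulate_factorial_counts(
            4, n_isg=300, n_synergistic=50, interaction=2.0
        )
        res = interaction_test(counts, design, list(isgs[:100]), params)
        assert len(res) == 100


class TestDecoupling:
    def test_arithmetic(self):
        intron_de = pd.DataFrame({"log2fc": [3.0, 2.0]}, index=["i1", "i2"])
        gene_de = pd.DataFrame({"log2fc": [0.2, 2.0]}, index=["g1", "g2"])
        out = intron_gene_decoupling(intron_de, gene_de, {"i1": "g1", "i2": "g2"})
        assert out.loc["i1", "delta"] == pytest.approx(2.8)
        assert out.loc["i2", "delta"] == pytest.approx(0.0)

    def test_unmapped_intron_rejected(self):
        intron_de = pd.DataFrame({"log2fc": [1.0]}, index=["i1"])
        gene_de = pd.DataFrame({"log2fc": [1.0]}, index=["g1"])
        with pytest.raises(ValidationError):
            intron_gene_decoupling(intron_de, gene_de, {"i1": "nope"})

    def test_mixture_proportion_recovered(self, params, sim_spec, sim_annotation):
        """The decoupled/coupled mixture in the Δ histogram matches the
        planted proportions."""
        from ecrscan.simulate import generate_counts

        counts = generate_counts(sim_spec, sim_annotation)
        design = counts.design
        lib = library_sizes(counts.gene_counts)
        nf = normalization_factors(counts.gene_counts)
        day = 4
        gene_de = differential_expression(
            counts.gene_counts, design, (f"CTRL_d{day}", f"hnRNPC_d{day}"),
            params, lib=lib, norm_factor=nf,
        )
        intron_de = differential_expression(
            counts.intron_counts, design, (f"CTRL_d{day}", f"hnRNPC_d{day}"),
            params, lib=lib, norm_factor=nf,
        )
        dec = intron_gene_decoupling(intron_de, gene_de, counts.intron_to_gene)
        measured = (dec["delta"] >= sim_spec.intron_effect / 2).mean()
        truth = counts.truth_introns
        planted = (truth["class"] == "decoupled").mean()
        assert measured == pytest.approx(planted, abs=0.05)

    def test_regulated_intron_selection(self):
        day1 = pd.DataFrame(
            {"log2fc": [2.5, 0.5], "p_adj": [0.001, 0.5]}, index=["i1", "i2"]
        )
        day2 = pd.DataFrame(
            {"log2fc": [-2.5, 3.0], "p_adj": [0.005, 0.5]}, index=["i1", "i2"]
        )
        sel = select_regulated_introns([day1, day2])
        assert list(sel) == ["i1"]


class TestRpkm:
    def test_formula(self):
        counts = pd.DataFrame({"s": [100.0]}, index=["f"])
        lib = pd.Series({"s": 1e7})
        out = rpkm(counts, pd.Series({"f": 1000.0}), lib)
        assert out.loc["f", "s"] == pytest.approx(10.0)
        half = rpkm(counts, pd.Series({"f": 2000.0}), lib)
        assert half.loc["f", "s"] == pytest.approx(5.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            rpkm(pd.DataFrame({"s": [1.0]}, index=["f"]),
                 pd.Series({"f": 0.0}), pd.Series({"s": 1e6}))

    def test_expressed_requires_all_conditions(self, params):
        design = pd.DataFrame(
            {"sample_id": ["a", "b"], "condition": ["CTRL", "KO"]}
        )
        table = pd.DataFrame({"a": [10.0, 10.0], "b": [10.0, 3.0]},
                             index=["ok", "low"])
        ok = expressed_features(table, design, params.ecr_min_rpkm)
        assert bool(ok["ok"]) and not bool(ok["low"])


def test_nb_dispersion_zero_limit_is_poisson():
    """Var/mean -> 1 as dispersion -> 0 (10,000 draws)."""
    rng = np.random.default_rng(9)
    draws = negative_binomial(rng, np.full(10_000, 50.0), 0.0)
    ratio = draws.var() / draws.mean()
    assert ratio == pytest.approx(1.0, abs=0.05)
    rng = np.random.default_rng(9)
    over = negative_binomial(rng, np.full(10_000, 50.0), 0.2)
    assert over.var() / over.mean() > 5
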