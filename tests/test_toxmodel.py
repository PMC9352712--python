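import dataclasses

import numpy as np
import pandas as pd
import pytest

from dsbtox import annot, simdata, toxmodel
from dsbtox.screenio import CountMatrix
from dsbtox.simdata import EffectSpec, SimConfig


def _sim(n_genes, seed, interaction=None, main=None, d2=0.0, theta=10.0, **kw):
    cfg = SimConfig(n_genes=n_genes, n_nontargeting=50, seed=seed,
                    dispersion=theta, with_sequences=False, **kw)
    eff = EffectSpec(interaction_effects=interaction or {},
                     feature_effects=main or {}, essentiality_effect=d2)
    sim = simdata.simulate_screen(cfg, eff)
    sim["config"] = cfg
    sim["features"] = annot.assemble(sim["library"], sim["annotations"])
    return sim


class TestFeatureInteraction:
    def test_recovers_planted_interaction(self):
        sim = _sim(500, seed=21, interaction={"dhs": -0.3}, d2=-0.1)
        fit = toxmodel.fit_feature_interaction(
            sim["counts"], sim["features"], "dhs",
            time_points=sim["config"].later_times,
        )
        t = fit.term("dhs:tp53wt")
        assert fit.converged and abs(t.estimate - (-0.3)) < 2 * t.se

    def test_dispersion_recovered(self):
        sim = _sim(1250, seed=22, theta=10.0)
        fit = toxmodel.fit_feature_interaction(
            sim["counts"], sim["features"], "dhs",
            time_points=sim["config"].later_times,
        )
        assert abs(fit.theta - 10.0) / 10.0 < 0.25

    def test_genotype_permutation_attenuates_interaction(self):
        sim = _sim(400, seed=23, interaction={"dhs": -0.3})
        cfg = sim["config"]
        ref = toxmodel.fit_feature_interaction(
            sim["counts"], sim["features"], "dhs", time_points=cfg.later_times
        ).term("dhs:tp53wt").estimate
        rng = np.random.default_rng(5)
        attenuated = 0
        n_perm = 60
        for _ in range(n_perm):
            perm = rng.permutation([s.genotype for s in sim["counts"].samples])
            shuffled = CountMatrix(
                sim["counts"].counts,
                [dataclasses.replace(s, genotype=g)
                 for s, g in zip(sim["counts"].samples, perm)],
                normalized=False,
            )
            est = toxmodel.fit_feature_interaction(
                shuffled, sim["features"], "dhs", time_points=cfg.later_times
            ).term("dhs:tp53wt").estimate
            attenuated += abs(est) < abs(ref)
        assert attenuated / n_perm >= 0.95

    def test_single_genotype_rejected(self):
        sim = _sim(50, seed=24, genotypes=("wt",))
        with pytest.raises(ValueError, match="both genotypes"):
            toxmodel.fit_feature_interaction(sim["counts"], sim["features"], "dhs")

    def test_offset_absorbs_count_scaling(self):
        sim = _sim(300, seed=25, interaction={"dhs": -0.3})
        cfg = sim["config"]

        def scaled(c):
            return CountMatrix(
                sim["counts"].counts * c,
                [dataclasses.replace(s, offset=s.offset + np.log(c))
                 for s in sim["counts"].samples],
                normalized=False,
            )

        f1 = toxmodel.fit_feature_interaction(
            sim["counts"], sim["features"], "dhs",
            time_points=cfg.later_times, family="poisson")
        f2 = toxmodel.fit_feature_interaction(
            scaled(3), sim["features"], "dhs",
            time_points=cfg.later_times, family="poisson")
        assert abs(f1.term("dhs:tp53wt").estimate - f2.term("dhs:tp53wt").estimate) < 1e-6
        # NB maximum likelihood: scaling leaves the NB2 family, so the
        # coefficient is only approximately invariant
        g1 = toxmodel.fit_feature_interaction(
            sim["counts"], sim["features"], "dhs", time_points=cfg.later_times)
        g2 = toxmodel.fit_feature_interaction(
            scaled(3), sim["features"], "dhs", time_points=cfg.later_times)
        assert abs(g1.term("dhs:tp53wt").estimate - g2.term("dhs:tp53wt").estimate) < 1e-2


class TestOtherModels:
    def test_wt_only_null_and_planted(self):
        null = _sim(400, seed=26)
        f0 = toxmodel.fit_wt_only(null["counts"], null["features"], "dhs",
                                  time_points=null["config"].later_times)
        assert abs(f0.term("dhs").estimate) < 3 * f0.term("dhs").se
        planted = _sim(400, seed=27, main={"dhs": -0.2})
        f1 = toxmodel.fit_wt_only(planted["counts"], planted["features"], "dhs",
                                  time_points=planted["config"].later_times)
        assert abs(f1.term("dhs").estimate - (-0.2)) < 2 * f1.term("dhs").se

    def test_single_level_feature_rejected(self):
        sim = _sim(50, seed=28)
        sim["features"].data["flat"] = 1
        with pytest.raises(ValueError, match="single level"):
            toxmodel.fit_wt_only(sim["counts"], sim["features"], "flat")

    def test_pairwise_collinear_flagged(self):
        sim = _sim(100, seed=29)
        sim["features"].data["dhs_copy"] = sim["features"].data["dhs"]
        fit = toxmodel.fit_pairwise_conditioned(
            sim["counts"], sim["features"], "dhs", "dhs_copy",
            time_points=sim["config"].later_times,
        )
        assert fit.rank_deficient and not fit.converged

    def test_pairwise_conditioning_removes_confounding(self):
        # toxic cofeature correlated with the (null) primary feature biases
        # the marginal fit; conditioning restores the planted zero
        cfg = SimConfig(n_genes=1000, n_nontargeting=50, seed=30, with_sequences=False)
        eff = EffectSpec(
            interaction_effects={"h3k27ac": -0.4},
            feature_correlation={("dhs", "h3k27ac"): 0.7},
        )
        sim = simdata.simulate_screen(cfg, eff)
        ft = annot.assemble(sim["library"], sim["annotations"])
        marginal = toxmodel.fit_feature_interaction(
            sim["counts"], ft, "dhs", time_points=cfg.later_times
        ).term("dhs:tp53wt").estimate
        conditioned = toxmodel.fit_pairwise_conditioned(
            sim["counts"], ft, "dhs", "h3k27ac", time_points=cfg.later_times
        ).term("dhs:tp53wt").estimate
        assert abs(conditioned) < abs(marginal)
        assert marginal < -0.05  # confounded estimate is clearly negative

    def test_status_and_d2_only(self):
        sim = _sim(500, seed=31, d2=-0.15)
        # add a global wt toxicity via an always-carried feature
        f_status = toxmodel.fit_status_only(sim["counts"], sim["features"],
                                            time_points=sim["config"].later_times)
        assert abs(f_status.term("tp53wt").estimate) < 3 * f_status.term("tp53wt").se
        f_d2 = toxmodel.fit_d2_only(sim["counts"], sim["features"],
                                    time_points=sim["config"].later_times)
        t = f_d2.term("d2")
        assert abs(t.estimate - (-0.15)) < 2 * t.se


class TestPanelModels:
    @staticmethod
    def _panel(seed, beta_int=-0.2, n_sg=300, n_lines=40, tissues=("breast", "ovary", "pancreas")):
        rng = np.random.default_rng(seed)
        tp = rng.random(n_lines) < 0.5
        hr = rng.random(n_lines) < 0.5
        tis = rng.choice(tissues, n_lines)
        d2 = rng.normal(0, 1, n_sg)
        off = np.log(rng.uniform(0.8, 1.2, n_lines)) + np.log(300.0)
        eta = (off[None, :] - 0.1 * d2[:, None]
               - 0.1 * tp[None, :] + beta_int * (tp * hr)[None, :])
        lam = rng.gamma(10.0, np.exp(eta) / 10.0)
        y = rng.poisson(lam)
        return pd.DataFrame({
            "count": y.ravel(),
            "tp53wt": np.tile(tp.astype(int), n_sg),
            "hrwt": np.tile(hr.astype(int), n_sg),
            "tissue": np.tile(tis, n_sg),
            "d2": np.repeat(d2, n_lines),
            "offset": np.tile(off, n_sg),
        })

    def test_tp53_hr_interaction_recovered(self):
        panel = self._panel(seed=40)
        fit = toxmodel.fit_tp53_hr(panel)
        t = fit.term("tp53wt:hrwt")
        assert abs(t.estimate - (-0.2)) < 2 * t.se

    def test_tissue_terms_null_when_no_tissue_effect(self):
        panel = self._panel(seed=41, beta_int=0.0)
        fit = toxmodel.fit_tp53_hr(panel)
        for name, t in fit.terms.items():
            if name.startswith("tissue["):
                assert abs(t.estimate) < 3.5 * t.se

    def test_single_tissue_dropped_with_warning(self):
        panel = self._panel(seed=42, tissues=("breast",))
        with pytest.warns(UserWarning, match="single-tissue"):
            fit = toxmodel.fit_tp53_hr(panel)
        assert not any(n.startswith("tissue[") for n in fit.terms)

    def test_feature_hr_matches_generating_model(self):
        rng = np.random.default_rng(43)
        n_sg, n_lines = 400, 30
        x = (rng.random(n_sg) < 0.5).astype(int)
        hr = (rng.random(n_lines) < 0.5).astype(int)
        off = np.full(n_lines, np.log(300.0))
        d2 = rng.normal(0, 1, n_sg)
        eta = off[None, :] - 0.1 * d2[:, None] - 0.3 * x[:, None] + 0.25 * (x[:, None] * hr[None, :])
        y = rng.poisson(rng.gamma(10.0, np.exp(eta) / 10.0))
        panel = pd.DataFrame({
            "count": y.ravel(),
            "feat": np.repeat(x, n_lines),
            "hrwt": np.tile(hr, n_sg),
            "tissue": "breast",
            "d2": np.repeat(d2, n_lines),
            "offset": np.tile(off, n_sg),
        })
        with pytest.warns(UserWarning):
            fit = toxmodel.fit_feature_hr(panel, "feat")
        t = fit.term("feat:hrwt")
        assert abs(t.estimate - 0.25) < 2 * t.se


class TestFdr:
    def test_bh_step_up_hand_example(self):
        q = toxmodel.adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(toxmodel.adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_is_identity(self):
        assert toxmodel.adjust_fdr([0.123]) == pytest.approx([0.123])

    def test_qvalue_no_larger_than_bh(self, rng):
        p = np.concatenate([rng.uniform(0, 1, 150), rng.uniform(0, 0.01, 50)])
        q = toxmodel.adjust_fdr(p, method="qvalue")
        bh = toxmodel.adjust_fdr(p, method="bh")
        assert (q <= bh + 1e-12).all()

    def test_qvalue_falls_back_to_bh_for_small_n(self, rng):
        p = rng.uniform(0, 1, 20)
        assert np.allclose(toxmodel.adjust_fdr(p, "qvalue"), toxmodel.adjust_fdr(p, "bh"))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            toxmodel.adjust_fdr([1.5])


def test_wald_interval_coverage_across_replicate_screens():
    """95% Wald CIs for the interaction cover the planted coefficient in
    93-97% of 300 replicate simulations."""
    cover = 0
    for i in range(300):
        sim = _sim(250, seed=30_000 + i, interaction={"dhs": -0.3},
                   pseudo_replicates=("pr1",))
        t = toxmodel.fit_feature_interaction(
            sim["counts"], sim["features"], "dhs",
            time_points=sim["config"].later_times,
        ).term("dhs:tp53wt")
        cover += abs(t.estimate - (-0.3)) < 1.959964 * t.se
    assert 0.93 <= cover / 300 <= 0.97


def test_fits_table_has_fdr_on_interaction_terms(small_screen, small_features):
    cfg = small_screen["config"]
    fits = [
        toxmodel.fit_feature_interaction(
            small_screen["counts"], small_features, f, time_points=cfg.later_times
        )
        for f in ("dhs", "h3k27ac")
    ]
    df = toxmodel.fits_table(fits, fdr_terms={"dhs:tp53wt": "", "h3k27ac:tp53wt": ""})
    inter = df[df["term"].str.endswith(":tp53wt")]
    assert inter["fdr"].notna().all()
    assert df["converged"].all()
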