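"""Reusable simulation experiments that exercise the full pipeline.

These routines wire the generator to the estimators under known ground
truth: interaction-coefficient recovery across replicate screens, type-I
error of the interaction test under the null, recall of planted toxic loci
through the LFC-threshold calling rules, and an essential-gene AUROC
benchmark on a screen with planted essentiality. They back both the test
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dsbtox import annot, locuscall, screenio, screenstats, simdata, toxmodel
from dsbtox.simdata import EffectSpec, SimConfig


def _subseed(seed: int, i: int) -> int:
    """Distinct per-replicate seeds, kept below 2**31."""
    return (seed * 100_003 + i) % (2**31 - 1)


def _one_rep_design(n_genes: int, seed: int, theta: float, **kw) -> SimConfig:
    # one pseudo-replicate, four time points: the fit pools the three later
    # time points across both genotypes
    return SimConfig(
        n_genes=n_genes, n_nontargeting=100, seed=seed, dispersion=theta,
        with_sequences=False, pseudo_replicates=("pr1",), **kw,
    )


def interaction_recovery(
    n_replicates: int = 100,
    n_genes: int = 1250,
    beta: float = -0.3,
    theta: float = 10.0,
    seed: int = 0,
) -> dict:
    """Fraction of replicate screens whose fitted feature x TP53 interaction
    lies within 2 estimated SE of the planted coefficient."""
    hits, ests = 0, []
    for i in range(n_replicates):
        cfg = _one_rep_design(n_genes, _subseed(seed, i), theta)
        eff = EffectSpec(interaction_effects={"dhs": beta}, essentiality_effect=-0.1)
        sim = simdata.simulate_screen(cfg, eff)
        ft = annot.assemble(sim["library"], sim["annotations"])
        t = toxmodel.fit_feature_interaction(
            sim["counts"], ft, "dhs", time_points=cfg.later_times
        ).term("dhs:tp53wt")
        ests.append(t.estimate)
        hits += abs(t.estimate - beta) < 2.0 * t.se
    return {
        "rate": hits / n_replicates,
        "n": n_replicates,
        "mean_estimate": float(np.mean(ests)),
    }


def null_rejection(
    n_fits: int = 500,
    n_genes: int = 250,
    theta: float = 10.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the interaction Wald test when no effect is planted."""
    rej = 0
    for i in range(n_fits):
        cfg = _one_rep_design(n_genes, _subseed(seed, 50_000 + i), theta)
        sim = simdata.simulate_screen(cfg, EffectSpec(interaction_effects={"dhs": 0.0}))
        ft = annot.assemble(sim["library"], sim["annotations"])
        p = toxmodel.fit_feature_interaction(
            sim["counts"], ft, "dhs", time_points=cfg.later_times
        ).term("dhs:tp53wt").p
        rej += p < alpha
    return {"rate": rej / n_fits, "n": n_fits}


def toxic_locus_calling(
    n_genes: int = 1250,
    carrier_fraction: float = 0.05,
    beta: float = -1.0,
    theta: float = 10.0,
    seed: int = 0,
) -> dict:
    """Plant a strongly toxic feature on a small carrier set and push the
    screen through normalisation, LFCs and the consistent-depletion calling
    rule; report recall/precision against the planted carriers plus the
    class sets.

    Uses the cumulative (linear-in-time) dropout mode, the regime the
    LFC-threshold rule addresses.
    """
    cfg = SimConfig(
        n_genes=n_genes, n_nontargeting=200, seed=seed, dispersion=theta,
        with_sequences=False, time_effect="linear",
    )
    eff = EffectSpec(
        interaction_effects={"dhs": beta}, feature_fractions={"dhs": carrier_fraction}
    )
    sim = simdata.simulate_screen(cfg, eff)
    ref = screenio.reference_guides(sim["library"], "nontargeting")
    norm = screenio.median_normalize(sim["counts"], ref)
    pairs = matched_wt_ko_pairs(norm)
    lfc = screenio.compute_lfc(norm, pairs)
    gene_lfc = lfc.drop(index=[r.sgrna_id for r in sim["library"] if r.is_nontargeting])
    targets = locuscall.call_target_loci(gene_lfc)
    non_selected = locuscall.call_non_selected(gene_lfc)
    background = locuscall.define_background(targets, sim["library"])
    carriers = set(sim["annotations"].index[sim["annotations"]["dhs"] > 0])
    recall = len(targets & carriers) / len(carriers)
    precision = len(targets & carriers) / len(targets) if targets else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "targets": targets,
        "background": background,
        "non_selected": non_selected,
        "carriers": carriers,
        "n_comparisons": len(pairs),
        "library": sim["library"],
    }


def matched_wt_ko_pairs(cm: screenio.CountMatrix) -> list[tuple[str, str]]:
    """wt vs ko sample pairs for every (pseudo-replicate, later time point)."""
    times = sorted({s.time_point for s in cm.samples}, key=lambda t: (len(t), t))
    base = times[0]
    ko = {(s.pseudo_replicate, s.time_point): s.sample_id
          for s in cm.samples if s.genotype == "ko"}
    return [
        (s.sample_id, ko[(s.pseudo_replicate, s.time_point)])
        for s in cm.samples
        if s.genotype == "wt" and s.time_point != base
        and (s.pseudo_replicate, s.time_point) in ko
    ]


def essential_gene_auroc(
    n_genes: int = 1000,
    essentiality_effect: float = 0.5,
    seed: int = 0,
) -> dict:
    """AUROC for separating strongly essential from neutral genes by mean
    normalised counts, per genotype.

    Gene essentiality enters through the D2 covariate; the benchmark sets
    are the lowest-decile (essential) and mid-band (non-essential) genes by
    D2 score.
    """
    cfg = SimConfig(n_genes=n_genes, n_nontargeting=100, seed=seed,
                    with_sequences=False, pseudo_replicates=("pr1",))
    sim = simdata.simulate_screen(cfg, EffectSpec(essentiality_effect=essentiality_effect))
    ref = screenio.reference_guides(sim["library"], "nontargeting")
    norm = screenio.median_normalize(sim["counts"], ref)
    gene_of = pd.Series({r.sgrna_id: r.gene for r in sim["library"] if not r.is_nontargeting})
    d2 = sim["annotations"].groupby(gene_of[sim["annotations"].index])["d2"].first()
    essential = set(d2.index[d2 <= d2.quantile(0.10)])
    nonessential = set(d2.index[(d2 >= d2.quantile(0.45)) & (d2 <= d2.quantile(0.55))])
    out = {}
    for gt in ("wt", "ko"):
        cols = [s.sample_id for s in norm.samples
                if s.genotype == gt and s.time_point == cfg.time_points[-1]]
        ranking = norm.counts[cols].mean(axis=1).groupby(gene_of.reindex(norm.counts.index)).mean()
        out[gt] = screenstats.auroc(ranking.dropna(), essential, nonessential)
    return out
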