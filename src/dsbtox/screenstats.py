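"""Gene-level screening statistics and conditional-essentiality analysis.

Covers: the essential / non-essential AUROC benchmark on mean normalised
counts, Z-standardised gene selection scores, two-component EM (Gaussian
mixture) clustering of control-vs-treatment Z-scores, the 2-SD conditional
hit rule, residual comparison of treatment~control fits between genotypes,
and an empirical permutation null for cross-comparison hit consistency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.mixture import GaussianMixture


def gene_scores_from_lfc(lfc: pd.DataFrame, gene_of: pd.Series) -> pd.Series:
    """Median sgRNA LFC per gene — the proxy used when external model-based
    gene selection scores (beta scores) are not supplied."""
    return lfc.mean(axis=1).groupby(gene_of.reindex(lfc.index)).median()


def auroc(ranking: pd.Series, essential: Iterable[str], nonessential: Iterable[str]) -> float:
    """Separation of essential from non-essential genes by the ranking score.

    ``ranking`` maps gene -> mean normalised count (essential genes drop
    out, so smaller is more essential). Equals the Mann-Whitney U statistic
    normalised by n1*n2, with ties counted 1/2: the probability that a
    random essential gene has lower counts than a random non-essential one.
    """
    ess = [g for g in essential if g in ranking.index]
    non = [g for g in nonessential if g in ranking.index]
    if not ess or not non:
        raise ValueError("both gene classes must intersect the ranking")
    u = mannwhitneyu(
        ranking[non].to_numpy(), ranking[ess].to_numpy(), alternative="two-sided"
    ).statistic
    return float(u) / (len(ess) * len(non))


def zscore(scores: pd.Series) -> pd.Series:
    """Standardise gene scores within one condition: (x - mean) / SD."""
    sd = float(scores.std(ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("scores are constant; cannot standardise")
    return (scores - scores.mean()) / sd


@dataclass
class EMClusterReport:
    labels: pd.Series  # 'selected' / 'non_selected' (all non_selected if k=1)
    n_components: int
    bics: dict[int, float]
    converged: bool


def em_two_cluster(
    z_control: pd.Series,
    z_treatment: pd.Series,
    max_components: int = 4,
    seed: int = 0,
) -> EMClusterReport:
    """Gaussian-mixture EM on (z_control, z_treatment); pick k by BIC.

    When the best model has two components, the component with the lower
    mean treatment Z is labelled 'selected'. Initialisation is seeded
    k-means, so results are deterministic given the seed.
    """
    genes = z_control.index.intersection(z_treatment.index)
    if len(genes) < 20:
        raise ValueError("need at least 20 genes for mixture clustering")
    X = np.column_stack([z_control[genes].to_numpy(), z_treatment[genes].to_numpy()])
    fits = {}
    bics = {}
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", random_state=seed, n_init=3
        ).fit(X)
        fits[k] = gm
        bics[k] = float(gm.bic(X))
    converged = {k: bool(f.converged_) for k, f in fits.items()}
    best = min((k for k in bics if converged[k]), key=lambda k: bics[k], default=None)
    if best is None:  # fall back to the best BIC regardless
        best = min(bics, key=bics.get)
    gm = fits[best]
    assign = gm.predict(X)
    labels = pd.Series("non_selected", index=genes)
    if best >= 2:
        selected_comp = int(np.argmin(gm.means_[:, 1]))
        labels[assign == selected_comp] = "selected"
    return EMClusterReport(
        labels=labels, n_components=best, bics=bics, converged=converged[best]
    )


def conditional_hit_call(
    z_control: pd.Series,
    z_treatment: pd.Series,
    sd_threshold: float = 2.0,
    pooled_diff_sd: bool = False,
) -> pd.Series:
    """Conditional-essentiality hit rule at the given SD threshold.

    A gene is a hit when the control Z is indistinguishable from 0
    (|z_c| < t), the treatment Z is below -t, and the control-treatment
    difference is itself below -t standard deviations of the per-gene
    difference distribution (standardised on its own SD; ``pooled_diff_sd``
    uses the SD pooled over both inputs' difference instead of ddof-1).
    """
    genes = z_control.index.intersection(z_treatment.index)
    zc, zt = z_control[genes], z_treatment[genes]
    diff = zt - zc
    sd = float(diff.std(ddof=0 if pooled_diff_sd else 1))
    if sd == 0:
        raise ValueError("degenerate difference distribution")
    zdiff = (diff - diff.mean()) / sd
    return (zc.abs() < sd_threshold) & (zt < -sd_threshold) & (zdiff < -sd_threshold)


def residual_compare(
    z_control: pd.Series, z_treatment: pd.Series, by_genotype: dict[str, tuple[pd.Series, pd.Series]] | None = None
) -> pd.DataFrame:
    """Residuals of the OLS fit z_treatment ~ z_control, per genotype.

    Pass either one pair (positional arguments) or ``by_genotype`` mapping
    genotype -> (z_control, z_treatment). With both genotypes present the
    output gains a per-gene residual difference (ko - wt): more-negative
    values mean the treatment conditionality is stronger in the p53-null
    background.
    """
    pairs = by_genotype or {"all": (z_control, z_treatment)}
    frames = {}
    for gt, (zc, zt) in pairs.items():
        genes = zc.index.intersection(zt.index)
        x, y = zc[genes].to_numpy(), zt[genes].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        frames[gt] = pd.Series(y - (slope * x + intercept), index=genes)
    out = pd.DataFrame(frames)
    if {"wt", "ko"} <= set(out.columns):
        out["residual_diff_ko_minus_wt"] = out["ko"] - out["wt"]
    return out


@dataclass
class PermutationResult:
    n_iter: int
    n_satisfying: int
    min_hits: int
    min_ko: int
    max_wt: int
    seed: int


def permutation_null(
    hit_labels: pd.DataFrame,
    ko_columns: Sequence[str],
    wt_columns: Sequence[str],
    n_iter: int = 1000,
    min_hits: int = 2,
    min_ko: int = 4,
    max_wt: int = 0,
    seed: int = 0,
) -> PermutationResult:
    """Reshuffle hit labels within each comparison; count lucky iterations.

    Each iteration independently permutes the boolean labels within every
    comparison column (preserving per-comparison hit counts) and checks
    whether at least ``min_hits`` genes are each a hit in >= ``min_ko`` of
    the p53-null comparisons while being a hit in <= ``max_wt`` wild-type
    comparisons. The returned frequency approximates the probability of the
    observed cross-comparison consistency arising by chance.
    """
    cols = list(ko_columns) + list(wt_columns)
    missing = [c for c in cols if c not in hit_labels.columns]
    if missing:
        raise ValueError(f"hit-label table lacks comparisons: {missing}")
    M = hit_labels[cols].to_numpy().astype(bool)
    n_genes = M.shape[0]
    col_sums = M.sum(axis=0)
    if (col_sums > n_genes).any():
        raise ValueError("per-comparison hit count exceeds the gene count")
    n_ko = len(ko_columns)
    rng = np.random.default_rng(seed)
    n_sat = 0
    perm = np.empty_like(M)
    for _ in range(n_iter):
        for j in range(M.shape[1]):
            perm[:, j] = M[rng.permutation(n_genes), j]
        assert (perm.sum(axis=0) == col_sums).all()
        ko_hits = perm[:, :n_ko].sum(axis=1)
        wt_hits = perm[:, n_ko:].sum(axis=1)
        if ((ko_hits >= min_ko) & (wt_hits <= max_wt)).sum() >= min_hits:
            n_sat += 1
    return PermutationResult(
        n_iter=n_iter, n_satisfying=n_sat, min_hits=min_hits,
        min_ko=min_ko, max_wt=max_wt, seed=seed,
    )
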