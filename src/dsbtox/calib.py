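"""Copy-number-equivalent calibration of toxicity effects and a linear
example p53-toxicity score.

Copy-number gain is a well-established driver of non-specific Cas9 cut
toxicity, so the fitted CN interaction coefficient provides a natural unit:
if a CN step of ``cn_ratio``-fold ploidy produces coefficient beta_cn, a
feature with coefficient beta_f corresponds (by cross-multiplication, the
rule of three) to targeting a region with ``cn_ratio * beta_f / beta_cn``
-fold increased local ploidy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


def count_fold_change(beta: float) -> float:
    """exp(beta): multiplicative change in expected sgRNA counts."""
    return float(np.exp(beta))


def cn_level_ratio(mean_cn_reference: float, mean_cn_high: float) -> float:
    """Fold change in ploidy between the two copy-number levels."""
    if mean_cn_reference <= 0:
        raise ValueError("reference CN must be positive")
    return mean_cn_high / mean_cn_reference


def ploidy_equivalent(beta_feature: float, beta_cn: float, cn_ratio: float = 2.9) -> float:
    """Express a feature coefficient in fold-ploidy units of the CN effect."""
    if beta_cn == 0:
        raise ValueError("beta_cn must be non-zero to serve as a calibration unit")
    if cn_ratio <= 0:
        raise ValueError("cn_ratio must be positive")
    return cn_ratio * beta_feature / beta_cn


@dataclass
class PloidyEquivalent:
    feature: str
    beta_feature: float
    beta_cn: float
    cn_ratio: float
    fold_ploidy: float
    count_fold_change: float


def calibration_table(
    feature_betas: Mapping[str, float], beta_cn: float, cn_ratio: float = 2.9
) -> pd.DataFrame:
    """Per-feature ploidy equivalents; summary columns use the printed
    precisions (1 decimal for fold ploidy, 2 for count fold change)."""
    rows = []
    for feature, beta in feature_betas.items():
        eq = PloidyEquivalent(
            feature=feature,
            beta_feature=beta,
            beta_cn=beta_cn,
            cn_ratio=cn_ratio,
            fold_ploidy=ploidy_equivalent(beta, beta_cn, cn_ratio),
            count_fold_change=count_fold_change(beta),
        )
        rows.append(
            {
                "feature": eq.feature,
                "beta_feature": eq.beta_feature,
                "beta_cn": eq.beta_cn,
                "cn_ratio": eq.cn_ratio,
                "fold_ploidy": eq.fold_ploidy,
                "fold_ploidy_1dp": round(eq.fold_ploidy, 1),
                "count_fold_change": eq.count_fold_change,
                "count_fold_change_2dp": round(eq.count_fold_change, 2),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


@dataclass
class ToxicityScore:
    sgrna_id: str
    score: float
    percentile: float


def score_sgrna(
    feature_vectors: pd.DataFrame,
    weights: Mapping[str, float],
) -> pd.DataFrame:
    """Linear example p53-toxicity score with library-wide percentile ranks.

    ``weights`` are per-covariate score weights; the convention used
    throughout is weight = negated interaction coefficient (averaged across
    pseudo-replicates), so that a more positive score predicts more
    p53-dependent toxicity. Every weighted covariate must be present and
    non-missing; guides with missing covariates are rejected rather than
    silently imputed.
    """
    missing_cols = [c for c in weights if c not in feature_vectors.columns]
    if missing_cols:
        raise KeyError(f"feature vectors lack weighted covariates: {missing_cols}")
    sub = feature_vectors[list(weights)].astype(float)
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)][:3].tolist()
        raise ValueError(f"missing covariate values (e.g. {bad}); no imputation policy set")
    w = pd.Series(weights, dtype=float)
    scores = sub.to_numpy() @ w.to_numpy()
    pct = pd.Series(scores).rank(pct=True).to_numpy() * 100.0
    return pd.DataFrame(
        {"score": scores, "percentile": pct}, index=feature_vectors.index
    )


def weights_from_fits(interaction_estimates: pd.DataFrame) -> dict[str, float]:
    """Default score weights: negated interaction coefficients averaged
    across pseudo-replicates.

    ``interaction_estimates`` has one row per (feature, pseudo-replicate)
    with columns ``feature`` and ``estimate``.
    """
    avg = interaction_estimates.groupby("feature")["estimate"].mean()
    return {f: -float(b) for f, b in avg.items()}
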