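"""Cell-line-panel analysis of per-sgRNA TP53-dependent fitness effects.

Given a per-sgRNA log2 fold-change matrix across many cell lines with known
TP53 status, each guide gets a standardised effect size (Cohen's d with
pooled SD, wild-type minus mutant: negative = worse fitness in TP53wt,
i.e. more p53 toxicity). Effect-size thresholds call panel-level target and
low-toxicity locus sets, which feed the TP53 x HR and feature x HR count
regressions.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from dsbtox.toxmodel import adjust_fdr


def panel_effect_sizes(lfc: pd.DataFrame, tp53_status: pd.Series) -> pd.DataFrame:
    """Per-guide Cohen's d (wt - mut) with two-sided t-test p and BH FDR.

    ``lfc`` is sgRNA x cell line; ``tp53_status`` maps line -> 'wt' or
    'mut'. Guides with zero pooled SD get an undefined effect (NaN) and are
    flagged.
    """
    lines = lfc.columns.intersection(tp53_status.index)
    status = tp53_status[lines]
    wt_cols = lines[status == "wt"]
    mut_cols = lines[status == "mut"]
    if len(wt_cols) < 2 or len(mut_cols) < 2:
        raise ValueError("need >= 2 cell lines per TP53 status group")
    A, B = lfc[wt_cols].to_numpy(), lfc[mut_cols].to_numpy()
    n1, n2 = A.shape[1], B.shape[1]
    m1, m2 = A.mean(axis=1), B.mean(axis=1)
    v1, v2 = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(pooled > 0, (m1 - m2) / pooled, np.nan)
    p = ttest_ind(A, B, axis=1).pvalue
    p = np.where(np.isfinite(p), p, 1.0)
    out = pd.DataFrame(
        {
            "effect_size": d,
            "p": p,
            "fdr": adjust_fdr(p),
            "n_wt": n1,
            "n_mut": n2,
            "undefined": ~np.isfinite(d),
        },
        index=lfc.index,
    )
    return out


def call_panel_loci(
    effects: pd.DataFrame,
    target_threshold: float = -0.4,
    control_band: tuple[float, float] = (-0.04, 0.04),
) -> tuple[set[str], set[str]]:
    """Threshold effect sizes into target and low-toxicity sets.

    Targets have effect size strictly below ``target_threshold`` (worse
    fitness in TP53wt); the low-toxicity controls lie strictly inside
    ``control_band``. Bounds are strict, so band-edge guides join neither
    set, and the sets are disjoint by construction.
    """
    d = effects["effect_size"]
    targets = set(effects.index[d < target_threshold])
    lo, hi = control_band
    low_tox = set(effects.index[(d > lo) & (d < hi)])
    return targets, low_tox


def prepare_hr_design(
    counts: pd.DataFrame,
    gene_of: pd.Series,
    tp53_status: Mapping[str, str],
    hr_status: Mapping[str, str],
    tissues: Mapping[str, str],
    nonessential_genes: Sequence[str],
    d2: pd.Series,
    sgrnas: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format model table for the TP53 x HR / feature x HR regressions.

    ``counts`` is sgRNA x cell line raw counts. Per-line offsets are the
    natural log of summed counts over guides in the supplied non-essential
    gene set (depth exposure unconfounded by selection). Lines missing a
    TP53 or HR status or a tissue label are dropped with a note column-free
    log; guides default to all rows of ``counts``.
    """
    ne = {g.upper() for g in nonessential_genes}
    ne_guides = [s for s in counts.index if str(gene_of.get(s, "")).upper() in ne]
    if not ne_guides:
        raise ValueError("no guides from the non-essential gene set in the count matrix")
    keep_lines = []
    for line in counts.columns:
        if line not in tp53_status or line not in hr_status:
            continue
        if line not in tissues:
            raise ValueError(f"cell line {line} has no tissue label")
        keep_lines.append(line)
    if not keep_lines:
        raise ValueError("no cell lines with complete status annotations")
    offsets = np.log(counts.loc[ne_guides, keep_lines].sum(axis=0).astype(float))
    ids = list(sgrnas) if sgrnas is not None else list(counts.index)
    sub = counts.loc[ids, keep_lines]
    n, m = len(ids), len(keep_lines)
    long = pd.DataFrame(
        {
            "sgrna_id": np.repeat(ids, m),
            "cell_line": np.tile(keep_lines, n),
            "count": sub.to_numpy().ravel(),
            "tp53wt": np.tile([1 if tp53_status[l] == "wt" else 0 for l in keep_lines], n),
            "hrwt": np.tile([1 if hr_status[l] == "wt" else 0 for l in keep_lines], n),
            "tissue": np.tile([tissues[l] for l in keep_lines], n),
            "offset": np.tile(offsets.to_numpy(), n),
        }
    )
    long["d2"] = d2.reindex(gene_of.reindex(long["sgrna_id"]).to_numpy()).to_numpy()
    return long
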