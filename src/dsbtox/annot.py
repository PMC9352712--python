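"""Turn raw per-sgRNA measurements into regression covariates.

Binning rules: chromatin-mark abundances go to bin 0 (absent) or bins 1/2
(increasing abundance, covering equal genome weight), with bin 1 masked out
of single-feature regressions to sharpen the absence-vs-abundance contrast;
copy-number bins 1-7 binarise to high (5-7) vs low (1-4); replication-timing
bins binarise to early (6) vs late (1-5) with bin 0 dropped; gene lengths
split at the median into short/long after removing genes > 200 kb; distance
to the 5' gene end is scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dsbtox import seqfeat
from dsbtox.simdata import CHROMATIN_MARKS


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def bin_chromatin(
    abundance: pd.Series | np.ndarray,
    genome_weights: pd.Series | np.ndarray | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Classify abundances into bins {0,1,2}; return (bins, bin-1 drop mask).

    Zeros are bin 0; positive territory is split at its genome-weight
    median into bins 1 and 2 (equal weight each side). Values tied with the
    split go to the lower bin. The mask marks bin-1 guides for exclusion
    from single-feature regressions.
    """
    a = pd.Series(abundance).astype(float)
    if (a < 0).any():
        raise ValueError("chromatin abundances must be non-negative")
    w = (
        pd.Series(genome_weights, index=a.index).astype(float)
        if genome_weights is not None
        else pd.Series(1.0, index=a.index)
    )
    bins = pd.Series(0, index=a.index, dtype=int)
    pos = a > 0
    if pos.any():
        split = _weighted_median(a[pos].to_numpy(), w[pos].to_numpy())
        bins[pos] = np.where(a[pos] > split, 2, 1)
    mask = bins == 1
    return bins, mask


def binarize_cn(cn_bin: pd.Series | np.ndarray) -> pd.Series:
    """Copy-number bins 1-7 -> high (5-7) vs low (1-4)."""
    cn = pd.Series(cn_bin).astype(int)
    if ((cn < 1) | (cn > 7)).any():
        raise ValueError("copy-number bins must lie in 1..7")
    return (cn >= 5).astype(int)


def binarize_rt(rt_bin: pd.Series | np.ndarray) -> tuple[pd.Series, pd.Series]:
    """Replication-timing bins 0-6 -> early (6) vs late (1-5); bin 0 dropped.

    Returns (early flag, drop mask for bin-0 guides).
    """
    rt = pd.Series(rt_bin).astype(int)
    if ((rt < 0) | (rt > 6)).any():
        raise ValueError("replication-timing bins must lie in 0..6")
    return (rt == 6).astype(int), rt == 0


def gene_length_bins(lengths: pd.Series, max_length: int = 200_000) -> pd.Series:
    """Per-gene short/long label; genes above ``max_length`` bp are dropped.

    Remaining genes split at the median length into two equal-sized bins
    (median-tied genes go to 'short').
    """
    lens = pd.Series(lengths).astype(float)
    kept = lens[lens <= max_length]
    if len(kept) < 2:
        raise ValueError("need at least two genes <= 200 kb to split short/long")
    med = float(kept.median())
    return pd.Series(np.where(kept > med, "long", "short"), index=kept.index)


def scale_dist5p(distance_bp, gene_length_bp):
    """Distance of the DSB to the 5' gene end, scaled to [0, 1]."""
    d = np.asarray(distance_bp, dtype=float)
    L = np.asarray(gene_length_bp, dtype=float)
    if (L <= 0).any():
        raise ValueError("gene lengths must be positive")
    out = d / L
    if ((out < 0) | (out > 1)).any():
        raise ValueError("distances must lie within the gene")
    return out


@dataclass
class FeatureTable:
    """Assembled per-sgRNA regression covariates with drop masks.

    ``data`` holds one row per gene-targeting sgRNA. ``drop_masks`` maps a
    covariate name to a boolean Series marking guides excluded from
    regressions on that covariate (bin-1 chromatin guides, RT bin 0, genes
    over 200 kb). ``split_points`` records every data-derived split for
    reproducibility.
    """

    data: pd.DataFrame
    drop_masks: dict[str, pd.Series] = field(default_factory=dict)
    split_points: dict[str, float] = field(default_factory=dict)

    def rows_for(self, feature: str) -> pd.DataFrame:
        mask = self.drop_masks.get(feature)
        if mask is None:
            return self.data
        return self.data.loc[~mask.reindex(self.data.index, fill_value=False)]


def assemble(
    library,
    raw: pd.DataFrame,
    motif_counts: pd.DataFrame | None = None,
    genome_weights: pd.Series | None = None,
    drop_missing_d2: bool = False,
) -> FeatureTable:
    """Build the final covariate table from raw annotations.

    Chromatin marks are binned (bin-1 masks recorded); CN and RT are
    binarised; gene length becomes a short/long factor with >200 kb guides
    masked; 5' distance is scaled by gene length; PAM context classes and
    MMEJ flags come from the sequence module when context sequences exist.
    """
    targets = [r for r in library if not r.is_nontargeting]
    ids = [r.sgrna_id for r in targets]
    missing = [i for i in ids if i not in raw.index]
    if missing:
        raise ValueError(f"raw annotations missing for {missing[:3]}...")
    raw = raw.loc[ids]
    out = pd.DataFrame(index=pd.Index(ids, name="sgrna_id"))
    masks: dict[str, pd.Series] = {}
    splits: dict[str, float] = {}

    for mark in CHROMATIN_MARKS:
        if mark not in raw.columns:
            continue
        bins, mask = bin_chromatin(raw[mark], genome_weights)
        out[mark] = bins
        masks[mark] = mask
        pos = raw[mark] > 0
        if pos.any():
            splits[mark] = _weighted_median(
                raw.loc[pos, mark].to_numpy(),
                np.ones(int(pos.sum()))
                if genome_weights is None
                else pd.Series(genome_weights).loc[raw.index[pos]].to_numpy(),
            )

    out["cn_high"] = binarize_cn(raw["cn_bin"])
    rt_early, rt_drop = binarize_rt(raw["rt_bin"])
    out["rt_early"] = rt_early
    masks["rt_early"] = rt_drop

    for flag in ("lamin", "ctcf", "cohesin", "mh"):
        if flag in raw.columns:
            out[flag] = raw[flag].astype(int)

    gene_of = pd.Series({r.sgrna_id: r.gene for r in targets})
    gene_len = raw.groupby(gene_of[raw.index])["gene_length"].first()
    length_bin = gene_length_bins(gene_len)
    out["gene_length_bin"] = gene_of.map(length_bin)
    masks["gene_length_bin"] = out["gene_length_bin"].isna()
    splits["gene_length_median"] = float(gene_len[gene_len <= 200_000].median())

    out["dist5p_scaled"] = scale_dist5p(raw["dist5p"], raw["gene_length"])
    if "expression" in raw.columns:
        out["expression"] = np.log(raw["expression"].astype(float) + 1.0)
        out["expression_high"] = (
            raw["expression"] > raw["expression"].median()
        ).astype(int)
    out["d2"] = raw["d2"]
    if out["d2"].isna().any():
        if drop_missing_d2:
            masks["_missing_d2"] = out["d2"].isna()
        else:
            raise ValueError("sgRNAs without a D2 score; pass drop_missing_d2=True")

    if all(r.context_seq for r in targets):
        half = len(targets[0].context_seq) // 2
        out["cpg"] = [seqfeat.count_cpg(r.context_seq) for r in targets]
        pam = [seqfeat.extract_pam_context(r) for r in targets]
        out["pam4"] = [p[0] for p in pam]
        out["pam_class"] = [p[1] for p in pam]
        if "mh" not in out.columns:
            out["mh"] = [
                int(seqfeat.is_mmej_candidate(r.context_seq, half + 1)) for r in targets
            ]

    if motif_counts is not None:
        for col in motif_counts.columns:
            out[f"motif_{col}"] = motif_counts[col].reindex(ids).fillna(0).astype(int)

    out["gene"] = gene_of[out.index]
    return FeatureTable(data=out, drop_masks=masks, split_points=splits)


def write_feature_table(ft: FeatureTable, path: str) -> None:
    """Serialise data + drop masks (mask_* columns) to one TSV."""
    df = ft.data.copy()
    for name, mask in ft.drop_masks.items():
        df[f"mask_{name}"] = mask.reindex(df.index, fill_value=False).astype(int)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_feature_table(path: str) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col="sgrna_id")
    masks = {}
    for col in [c for c in df.columns if c.startswith("mask_")]:
        masks[col[len("mask_"):]] = df.pop(col).astype(bool)
    return FeatureTable(data=df, drop_masks=masks)
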