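"""Classify sgRNAs into p53-toxic target, background and non-selected loci.

A guide is a *target locus* when its TP53wt-vs-TP53-null log2 fold change is
below a negative threshold in every (pseudo-replicate x later-time-point)
comparison — consistent depletion in wild-type cells relative to the
p53-null control, pointing at break toxicity rather than gene function.
*Background loci* are the remaining guides in genes that contain a target,
controlling for gene-level effects. *Non-selected loci* show |LFC| below the
threshold everywhere and anchor the off-target score cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from dsbtox.screenio import SgRNARecord

FILTER_NAMES = ("tp53_interactor", "go_term", "gene_family", "offtarget_exact", "offtarget_cfd")


@dataclass
class LocusLabel:
    sgrna_id: str
    label: str  # target | background | non_selected | unclassified
    filters_failed: list[str] = field(default_factory=list)


@dataclass
class OffTargetProfile:
    """Off-target summary for one guide: exact secondary match flag and the
    total CFD score (sum over the top-5 predicted off-targets)."""

    sgrna_id: str
    has_exact_offtarget_match: bool
    total_cfd: float

    def __post_init__(self) -> None:
        if self.total_cfd < 0:
            raise ValueError("total_cfd must be non-negative")


def _check_comparisons(lfc: pd.DataFrame, expected: Sequence[str] | None) -> None:
    if expected is not None:
        missing = [c for c in expected if c not in lfc.columns]
        if missing:
            raise ValueError(f"LFC table is missing comparisons: {missing}")


def call_target_loci(
    lfc: pd.DataFrame,
    threshold: float = -0.5,
    expected_comparisons: Sequence[str] | None = None,
) -> set[str]:
    """Guides with LFC < threshold in *every* comparison column."""
    _check_comparisons(lfc, expected_comparisons)
    hit = (lfc < threshold).all(axis=1)
    return set(lfc.index[hit])


def call_non_selected(
    lfc: pd.DataFrame,
    threshold: float = 0.5,
    expected_comparisons: Sequence[str] | None = None,
) -> set[str]:
    """Guides with |LFC| < threshold in every comparison column."""
    _check_comparisons(lfc, expected_comparisons)
    hit = (lfc.abs() < threshold).all(axis=1)
    return set(lfc.index[hit])


def define_background(
    targets: Iterable[str],
    library: Sequence[SgRNARecord],
    exclude_positive: set[str] | None = None,
) -> set[str]:
    """Same-gene companions of the target guides, minus the targets.

    ``exclude_positive`` optionally removes consistently positively selected
    guides from the background (off by default; background guides are
    defined only by gene membership).
    """
    targets = set(targets)
    by_id = {r.sgrna_id: r for r in library if not r.is_nontargeting}
    unknown = targets - set(by_id)
    if unknown:
        raise ValueError(f"target sgRNAs not in library: {sorted(unknown)[:3]}")
    target_genes = {by_id[t].gene for t in targets}
    background = {
        r.sgrna_id
        for r in by_id.values()
        if r.gene in target_genes and r.sgrna_id not in targets
    }
    if exclude_positive:
        background -= set(exclude_positive)
    return background


def apply_exclusion_filters(
    targets: Iterable[str],
    library: Sequence[SgRNARecord],
    tp53_interactors: Iterable[str] = (),
    go_genes: Iterable[str] = (),
    family_prefixes: Sequence[str] = ("OR", "USP", "FAM"),
    family_overrides: Iterable[str] = (),
) -> tuple[set[str], dict[str, list[str]]]:
    """Drop targets in TP53-pathway, GO-enriched or paralog-family genes.

    Family membership is a symbol-prefix match (e.g. OR5A1, USP7, FAM83B)
    where the prefix must be followed by a digit; ``family_overrides`` lists
    symbols exempt from the prefix rule. Returns the retained set and a
    provenance map sgRNA -> filters that removed it.
    """
    interactors = {g.upper() for g in tp53_interactors}
    go = {g.upper() for g in go_genes}
    overrides = {g.upper() for g in family_overrides}
    by_id = {r.sgrna_id: r for r in library}
    kept: set[str] = set()
    provenance: dict[str, list[str]] = {}
    for sid in targets:
        gene = (by_id[sid].gene or "").upper()
        failed = []
        if gene in interactors:
            failed.append("tp53_interactor")
        if gene in go:
            failed.append("go_term")
        if gene not in overrides and any(
            gene.startswith(p.upper()) and len(gene) > len(p) and gene[len(p)].isdigit()
            for p in family_prefixes
        ):
            failed.append("gene_family")
        if failed:
            provenance[sid] = failed
        else:
            kept.add(sid)
    return kept, provenance


def offtarget_filter(
    targets: Iterable[str],
    profiles: Mapping[str, OffTargetProfile] | Sequence[OffTargetProfile],
    non_selected: Iterable[str],
    percentile: float = 95.0,
) -> tuple[set[str], float, dict[str, list[str]]]:
    """Remove high-off-targeting guides from the target set.

    The cutoff is the given percentile (linear interpolation between order
    statistics) of total CFD over the non-selected loci; a target is removed
    if it has any exact secondary match or total CFD above the cutoff.
    Returns (kept targets, cutoff, provenance).
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.sgrna_id: p for p in profiles}
    ns = [s for s in non_selected if s in profiles]
    if not ns:
        raise ValueError("empty non-selected set (or no profiles for it)")
    cutoff = float(
        np.percentile([profiles[s].total_cfd for s in ns], percentile, method="linear")
    )
    kept: set[str] = set()
    provenance: dict[str, list[str]] = {}
    for sid in targets:
        p = profiles.get(sid)
        if p is None:
            raise KeyError(f"no off-target profile for target sgRNA {sid}")
        failed = []
        if p.has_exact_offtarget_match:
            failed.append("offtarget_exact")
        if p.total_cfd > cutoff:
            failed.append("offtarget_cfd")
        if failed:
            provenance[sid] = failed
        else:
            kept.add(sid)
    return kept, cutoff, provenance


def label_table(
    library: Sequence[SgRNARecord],
    targets: set[str],
    background: set[str],
    non_selected: set[str],
    provenance: Mapping[str, list[str]] | None = None,
) -> pd.DataFrame:
    """One row per guide with its class label and filter provenance."""
    provenance = provenance or {}
    rows = []
    for r in library:
        if r.is_nontargeting:
            continue
        sid = r.sgrna_id
        if sid in targets:
            label = "target"
        elif sid in background:
            label = "background"
        elif sid in non_selected:
            label = "non_selected"
        else:
            label = "unclassified"
        rows.append(
            {
                "sgrna_id": sid,
                "gene": r.gene,
                "label": label,
                "filters_failed": ";".join(provenance.get(sid, [])),
            }
        )
    return pd.DataFrame(rows).set_index("sgrna_id")
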