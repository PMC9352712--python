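"""Screen data containers, normalisation and log2 fold changes.

Raw sgRNA counts arrive as a (sgRNA x sample) integer matrix plus per-sample
metadata (genotype, pseudo-replicate/treatment, time point, batch). Counts are
depth-normalised by the median-of-ratios method restricted to a reference set
of guides — all guides, non-targeting controls, or guides in non-essential
genes — and per-guide log2 fold changes are computed between paired samples,
typically TP53wt (pseudo-treatment) versus TP53-null (pseudo-control) at the
same treatment arm and time point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOTYPES = ("wt", "ko")

LIBRARY_COLUMNS = [
    "sgrna_id",
    "gene",
    "protospacer",
    "pam4",
    "chrom",
    "cut_pos",
    "strand",
    "is_nontargeting",
]


@dataclass
class SgRNARecord:
    """One guide: identity, sequence and genomic cut locus.

    ``pam4`` is the PAM with its 1-bp upstream context, in protospacer
    orientation (upstream base + NGG); ``cut_pos`` is the 0-based index of the
    base immediately 5' of the blunt Cas9 cut. Non-targeting guides carry no
    locus (``gene`` is None, coordinates are None).
    """

    sgrna_id: str
    gene: str | None
    protospacer: str
    pam4: str
    chrom: str | None = None
    cut_pos: int | None = None
    strand: str = "+"
    context_seq: str = ""
    is_nontargeting: bool = False

    def __post_init__(self) -> None:
        if not self.is_nontargeting:
            if set(self.protospacer) - set("ACGT"):
                raise ValueError(
                    f"{self.sgrna_id}: protospacer must be over ACGT, got "
                    f"{self.protospacer!r}"
                )
            # guide orientation has GG at positions 2-3; genome orientation of a
            # minus-strand record reverse-complements to CC at positions 0-1
            if len(self.pam4) >= 4 and not (self.pam4[2:4] == "GG" or self.pam4[:2] == "CC"):
                raise ValueError(
                    f"{self.sgrna_id}: canonical SpCas9 PAM requires GG at "
                    f"positions 2-3 of {self.pam4!r} (or CC-leading genomic orientation)"
                )


@dataclass
class SampleMeta:
    """Metadata for one sequenced sample.

    ``offset`` is the natural log of the total non-targeting sgRNA counts in
    the sample; it enters the count regressions as a fixed exposure term.
    """

    sample_id: str
    genotype: str
    pseudo_replicate: str
    time_point: str
    batch: str = "b1"
    offset: float = float("nan")

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")


class CountMatrix:
    """sgRNA x sample count matrix with aligned sample metadata."""

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: Sequence[SampleMeta],
        normalized: bool = False,
        reference_set_used: str | None = None,
    ) -> None:
        sample_ids = [s.sample_id for s in samples]
        if list(counts.columns) != sample_ids:
            raise ValueError("count columns must match sample metadata order")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not normalized:
            arr = counts.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("raw counts must be integral")
        self.counts = counts
        self.samples = list(samples)
        self.normalized = normalized
        self.reference_set_used = reference_set_used

    @property
    def sgrna_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "genotype": [s.genotype for s in self.samples],
                "pseudo_replicate": [s.pseudo_replicate for s in self.samples],
                "time_point": [s.time_point for s in self.samples],
                "batch": [s.batch for s in self.samples],
                "offset": [s.offset for s in self.samples],
            }
        )

    def with_offsets_from_nontargeting(self, nontargeting_ids: Iterable[str]) -> "CountMatrix":
        """Set each sample's offset to log(total non-targeting counts)."""
        nt = [i for i in nontargeting_ids if i in self.counts.index]
        if not nt:
            raise ValueError("no non-targeting sgRNAs found in the matrix")
        totals = self.counts.loc[nt].sum(axis=0)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0].tolist()
            raise ValueError(f"zero non-targeting counts in samples: {bad}")
        samples = [
            replace(s, offset=float(np.log(totals[s.sample_id]))) for s in self.samples
        ]
        return CountMatrix(self.counts, samples, self.normalized, self.reference_set_used)


def reference_guides(
    library: Sequence[SgRNARecord],
    mode: str,
    nonessential_genes: Iterable[str] | None = None,
) -> set[str]:
    """Pick the normalisation reference guide set.

    ``mode`` is one of ``all`` (every guide), ``nontargeting`` (non-targeting
    controls) or ``nonessential`` (guides in a supplied non-essential gene
    list).
    """
    if mode == "all":
        return {r.sgrna_id for r in library}
    if mode == "nontargeting":
        return {r.sgrna_id for r in library if r.is_nontargeting}
    if mode == "nonessential":
        if nonessential_genes is None:
            raise ValueError("mode 'nonessential' needs a gene list")
        genes = {g.upper() for g in nonessential_genes}
        return {
            r.sgrna_id for r in library if r.gene is not None and r.gene.upper() in genes
        }
    raise ValueError(f"unknown reference mode {mode!r}")


def median_normalize(cm: CountMatrix, reference: Iterable[str]) -> CountMatrix:
    """Median-of-ratios depth normalisation on a reference guide set.

    For each reference guide i with all-positive counts, let g_i be the
    geometric mean of its counts across samples; the size factor of sample j
    is the median over those guides of c_ij / g_i, and normalised counts are
    c_ij / s_j. Restricting the median to a reference set (e.g. non-essential
    genes) keeps genuinely depleted guides from dragging the size factors.
    """
    ref = [r for r in reference if r in cm.counts.index]
    if len(ref) < 10:
        raise ValueError(
            f"reference set intersects only {len(ref)} sgRNAs in the matrix (need >= 10)"
        )
    sub = cm.counts.loc[ref].to_numpy(dtype=float)
    pos = (sub > 0).all(axis=1)
    if not pos.any():
        raise ValueError("every reference sgRNA has a zero count in some sample")
    sub = sub[pos]
    geo = np.exp(np.log(sub).mean(axis=1))
    size_factors = np.median(sub / geo[:, None], axis=0)
    if (size_factors <= 0).any() or not np.isfinite(size_factors).all():
        bad = [cm.sample_ids[j] for j in np.where(size_factors <= 0)[0]]
        raise ValueError(f"degenerate size factor for samples: {bad}")
    norm = cm.counts / size_factors
    out = CountMatrix(norm, cm.samples, normalized=True, reference_set_used="custom")
    out.size_factors = pd.Series(size_factors, index=cm.sample_ids)
    return out


def merge_batches(cm: CountMatrix, batch_map: Mapping[str, Sequence[str]]) -> CountMatrix:
    """Sum raw counts of technical batches before normalisation.

    ``batch_map`` maps a merged sample id to the sample ids it absorbs; every
    group must share genotype, pseudo-replicate and time point. Samples not
    mentioned pass through unchanged.
    """
    if cm.normalized:
        raise ValueError("merge batches on raw counts, before normalisation")
    grouped: set[str] = set()
    cols: dict[str, pd.Series] = {}
    metas: list[SampleMeta] = []
    for new_id, members in batch_map.items():
        ms = [cm.meta(m) for m in members]
        keys = {(m.genotype, m.pseudo_replicate, m.time_point) for m in ms}
        if len(keys) != 1:
            raise ValueError(
                f"batch group {new_id!r} mixes genotype/treatment/time: {sorted(keys)}"
            )
        grouped.update(members)
        cols[new_id] = cm.counts[list(members)].sum(axis=1)
        metas.append(replace(ms[0], sample_id=new_id, batch="merged", offset=float("nan")))
    for s in cm.samples:
        if s.sample_id not in grouped:
            cols[s.sample_id] = cm.counts[s.sample_id]
            metas.append(s)
    counts = pd.DataFrame(cols, index=cm.counts.index)[[m.sample_id for m in metas]]
    return CountMatrix(counts, metas, normalized=False)


def compute_lfc(
    cm: CountMatrix,
    pairs: Sequence[tuple[str, str]],
    pseudocount: float = 1.0,
    drop_zero_control: bool = False,
) -> pd.DataFrame:
    """Per-guide log2 fold change for each (treated, control) sample pair.

    LFC = log2((n_treated + pc) / (n_control + pc)); the pseudocount keeps
    dropouts finite. With ``drop_zero_control`` (the remove-0 behaviour),
    guides with a zero count in any control sample are dropped.
    """
    if not cm.normalized:
        raise ValueError("compute LFCs on normalised counts")
    missing = [s for p in pairs for s in p if s not in cm.counts.columns]
    if missing:
        raise KeyError(f"samples not in matrix: {sorted(set(missing))}")
    out = {}
    for treated, control in pairs:
        num = cm.counts[treated] + pseudocount
        den = cm.counts[control] + pseudocount
        out[f"{treated}_vs_{control}"] = np.log2(num / den)
    lfc = pd.DataFrame(out, index=cm.counts.index)
    if drop_zero_control:
        keep = np.ones(len(lfc), dtype=bool)
        for _, control in pairs:
            keep &= (cm.counts[control] > 0).to_numpy()
        lfc = lfc.loc[keep]
    return lfc


# ---------------------------------------------------------------------------
# Plain-text I/O: TSV tables and FASTA context windows.

def write_counts(cm: CountMatrix, path: str) -> None:
    df = cm.counts.copy()
    if not cm.normalized:
        df = df.astype(np.int64)
    df.index.name = "sgrna_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_counts(path: str, meta_path: str) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sgrna_id")
    meta = read_sample_meta(meta_path)
    arr = df.to_numpy()
    normalized = not np.allclose(arr, np.round(arr))
    return CountMatrix(df[[m.sample_id for m in meta]], meta, normalized=normalized)


def write_sample_meta(samples: Sequence[SampleMeta], path: str) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "genotype": [s.genotype for s in samples],
            "pseudo_replicate": [s.pseudo_replicate for s in samples],
            "time_point": [s.time_point for s in samples],
            "batch": [s.batch for s in samples],
            "offset": [s.offset for s in samples],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sample_meta(path: str) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            genotype=str(r.genotype),
            pseudo_replicate=str(r.pseudo_replicate),
            time_point=str(r.time_point),
            batch=str(r.batch),
            offset=float(r.offset) if not pd.isna(r.offset) else float("nan"),
        )
        for r in df.itertuples()
    ]


def write_library(library: Sequence[SgRNARecord], path: str) -> None:
    rows = []
    for r in library:
        rows.append(
            {
                "sgrna_id": r.sgrna_id,
                "gene": "" if r.gene is None else r.gene,
                "protospacer": r.protospacer,
                "pam4": r.pam4,
                "chrom": "" if r.chrom is None else r.chrom,
                "cut_pos": "" if r.cut_pos is None else r.cut_pos,
                "strand": r.strand,
                "is_nontargeting": int(r.is_nontargeting),
            }
        )
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_library(path: str, fasta_path: str | None = None) -> list[SgRNARecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    contexts: dict[str, str] = {}
    if fasta_path is not None:
        contexts = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    out = []
    for r in df.itertuples():
        out.append(
            SgRNARecord(
                sgrna_id=r.sgrna_id,
                gene=r.gene or None,
                protospacer=r.protospacer,
                pam4=r.pam4,
                chrom=r.chrom or None,
                cut_pos=int(r.cut_pos) if r.cut_pos != "" else None,
                strand=r.strand,
                context_seq=contexts.get(r.sgrna_id, ""),
                is_nontargeting=bool(int(r.is_nontargeting)),
            )
        )
    return out


def write_context_fasta(library: Sequence[SgRNARecord], path: str) -> None:
    records = [
        SeqRecord(Seq(r.context_seq), id=r.sgrna_id, description="")
        for r in library
        if r.context_seq
    ]
    SeqIO.write(records, path, "fasta")


def read_gene_list(path: str) -> set[str]:
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}
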