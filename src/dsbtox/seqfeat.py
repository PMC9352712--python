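"""Sequence covariates at Cas9 cut sites.

Covers microhomology-pair detection (candidacy for microhomology-mediated
end joining, MMEJ), PAM 1-bp-upstream context classes, CpG dimer counts and
IUPAC-consensus motif occurrence counts in windows centred on the break.

Coordinate convention: ``cut_index`` is the number of bases 5' of the blunt
cut, i.e. ``seq[:cut_index]`` lies entirely upstream of the break and
``seq[cut_index:]`` entirely downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class MHPair:
    """A pair of identical arms flanking the cut that could drive MMEJ.

    Offsets are measured in bp from the cut to the cut-proximal end of each
    arm (0 = the arm abuts the break).
    """

    arm_seq: str
    arm_len: int
    upstream_offset: int
    downstream_offset: int


def find_mh_pairs(
    context_seq: str,
    cut_index: int,
    min_len: int = 5,
    max_len: int = 15,
    window: int = 15,
) -> list[MHPair]:
    """Enumerate exact-match microhomology arm pairs flanking the cut.

    One arm lies entirely 5' of the cut and the other entirely 3'; arm
    length is in [min_len, max_len] and each arm's cut-proximal end is
    within ``window`` bp of the break. Arms containing N never match. Both
    maximal and contained (non-maximal) arms are reported.
    """
    seq = context_seq.upper()
    if set(seq) - VALID_BASES:
        raise ValueError("sequence must be over A/C/G/T/N")
    if not 0 < cut_index < len(seq):
        raise ValueError(f"cut_index {cut_index} outside sequence of length {len(seq)}")
    up, down = seq[:cut_index], seq[cut_index:]
    # index upstream candidate arms by sequence for O(window^2 * len) total
    upstream: dict[str, list[int]] = {}
    for off in range(min(window, len(up)) + 1):
        for length in range(min_len, max_len + 1):
            start = len(up) - off - length
            if start < 0:
                continue
            arm = up[start : start + length]
            if "N" in arm:
                continue
            upstream.setdefault(arm, []).append(off)
    pairs: list[MHPair] = []
    for off in range(min(window, len(down)) + 1):
        for length in range(min_len, max_len + 1):
            if off + length > len(down):
                continue
            arm = down[off : off + length]
            if "N" in arm or arm not in upstream:
                continue
            for up_off in upstream[arm]:
                pairs.append(MHPair(arm, length, up_off, off))
    return sorted(set(pairs), key=lambda p: (p.arm_len, p.upstream_offset, p.downstream_offset))


def is_mmej_candidate(
    context_seq: str,
    cut_index: int,
    min_len: int = 5,
    max_len: int = 15,
    window: int = 15,
) -> bool:
    """True iff at least one qualifying microhomology pair flanks the cut."""
    # early-exit scan (same enumeration, stops at the first hit)
    seq = context_seq.upper()
    if set(seq) - VALID_BASES:
        raise ValueError("sequence must be over A/C/G/T/N")
    if not 0 < cut_index < len(seq):
        raise ValueError(f"cut_index {cut_index} outside sequence of length {len(seq)}")
    up, down = seq[:cut_index], seq[cut_index:]
    arms = set()
    for off in range(min(window, len(up)) + 1):
        for length in range(min_len, max_len + 1):
            start = len(up) - off - length
            if start < 0:
                continue
            arm = up[start : start + length]
            if "N" not in arm:
                arms.add(arm)
    for off in range(min(window, len(down)) + 1):
        for length in range(min_len, max_len + 1):
            if off + length > len(down):
                continue
            arm = down[off : off + length]
            if "N" not in arm and arm in arms:
                return True
    return False


def extract_pam_context(record) -> tuple[str, str]:
    """Return (4-mer, class) for the PAM with 1-bp upstream context.

    The 4-mer is upstream base + NGG in protospacer orientation; the class
    collapses the PAM's variable base: e.g. "CAGG" and "CGGG" both belong to
    class "C-NGG". Minus-strand records whose stored 4-mer is in genomic
    orientation are reverse-complemented first.
    """
    pam4 = record.pam4.upper()
    if len(pam4) != 4:
        raise ValueError(f"malformed pam4 {record.pam4!r} (need 4 bases)")
    if pam4[2:4] != "GG":
        flipped = reverse_complement(pam4)
        if record.strand == "-" and flipped[2:4] == "GG":
            pam4 = flipped
        else:
            raise ValueError(f"malformed PAM in {record.pam4!r}: positions 2-3 must be GG")
    if set(pam4) - set("ACGT"):
        raise ValueError(f"malformed pam4 {record.pam4!r}")
    return pam4, f"{pam4[0]}-NGG"


def count_cpg(context_seq: str) -> int:
    """Number of CpG dimers in the sequence (5'->3' scan)."""
    return context_seq.upper().count("CG")


def _iupac_regex(consensus: str) -> str:
    parts = []
    for ch in consensus.upper():
        if ch not in ambiguous_dna_values:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in consensus {consensus!r}")
        vals = ambiguous_dna_values[ch]
        parts.append(vals if len(vals) == 1 else f"[{vals}]")
    return "".join(parts)


@dataclass
class MotifCovariate:
    """Occurrence counts of one motif consensus across a locus set."""

    motif_id: str
    consensus: str
    window_half_width: int
    counts: pd.Series  # per sgRNA, capped
    cap: int

    @property
    def prevalence(self) -> float:
        return float((self.counts > 0).mean())


def scan_motif(
    context_seqs: Mapping[str, str],
    consensus: str,
    window_half_width: int,
    cap: int = 5,
    cut_indices: Mapping[str, int] | None = None,
    motif_id: str | None = None,
) -> MotifCovariate:
    """Count IUPAC-consensus matches (both strands) near the cut.

    A match is counted when its span intersects the window of
    ``2 * window_half_width`` bp centred on the cut; overlapping matches all
    count, and per-locus counts are capped at ``cap``. When ``cut_indices``
    is omitted the cut is assumed at the centre of each context window.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    fwd = re.compile(f"(?=({_iupac_regex(consensus)}))")
    rev = re.compile(f"(?=({_iupac_regex(reverse_complement(consensus.upper()))}))")
    L = len(consensus)
    counts = {}
    for sid, seq in context_seqs.items():
        seq = seq.upper()
        cut = cut_indices[sid] if cut_indices is not None else len(seq) // 2 + 1
        lo, hi = cut - window_half_width, cut + window_half_width
        n = 0
        for pat in (fwd, rev):
            for m in pat.finditer(seq):
                start = m.start()
                if start < hi and start + L > lo:
                    n += 1
        counts[sid] = min(n, cap)
    return MotifCovariate(
        motif_id=motif_id or consensus,
        consensus=consensus,
        window_half_width=window_half_width,
        counts=pd.Series(counts, dtype=int),
        cap=cap,
    )


def prevalence_filter(
    covariates: Sequence[MotifCovariate],
    universe: Sequence[str],
    min_prevalence: float = 0.10,
) -> list[MotifCovariate]:
    """Keep motifs present (count >= 1) in at least ``min_prevalence`` of the
    locus universe (inclusive threshold)."""
    ids = list(universe)
    kept = []
    for cov in covariates:
        counts = cov.counts.reindex(ids).fillna(0)
        if float((counts > 0).mean()) >= min_prevalence:
            kept.append(cov)
    return kept


def motif_table(covariates: Sequence[MotifCovariate], binary: bool = False) -> pd.DataFrame:
    """Assemble per-locus motif counts (or presence flags) into a table."""
    df = pd.DataFrame({c.motif_id: c.counts for c in covariates})
    return (df > 0).astype(int) if binary else df.fillna(0).astype(int)
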