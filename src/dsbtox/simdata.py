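"""Synthetic isogenic-pair CRISPR screens with known planted effects.

The generator emulates the design of a TP53wt / TP53-null screen pair: a
library of gene-targeting guides plus non-targeting controls, per-guide
chromatin/sequence annotations, and negative-binomially distributed raw
counts over (genotype x pseudo-replicate x time point) samples whose log-mean
is

    log mu = offset + baseline + s(t) * [ beta_D2 * D2
             + sum_f beta_f * x_f + sum_f beta_fxTP53 * x_f * 1(wt) ]

with NB size parameter theta (var = mu + mu^2/theta). Non-targeting guides
carry only offset + baseline. ``s(t)`` is 0 at the baseline time point; after
baseline it is 1 in ``step`` mode (the default — the planted coefficient is
then exactly the estimand of the pooled interaction regression) or the time
index 1/2/3 in ``linear`` mode (cumulative dropout over the time course).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from dsbtox import seqfeat
from dsbtox.screenio import CountMatrix, SampleMeta, SgRNARecord

CHROMATIN_MARKS = (
    "dhs",
    "h3k9ac",
    "h3k27ac",
    "h3k4me1",
    "h3k4me2",
    "h3k4me3",
    "h4k20me1",
    "h2az",
    "h3k79me2",
    "h3k36me3",
    "h3k9me3",
    "h3k27me3",
)
BINARY_FLAGS = ("lamin", "ctcf", "cohesin", "mh")
DERIVED_FLAGS = ("cn_high", "rt_early")
KNOWN_FEATURES = CHROMATIN_MARKS + BINARY_FLAGS + DERIVED_FLAGS

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Design and noise parameters of a simulated screen."""

    n_genes: int
    sgrnas_per_gene: int = 4
    n_nontargeting: int = 100
    pseudo_replicates: Sequence[str] = ("pr1", "pr2", "pr3")
    time_points: Sequence[str] = ("t0", "t9", "t12", "t15")
    genotypes: Sequence[str] = ("wt", "ko")
    dispersion: float = 10.0
    baseline_log_mean: float = float(np.log(500.0))
    seed: int = 0
    context_len: int = 201
    mh_fraction: float | None = None
    time_effect: str = "step"  # or "linear"
    depth_sd: float = 0.1  # sd of per-sample log depth factor
    with_sequences: bool = True

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.sgrnas_per_gene <= 0:
            raise ValueError("n_genes and sgrnas_per_gene must be positive")
        if self.n_nontargeting < 0:
            raise ValueError("n_nontargeting must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion (NB size theta) must be positive")
        if len(self.time_points) < 2:
            raise ValueError("need a baseline and at least one later time point")
        if self.time_effect not in ("step", "linear"):
            raise ValueError("time_effect must be 'step' or 'linear'")
        if self.mh_fraction is not None and not 0.0 <= self.mh_fraction <= 1.0:
            raise ValueError("mh_fraction must lie in [0, 1]")
        if self.context_len < 61 or self.context_len % 2 == 0:
            raise ValueError("context_len must be odd and >= 61")

    @property
    def baseline_time(self) -> str:
        return self.time_points[0]

    @property
    def later_times(self) -> list[str]:
        return list(self.time_points[1:])

    def time_scale(self, time_point: str) -> float:
        idx = list(self.time_points).index(time_point)
        if idx == 0:
            return 0.0
        return 1.0 if self.time_effect == "step" else float(idx)


@dataclass
class EffectSpec:
    """Planted effect sizes and covariate structure.

    Effects are on the natural-log count scale. ``feature_fractions`` gives
    the fraction of gene-targeting guides carrying each feature (for
    chromatin marks this is one minus the zero-inflation); features not
    listed default to 0.5. ``feature_correlation`` maps unordered mark pairs
    to the target Pearson correlation of their final (zero-inflated)
    abundances.
    """

    feature_effects: Mapping[str, float] = field(default_factory=dict)
    interaction_effects: Mapping[str, float] = field(default_factory=dict)
    essentiality_effect: float = 0.0
    feature_fractions: Mapping[str, float] = field(default_factory=dict)
    feature_correlation: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            list(self.feature_effects)
            + list(self.interaction_effects)
            + list(self.feature_fractions)
        ):
            if name not in KNOWN_FEATURES:
                raise ValueError(
                    f"unknown feature {name!r}; known: {sorted(KNOWN_FEATURES)}"
                )
        for (a, b), r in self.feature_correlation.items():
            if a not in CHROMATIN_MARKS or b not in CHROMATIN_MARKS:
                raise ValueError(f"correlations are between chromatin marks, got {(a, b)}")
            if not -1.0 <= r <= 1.0:
                raise ValueError("correlations must lie in [-1, 1]")

    def fraction(self, name: str) -> float:
        f = float(self.feature_fractions.get(name, 0.5))
        if not 0.0 < f < 1.0:
            raise ValueError(f"fraction for {name!r} must lie in (0, 1), got {f}")
        return f


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def generate_library(config: SimConfig) -> list[SgRNARecord]:
    """Deterministically generate a guide library with context windows.

    Each gene receives ``sgrnas_per_gene`` guides. The 201-nt (default)
    context window is centred on the blunt cut: the protospacer is laid into
    the window so that the cut falls 3 bp 5' of the NGG PAM, and ``pam4`` is
    the 1-bp-upstream context plus the PAM. When ``mh_fraction`` is set, that
    exact fraction of gene-targeting guides is made a microhomology (MMEJ)
    candidate: an arm copied from just upstream of the cut is planted past
    the PAM, and chance microhomologies are scrubbed from the remaining
    guides by resampling their downstream flank.
    """
    rng = np.random.default_rng(config.seed)
    c = config.context_len // 2  # index of the base immediately 5' of the cut
    cut_index = c + 1  # split point: seq[:cut_index] is 5' of the cut
    records: list[SgRNARecord] = []
    n_target = config.n_genes * config.sgrnas_per_gene
    if config.mh_fraction is None:
        mh_plant = None
    else:
        mh_plant = np.zeros(n_target, dtype=bool)
        n_mh = int(round(config.mh_fraction * n_target))
        mh_plant[rng.permutation(n_target)[:n_mh]] = True

    idx = 0
    for g in range(config.n_genes):
        gene = f"GENE{g + 1:05d}"
        for k in range(config.sgrnas_per_gene):
            for _attempt in range(100):
                proto = _random_seq(rng, 20)
                pam = _random_seq(rng, 1) + "GG"
                if not config.with_sequences:
                    seq = ""
                    break
                ctx = list(_random_seq(rng, config.context_len))
                # protospacer occupies [c-16, c+4); PAM [c+4, c+7)
                ctx[c - 16 : c + 4] = list(proto)
                ctx[c + 4 : c + 7] = list(pam)
                if mh_plant is not None:
                    ctx = _control_microhomology(rng, ctx, cut_index, mh_plant[idx])
                    if ctx is None:  # chance arm pair pinned in the guide bases
                        continue
                seq = "".join(ctx)
                break
            else:
                raise RuntimeError("could not realise microhomology constraint")
            records.append(
                SgRNARecord(
                    sgrna_id=f"sg{idx + 1:06d}",
                    gene=gene,
                    protospacer=proto,
                    pam4=proto[-1] + pam,
                    chrom="chrS",
                    cut_pos=100_000 + 1_000 * idx,
                    strand="+" if rng.random() < 0.5 else "-",
                    context_seq=seq,
                    is_nontargeting=False,
                )
            )
            idx += 1
    for j in range(config.n_nontargeting):
        records.append(
            SgRNARecord(
                sgrna_id=f"nt{j + 1:05d}",
                gene=None,
                protospacer=_random_seq(rng, 20),
                pam4="",
                chrom=None,
                cut_pos=None,
                strand="+",
                context_seq="",
                is_nontargeting=True,
            )
        )
    return records


def _control_microhomology(
    rng: np.random.Generator, ctx: list[str], cut_index: int, plant: bool
) -> list[str] | None:
    """Force the presence/absence of a microhomology pair around the cut.

    Returns None when absence cannot be realised without altering the guide
    sequence itself (a chance arm pair entirely within the protospacer/PAM
    bases); the caller then redraws the whole guide.
    """
    seq = "".join(ctx)
    if plant:
        if seqfeat.is_mmej_candidate(seq, cut_index):
            return ctx
        arm_len = int(rng.integers(5, 9))
        up_off = int(rng.integers(0, 4))  # cut-proximal end within protospacer
        down_off = int(rng.integers(6, 11))  # past the PAM, still within 15 bp
        start = cut_index - up_off - arm_len
        arm = seq[start : start + arm_len]
        pos = cut_index + down_off
        ctx[pos : pos + arm_len] = list(arm)
        return ctx
    # scrub: resample the flanks outside the protospacer/PAM until clean
    lo = cut_index + 6  # first base past the PAM
    hi = cut_index - 17  # last base before the protospacer
    for _ in range(30):
        seq = "".join(ctx)
        if not seqfeat.is_mmej_candidate(seq, cut_index):
            return ctx
        ctx[lo:] = list(_random_seq(rng, len(ctx) - lo))
        ctx[:hi] = list(_random_seq(rng, hi))
    return None


# -- correlated zero-inflated abundances ------------------------------------

_GH_NODES = 96


def _censored_moments(a: float, nodes: np.ndarray, weights: np.ndarray):
    x = np.maximum(nodes - a, 0.0)
    m1 = float(weights @ x)
    m2 = float(weights @ x**2)
    return m1, m2 - m1**2


def _censored_corr(rho: float, a: float, b: float) -> float:
    """Pearson correlation of max(Z1-a,0), max(Z2-b,0) for BVN(rho) latents."""
    z, w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    w = w / w.sum()
    m1a, va = _censored_moments(a, z, w)
    m1b, vb = _censored_moments(b, z, w)
    s = np.sqrt(max(1.0 - rho**2, 1e-12))
    cond_mean = np.array(
        [w @ np.maximum(rho * zi + s * z - b, 0.0) for zi in z]
    )
    exy = float(w @ (np.maximum(z - a, 0.0) * cond_mean))
    return (exy - m1a * m1b) / np.sqrt(va * vb)


def _latent_corr(target: float, a: float, b: float) -> float:
    """Invert the censoring attenuation so abundances hit the target corr."""
    if target == 0.0:
        return 0.0
    lo, hi = (0.0, 0.999) if target > 0 else (-0.999, 0.0)
    f = lambda r: _censored_corr(r, a, b) - target
    if f(lo) * f(hi) > 0:
        raise ValueError(f"target correlation {target} not attainable after censoring")
    return float(brentq(f, lo, hi, xtol=1e-4))


def generate_annotations(
    library: Sequence[SgRNARecord], effects: EffectSpec, seed: int
) -> pd.DataFrame:
    """Per-guide raw covariates: chromatin abundances, CN/RT bins, D2, etc.

    Chromatin-mark abundances follow a zero-inflated censored-normal law:
    a latent Gaussian (with cross-mark correlation calibrated so the final
    abundances reach the configured Pearson correlation) is shifted and
    clipped at zero, so that ``1 - fraction(f)`` of guides have abundance 0.
    Binary flags (lamin B1, CTCF, cohesin) are Bernoulli; the MMEJ flag is
    scanned from the context sequence when present. D2 essentiality scores
    and gene lengths are drawn per gene and shared by its guides.
    """
    targets = [r for r in library if not r.is_nontargeting]
    if not targets:
        raise ValueError("library has no gene-targeting sgRNAs")
    rng = np.random.default_rng(seed)
    n = len(targets)
    marks = list(CHROMATIN_MARKS)
    thresholds = {f: float(norm.ppf(1.0 - effects.fraction(f))) for f in marks}

    corr = np.eye(len(marks))
    for (fa, fb), r in effects.feature_correlation.items():
        ia, ib = marks.index(fa), marks.index(fb)
        rl = _latent_corr(float(r), thresholds[fa], thresholds[fb])
        corr[ia, ib] = corr[ib, ia] = rl
    ev = np.linalg.eigvalsh(corr)
    if ev.min() < -1e-8:
        raise ValueError("configured feature correlations are not positive semi-definite")
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(marks)))
    z = rng.standard_normal((n, len(marks))) @ chol.T

    ann = pd.DataFrame(index=pd.Index([r.sgrna_id for r in targets], name="sgrna_id"))
    for j, f in enumerate(marks):
        ann[f] = np.maximum(z[:, j] - thresholds[f], 0.0)
    for f in ("lamin", "ctcf", "cohesin"):
        ann[f] = (rng.random(n) < effects.fraction(f)).astype(int)

    has_ctx = all(r.context_seq for r in targets)
    if has_ctx:
        half = len(targets[0].context_seq) // 2
        ann["mh"] = [
            int(seqfeat.is_mmej_candidate(r.context_seq, half + 1)) for r in targets
        ]
    else:
        ann["mh"] = (rng.random(n) < effects.fraction("mh")).astype(int)

    ann["cn_bin"] = rng.choice(
        np.arange(1, 8), size=n, p=np.array([5, 20, 25, 25, 15, 7, 3]) / 100.0
    )
    ann["rt_bin"] = rng.choice(
        np.arange(0, 7), size=n, p=np.array([2, 10, 15, 20, 20, 18, 15]) / 100.0
    )

    genes = pd.Index([r.gene for r in targets])
    uniq = genes.unique()
    d2_by_gene = pd.Series(rng.normal(0.0, 1.0, len(uniq)), index=uniq)
    len_by_gene = pd.Series(
        np.exp(rng.normal(np.log(30_000), 0.8, len(uniq))).astype(int), index=uniq
    )
    ann["d2"] = d2_by_gene[genes].to_numpy()
    ann["gene_length"] = len_by_gene[genes].to_numpy()
    ann["dist5p"] = (rng.random(n) * ann["gene_length"]).astype(int)
    ann["expression"] = np.exp(rng.normal(1.0, 1.0, n))
    return ann


def carrier_matrix(ann: pd.DataFrame, features: Sequence[str]) -> pd.DataFrame:
    """Binary carrier status for each feature (mark present / flag set)."""
    out = {}
    for f in features:
        if f in CHROMATIN_MARKS:
            out[f] = (ann[f] > 0).astype(int)
        elif f in BINARY_FLAGS:
            out[f] = ann[f].astype(int)
        elif f == "cn_high":
            out[f] = (ann["cn_bin"] >= 5).astype(int)
        elif f == "rt_early":
            out[f] = (ann["rt_bin"] == 6).astype(int)
        else:
            raise ValueError(f"unknown feature {f!r}")
    return pd.DataFrame(out, index=ann.index)


def simulate_counts(
    library: Sequence[SgRNARecord],
    ann: pd.DataFrame,
    effects: EffectSpec,
    config: SimConfig,
) -> CountMatrix:
    """Draw NB raw counts for every (genotype, pseudo-replicate, time) sample.

    Sample offsets on the returned matrix are set to the log of the total
    non-targeting counts per sample (falling back to total library counts
    when the design has no non-targeting guides), matching the exposure term
    used by the regression models.
    """
    targets = [r for r in library if not r.is_nontargeting]
    missing = [r.sgrna_id for r in targets if r.sgrna_id not in ann.index]
    if missing:
        raise ValueError(f"annotations missing for {len(missing)} sgRNAs, e.g. {missing[:3]}")
    rng = np.random.default_rng([config.seed, 7_654_321])

    feats = sorted(set(effects.feature_effects) | set(effects.interaction_effects))
    x = carrier_matrix(ann.loc[[r.sgrna_id for r in targets]], feats) if feats else None
    d2 = ann.loc[[r.sgrna_id for r in targets], "d2"].to_numpy()

    base_main = effects.essentiality_effect * d2
    base_int = np.zeros(len(targets))
    for f in feats:
        xf = x[f].to_numpy()
        base_main = base_main + effects.feature_effects.get(f, 0.0) * xf
        base_int = base_int + effects.interaction_effects.get(f, 0.0) * xf

    samples: list[SampleMeta] = []
    cols: dict[str, np.ndarray] = {}
    ids = [r.sgrna_id for r in library]
    nt_mask = np.array([r.is_nontargeting for r in library])
    n_all = len(library)
    for gt in config.genotypes:
        for pr in config.pseudo_replicates:
            for tp in config.time_points:
                sid = f"{gt}_{pr}_{tp}"
                depth = rng.normal(0.0, config.depth_sd)
                s = config.time_scale(tp)
                eta = np.full(n_all, config.baseline_log_mean + depth)
                effect = base_main + (base_int if gt == "wt" else 0.0)
                eta[~nt_mask] += s * effect
                if eta.max() > 30.0:
                    raise ValueError(
                        "simulated log-mean exceeds 30; reduce baseline_log_mean "
                        "or the planted effect sizes"
                    )
                lam = rng.gamma(config.dispersion, np.exp(eta) / config.dispersion)
                cols[sid] = rng.poisson(lam)
                samples.append(
                    SampleMeta(sample_id=sid, genotype=gt, pseudo_replicate=pr, time_point=tp)
                )
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="sgrna_id"))
    cm = CountMatrix(counts, samples, normalized=False)
    nt_ids = [r.sgrna_id for r in library if r.is_nontargeting]
    if nt_ids:
        return cm.with_offsets_from_nontargeting(nt_ids)
    totals = counts.sum(axis=0)
    metas = [
        SampleMeta(
            s.sample_id, s.genotype, s.pseudo_replicate, s.time_point, s.batch,
            offset=float(np.log(totals[s.sample_id])),
        )
        for s in samples
    ]
    return CountMatrix(counts, metas, normalized=False)


def simulate_screen(
    config: SimConfig, effects: EffectSpec | None = None
) -> dict[str, object]:
    """Convenience wrapper: library + annotations + counts in one call."""
    effects = effects or EffectSpec()
    library = generate_library(config)
    ann = generate_annotations(library, effects, seed=config.seed + 1)
    counts = simulate_counts(library, ann, effects, config)
    return {"library": library, "annotations": ann, "counts": counts, "effects": effects}
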