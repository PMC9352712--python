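"""Negative-binomial GLMs linking sgRNA counts to chromatin features.

The central model regresses raw sgRNA counts on a locus feature, TP53
status and their interaction, with gene essentiality (D2) as a correcting
covariate and a fixed per-sample exposure offset (log total non-targeting
counts):

    counts ~ feature * TP53_status + D2 + offset

Reference levels are feature absent and genotype TP53-null, so the
interaction coefficient measures the extra (natural-log) depletion of
feature-carrying loci specific to TP53 wild-type cells — the p53-dependent
component of cut toxicity. Dispersion (NB2, var = mu + alpha*mu^2) is
estimated by maximum likelihood jointly with the coefficients; a Poisson
fallback is reported when the NB optimiser fails.

Variants: TP53wt-only (feature per se), pairwise conditioning on a second
feature, status-only / D2-only baselines, and cell-line-panel models with
TP53 x HR-status or feature x HR-status interactions plus tissue controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from dsbtox.annot import FeatureTable
from dsbtox.screenio import CountMatrix


@dataclass
class Term:
    estimate: float
    se: float
    z: float
    p: float


@dataclass
class FitResult:
    """One fitted count regression."""

    model_id: str
    formula: str
    terms: dict[str, Term]
    theta: float  # NB size; inf for the Poisson fallback
    n_obs: int
    converged: bool
    poisson_fallback: bool = False
    rank_deficient: bool = False
    fdr: dict[str, float] = field(default_factory=dict)

    def term(self, name: str) -> Term:
        return self.terms[name]

    @property
    def alpha(self) -> float:
        return 0.0 if np.isinf(self.theta) else 1.0 / self.theta


def _fit_count_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    names: Sequence[str],
    model_id: str,
    formula: str,
    family: str = "nb",
) -> FitResult:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        return FitResult(
            model_id=model_id,
            formula=formula,
            terms={},
            theta=float("nan"),
            n_obs=len(y),
            converged=False,
            rank_deficient=True,
        )
    if family not in ("nb", "poisson"):
        raise ValueError("family must be 'nb' or 'poisson'")
    if family == "poisson":
        fb = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        terms = {}
        for i, name in enumerate(names):
            est, se = float(fb.params[i]), float(fb.bse[i])
            z = est / se if se > 0 else float("nan")
            terms[name] = Term(est, se, float(z), float(2.0 * norm.sf(abs(z))))
        return FitResult(
            model_id=model_id, formula=formula, terms=terms, theta=float("inf"),
            n_obs=len(y), converged=True,
        )
    converged = True
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # Poisson warm start + method-of-moments dispersion initialisation
        fb = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        mu = fb.fittedvalues
        alpha0 = float(((y - mu) ** 2 - mu).sum() / (mu**2).sum())
        alpha0 = min(max(alpha0, 1e-4), 10.0)
        try:
            res = sm.NegativeBinomial(y, X, offset=offset).fit(
                start_params=np.append(fb.params, alpha0),
                disp=0, maxiter=200,
            )
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            converged = False
            res = None
        if res is None or not converged or not np.isfinite(res.bse[:-1]).all():
            fallback = True
            params, bse = fb.params, fb.bse
            theta = float("inf")
        else:
            params, bse = res.params[:-1], res.bse[:-1]
            theta = 1.0 / float(res.params[-1]) if res.params[-1] > 0 else float("inf")
    terms = {}
    for i, name in enumerate(names):
        est, se = float(params[i]), float(bse[i])
        z = est / se if se > 0 else float("nan")
        p = 2.0 * norm.sf(abs(z)) if np.isfinite(z) else float("nan")
        terms[name] = Term(est, se, float(z), float(p))
    return FitResult(
        model_id=model_id,
        formula=formula,
        terms=terms,
        theta=theta,
        n_obs=len(y),
        converged=converged or fallback,
        poisson_fallback=fallback,
    )


def _long_format(
    counts: CountMatrix,
    features: FeatureTable | pd.DataFrame,
    time_points: Sequence[str] | None,
    pseudo_replicates: Sequence[str] | None,
    genotypes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Stack counts into (sgRNA x sample) rows joined with per-guide covariates."""
    if counts.normalized:
        raise ValueError("count regressions use raw counts; the offset absorbs depth")
    data = features.data if isinstance(features, FeatureTable) else features
    keep = [
        s
        for s in counts.samples
        if (time_points is None or s.time_point in time_points)
        and (pseudo_replicates is None or s.pseudo_replicate in pseudo_replicates)
        and (genotypes is None or s.genotype in genotypes)
    ]
    if not keep:
        raise ValueError("no samples left after time/replicate selection")
    if any(not np.isfinite(s.offset) for s in keep):
        raise ValueError("sample offsets are unset; call with_offsets_from_nontargeting")
    ids = data.index.intersection(counts.counts.index)
    sub = counts.counts.loc[ids, [s.sample_id for s in keep]]
    n, m = len(ids), len(keep)
    y = sub.to_numpy().ravel()
    off = np.tile(np.array([s.offset for s in keep]), n)
    wt = np.tile(np.array([1.0 if s.genotype == "wt" else 0.0 for s in keep]), n)
    rows = data.loc[ids].iloc[np.repeat(np.arange(n), m)].reset_index()
    return rows, y, np.column_stack([off, wt])


def _feature_column(rows: pd.DataFrame, feature: str) -> np.ndarray:
    col = rows[feature]
    if col.dtype == object:
        levels = sorted(col.dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"feature {feature!r} must be binary, has levels {levels}")
        return (col == levels[1]).astype(float).to_numpy()
    x = col.astype(float).to_numpy()
    uniq = np.unique(x[~np.isnan(x)])
    if len(uniq) < 2:
        raise ValueError(f"feature {feature!r} has a single level; cannot fit")
    if set(uniq) == {0.0, 2.0}:  # masked chromatin bins: presence indicator
        return (x > 0).astype(float)
    return x


def fit_feature_interaction(
    counts: CountMatrix,
    features: FeatureTable,
    feature: str,
    time_points: Sequence[str] | None = None,
    pseudo_replicates: Sequence[str] | None = None,
    model_id: str | None = None,
    family: str = "nb",
) -> FitResult:
    """Fit counts ~ feature * TP53 + D2 + offset; report the interaction.

    The feature's drop mask (bin-1 guides etc.) is applied before fitting.
    ``time_points`` / ``pseudo_replicates`` restrict the samples, e.g. to
    the later time points of one pseudo-replicate as in per-replicate
    analyses.
    """
    ft = FeatureTable(
        data=features.rows_for(feature) if isinstance(features, FeatureTable) else features
    )
    rows, y, extra = _long_format(counts, ft, time_points, pseudo_replicates)
    off, wt = extra[:, 0], extra[:, 1]
    if len(np.unique(wt)) < 2:
        raise ValueError("both genotypes are required for an interaction fit")
    x = _feature_column(rows, feature)
    d2 = rows["d2"].astype(float).to_numpy()
    X = np.column_stack([np.ones_like(x), x, wt, x * wt, d2])
    names = ["intercept", feature, "tp53wt", f"{feature}:tp53wt", "d2"]
    return _fit_count_glm(
        y, X, off, names,
        model_id or f"interaction:{feature}",
        f"counts ~ {feature} * tp53wt + d2 + offset",
        family=family,
    )


def fit_wt_only(
    counts: CountMatrix,
    features: FeatureTable,
    feature: str,
    time_points: Sequence[str] | None = None,
    pseudo_replicates: Sequence[str] | None = None,
) -> FitResult:
    """Fit TP53wt counts ~ feature + D2 + offset (feature effect per se)."""
    ft = FeatureTable(data=features.rows_for(feature) if isinstance(features, FeatureTable) else features)
    rows, y, extra = _long_format(counts, ft, time_points, pseudo_replicates, genotypes=["wt"])
    off = extra[:, 0]
    x = _feature_column(rows, feature)
    d2 = rows["d2"].astype(float).to_numpy()
    X = np.column_stack([np.ones_like(x), x, d2])
    return _fit_count_glm(
        y, X, off, ["intercept", feature, "d2"],
        f"wt_only:{feature}", f"wt counts ~ {feature} + d2 + offset",
    )


def fit_pairwise_conditioned(
    counts: CountMatrix,
    features: FeatureTable,
    feature: str,
    cofeature: str,
    interaction_mode: bool = True,
    time_points: Sequence[str] | None = None,
    pseudo_replicates: Sequence[str] | None = None,
) -> FitResult:
    """Primary interaction fit conditioned on a second feature.

    With ``interaction_mode`` the cofeature also interacts with TP53 status;
    otherwise only its main effect enters.
    """
    data = features.rows_for(feature)
    mask = features.drop_masks.get(cofeature)
    if mask is not None:
        data = data.loc[~mask.reindex(data.index, fill_value=False)]
    rows, y, extra = _long_format(counts, FeatureTable(data=data), time_points, pseudo_replicates)
    off, wt = extra[:, 0], extra[:, 1]
    x = _feature_column(rows, feature)
    cx = _feature_column(rows, cofeature)
    d2 = rows["d2"].astype(float).to_numpy()
    cols = [np.ones_like(x), x, wt, x * wt, d2, cx]
    names = ["intercept", feature, "tp53wt", f"{feature}:tp53wt", "d2", cofeature]
    if interaction_mode:
        cols.append(cx * wt)
        names.append(f"{cofeature}:tp53wt")
    return _fit_count_glm(
        y, np.column_stack(cols), off, names,
        f"pairwise:{feature}|{cofeature}",
        f"counts ~ {feature} * tp53wt + {cofeature}"
        + (" * tp53wt" if interaction_mode else "") + " + d2 + offset",
    )


def fit_status_only(
    counts: CountMatrix,
    features: FeatureTable,
    time_points: Sequence[str] | None = None,
    pseudo_replicates: Sequence[str] | None = None,
) -> FitResult:
    """Fit counts ~ TP53 status + D2 + offset (global wt toxicity)."""
    rows, y, extra = _long_format(counts, features, time_points, pseudo_replicates)
    off, wt = extra[:, 0], extra[:, 1]
    d2 = rows["d2"].astype(float).to_numpy()
    X = np.column_stack([np.ones_like(wt), wt, d2])
    return _fit_count_glm(
        y, X, off, ["intercept", "tp53wt", "d2"],
        "status_only", "counts ~ tp53wt + d2 + offset",
    )


def fit_d2_only(
    counts: CountMatrix,
    features: FeatureTable,
    time_points: Sequence[str] | None = None,
    pseudo_replicates: Sequence[str] | None = None,
) -> FitResult:
    """Fit counts ~ D2 + offset (essentiality alone)."""
    rows, y, extra = _long_format(counts, features, time_points, pseudo_replicates)
    off = extra[:, 0]
    d2 = rows["d2"].astype(float).to_numpy()
    X = np.column_stack([np.ones_like(d2), d2])
    return _fit_count_glm(y, X, off, ["intercept", "d2"], "d2_only", "counts ~ d2 + offset")


def _tissue_dummies(tissue: pd.Series, reference: str) -> tuple[np.ndarray, list[str]]:
    levels = [t for t in pd.unique(tissue) if t != reference]
    if reference not in set(tissue):
        raise ValueError(f"reference tissue {reference!r} absent from the panel")
    cols = [(tissue == t).astype(float).to_numpy() for t in levels]
    return (np.column_stack(cols) if cols else np.empty((len(tissue), 0))), [
        f"tissue[{t}]" for t in levels
    ]


def fit_tp53_hr(
    panel: pd.DataFrame,
    model_id: str = "tp53_x_hr",
) -> FitResult:
    """Fit counts ~ TP53 * HR + D2 + tissue + offset on a cell-line panel.

    ``panel`` is a long-format table with columns count, tp53wt (0/1),
    hrwt (0/1), d2, tissue, offset — one row per (sgRNA, cell line). Tissue
    enters as treatment-coded dummies with breast as the reference level
    when present. The interaction term tests whether p53-dependent DSB
    toxicity is attenuated in HR-proficient lines.
    """
    y = panel["count"].to_numpy()
    tp, hr = panel["tp53wt"].astype(float).to_numpy(), panel["hrwt"].astype(float).to_numpy()
    d2 = panel["d2"].astype(float).to_numpy()
    off = panel["offset"].astype(float).to_numpy()
    tissue = panel["tissue"].astype(str)
    ref = "breast" if "breast" in set(tissue) else sorted(set(tissue))[0]
    if tissue.nunique() > 1:
        T, tnames = _tissue_dummies(tissue, ref)
    else:
        warnings.warn("single-tissue panel: tissue term dropped")
        T, tnames = np.empty((len(y), 0)), []
    X = np.column_stack([np.ones_like(tp), tp, hr, tp * hr, d2, T])
    names = ["intercept", "tp53wt", "hrwt", "tp53wt:hrwt", "d2", *tnames]
    return _fit_count_glm(
        y, X, off, names, model_id, "counts ~ tp53wt * hrwt + d2 + tissue + offset"
    )


def fit_feature_hr(panel: pd.DataFrame, feature: str) -> FitResult:
    """Fit counts ~ feature * HR + D2 + tissue + offset on a panel."""
    y = panel["count"].to_numpy()
    x = panel[feature].astype(float).to_numpy()
    hr = panel["hrwt"].astype(float).to_numpy()
    d2 = panel["d2"].astype(float).to_numpy()
    off = panel["offset"].astype(float).to_numpy()
    tissue = panel["tissue"].astype(str)
    ref = "breast" if "breast" in set(tissue) else sorted(set(tissue))[0]
    if tissue.nunique() > 1:
        T, tnames = _tissue_dummies(tissue, ref)
    else:
        warnings.warn("single-tissue panel: tissue term dropped")
        T, tnames = np.empty((len(y), 0)), []
    X = np.column_stack([np.ones_like(x), x, hr, x * hr, d2, T])
    names = ["intercept", feature, "hrwt", f"{feature}:hrwt", "d2", *tnames]
    return _fit_count_glm(
        y, X, off, names, f"feature_x_hr:{feature}",
        f"counts ~ {feature} * hrwt + d2 + tissue + offset",
    )


def adjust_fdr(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg or Storey q-values.

    The q-value route estimates the null proportion pi0 on a lambda grid
    with a cubic-spline-free linear extrapolation and falls back to BH
    (pi0 = 1) when the estimate is unstable or fewer than 100 tests are
    supplied.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "qvalue":
        bh = multipletests(p, method="fdr_bh")[1]
        if len(p) < 100:
            return bh
        lams = np.arange(0.05, 0.95, 0.05)
        pi0s = np.array([(p > l).mean() / (1.0 - l) for l in lams])
        # smooth tail estimate: average over the upper half of the grid
        pi0 = float(np.clip(pi0s[lams >= 0.5].mean(), 0.0, 1.0))
        if not np.isfinite(pi0) or pi0 <= 0:
            return bh
        return np.minimum(bh * pi0, 1.0)
    raise ValueError(f"unknown FDR method {method!r}")


def fits_table(fits: Sequence[FitResult], fdr_terms: Mapping[str, str] | None = None) -> pd.DataFrame:
    """One row per model x term, with optional FDR over selected terms."""
    rows = []
    for f in fits:
        for name, t in f.terms.items():
            rows.append(
                {
                    "model_id": f.model_id,
                    "formula": f.formula,
                    "term": name,
                    "estimate": t.estimate,
                    "se": t.se,
                    "z": t.z,
                    "p": t.p,
                    "theta": f.theta,
                    "n_obs": f.n_obs,
                    "converged": f.converged,
                    "poisson_fallback": f.poisson_fallback,
                }
            )
    df = pd.DataFrame(rows)
    if fdr_terms:
        sel = df["term"].isin(set(fdr_terms)).to_numpy()
        df["fdr"] = np.nan
        if sel.any():
            df.loc[sel, "fdr"] = adjust_fdr(df.loc[sel, "p"].to_numpy())
    return df
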