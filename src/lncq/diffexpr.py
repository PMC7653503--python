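"""Per-feature linear models with empirical-Bayes variance moderation.

For each feature a linear model is fitted to the log2 expression values
(``-delta_ct``) with a two-group indicator and optional covariates; the
indicator coefficient is the log2 fold change directly.  Residual variances
across features are then shrunk toward a common prior value: the prior
``(d0, s0^2)`` is estimated by matching the first two moments of the log
residual variances to a scaled-F model (digamma/trigamma inversion), the
posterior variance is

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

and the moderated t-statistic ``coef / (s_tilde * sqrt(v_unscaled))`` is
referred to a t distribution with ``d0 + d`` degrees of freedom (capped at
the pooled residual degrees of freedom across features).  Nominal p-values
are corrected by the Benjamini-Hochberg step-up procedure within each
comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("lncq")


# ---------------------------------------------------------------------------
# comparison specification
# ---------------------------------------------------------------------------

Selector = "str | dict[str, object]"


@dataclass
class ComparisonSpec:
    """Two-group contrast definition.

    ``group_a`` / ``group_b`` select samples: a plain string matches the
    metadata ``group`` column; a dict maps metadata columns to a value or a
    list of allowed values (so stratified contrasts such as allergic vs
    non-allergic asthma are expressible).  The reported log2FC is
    group_a minus group_b.
    """

    name: str
    group_a: object
    group_b: object
    covariates: list[str] = field(default_factory=list)
    significance: str = "adjusted_p"  # nominal_p | adjusted_p
    alpha: float = 0.05
    positive_label: str = "a"  # which side is the "disease"/positive class

    def __post_init__(self) -> None:
        if self.significance not in ("nominal_p", "adjusted_p"):
            raise ValueError(f"unknown significance type {self.significance!r}")

    def select(self, metadata: pd.DataFrame, which: str) -> pd.Index:
        sel = self.group_a if which == "a" else self.group_b
        if isinstance(sel, str):
            sel = {"group": sel}
        mask = pd.Series(True, index=metadata.index)
        for col, allowed in sel.items():
            if not isinstance(allowed, (list, tuple, set)):
                allowed = [allowed]
            mask &= metadata[col].isin(list(allowed))
        return metadata.index[mask]

    def masks(self, metadata: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
        a, b = self.select(metadata, "a"), self.select(metadata, "b")
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"comparison {self.name!r}: empty group selection")
        overlap = a.intersection(b)
        if len(overlap):
            raise ValueError(
                f"comparison {self.name!r}: selectors overlap on {list(overlap)}"
            )
        return a, b


@dataclass
class ModerationPrior:
    d0: float  # prior degrees of freedom, possibly math.inf
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if self.s0_sq <= 0 and self.d0 > 0:
            raise ValueError("s0_sq must be > 0")


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


# ---------------------------------------------------------------------------
# per-feature linear models
# ---------------------------------------------------------------------------


def _design_matrix(
    metadata: pd.DataFrame, samples: pd.Index, group_a: pd.Index, covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(samples)), np.asarray([s in set(group_a) for s in samples], float)]
    names = ["intercept", "group"]
    for cov in covariates:
        vals = metadata.loc[samples, cov]
        if vals.dtype == object or str(vals.dtype) == "category" or vals.dtype == bool:
            levels = sorted(map(str, vals.astype(str).unique()))
            for lev in levels[1:]:  # drop first level
                cols.append((vals.astype(str) == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
        else:
            cols.append(vals.to_numpy(float))
            names.append(cov)
    X = np.column_stack(cols)
    return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # identify columns that add no rank
    bad, rank, kept = [], 0, []
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept.append(j)
            rank = r
        else:
            bad.append(names[j])
    raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")


def fit_feature_models(
    log2_expr: pd.DataFrame,
    metadata: pd.DataFrame,
    comparison: ComparisonSpec,
    missing_max: float = 0.5,
) -> pd.DataFrame:
    """OLS per feature on log2 expression within the comparison's samples.

    Returns a DataFrame indexed by feature with columns ``coef`` (log2FC,
    group_a minus group_b), ``s2`` (residual variance), ``df`` (residual
    degrees of freedom) and ``v_unscaled`` (the unscaled variance of the
    group coefficient, i.e. the corresponding diagonal entry of (X'X)^-1).
    Features missing in more than ``missing_max`` of either group's samples
    are dropped from the comparison.
    """
    a, b = comparison.masks(metadata)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"comparison {comparison.name!r}: need >= 2 samples per group, "
            f"got {len(a)} vs {len(b)}"
        )
    samples = a.append(b)
    samples = pd.Index([s for s in log2_expr.columns if s in set(samples)])
    a = pd.Index([s for s in samples if s in set(a)])
    b = pd.Index([s for s in samples if s in set(b)])
    X, names = _design_matrix(metadata, samples, a, comparison.covariates)
    _check_full_rank(X, names)
    coef_idx = names.index("group")

    Y = log2_expr[samples]
    keep = []
    for f in Y.index:
        miss_a = Y.loc[f, a].isna().mean()
        miss_b = Y.loc[f, b].isna().mean()
        if miss_a <= missing_max and miss_b <= missing_max:
            keep.append(f)
        else:
            logger.info(
                "feature %s dropped from %s (missingness %.2f / %.2f)",
                f, comparison.name, miss_a, miss_b,
            )
    Y = Y.loc[keep]

    out = {}
    complete = ~Y.isna().any(axis=1)
    if complete.any():
        # shared design: one pseudo-inverse for all complete features
        Yc = Y.loc[complete].to_numpy(float)
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = Yc @ (XtX_inv @ X.T).T
        resid = Yc - beta @ X.T
        df = X.shape[0] - X.shape[1]
        s2 = (resid**2).sum(axis=1) / df
        v = XtX_inv[coef_idx, coef_idx]
        for i, f in enumerate(Y.index[complete]):
            out[f] = (beta[i, coef_idx], s2[i], df, v)
    for f in Y.index[~complete]:
        mask = Y.loc[f].notna().to_numpy()
        Xf, yf = X[mask], Y.loc[f].to_numpy(float)[mask]
        if np.linalg.matrix_rank(Xf) < Xf.shape[1] or mask.sum() <= Xf.shape[1]:
            logger.info("feature %s unestimable after missingness in %s", f, comparison.name)
            continue
        XtX_inv = np.linalg.inv(Xf.T @ Xf)
        bhat = XtX_inv @ Xf.T @ yf
        df = mask.sum() - Xf.shape[1]
        s2 = float(((yf - Xf @ bhat) ** 2).sum()) / df
        out[f] = (bhat[coef_idx], s2, df, XtX_inv[coef_idx, coef_idx])
    fit = pd.DataFrame.from_dict(
        out, orient="index", columns=["coef", "s2", "df", "v_unscaled"]
    )
    fit.index.name = "feature"
    return fit.loc[[f for f in Y.index if f in fit.index]]


# ---------------------------------------------------------------------------
# empirical Bayes moderation
# ---------------------------------------------------------------------------


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma_inverse requires x > 0")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def estimate_moderation_prior(
    residual_variances, residual_dfs
) -> ModerationPrior:
    """Moment-matching estimate of the variance prior across features.

    Under the scaled-F model ``s^2 ~ s0^2 F(d, d0)``, ``e = log s^2
    - digamma(d/2) + log(d/2)`` has mean ``log s0^2 - digamma(d0/2)
    + log(d0/2)`` and excess variance ``trigamma(d0/2)`` beyond the sampling
    component ``trigamma(d/2)``; the prior is recovered by inverting the
    trigamma function.  When the observed spread does not exceed the sampling
    component, ``d0`` is reported infinite (complete shrinkage to s0^2).
    """
    s2 = np.asarray(residual_variances, float)
    df = np.asarray(residual_dfs, float)
    ok = (s2 > 0) & (df > 0)
    if not ok.any():
        logger.warning("all residual variances are zero; returning d0 = 0")
        return ModerationPrior(d0=0.0, s0_sq=float(np.max(s2, initial=0.0)) or 1.0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        raise ValueError("need >= 2 features with positive residual df")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(fit: pd.DataFrame, prior: ModerationPrior) -> pd.DataFrame:
    """Moderated t-statistics, total df and two-sided p-values.

    The posterior variance interpolates the feature's residual variance and
    the prior: ``s2_post = (d0 s0^2 + d s^2)/(d0 + d)`` (``s0^2`` exactly when
    d0 is infinite).  Total df is ``d0 + d`` capped at the pooled residual df
    across features, and p comes from the t distribution on that df.
    """
    d0, s0 = prior.d0, prior.s0_sq
    df = fit["df"].to_numpy(float)
    s2 = fit["s2"].to_numpy(float)
    if np.any(d0 + df == 0):
        raise ValueError("d0 + d = 0: no information to form a posterior variance")
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0)
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
    t = fit["coef"].to_numpy(float) / np.sqrt(s2_post * fit["v_unscaled"].to_numpy(float))
    df_pooled = float(df.sum())
    df_total = np.minimum(d0 + df, df_pooled)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = fit.copy()
    out["s2_post"] = s2_post
    out["t"] = t
    out["df_total"] = df_total
    out["p"] = p
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment within one comparison."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def b_statistic(
    moderated: pd.DataFrame, prior: ModerationPrior, proportion: float = 0.01
) -> np.ndarray:
    """Log-odds of differential expression (B-statistic).

    The coefficient prior variance ``v0`` is estimated from the top
    ``proportion`` tail of the moderated t-statistics by the method of
    moments (each top statistic's squared excess over its matched null
    quantile, averaged); B is then the log posterior odds under the
    two-component normal mixture.  Secondary to the p-values and reported for
    completeness.
    """
    t = np.abs(moderated["t"].to_numpy(float))
    v1 = moderated["v_unscaled"].to_numpy(float)
    df_total = moderated["df_total"].to_numpy(float)
    ngenes = len(t)
    ntarget = math.ceil(proportion / 2.0 * ngenes)
    if ntarget < 1:
        return np.full(ngenes, np.nan)
    p_eff = max(ntarget / ngenes, proportion)
    max_df = float(np.max(df_total))
    order = np.argsort(-t)[:ntarget]
    t_top, v1_top = t[order], v1[order]
    r = np.arange(1, ntarget + 1)
    p0 = 2.0 * stats.t.sf(t_top, max_df)
    ptarget = ((r - 0.5) / ngenes - (1.0 - p_eff) * p0) / p_eff
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2.0, max_df)
        v0[pos] = v1_top[pos] * ((t_top[pos] / qtarget) ** 2 - 1.0)
    var_prior = float(np.mean(np.clip(v0, 0.0, None)))
    rr = (v1 + var_prior) / v1
    t2 = moderated["t"].to_numpy(float) ** 2
    with np.errstate(over="ignore"):
        kernel = np.where(
            np.isinf(df_total) | (df_total > 1e6),
            t2 * (1.0 - 1.0 / rr) / 2.0,
            (1.0 + df_total) / 2.0 * np.log((t2 + df_total) / (t2 / rr + df_total)),
        )
    return math.log(proportion / (1.0 - proportion)) - np.log(rr) / 2.0 + kernel


def run_comparison(
    log2_expr: pd.DataFrame,
    metadata: pd.DataFrame,
    comparison: ComparisonSpec,
    missing_max: float = 0.5,
    with_b: bool = False,
) -> pd.DataFrame:
    """Fit, moderate and adjust one comparison; returns the DE table."""
    fit = fit_feature_models(log2_expr, metadata, comparison, missing_max)
    prior = estimate_moderation_prior(fit["s2"], fit["df"])
    mod = moderated_t(fit, prior)
    mod["p_adj"] = bh_adjust(mod["p"])
    chosen = mod["p"] if comparison.significance == "nominal_p" else mod["p_adj"]
    mod["significant"] = chosen < comparison.alpha
    mod["comparison"] = comparison.name
    mod = mod.rename(columns={"coef": "log2fc"})
    if with_b:
        mod["B"] = b_statistic(mod, prior)
    cols = ["comparison", "log2fc", "t", "df_total", "p", "p_adj", "significant"]
    if with_b:
        cols.append("B")
    return mod[cols]


# ---------------------------------------------------------------------------
# screens and PCA
# ---------------------------------------------------------------------------


def screen_sex_dimorphic(
    log2_expr: pd.DataFrame, metadata: pd.DataFrame, alpha: float = 0.05
) -> list[str]:
    """Features with inherently sex-different expression (BH-significant sex
    coefficient, pooling groups with group as covariate); such features are
    excluded from candidate biomarker selection."""
    sexes = metadata["sex"].unique()
    counts = metadata["sex"].value_counts()
    if len(sexes) < 2 or (counts < 2).any():
        raise ValueError("sex screen needs >= 2 samples of each sex")
    comp = ComparisonSpec(
        name="sex_screen",
        group_a={"sex": "male"},
        group_b={"sex": "female"},
        covariates=["group"],
        significance="adjusted_p",
        alpha=alpha,
    )
    table = run_comparison(log2_expr, metadata, comp)
    return table.index[table["significant"]].tolist()


def covariate_correlation(
    log2_expr: pd.DataFrame, metadata: pd.DataFrame, covariate: str
) -> pd.DataFrame:
    """Per-feature Spearman correlation with a numeric sample covariate
    (e.g. blood eosinophil or neutrophil percentage), BH-adjusted."""
    vals = pd.to_numeric(metadata.loc[log2_expr.columns, covariate], errors="coerce")
    ok = vals.notna()
    if ok.sum() < 5:
        raise ValueError(f"covariate {covariate!r} non-missing for < 5 samples")
    if vals[ok].nunique() == 1:
        raise ValueError(f"covariate {covariate!r} is constant")
    rows = {}
    for f in log2_expr.index:
        x = log2_expr.loc[f, ok[ok].index]
        mask = x.notna()
        if mask.sum() < 5:
            continue
        rho, p = stats.spearmanr(x[mask], vals[ok][mask])
        rows[f] = (rho, p)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["rho", "p"])
    out["p_adj"] = bh_adjust(out["p"].clip(lower=np.nextafter(0, 1)))
    out.index.name = "feature"
    return out


def pca(log2_expr: pd.DataFrame, scale: bool = False) -> PCAResult:
    """Principal component analysis of samples in feature space.

    Samples are observations; features are variables, column-centered (and
    optionally unit-scaled) before SVD.
    """
    if log2_expr.shape[0] < 2 or log2_expr.shape[1] < 2:
        raise ValueError("PCA needs >= 2 features and >= 2 samples")
    X = log2_expr.T.to_numpy(float)  # samples x features
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values; filter or impute first")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    ev = S**2 / (n - 1)
    comps = [f"PC{i + 1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(U * S, index=log2_expr.columns, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=log2_expr.index, columns=comps),
        explained_variance=ev,
        explained_variance_ratio=ev / ev.sum() if ev.sum() > 0 else ev,
    )
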