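"""Negative-binomial Wald differential expression between compartments.

A deliberately compact DE core for two-group designs: median-of-ratios size
factors, method-of-moments dispersions moderated toward a 1/mean trend, a
per-gene NB GLM (log link, Var = mu + alpha*mu^2) fit by vectorized IRLS,
a Wald test on the compartment coefficient, empirical-Bayes normal-prior
shrinkage of log2 fold changes, and Benjamini-Hochberg correction. The
positive direction is "higher in roots".

The GLM fits run vectorized across genes (all genes share the same
two-column design), so thousands of genes per strain fit in milliseconds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CountMatrix

logger = logging.getLogger(__name__)

ALPHA_MIN = 1e-8
RESULT_COLUMNS = [
    "baseMean",
    "log2FC_mle",
    "SE",
    "log2FC_shrunk",
    "pvalue",
    "padj",
    "tested",
]


class StrainIneligibleError(ValueError):
    """Too few genes detected in all samples to normalize this strain."""


def size_factors(counts: pd.DataFrame, min_ref_genes: int = 10) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are those with nonzero counts in every sample; fewer
    than ``min_ref_genes`` of them makes the strain ineligible for DE.
    """
    arr = counts.to_numpy(dtype=float)
    if arr.shape[1] == 1:
        return pd.Series(1.0, index=counts.columns, name="size_factor")
    ref = (arr > 0).all(axis=1)
    if ref.sum() < min_ref_genes:
        raise StrainIneligibleError(
            f"only {int(ref.sum())} genes detected in all samples "
            f"(need >= {min_ref_genes}) — cannot normalize"
        )
    logs = np.log(arr[ref])
    log_geo = logs.mean(axis=1, keepdims=True)
    log_sf = np.median(logs - log_geo, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean exactly 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame,
    sf: pd.Series,
    alpha_min: float = ALPHA_MIN,
    condition: pd.Series | np.ndarray | None = None,
    prior_df: float = 16.0,
    outlier_mult: float = 8.0,
) -> pd.DataFrame:
    """Moments dispersion per gene, moderated toward an a0 + a1/mean trend.

    raw alpha = max(alpha_min, (var - mean) / mean^2) on normalized counts;
    when ``condition`` is given the variance is pooled within groups, so a
    real expression difference between compartments does not masquerade as
    overdispersion. The trend is least-squares in 1/mean over genes with
    informative raw values. The final estimate is a log-scale weighted mean
    of raw and trend with the data's residual df weighed against
    ``prior_df``: the trend is fitted across all genes, so it carries far
    more information than the handful of residual df behind any one gene's
    raw value. Genes whose within-group variance does not even exceed their
    mean carry no moments information and fall back to the trend; genes
    more than ``outlier_mult``-fold above the trend keep their raw value
    (dispersion outliers should not be shrunk into false positives).
    All-zero genes get NaN.
    """
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    m = norm.mean(axis=1)
    n_total = norm.shape[1]
    if condition is None:
        v = norm.var(axis=1, ddof=1)
        resid_df = n_total - 1
    else:
        x = np.asarray(condition)
        groups = [norm[:, x == g] for g in np.unique(x)]
        sse = sum(((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for g in groups)
        resid_df = max(n_total - len(groups), 1)
        v = sse / resid_df
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - m) / m**2
    raw = np.where(m > 0, np.maximum(raw, alpha_min), np.nan)
    informative = np.isfinite(raw) & (raw > alpha_min)
    if informative.sum() >= 2:
        X = np.column_stack([np.ones(informative.sum()), 1.0 / m[informative]])
        coef, *_ = np.linalg.lstsq(X, raw[informative], rcond=None)
        a0, a1 = coef
    elif informative.any():
        a0, a1 = float(np.nanmean(raw[informative])), 0.0
    else:
        a0, a1 = alpha_min, 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(m > 0, m, np.inf)
    trend = np.maximum(trend, alpha_min)
    w = resid_df / (resid_df + prior_df)
    raw_eff = np.where(informative, raw, trend)  # floor values carry no evidence
    final = np.exp(w * np.log(raw_eff) + (1.0 - w) * np.log(trend))
    final = np.where(informative & (raw > outlier_mult * trend), raw, final)
    final = np.where(np.isfinite(raw), np.maximum(final, alpha_min), np.nan)
    return pd.DataFrame(
        {"raw": raw, "trend": trend, "final": final}, index=counts.index
    )


def _condition_indicator(condition: pd.Series | np.ndarray, columns) -> np.ndarray:
    cond = pd.Series(np.asarray(condition), index=columns)
    levels = sorted(cond.unique())
    if set(levels) <= {0, 1}:
        return cond.to_numpy(dtype=float)
    if "matrix" in levels and "root" in levels and len(levels) == 2:
        return (cond == "root").to_numpy(dtype=float)
    if len(levels) != 2:
        raise ValueError(f"need exactly two condition levels, got {levels}")
    return (cond == levels[1]).to_numpy(dtype=float)


def nb_wald_test(
    counts: pd.DataFrame,
    sf: pd.Series,
    disp: pd.DataFrame,
    condition: pd.Series | np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Wald test of the compartment effect in a per-gene NB GLM.

    log mu_ij = log s_j + b0 + b1 x_j, alpha fixed per gene; log2FC = b1/ln2,
    SE from the Fisher information, p = 2 * (1 - Phi(|b1| / SE)).
    """
    y = counts.to_numpy(dtype=float)
    s = sf.loc[counts.columns].to_numpy(dtype=float)
    x = _condition_indicator(condition, counts.columns)
    if len(np.unique(x)) < 2:
        raise ValueError("both conditions must be present")
    alpha = disp.loc[counts.index, "final"].to_numpy(dtype=float)
    n_genes, _ = y.shape
    offset = np.log(s)[None, :]

    norm = y / s[None, :]
    base_mean = norm.mean(axis=1)
    testable = base_mean > 0
    alpha_safe = np.where(np.isfinite(alpha), alpha, ALPHA_MIN)

    m0 = norm[:, x == 0].mean(axis=1)
    m1 = norm[:, x == 1].mean(axis=1)
    b0 = np.log(np.maximum(m0, 1e-8))
    b1 = np.log(np.maximum(m1, 1e-8)) - b0

    active = testable.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        eta = offset + b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta, -700, 700))
        W = mu / (1.0 + alpha_safe[:, None] * mu)
        z = (eta - offset) + (y - mu) / np.maximum(mu, 1e-300)
        Sw = W.sum(axis=1)
        Swx = (W * x).sum(axis=1)
        Swz = (W * z).sum(axis=1)
        Swxz = (W * x * z).sum(axis=1)
        det = Sw * Swx - Swx**2  # x binary: sum(W x^2) == sum(W x)
        det = np.where(np.abs(det) > 1e-300, det, np.nan)
        nb0 = (Swx * Swz - Swx * Swxz) / det
        nb1 = (Sw * Swxz - Swx * Swz) / det
        nb0 = np.clip(nb0, -30, 30)
        nb1 = np.clip(nb1, -30, 30)
        delta = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        upd = active & np.isfinite(delta)
        b0 = np.where(upd, nb0, b0)
        b1 = np.where(upd, nb1, b1)
        active = upd & (delta >= tol)
    converged = testable & ~active
    if active.any():
        warnings.warn(
            f"{int(active.sum())} genes did not converge; marked untested",
            stacklevel=2,
        )

    eta = offset + b0[:, None] + b1[:, None] * x[None, :]
    mu = np.exp(np.clip(eta, -700, 700))
    W = mu / (1.0 + alpha_safe[:, None] * mu)
    Sw = W.sum(axis=1)
    Swx = (W * x).sum(axis=1)
    det = Sw * Swx - Swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = Sw / det
    se_b1 = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    zstat = b1 / se_b1
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))

    ln2 = np.log(2.0)
    out = pd.DataFrame(index=counts.index)
    out["baseMean"] = base_mean
    out["log2FC_mle"] = np.where(converged, b1 / ln2, np.nan)
    out["SE"] = np.where(converged, se_b1 / ln2, np.nan)
    out["pvalue"] = np.where(converged, pvals, np.nan)
    out["tested"] = converged & np.isfinite(out["SE"]) & np.isfinite(out["pvalue"])
    out.loc[~out["tested"], ["log2FC_mle", "SE", "pvalue"]] = np.nan
    return out


def shrink_lfc(de: pd.DataFrame) -> pd.DataFrame:
    """Normal-prior empirical-Bayes shrinkage of log2 fold changes.

    Prior SD tau is the upper quartile of |log2FC_mle| over well-estimated
    genes (SE below the median SE); shrunk = mle * tau^2 / (tau^2 + SE^2),
    so noisy estimates move toward zero and precise ones barely change.
    """
    de = de.copy()
    tested = de["tested"].fillna(False).astype(bool)
    se = de.loc[tested, "SE"]
    if tested.sum() == 0 or not np.isfinite(se).any():
        de["log2FC_shrunk"] = np.where(tested, 0.0, np.nan)
        return de
    med_se = float(np.nanmedian(se))
    precise = de.index[tested & (de["SE"] < med_se)]
    if len(precise) == 0:
        precise = de.index[tested]
    tau = float(np.nanpercentile(np.abs(de.loc[precise, "log2FC_mle"]), 75))
    if tau <= 0 or not np.isfinite(tau):
        de["log2FC_shrunk"] = np.where(tested, 0.0, np.nan)
        return de
    factor = tau**2 / (tau**2 + de["SE"] ** 2)
    de["log2FC_shrunk"] = np.where(tested, de["log2FC_mle"] * factor, np.nan)
    return de


def bh_adjust(pvals: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through."""
    p = pd.Series(np.asarray(pvals, dtype=float))
    if isinstance(pvals, pd.Series):
        p.index = pvals.index
    finite = p.notna()
    vals = p[finite].to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = pd.Series(np.nan, index=p.index)
    if finite.any():
        out[finite] = multipletests(vals, method="fdr_bh")[1]
    return out


def de_pipeline(
    counts: pd.DataFrame,
    condition: pd.Series | np.ndarray,
    min_ref_genes: int = 10,
    alpha_min: float = ALPHA_MIN,
) -> pd.DataFrame:
    """size factors -> dispersions -> Wald -> shrinkage -> BH, one matrix."""
    sf = size_factors(counts, min_ref_genes=min_ref_genes)
    x = _condition_indicator(condition, counts.columns)
    disp = estimate_dispersions(counts, sf, alpha_min=alpha_min, condition=x)
    de = nb_wald_test(counts, sf, disp, condition)
    de = shrink_lfc(de)
    de["padj"] = bh_adjust(de["pvalue"])
    return de[RESULT_COLUMNS]


class NegativeBinomialDE:
    """scikit-learn-style estimator for the two-compartment NB Wald test.

    Parameters
    ----------
    min_ref_genes : minimum genes detected in all samples for normalization.
    alpha_min : dispersion floor.
    alpha : adjusted-p threshold defining a differentially expressed gene.

    Fit on ``X`` (samples x genes DataFrame) and ``y`` (condition label per
    sample; "root" is the positive direction). Fitted attributes:
    ``size_factors_``, ``dispersions_``, ``results_``.
    """

    def __init__(self, min_ref_genes: int = 10, alpha_min: float = ALPHA_MIN, alpha: float = 0.05):
        self.min_ref_genes = min_ref_genes
        self.alpha_min = alpha_min
        self.alpha = alpha

    def get_params(self, deep: bool = True) -> dict:
        return {
            "min_ref_genes": self.min_ref_genes,
            "alpha_min": self.alpha_min,
            "alpha": self.alpha,
        }

    def set_params(self, **params) -> "NegativeBinomialDE":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame, y) -> "NegativeBinomialDE":
        counts = X.T if isinstance(X, pd.DataFrame) else pd.DataFrame(X).T
        self.size_factors_ = size_factors(counts, min_ref_genes=self.min_ref_genes)
        x = _condition_indicator(y, counts.columns)
        self.dispersions_ = estimate_dispersions(counts, self.size_factors_, self.alpha_min, condition=x)
        de = nb_wald_test(counts, self.size_factors_, self.dispersions_, y)
        de = shrink_lfc(de)
        de["padj"] = bh_adjust(de["pvalue"])
        self.results_ = de[RESULT_COLUMNS]
        return self

    def predict(self, X=None) -> pd.Series:
        """Boolean DE call per gene (padj < alpha)."""
        return self.results_["padj"] < self.alpha


@dataclass
class PerStrainDE:
    strain: str
    status: str  # "ok" or the ineligibility reason
    result: pd.DataFrame | None = None
    housekeeping_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def tested(self) -> bool:
        return self.status == "ok"


def run_per_strain_de(
    per_strain: CountMatrix,
    strains: list[str] | None = None,
    housekeeping: dict[str, list[str]] | None = None,
    min_ref_genes: int = 10,
    alpha: float = 0.05,
) -> dict[str, PerStrainDE]:
    """Independent DE per strain; ineligible strains reported with reason.

    ``housekeeping`` maps strain -> user-designated stable gene ids; any of
    them called DE (padj < alpha) is flagged in the QC output, since
    housekeeping genes are expected to show no differential regulation.
    """
    comp = per_strain.samples.loc[per_strain.counts.columns, "compartment"]
    for needed in ("matrix", "root"):
        if needed not in set(comp):
            raise ValueError(f"compartment {needed!r} entirely missing")
    feats = per_strain.features
    if strains is None:
        strains = sorted(feats.loc[feats["kingdom"] != "host", "strain_id"].unique())
    out: dict[str, PerStrainDE] = {}
    for s in strains:
        sub = per_strain.counts.loc[feats["strain_id"] == s]
        if sub.empty:
            out[s] = PerStrainDE(strain=s, status="no genes in per-strain matrix")
            continue
        try:
            res = de_pipeline(sub, comp, min_ref_genes=min_ref_genes)
        except StrainIneligibleError as err:
            out[s] = PerStrainDE(strain=s, status=str(err))
            continue
        flags = {}
        for hk in (housekeeping or {}).get(s, []):
            if hk in res.index:
                padj = res.loc[hk, "padj"]
                flags[hk] = bool(np.isfinite(padj) and padj < alpha)
                if flags[hk]:
                    logger.warning("housekeeping gene %s of %s called DE", hk, s)
        out[s] = PerStrainDE(strain=s, status="ok", result=res, housekeeping_flags=flags)
    return out
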