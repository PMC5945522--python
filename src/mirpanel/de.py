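"""Negative-binomial Wald differential expression for miRNA count matrices.

One cancer subtype is compared against controls per call.  The model for
miRNA i in sample j is

    K_ij ~ NB(mu_ij, alpha_i),      Var = mu + alpha * mu^2
    log mu_ij = log s_j + x_j' beta_i

with s_j the median-of-ratios size factor, x_j the design row (intercept,
subtype indicator, optional surrogate-variable columns) and alpha_i a
per-miRNA dispersion estimated by a moment estimator shrunk towards a
mean-dispersion trend.  The subtype coefficient is tested with a Wald
statistic (normal approximation) and p-values are Benjamini-Hochberg
adjusted within the comparison.  Fold changes are reported in log2 units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CohortMetadata, CountMatrix

LN2 = np.log(2.0)

MIN_DISPERSION = 1e-8
MAX_DISPERSION = 10.0


class NormalizationError(ValueError):
    pass


class DesignError(ValueError):
    pass


@dataclass
class SizeFactors:
    """Per-sample positive depth multipliers with geometric mean 1."""

    values: pd.Series

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise NormalizationError("size factors must be positive and finite")
        log_gm = np.mean(np.log(v))
        if abs(log_gm) > 1e-9:
            self.values = self.values / np.exp(log_gm)

    def reindex(self, sample_ids) -> np.ndarray:
        return self.values.reindex(sample_ids).to_numpy(dtype=float)


def size_factors(m: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    For each miRNA with strictly positive counts in every sample, compute a
    per-miRNA geometric mean; each sample's factor is the median over those
    miRNAs of count/geometric-mean, rescaled to geometric mean one.
    """
    k = m.counts.astype(float)
    all_pos = (k > 0).all(axis=1)
    if not all_pos.any():
        raise NormalizationError(
            "no miRNA has positive counts in every sample; add a pseudo-reference "
            "(e.g. filter samples or use counts+1) before computing size factors"
        )
    logs = np.log(k[all_pos])
    log_gm = logs.mean(axis=1, keepdims=True)
    ratios = logs - log_gm
    log_sf = np.median(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()
    return SizeFactors(pd.Series(np.exp(log_sf), index=m.sample_ids))


def estimate_dispersion(
    m: CountMatrix,
    groups,
    sf: SizeFactors,
    trend_weight: float = 0.5,
) -> pd.Series:
    """Per-miRNA dispersion: within-group moment estimate shrunk to a trend.

    The moment estimate is alpha~ = max(0, (Var - mean) / mean^2) on size-
    factor-normalized counts, pooled across design groups weighted by their
    degrees of freedom.  A trend alpha(mu) = a0 + a1/mu is fitted by least
    squares over miRNAs and the final estimate is the weighted average
    ``(1 - trend_weight) * alpha~ + trend_weight * trend(mu)``.
    """
    s = sf.reindex(m.sample_ids)
    q = m.counts / s[None, :]
    groups = np.asarray(list(groups))
    if groups.shape[0] != q.shape[1]:
        raise DesignError("groups length must match the number of samples")

    labels = pd.unique(groups)
    resid_df = q.shape[1] - len(labels)
    if resid_df < 3:
        raise DesignError("need >= 3 residual degrees of freedom for dispersion")

    num = np.zeros(q.shape[0])
    den = 0.0
    mu_overall = q.mean(axis=1)
    for g in labels:
        sel = groups == g
        ng = int(sel.sum())
        if ng < 2:
            raise DesignError(f"design group {g!r} has fewer than 2 samples")
        qg = q[:, sel]
        mu_g = qg.mean(axis=1)
        var_g = qg.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_g = (var_g - mu_g) / np.square(mu_g)
        a_g = np.where(np.isfinite(a_g), a_g, 0.0)
        num += (ng - 1) * np.maximum(a_g, 0.0)
        den += ng - 1
    alpha_mom = num / den

    ok = mu_overall > 0
    if ok.sum() < 10:
        warnings.warn("fewer than 10 informative miRNAs; dispersion trend "
                      "replaced by the global mean", stacklevel=2)
        trend = np.full_like(alpha_mom, max(float(alpha_mom[ok].mean()) if ok.any() else 0.0, 0.0))
    else:
        # least squares of alpha~ on [1, 1/mu]
        x = np.column_stack([np.ones(ok.sum()), 1.0 / mu_overall[ok]])
        coef, *_ = np.linalg.lstsq(x, alpha_mom[ok], rcond=None)
        a0, a1 = coef
        with np.errstate(divide="ignore"):
            trend = a0 + a1 / np.maximum(mu_overall, 1e-8)
        trend = np.maximum(trend, 0.0)

    alpha = (1.0 - trend_weight) * alpha_mom + trend_weight * trend
    alpha = np.clip(alpha, MIN_DISPERSION, MAX_DISPERSION)
    return pd.Series(alpha, index=m.mirna_ids, name="dispersion")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    NaN entries (untested features) are ignored and returned as NaN; they do
    not count toward the number of tests.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m_tests = pv.size
    if m_tests == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m_tests / np.arange(1, m_tests + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m_tests)
    res[order] = adj
    out[mask] = res
    return out


def _irls_nb(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for NB GLMs with log link and fixed dispersion.

    ``y`` is miRNA x sample, ``x`` the shared n x p design, ``offset`` the
    per-sample log size factor, ``alpha`` the per-miRNA dispersion.  Returns
    (beta [m x p], se [m x p], converged [m]) on the natural-log scale.
    """
    m, n = y.shape
    p = x.shape[1]
    # log-linear initialisation on shifted counts
    z0 = np.log((y + 0.5) / np.exp(offset)[None, :])
    beta, *_ = np.linalg.lstsq(x, z0.T, rcond=None)
    beta = beta.T  # m x p

    converged = np.zeros(m, dtype=bool)
    xt = x.T
    a = alpha[:, None]
    info = np.empty((m, p, p))
    for _ in range(max_iter):
        eta = beta @ xt + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + a * mu)  # Fisher weights for log link
        z = (eta - offset[None, :]) + (y - mu) / mu
        info = np.einsum("np,mn,nq->mpq", x, w, x)
        rhs = np.einsum("np,mn->mp", x, w * z)
        try:
            new_beta = np.linalg.solve(info, rhs[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            ridge = info + 1e-8 * np.eye(p)[None, :, :]
            new_beta = np.linalg.solve(ridge, rhs[:, :, None])[:, :, 0]
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = new_beta
        newly = delta < tol
        converged |= newly
        if converged.all():
            break

    ok = np.all(np.isfinite(beta), axis=1)
    converged &= ok
    with np.errstate(invalid="ignore"):
        cov = np.linalg.pinv(info)
        se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return beta, se, converged


def nb_wald_test(
    m: CountMatrix,
    meta: CohortMetadata,
    subtype: str,
    sv=None,
    sf: SizeFactors | None = None,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """NB Wald test of one subtype versus controls.

    Returns a DataFrame indexed by miRNA id with columns
    ``mean_read_count, log2FC, dispersion, wald_stat, p, fdr, converged``.
    Fold changes are subtype-over-control in log2 units.  miRNAs whose fit
    fails (all-zero counts, IRLS divergence) carry NaN statistics and are
    excluded from the BH family.
    """
    meta = meta.aligned_to(m)
    classes = meta.classes.to_numpy()
    keep = (classes == subtype) | (classes == "control")
    if not (classes == subtype).any() or not (classes == "control").any():
        raise DesignError(f"need both {subtype!r} and control samples")
    sample_ids = [s for s, k in zip(m.sample_ids, keep) if k]
    sub = m.subset_samples(sample_ids)
    sub_meta = meta.subset(sample_ids)
    group = (sub_meta.classes.to_numpy() == subtype).astype(float)

    if sf is None:
        sf = size_factors(sub)
    s = sf.reindex(sub.sample_ids)
    if dispersion is None:
        dispersion = estimate_dispersion(sub, sub_meta.classes, sf)
    alpha = dispersion.reindex(sub.mirna_ids).to_numpy()

    design = [np.ones(len(sample_ids)), group]
    if sv is not None and getattr(sv, "n_sv", 0) > 0:
        design.extend(sv.scores.reindex(sub.sample_ids).to_numpy().T)
    x = np.column_stack(design)

    y = sub.counts.astype(float)
    testable = y.sum(axis=1) > 0
    beta = np.full((y.shape[0], x.shape[1]), np.nan)
    se = np.full_like(beta, np.nan)
    conv = np.zeros(y.shape[0], dtype=bool)
    if testable.any():
        b, e, c = _irls_nb(y[testable], x, np.log(s), alpha[testable])
        beta[testable] = b
        se[testable] = e
        conv[testable] = c

    with np.errstate(invalid="ignore", divide="ignore"):
        wald = beta[:, 1] / se[:, 1]
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    pvals = np.where(conv & np.isfinite(wald), pvals, np.nan)
    n_failed = int((~conv).sum())
    if n_failed:
        warnings.warn(f"{n_failed} miRNA fit(s) failed or diverged; excluded "
                      "from the FDR family", stacklevel=2)

    res = pd.DataFrame(
        {
            "mean_read_count": sub.counts.mean(axis=1),
            "log2FC": beta[:, 1] / LN2,
            "dispersion": alpha,
            "wald_stat": np.where(conv, wald, np.nan),
            "p": pvals,
            "fdr": bh_adjust(pvals),
            "converged": conv,
        },
        index=pd.Index(sub.mirna_ids, name="mirna_id"),
    )
    return res


def write_de(res: pd.DataFrame, path) -> None:
    res.to_csv(path, sep="\t")
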