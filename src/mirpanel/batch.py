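"""Surrogate-variable estimation for unwanted (e.g. batch) variation.

The number of latent components is decided on the *residuals* of the known
class design, by parallel analysis: counts are transformed to
log2(1 + depth-normalized), each miRNA is regressed on the class
indicators, rows are scaled by their delta-method precision (so that
high-count miRNAs, whose log-scale noise is small, carry proportionally
more weight), columns are standardized, and each residual singular value's
variance share is compared with its null distribution under independent
within-row permutations; components whose observed share exceeds the
permutation 95th percentile are kept.

The surrogate *scores* themselves are then taken from the full (design-
uncentered) matrix: the top right-singular vectors of the row-weighted,
row-centered log-expression matrix.  Scores estimated from residuals are
orthogonal to the class design by construction and therefore cannot absorb
the component of a batch effect that is confounded with the class — the
class coefficient would silently keep that bias.  Scores from the full
matrix retain the confounded component, so adding them to the model
removes it.  The trade-off, shared with surrogate-variable analysis in
general, is that a dense latent factor is assumed to dominate the sparse
true-signal directions; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CohortMetadata, CountMatrix
from .de import DesignError, SizeFactors, size_factors

LN2 = np.log(2.0)


@dataclass
class SurrogateVariables:
    """Per-sample surrogate-variable scores, one column per component.

    Columns have zero mean across samples and are mutually orthogonal.
    """

    scores: pd.DataFrame  # samples x n_sv
    singular_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_sv(self) -> int:
        return self.scores.shape[1]

    @classmethod
    def empty(cls, sample_ids) -> "SurrogateVariables":
        return cls(pd.DataFrame(index=pd.Index(sample_ids), columns=[], dtype=float))


def _class_design(meta: CohortMetadata) -> np.ndarray:
    classes = meta.classes
    levels = pd.unique(classes)
    cols = [np.ones(len(classes))]
    cols += [(classes == lvl).to_numpy(float) for lvl in levels[1:]]
    return np.column_stack(cols)


def _row_weights(q: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """1/SD of log2 normalized counts by the delta method.

    Per-row variance ~ (1/mu + alpha0) / ln2^2 with alpha0 the median
    within-class moment dispersion — a single robust overdispersion level
    is enough for weighting purposes.
    """
    mu = np.maximum(q.mean(axis=1), 1e-3)
    alphas = []
    for g in pd.unique(classes):
        sel = classes == g
        if sel.sum() < 2:
            continue
        m_g = q[:, sel].mean(axis=1)
        v_g = q[:, sel].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v_g - m_g) / np.square(m_g)
        alphas.append(np.where(np.isfinite(a), a, 0.0))
    alpha0 = float(np.median(np.maximum(np.concatenate(alphas), 0.0))) if alphas else 0.0
    sd = np.sqrt(1.0 / mu + alpha0) / LN2
    return 1.0 / sd


def estimate_sv(
    m: CountMatrix,
    meta: CohortMetadata,
    max_sv: int = 5,
    n_perm: int = 100,
    seed: int = 0,
    quantile: float = 0.95,
    sf: SizeFactors | None = None,
) -> SurrogateVariables:
    """Estimate surrogate variables from a count matrix.

    Requires every class to have at least 2 samples and more samples than
    design columns + 1.  ``max_sv = 0`` short-circuits to an empty result.
    """
    meta = meta.aligned_to(m)
    counts_per_class = pd.Series(meta.classes).value_counts()
    if (counts_per_class < 2).any():
        raise DesignError("every class needs at least 2 samples for SV estimation")
    x = _class_design(meta)
    if m.shape[1] <= x.shape[1] + 1:
        raise DesignError("too few samples relative to the design")
    if max_sv == 0:
        return SurrogateVariables.empty(m.sample_ids)

    if sf is None:
        sf = size_factors(m)
    s = sf.reindex(m.sample_ids)
    q = m.counts / s[None, :]
    logq = np.log2(1.0 + q)
    w = _row_weights(q, meta.classes.to_numpy())

    # residuals of each miRNA on the known design, precision-weighted
    hat, *_ = np.linalg.lstsq(x, logq.T, rcond=None)
    resid = (logq - (x @ hat).T) * w[:, None]
    # equalize per-sample residual scale: depth differences leave samples
    # with unequal noise, which would mimic a leading component under the
    # row-permutation null; re-center rows so the spectrum stays clean
    col_sd = resid.std(axis=0, ddof=1)
    col_sd[col_sd == 0] = 1.0
    resid = resid / col_sd[None, :]
    resid = resid - resid.mean(axis=1, keepdims=True)

    sv_obs = np.linalg.svd(resid, compute_uv=False)
    share_obs = sv_obs**2 / np.sum(sv_obs**2)

    rng = np.random.default_rng(seed)
    k_max = min(max_sv, len(sv_obs))
    exceed = np.zeros((n_perm, k_max))
    for b in range(n_perm):
        idx = np.argsort(rng.random(resid.shape), axis=1)
        perm = np.take_along_axis(resid, idx, axis=1)
        sv_b = np.linalg.svd(perm, compute_uv=False)
        exceed[b] = (sv_b**2 / np.sum(sv_b**2))[:k_max]
    thresh = np.quantile(exceed, quantile, axis=0)

    n_sv = 0
    for k in range(k_max):
        if share_obs[k] > thresh[k]:
            n_sv += 1
        else:
            break
    if n_sv == 0:
        return SurrogateVariables.empty(m.sample_ids)

    # scores from the full matrix (row-centered only), so the class-
    # confounded component of the latent factor is retained
    full = (logq - logq.mean(axis=1, keepdims=True)) * w[:, None]
    _, svals, vt = np.linalg.svd(full, full_matrices=False)
    scores = vt[:n_sv].T
    scores = scores - scores.mean(axis=0, keepdims=True)
    scores, _ = np.linalg.qr(scores)
    return SurrogateVariables(
        pd.DataFrame(
            scores,
            index=pd.Index(m.sample_ids),
            columns=[f"SV{k + 1}" for k in range(n_sv)],
        ),
        svals[:n_sv],
    )
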