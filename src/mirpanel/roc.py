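"""ROC analysis: AUC, DeLong variance/CI, and paired model comparison.

The clinical question is whether adding a urinary miRNA panel to a baseline
risk model (age + smoking) improves case-control discrimination.  Two
nested logistic models are fitted on the same samples; their in-sample
predicted probabilities are compared as ROC scores with the nonparametric
DeLong approach: the AUC is the Mann-Whitney probability that a random case
outscores a random control (ties count 1/2), its variance comes from the
case and control placement values, and the paired AUC difference is tested
with a normal approximation that accounts for the correlation induced by
scoring the same subjects twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .counts import CohortMetadata
from .qpcr import DeltaCt, _covariate_design


@dataclass
class DeLongResult:
    auc0: float
    auc1: float
    var0: float
    var1: float
    cov01: float
    p: float
    flagged: bool = False  # zero-variance difference convention


@dataclass
class ModelComparison:
    auc0: float
    ci0: tuple[float, float]
    auc1: float
    ci1: tuple[float, float]
    delong_p: float
    n_cases: int
    n_controls: int
    model0: list[str]
    model1: list[str]
    n_excluded: int = 0

    def as_dict(self) -> dict:
        return {
            "auc0": self.auc0,
            "ci0": list(self.ci0),
            "auc1": self.auc1,
            "ci1": list(self.ci1),
            "delong_p": self.delong_p,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "model0": self.model0,
            "model1": self.model1,
            "n_excluded": self.n_excluded,
        }


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    cases = labels == 1
    if not cases.any() or cases.all():
        raise ValueError("labels must contain both classes")
    return cases, ~cases


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(case score > control score) + P(tie)/2."""
    scores = np.asarray(scores, dtype=float)
    cases, controls = _check_labels(labels)
    m, n = int(cases.sum()), int(controls.sum())
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[cases].sum() - m * (m + 1) / 2.0
    return float(u / (m * n))


def _placements(scores: np.ndarray, cases: np.ndarray, controls: np.ndarray):
    """DeLong placement values V10 (per case) and V01 (per control).

    Midrank formulation: V10_i is the fraction of controls a case outscores
    (ties half), and symmetrically for V01.
    """
    sx = scores[cases]
    sy = scores[controls]
    m, n = sx.size, sy.size
    all_ranks = stats.rankdata(np.concatenate([sx, sy]))
    rx = stats.rankdata(sx)
    ry = stats.rankdata(sy)
    v10 = (all_ranks[:m] - rx) / n
    v01 = 1.0 - (all_ranks[m:] - ry) / m
    return v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance) of a single ROC curve."""
    scores = np.asarray(scores, dtype=float)
    cases, controls = _check_labels(labels)
    v10, v01 = _placements(scores, cases, controls)
    a = float(v10.mean())
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    return a, float(var)


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUC with a normal-approximation CI on the AUC scale, truncated to [0,1]."""
    a, var = delong_variance(scores, labels)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return a, (max(0.0, a - half), min(1.0, a + half))


def delong_test(scores0, scores1, labels) -> DeLongResult:
    """Two-sided DeLong test for the difference of two paired AUCs."""
    scores0 = np.asarray(scores0, dtype=float)
    scores1 = np.asarray(scores1, dtype=float)
    if scores0.shape != scores1.shape:
        raise ValueError("paired score vectors must have equal length")
    cases, controls = _check_labels(labels)
    v10_0, v01_0 = _placements(scores0, cases, controls)
    v10_1, v01_1 = _placements(scores1, cases, controls)
    a0, a1 = float(v10_0.mean()), float(v10_1.mean())
    m, n = v10_0.size, v01_0.size

    s10 = np.cov(np.vstack([v10_0, v10_1]), ddof=1)
    s01 = np.cov(np.vstack([v01_0, v01_1]), ddof=1)
    s = s10 / m + s01 / n  # 2x2 covariance of (auc0, auc1)
    var_diff = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    if var_diff <= 0:
        return DeLongResult(a0, a1, s[0, 0], s[1, 1], s[0, 1], 1.0, flagged=True)
    z = (a1 - a0) / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z)))
    return DeLongResult(a0, a1, float(s[0, 0]), float(s[1, 1]), float(s[0, 1]), p)


def _fit_probs(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    model = LogisticRegression(C=np.inf, max_iter=2000)
    model.fit(x, y)
    return model.predict_proba(x)[:, 1]


def compare_models(
    d: DeltaCt | pd.DataFrame,
    meta: CohortMetadata,
    panel: list[str],
    subtype: str | None = None,
    max_missing: float = 0.20,
) -> ModelComparison:
    """Covariate-only vs covariate+panel logistic models, DeLong-compared.

    Model 0 uses age + smoking; Model 1 adds one −ΔCt (log2-abundance)
    covariate per panel miRNA.  ``subtype`` restricts cases to one class;
    by default all cancer classes count as cases.  Samples with a missing
    panel value are list-wise deleted; an assay missing in more than
    ``max_missing`` of samples is an error.
    """
    dv = d.values if isinstance(d, DeltaCt) else d
    missing_assays = [a for a in panel if a not in dv.columns]
    if missing_assays:
        raise KeyError(f"panel assay(s) not measured: {missing_assays}")
    classes = meta.data.loc[dv.index, "class"]
    if subtype is None:
        keep = pd.Series(True, index=dv.index)
        y = (classes != "control").to_numpy(int)
    else:
        keep = (classes == subtype) | (classes == "control")
        y = (classes[keep] == subtype).to_numpy(int)
    dv = dv[keep.to_numpy()]

    frac_missing = dv[panel].isna().mean(axis=0)
    bad = frac_missing[frac_missing > max_missing]
    if not bad.empty:
        raise ValueError(
            f"assay(s) missing in more than {max_missing:.0%} of samples: "
            f"{list(bad.index)}"
        )
    complete = dv[panel].notna().all(axis=1).to_numpy()
    n_excluded = int((~complete).sum())
    dv = dv[complete]
    y = y[complete]

    covars = _covariate_design(meta.data.loc[dv.index])
    expr = -dv[panel].to_numpy(float)
    probs0 = _fit_probs(covars, y)
    probs1 = _fit_probs(np.column_stack([covars, expr]), y)

    res = delong_test(probs0, probs1, y)
    _, ci0 = delong_ci(probs0, y)
    _, ci1 = delong_ci(probs1, y)
    return ModelComparison(
        auc0=res.auc0,
        ci0=ci0,
        auc1=res.auc1,
        ci1=ci1,
        delong_p=res.p,
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        model0=["age", "smoking"],
        model1=["age", "smoking"] + list(panel),
        n_excluded=n_excluded,
    )


def roc_curve_table(scores, labels) -> pd.DataFrame:
    """FPR/TPR coordinates of the empirical ROC curve (for plotting)."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
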