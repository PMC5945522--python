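"""qPCR validation statistics: ΔCt, ΔΔCt fold changes, adjusted tests.

Raw Ct values (one PCR cycle ≈ one halving of template) are normalized per
sample to the arithmetic mean Ct of the endogenous-control assays:

    ΔCt_ij = Ct_ij − mean(control-assay Ct in sample j)

Group contrasts use the standard 2^−ΔΔCt convention reported in log2 units:
ΔΔCt = mean ΔCt(cases) − mean ΔCt(controls) and log2 fold change = −ΔΔCt,
so a positive value means up-regulation in cases.  Case-control association
is assessed per assay by logistic regression of class on −ΔCt adjusting for
age and smoking (Wald p, BH-adjusted within the panel), with a Firth-style
penalized fallback under complete separation.  Ordered-subtype trends use a
linear model of −ΔCt on the ordinal class score with the same covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .counts import CLASS_LEVELS, SMOKING_LEVELS, CohortMetadata

CT_RANGE = (0.0, 45.0)

#: Ordinal score of the ordered disease spectrum.
CLASS_SCORE = {c: i for i, c in enumerate(CLASS_LEVELS)}


@dataclass
class CtMatrix:
    """Raw Ct values, sample x assay, with designated control assays.

    ``spike_in`` names an exogenous RT spike-in used only for QC (it never
    enters normalization); plates whose spike-in Ct SD exceeds
    ``spike_sd_max`` cycles are flagged.
    """

    data: pd.DataFrame  # samples x assays
    controls: list[str]
    spike_in: str | None = None
    spike_sd_max: float = 1.0
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if ((finite <= CT_RANGE[0]) | (finite >= CT_RANGE[1])).any():
            raise ValueError(f"Ct values must lie within {CT_RANGE}")
        if np.isnan(vals).any():
            self.qc_flags.append(f"{int(np.isnan(vals).sum())} missing Ct value(s)")
        missing_ctrl = [c for c in self.controls if c not in self.data.columns]
        if missing_ctrl:
            raise ValueError(f"control assay(s) not measured: {missing_ctrl}")
        if self.spike_in and self.spike_in in self.data.columns:
            sd = float(self.data[self.spike_in].std(ddof=1))
            if sd > self.spike_sd_max:
                self.qc_flags.append(
                    f"spike-in Ct SD {sd:.2f} exceeds {self.spike_sd_max} cycles"
                )

    @property
    def assay_ids(self) -> list[str]:
        drop = set(self.controls) | ({self.spike_in} if self.spike_in else set())
        return [a for a in self.data.columns if a not in drop]


def read_ct(path, controls: list[str], spike_in: str | None = None) -> CtMatrix:
    """Read a long-form Ct TSV (columns sample_id, assay_id, ct)."""
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot(index="sample_id", columns="assay_id", values="ct")
    return CtMatrix(wide, controls=controls, spike_in=spike_in)


@dataclass
class DeltaCt:
    values: pd.DataFrame  # samples x target assays
    excluded_samples: list[str]


def delta_ct(ct: CtMatrix) -> DeltaCt:
    """ΔCt per sample and target assay; samples missing a control are dropped."""
    ctrl = ct.data[ct.controls]
    ok = ctrl.notna().all(axis=1)
    excluded = list(ct.data.index[~ok])
    if excluded:
        warnings.warn(
            f"{len(excluded)} sample(s) lack a control Ct and were excluded",
            stacklevel=2,
        )
    ref = ctrl.loc[ok].mean(axis=1)
    targets = ct.data.loc[ok, ct.assay_ids]
    return DeltaCt(targets.sub(ref, axis=0), excluded)


def log2_fold_change(
    d: DeltaCt | pd.DataFrame, meta: CohortMetadata, subtype: str
) -> pd.Series:
    """log2 fold change (−ΔΔCt) of each assay, subtype versus controls."""
    dv = d.values if isinstance(d, DeltaCt) else d
    classes = meta.data.loc[dv.index, "class"]
    case = dv[(classes == subtype).to_numpy()]
    ctrl = dv[(classes == "control").to_numpy()]
    if case.empty or ctrl.empty:
        raise ValueError(f"need both {subtype!r} and control samples")
    ddct = case.mean(axis=0) - ctrl.mean(axis=0)
    out = -ddct
    out.name = "log2FC"
    return out


def _covariate_design(meta_rows: pd.DataFrame) -> np.ndarray:
    """Age plus two smoking indicator contrasts (former/current vs never)."""
    cols = [meta_rows["age"].to_numpy(float)]
    for lvl in SMOKING_LEVELS[1:]:
        cols.append((meta_rows["smoking"] == lvl).to_numpy(float))
    return np.column_stack(cols)


def _firth_logit(x: np.ndarray, y: np.ndarray, max_iter: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Firth-penalized logistic fit (Jeffreys prior); returns (beta, se)."""
    n, p = x.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = prob * (1.0 - prob)
        xs = x * np.sqrt(w)[:, None]
        info = xs.T @ xs
        cov = np.linalg.pinv(info)
        hat = np.einsum("ij,jk,ik->i", xs, cov, xs)
        grad = x.T @ (y - prob + hat * (0.5 - prob))
        step = cov @ grad
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = np.clip(x @ beta, -30, 30)
    prob = 1.0 / (1.0 + np.exp(-eta))
    info = x.T @ (x * (prob * (1 - prob))[:, None])
    se = np.sqrt(np.diag(np.linalg.pinv(info)))
    return beta, se


def association_test(
    d: DeltaCt | pd.DataFrame, meta: CohortMetadata, subtype: str
) -> pd.DataFrame:
    """Per-assay logistic regression of class on −ΔCt, age and smoking.

    Returns coef (log-odds per log2 expression unit), Wald p, BH-adjusted p
    across the assay panel, and a ``firth`` flag for separation fallbacks.
    """
    dv = d.values if isinstance(d, DeltaCt) else d
    classes = meta.data.loc[dv.index, "class"]
    keep = (classes == subtype) | (classes == "control")
    dv = dv[keep.to_numpy()]
    y = (classes[keep] == subtype).to_numpy(float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(f"need both {subtype!r} and control samples")
    covars = _covariate_design(meta.data.loc[dv.index])

    rows = []
    for assay in dv.columns:
        expr = -dv[assay].to_numpy(float)  # log2-abundance scale
        ok = np.isfinite(expr)
        if ok.sum() < covars.shape[1] + 2 or np.nanstd(expr) == 0:
            rows.append({"assay_id": assay, "coef": np.nan, "p": np.nan, "firth": False})
            continue
        x = np.column_stack([np.ones(ok.sum()), expr[ok], covars[ok]])
        firth = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y[ok], x).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", False) or np.any(
                np.abs(fit.params) > 30
            ):
                raise np.linalg.LinAlgError
            coef, se = fit.params[1], fit.bse[1]
        except Exception:
            beta, bse = _firth_logit(x, y[ok])
            coef, se = beta[1], bse[1]
            firth = True
        p = 2 * stats.norm.sf(abs(coef / se)) if se > 0 else np.nan
        rows.append({"assay_id": assay, "coef": coef, "p": p, "firth": firth})

    res = pd.DataFrame(rows).set_index("assay_id")
    from .de import bh_adjust

    res["fdr"] = bh_adjust(res["p"].to_numpy())
    return res


def trend_test(
    d: DeltaCt | pd.DataFrame,
    meta: CohortMetadata,
    cases_only: bool = False,
    adjust: bool = True,
) -> pd.DataFrame:
    """Ordered-subtype trend: linear model of −ΔCt on the ordinal class score.

    The score is control(0) < NMIBC_G1G2(1) < NMIBC_G3(2) < MIBC(3);
    ``cases_only`` drops controls and rescores the remaining groups 0,1,2…
    Age and smoking enter as covariates unless ``adjust`` is False.
    Returns per-assay slope and two-sided p.
    """
    dv = d.values if isinstance(d, DeltaCt) else d
    classes = meta.data.loc[dv.index, "class"]
    if cases_only:
        keep = (classes != "control").to_numpy()
        dv = dv[keep]
        classes = classes[keep]
        present = [c for c in CLASS_LEVELS[1:] if (classes == c).any()]
        score_map = {c: i for i, c in enumerate(present)}
    else:
        score_map = CLASS_SCORE
    if classes.nunique() < 2:
        raise ValueError("trend test needs at least 2 ordered groups")
    score = classes.map(score_map).to_numpy(float)
    covars = _covariate_design(meta.data.loc[dv.index]) if adjust else None

    rows = []
    for assay in dv.columns:
        expr = -dv[assay].to_numpy(float)
        ok = np.isfinite(expr)
        x = [np.ones(ok.sum()), score[ok]]
        if covars is not None:
            x.append(covars[ok])
        design = np.column_stack(x)
        fit = sm.OLS(expr[ok], design).fit()
        rows.append(
            {"assay_id": assay, "slope": fit.params[1], "trend_p": fit.pvalues[1]}
        )
    return pd.DataFrame(rows).set_index("assay_id")


def write_qpcr(res: pd.DataFrame, path) -> None:
    res.to_csv(path, sep="\t")
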