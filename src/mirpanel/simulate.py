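"""Synthetic urinary-miRNA cohorts: counts, metadata and qPCR Ct tables.

The generator produces data with the statistical structure the analysis
pipeline assumes, so every downstream stage can be exercised without access
to patient sequencing data:

* read counts are negative-binomial with a per-sample sequencing-depth
  multiplier, Var = mu + alpha * mu^2, and a mean-dependent dispersion trend
  alpha(mu) = a0 + a1/mu;
* a latent two-level batch factor shifts log2 expression with per-miRNA
  loadings (the rank-one structure a single surrogate variable can recover);
* differential expression is planted as (miRNA, class, log2 fold change)
  triples; "housekeeping" miRNAs are planted with zero class effect and
  near-zero dispersion;
* Ct values are linearly linked to latent log2 expression with Gaussian
  measurement noise (nominal slope -1: one PCR cycle per doubling).

Age and smoking are drawn independently of class by default, so they are
null covariates — covariate-adjusted tests can be checked for type-I error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts import CLASS_LEVELS, SMOKING_LEVELS, CohortMetadata, CountMatrix

#: Smoking prevalence in an elderly urological case-control cohort
#: (roughly one-half former, one-third current smokers).
SMOKING_PROBS = (0.12, 0.50, 0.38)

#: Age range (years) typical of bladder-cancer studies.
AGE_RANGE = (42.0, 75.0)

CT_INTERCEPT = 35.0


class InvalidConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Parameters
    ----------
    n_per_class
        Either a single count applied to every class or a mapping
        ``{class label: count}``; classes absent from the mapping get 0.
    n_mirna
        Total number of miRNAs (including planted ones).
    baseline_log2_mean_range
        Interval of baseline log2 mean counts, uniform per miRNA.  The
        default (2, 13) spans ~4 to ~8000 reads, the dynamic range of
        urinary miRNA counts after low-count filtering.
    dispersion_model
        Coefficients (a0, a1) of the dispersion trend alpha(mu) = a0 + a1/mu.
        Defaults emulate a modest biological CV (~22%) plus shot noise.
    depth_factor_range
        Per-sample depth multipliers, uniform.
    batch_effect_sd
        SD of the per-miRNA log2 batch loading; 0 disables the batch factor.
    batch_confound
        P(batch = 1 | case).  0.5 (default) gives a class-balanced batch;
        values away from 0.5 confound batch with disease status.
    planted_de
        Triples (mirna id, class label, log2 fold change) of planted
        subtype-specific effects; ids are created if not already implied by
        ``n_mirna`` naming.
    planted_stable
        miRNA ids with zero class effect and near-zero dispersion
        (candidate endogenous controls).
    ct_slope
        Ct units per log2 expression unit (nominal -1).
    ct_noise_sd
        SD of Gaussian Ct measurement noise (cycles).
    seed
        RNG seed; identical (config, seed) gives bit-identical tables.
    """

    n_per_class: int | Mapping[str, int] = 25
    n_mirna: int = 200
    baseline_log2_mean_range: tuple[float, float] = (2.0, 13.0)
    dispersion_model: tuple[float, float] = (0.05, 5.0)
    depth_factor_range: tuple[float, float] = (0.5, 1.5)
    batch_effect_sd: float = 0.0
    batch_confound: float = 0.5
    planted_de: Sequence[tuple[str, str, float]] = field(default_factory=list)
    planted_stable: Sequence[str] = field(default_factory=list)
    stable_dispersion: float = 1e-4
    ct_slope: float = -1.0
    ct_noise_sd: float = 0.5
    seed: int = 0

    def class_sizes(self) -> dict[str, int]:
        if isinstance(self.n_per_class, Mapping):
            sizes = {c: int(self.n_per_class.get(c, 0)) for c in CLASS_LEVELS}
        else:
            sizes = {c: int(self.n_per_class) for c in CLASS_LEVELS}
        return {c: n for c, n in sizes.items() if n > 0}

    def validate(self) -> None:
        sizes = self.class_sizes()
        if not sizes or any(n <= 0 for n in sizes.values()):
            raise InvalidConfigError("every simulated class needs n_per_class >= 1")
        if self.n_mirna <= 0:
            raise InvalidConfigError("n_mirna must be positive")
        lo, hi = self.baseline_log2_mean_range
        if not lo <= hi:
            raise InvalidConfigError("baseline_log2_mean_range must be ordered")
        if not 0.0 <= self.batch_confound <= 1.0:
            raise InvalidConfigError("batch_confound must lie in [0, 1]")
        for mid, cls, _ in self.planted_de:
            if cls not in CLASS_LEVELS:
                raise InvalidConfigError(f"planted_de class {cls!r} unknown")
            if mid in self.planted_stable:
                raise InvalidConfigError(
                    f"{mid!r} cannot be both planted DE and planted stable"
                )


def _mirna_ids(config: SimulationConfig) -> list[str]:
    named = [mid for mid, _, _ in config.planted_de]
    # preserve first-appearance order, then stable ids, then filler
    seen: dict[str, None] = {}
    for mid in named:
        seen.setdefault(mid)
    for mid in config.planted_stable:
        seen.setdefault(mid)
    ids = list(seen)
    if len(ids) > config.n_mirna:
        raise InvalidConfigError("n_mirna smaller than the number of planted miRNAs")
    width = max(4, len(str(config.n_mirna)))
    k = 0
    while len(ids) < config.n_mirna:
        mid = f"miR-sim-{k:0{width}d}"
        if mid not in seen:
            ids.append(mid)
        k += 1
    return ids


def _latent_log2(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[str], pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Build metadata and the latent log2-expression matrix (miRNA x sample).

    Returns (mirna ids, metadata frame, depth factors, latent log2 matrix).
    The latent matrix excludes depth: mu_ij = depth_j * 2**latent_ij.
    """
    config.validate()
    sizes = config.class_sizes()
    classes = [c for c, n in sizes.items() for _ in range(n)]
    n = len(classes)
    sample_ids = [f"S{j:03d}" for j in range(n)]

    age = rng.uniform(*AGE_RANGE, size=n).round(1)
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=SMOKING_PROBS)
    is_case = np.array([c != "control" for c in classes])
    p_batch = np.where(is_case, config.batch_confound, 1.0 - config.batch_confound)
    batch = (rng.random(n) < p_batch).astype(int)

    meta = pd.DataFrame(
        {
            "class": classes,
            "age": age,
            "smoking": smoking,
            "batch": [f"B{b}" for b in batch],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    ids = _mirna_ids(config)
    m = len(ids)
    baseline = rng.uniform(*config.baseline_log2_mean_range, size=m)
    stable_set = set(config.planted_stable)
    # anchor housekeeping candidates mid-range so they are well detected
    mid_b = float(np.mean(config.baseline_log2_mean_range))
    for i, mid in enumerate(ids):
        if mid in stable_set:
            baseline[i] = mid_b

    delta = np.zeros((m, n))
    index_of = {mid: i for i, mid in enumerate(ids)}
    class_arr = np.asarray(classes)
    for mid, cls, lfc in config.planted_de:
        delta[index_of[mid], class_arr == cls] += lfc

    gamma = rng.normal(0.0, config.batch_effect_sd, size=m)
    gamma[[index_of[mid] for mid in stable_set]] = 0.0
    batch_score = batch - 0.5
    latent = baseline[:, None] + delta + gamma[:, None] * batch_score[None, :]

    depth = rng.uniform(*config.depth_factor_range, size=n)
    latent_df = pd.DataFrame(latent, index=ids, columns=sample_ids)
    return ids, meta, depth, latent_df


def _dispersions(config: SimulationConfig, ids: list[str], mu_base: np.ndarray) -> np.ndarray:
    a0, a1 = config.dispersion_model
    alpha = np.maximum(a0 + a1 / np.maximum(mu_base, 1e-8), 0.0)
    stable_set = set(config.planted_stable)
    for i, mid in enumerate(ids):
        if mid in stable_set:
            alpha[i] = config.stable_dispersion
    return alpha


def generate_counts(config: SimulationConfig) -> tuple[CountMatrix, CohortMetadata]:
    """Simulate an NB count matrix and matching cohort metadata.

    Counts are K_ij ~ NB(mean = depth_j * 2**latent_ij, dispersion alpha_i),
    sampled with the mean/dispersion parameterization Var = mu + alpha*mu^2
    (alpha -> 0 degenerates to Poisson).
    """
    rng = np.random.default_rng(config.seed)
    ids, meta, depth, latent = _latent_log2(config, rng)
    mu = depth[None, :] * np.exp2(latent.to_numpy())
    alpha = _dispersions(config, ids, np.exp2(latent.to_numpy()).mean(axis=1))

    counts = np.empty(mu.shape, dtype=np.int64)
    for i in range(mu.shape[0]):
        if alpha[i] <= 1e-12:
            counts[i] = rng.poisson(mu[i])
        else:
            size = 1.0 / alpha[i]  # NB "number of successes"
            p = size / (size + mu[i])
            counts[i] = rng.negative_binomial(size, p)

    cm = CountMatrix(pd.DataFrame(counts, index=ids, columns=latent.columns))
    return cm, CohortMetadata(meta)


def generate_ct(
    config: SimulationConfig,
    counts: CountMatrix,
    metadata: CohortMetadata,
    assays: Sequence[str],
    controls: Sequence[str],
    spike_in: str = "UniSp6",
) -> pd.DataFrame:
    """Simulate a raw Ct table (sample x assay) for the given assay panel.

    Ct_ij = 35 + ct_slope * latent_log2_ij + eps, eps ~ N(0, ct_noise_sd^2).
    The latent log2 expression is regenerated from the same (config, seed)
    stream used for the counts, so qPCR and sequencing measure the same
    underlying signal.  Control assays and the spike-in are included for
    every sample; the spike-in is constant (Ct 20) plus measurement noise.
    """
    for a in list(assays) + list(controls):
        if a not in counts.data.index:
            raise KeyError(f"unknown assay id {a!r}: not in the count matrix")
    rng = np.random.default_rng(config.seed)
    ids, meta, _depth, latent = _latent_log2(config, rng)
    if list(latent.columns) != list(counts.sample_ids):
        raise ValueError("counts/metadata were not generated from this config")

    panel = list(dict.fromkeys(list(assays) + list(controls)))
    sub = latent.loc[panel]  # assay x sample latent log2 expression
    ct = CT_INTERCEPT + config.ct_slope * sub.to_numpy()
    ct_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    ct = ct + ct_rng.normal(0.0, config.ct_noise_sd, size=ct.shape)
    out = pd.DataFrame(ct.T, index=sub.columns, columns=panel)
    out[spike_in] = 20.0 + ct_rng.normal(0.0, 0.1, size=out.shape[0])
    out.index.name = "sample_id"
    return out


def nb_bayes_accuracy(mean0: float, lfc: float, alpha: float) -> float:
    """Exact Bayes classification accuracy between two NB count distributions.

    Classes are equiprobable with means ``mean0`` and ``mean0 * 2**lfc`` and
    common dispersion ``alpha`` (Var = mu + alpha*mu^2).  The optimal rule
    picks the class with the larger pmf; its accuracy is
    ``0.5 * sum_k max(pmf0(k), pmf1(k))``.
    """
    from scipy import stats as _stats

    mu0, mu1 = mean0, mean0 * 2.0**lfc
    size = 1.0 / alpha
    hi = int(max(mu0, mu1) + 12 * np.sqrt(max(mu0, mu1) * (1 + alpha * max(mu0, mu1)))) + 1
    k = np.arange(hi)
    p0 = _stats.nbinom.pmf(k, size, size / (size + mu0))
    p1 = _stats.nbinom.pmf(k, size, size / (size + mu1))
    return float(0.5 * np.sum(np.maximum(p0, p1)))


def lfc_for_bayes_accuracy(
    mean0: float, alpha: float, accuracy: float = 0.85
) -> float:
    """log2 fold change at which the NB two-class Bayes accuracy equals target."""
    from scipy.optimize import brentq

    return float(
        brentq(lambda d: nb_bayes_accuracy(mean0, d, alpha) - accuracy, 1e-3, 8.0)
    )


def write_ct(ct: pd.DataFrame, path) -> None:
    """Write a Ct table in long form: sample_id, assay_id, ct."""
    long = ct.rename_axis("sample_id").reset_index().melt(
        id_vars="sample_id", var_name="assay_id", value_name="ct"
    )
    long.to_csv(path, sep="\t", index=False)
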