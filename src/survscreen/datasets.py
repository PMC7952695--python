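"""Synthetic cohort generation.

Emulates the statistical structure the screening analysis assumes:

* a gene-by-sample matrix of expression z-scores (per-gene i.i.d. standard
  normal by default, so the z-scoring is self-consistent), with optional
  planted cutpoint effects — genes whose above-cutoff samples carry a true
  hazard ratio under proportional hazards;
* recurrence-free survival with an exponential baseline hazard, independent
  exponential censoring truncated at an administrative follow-up horizon;
* clinical covariates shaped like a high-risk (Gleason >= 8) prostatectomy
  cohort: age in years, Gleason score 8-10, ordinal T category, initial PSA;
* immunohistochemistry fields as multinomial draws over the four staining
  intensity categories, feeding H-score computation;
* therapy-specific PSA criteria mapping a longitudinal PSA series to a
  biochemical recurrence time or censoring.

All randomness flows through explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlantedEffect",
    "CovariateSpec",
    "SimulationConfig",
    "simulate_cohort",
    "simulate_survival_for_marker",
    "simulate_ihc_fields",
    "simulate_hscore_cohort",
    "recurrence_from_psa",
]

THERAPIES = ("RP", "RT", "HT")


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth cutpoint effect for one gene.

    Samples with expression above ``true_cutoff_z`` have their hazard
    multiplied by ``true_hr``.
    """

    gene_index: int
    true_cutoff_z: float
    true_hr: float

    def __post_init__(self):
        if self.true_hr <= 0:
            raise ValueError("true_hr must be > 0")
        if self.gene_index < 0:
            raise ValueError("gene_index must be non-negative")


@dataclass(frozen=True)
class CovariateSpec:
    """Distributions for the clinical covariates.

    Defaults emulate a TCGA-style high-risk prostatectomy sub-cohort:
    mean age ~62 (range 44-78), Gleason score mass at 9, predominantly
    pT3 disease, log-normal initial PSA around 10 ng/mL, all treated by
    radical prostatectomy.
    """

    age_mean: float = 62.4
    age_sd: float = 7.5
    age_range: tuple[float, float] = (44.0, 78.0)
    gs_probs: tuple[float, float, float] = (0.30, 0.665, 0.035)  # GS 8 / 9 / 10
    t_probs: tuple[float, float, float] = (0.135, 0.83, 0.035)  # T 2 / 3 / 4
    ipsa_log_mean: float = np.log(10.0)
    ipsa_log_sd: float = 0.8
    therapy_probs: tuple[float, float, float] = (1.0, 0.0, 0.0)  # RP / RT / HT

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        age = np.clip(rng.normal(self.age_mean, self.age_sd, n), *self.age_range)
        gs = rng.choice([8, 9, 10], size=n, p=self.gs_probs)
        t_cat = rng.choice([2, 3, 4], size=n, p=self.t_probs)
        ipsa = rng.lognormal(self.ipsa_log_mean, self.ipsa_log_sd, n)
        therapy = rng.choice(list(THERAPIES), size=n, p=self.therapy_probs)
        return pd.DataFrame(
            {"age": age, "gs": gs, "t_category": t_cat, "ipsa": ipsa, "therapy": therapy}
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Full cohort simulation recipe.

    Rates are per month; ``max_followup`` truncates the censoring time
    (administrative end of follow-up). ``covariate_log_hr`` optionally makes
    covariates prognostic (log hazard ratio per unit); ``confounder``
    = (gene_index, covariate, rho) correlates one gene with a covariate to
    exercise multivariate adjustment; ``correlated_block`` = (indices, rho)
    adds an equicorrelated gene block for robustness checks.
    """

    n_samples: int = 201
    n_genes: int = 200
    planted: tuple[PlantedEffect, ...] = ()
    baseline_hazard: float = 0.02
    censoring_rate: float = 0.015
    max_followup: float = 120.0
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    covariate_log_hr: dict | None = None
    confounder: tuple[int, str, float] | None = None
    correlated_block: tuple[tuple[int, ...], float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if min(self.baseline_hazard, self.censoring_rate) <= 0:
            raise ValueError("hazard and censoring rates must be > 0")
        if self.max_followup <= 0:
            raise ValueError("max_followup must be > 0")
        idx = [p.gene_index for p in self.planted]
        if len(set(idx)) != len(idx):
            raise ValueError("planted gene indices must be distinct")
        if any(i >= self.n_genes for i in idx):
            raise ValueError("planted gene index out of range")


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an expression matrix and a clinical table from ``config``.

    Returns
    -------
    expression : DataFrame, genes x samples
        Standard-normal z-scores, index of gene symbols, columns of sample
        IDs.
    clinical : DataFrame, indexed by sample ID
        Columns time (months), event (0/1), age, gs, t_category, ipsa,
        therapy.
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes
    genes = [f"G{i:05d}" for i in range(g)]
    samples = [f"S{i:04d}" for i in range(n)]

    expr = rng.standard_normal((g, n))
    if config.correlated_block is not None:
        idx, rho = config.correlated_block
        shared = rng.standard_normal(n)
        for i in idx:
            expr[i] = rho * shared + np.sqrt(1 - rho**2) * expr[i]

    covars = config.covariate_spec.sample(n, rng)
    covars.index = pd.Index(samples, name="sample_id")

    if config.confounder is not None:
        gi, cov_name, rho = config.confounder
        z = covars[cov_name].to_numpy(dtype=float)
        z = (z - z.mean()) / z.std()
        expr[gi] = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)

    log_hazard = np.full(n, np.log(config.baseline_hazard))
    for p in config.planted:
        log_hazard += np.log(p.true_hr) * (expr[p.gene_index] > p.true_cutoff_z)
    if config.covariate_log_hr:
        for name, coef in config.covariate_log_hr.items():
            v = covars[name].to_numpy(dtype=float)
            log_hazard += coef * (v - v.mean())

    event_time = rng.exponential(1.0, n) / np.exp(log_hazard)
    censor_time = np.minimum(rng.exponential(1.0 / config.censoring_rate, n),
                             config.max_followup)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)
    clinical = covars.copy()
    clinical.insert(0, "time", time)
    clinical.insert(1, "event", event)
    return expression, clinical


def simulate_survival_for_marker(marker, true_cutoff: float, true_hr: float,
                                 baseline_hazard: float = 0.02,
                                 censoring_rate: float = 0.015,
                                 max_followup: float = 120.0,
                                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Survival times for an arbitrary marker with one planted cutpoint effect."""
    if true_hr <= 0:
        raise ValueError("true_hr must be > 0")
    marker = np.asarray(marker, dtype=float)
    rng = np.random.default_rng(seed)
    hazard = baseline_hazard * np.where(marker > true_cutoff, true_hr, 1.0)
    event_time = rng.exponential(1.0, marker.size) / hazard
    censor_time = np.minimum(rng.exponential(1.0 / censoring_rate, marker.size),
                             max_followup)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return time, event


def simulate_ihc_fields(n_fields: int, n_cells: int, category_probs, seed: int = 0) -> np.ndarray:
    """Multinomial intensity-category counts per high-power field.

    Categories are {negative: 0, low: 1, positive: 2, high: 3}; each of the
    ``n_fields`` rows sums to ``n_cells`` exactly.
    """
    probs = np.asarray(category_probs, dtype=float)
    if probs.shape != (4,):
        raise ValueError("category_probs must have length 4")
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("category_probs must be non-negative and sum to 1")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_cells, probs, size=n_fields)


def simulate_hscore_cohort(n_samples: int = 107, true_cutoff: float = 70.0,
                           true_hr: float = 4.0, h_mean: float = 60.0,
                           h_sd: float = 45.0, baseline_hazard: float = 0.03,
                           censoring_rate: float = 0.015,
                           max_followup: float = 120.0,
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-patient H-scores in [0, 300] with a planted survival cutpoint.

    Emulates a biopsy-validation cohort: protein H-scores from a clipped
    normal, survival with hazard multiplied by ``true_hr`` above
    ``true_cutoff``. Returns ``(h_scores, time, event)``.
    """
    rng = np.random.default_rng(seed)
    h = np.clip(rng.normal(h_mean, h_sd, n_samples), 0.0, 300.0)
    time, event = simulate_survival_for_marker(
        h, true_cutoff, true_hr, baseline_hazard, censoring_rate, max_followup,
        seed=int(rng.integers(2**31 - 1)),
    )
    return h, time, event


def recurrence_from_psa(psa_series, therapy: str, nadir: float | None = None,
                        testosterone: float | None = None) -> tuple[float, int]:
    """Map a longitudinal PSA series to a biochemical recurrence time.

    Therapy-specific criteria (European urology practice):

    * RP — first PSA measurement > 0.2 ng/mL that is also rising;
    * RT — first PSA measurement > nadir + 2 ng/mL;
    * HT — first rising PSA measurement, provided serum testosterone is at
      castrate level (< 50 ng/dL).

    "Rising" means strictly greater than the immediately preceding
    measurement, so the first measurement can never qualify. A criterion met
    exactly at the last visit is an event at that time; otherwise the patient
    is censored at the last measurement. Returns ``(months, event)``.
    """
    series = [(float(t), float(v)) for t, v in psa_series]
    if not series:
        raise ValueError("empty PSA series")
    times = [t for t, _ in series]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("PSA series must be strictly time-ordered")
    if therapy not in THERAPIES:
        raise ValueError(f"therapy must be one of {THERAPIES}")
    if therapy == "RT" and nadir is None:
        raise ValueError("nadir is required for RT")
    if therapy == "HT" and testosterone is None:
        raise ValueError("testosterone is required for HT")

    for i, (t, v) in enumerate(series):
        rising = i > 0 and v > series[i - 1][1]
        if therapy == "RP" and v > 0.2 and rising:
            return t, 1
        if therapy == "RT" and v > nadir + 2.0:
            return t, 1
        if therapy == "HT" and rising and testosterone < 50.0:
            return t, 1
    return series[-1][0], 0
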