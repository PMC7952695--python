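"""Genome-wide cutpoint screening and per-gene survival reports.

The screen runs the optimal-cutpoint selector over every gene, keeps genes
whose selection-corrected p-value clears ``alpha``, then bands them by the
cutoff's z-score location: a cutoff at z >= 1 means only high expressers are
separated (an "overexpression" gene), a cutoff at z <= -1 an
"under-expression" gene, and a cutoff near zero is discarded as merely
splitting the cohort around its average. Banded genes are partitioned into
shorter- and longer-survival lists by which side of the cutoff carries the
worse outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._validation import check_survival_y
from .cutpoint import CutpointResult, best_cutpoint
from .survival import (
    CoxFit,
    CoxPH,
    KMCurve,
    benjamini_hochberg,
    km_estimate,
    logrank_test,
    mean_time_to_event,
)

__all__ = [
    "ScreenResult",
    "GeneReport",
    "GenomeWideScreen",
    "screen_genes",
    "classify_gene",
    "gene_report",
]

CLASS_LABELS = (
    "shorter_survival_over",
    "longer_survival_over",
    "shorter_survival_under",
    "longer_survival_under",
    "excluded",
)


def classify_gene(res: CutpointResult, z_hi: float = 1.0, z_lo: float = -1.0,
                  alpha: float = 0.05, cutoff_z: float | None = None,
                  direction_rule: str = "hr") -> str:
    """Assign a screened gene to a survival/expression class.

    ``excluded`` when the corrected p-value misses ``alpha`` or the cutoff's
    z-score falls strictly inside (z_lo, z_hi). Otherwise the label joins the
    z band (over / under) with the survival direction:

    * ``direction_rule="hr"`` (default): the banded expression class is
      "shorter survival" when its members fare worse — for an overexpression
      gene (z >= z_hi) when the above-cutoff hazard ratio exceeds 1, for an
      under-expression gene (z <= z_lo) when it is below 1 (the low group
      carries the excess hazard).
    * ``direction_rule="band"``: direction read off the band sign alone
      (over -> shorter, under -> longer).
    """
    if direction_rule not in ("hr", "band"):
        raise ValueError(f"unknown direction_rule {direction_rule!r}")
    z = res.best_cutoff if cutoff_z is None else cutoff_z
    if res.p_value >= alpha or (z_lo < z < z_hi):
        return "excluded"
    over = z >= z_hi
    if direction_rule == "band":
        return "shorter_survival_over" if over else "longer_survival_under"
    if over:
        return "shorter_survival_over" if res.hr_high_vs_low > 1 else "longer_survival_over"
    return "shorter_survival_under" if res.hr_high_vs_low < 1 else "longer_survival_under"


@dataclass
class ScreenResult:
    """Gene lists and per-gene statistics from the genome-wide screen."""

    per_gene: pd.DataFrame
    skipped: dict
    alpha: float
    z_hi: float
    z_lo: float
    survival_associated: list = field(default_factory=list)
    overexpression_set: list = field(default_factory=list)
    underexpression_set: list = field(default_factory=list)
    shorter_survival_genes: list = field(default_factory=list)
    longer_survival_genes: list = field(default_factory=list)

    def cascade(self) -> dict:
        """Counts at each stage: analyzed -> associated -> banded -> split."""
        return {
            "total": len(self.per_gene) + len(self.skipped),
            "analyzed": len(self.per_gene),
            "skipped": len(self.skipped),
            "associated": len(self.survival_associated),
            "banded": len(self.shorter_survival_genes) + len(self.longer_survival_genes),
            "shorter": len(self.shorter_survival_genes),
            "longer": len(self.longer_survival_genes),
        }

    def to_tsv(self, path) -> None:
        self.per_gene.to_csv(path, sep="\t", index=False)


class GenomeWideScreen(BaseEstimator):
    """Per-gene optimal-cutpoint screen with p and z-band filters.

    ``fit`` expects ``X`` as a samples x genes DataFrame (sklearn
    orientation) and ``y`` as survival outcomes; :func:`screen_genes` accepts
    the genes x samples layout used by the file formats.

    Parameters mirror the screening thresholds: ``alpha`` on the corrected
    cutpoint p-value, ``z_hi``/``z_lo`` bands on the cutoff z-score (band
    edges inclusive), ``min_group`` forwarded to the cutpoint selector,
    ``standardize`` converts cutoffs to z-scores per gene when the input is
    not already z-scored, ``direction_rule`` as in :func:`classify_gene`.
    """

    def __init__(self, alpha: float = 0.05, z_hi: float = 1.0, z_lo: float = -1.0,
                 min_group: int | None = None, standardize: bool = False,
                 direction_rule: str = "hr"):
        self.alpha = alpha
        self.z_hi = z_hi
        self.z_lo = z_lo
        self.min_group = min_group
        self.standardize = standardize
        self.direction_rule = direction_rule

    def fit(self, X, y):
        if self.z_lo >= self.z_hi:
            raise ValueError("z_lo must be below z_hi")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        time, event = check_survival_y(y)
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"G{i:05d}" for i in range(X.shape[1])]
        if X.shape[0] != time.size:
            raise ValueError("X rows must match survival outcomes (samples x genes)")

        rows, skipped = [], {}
        for gene in X.columns:
            x = X[gene].to_numpy(dtype=float)
            keep = np.isfinite(x)
            try:
                res = best_cutpoint(x[keep], time[keep], event[keep],
                                    min_group=self.min_group, gene=str(gene))
            except ValueError as exc:
                skipped[str(gene)] = str(exc)
                continue
            if self.standardize:
                mu, sd = x[keep].mean(), x[keep].std()
                cutoff_z = (res.best_cutoff - mu) / sd if sd > 0 else np.nan
            else:
                cutoff_z = res.best_cutoff
            label = classify_gene(res, self.z_hi, self.z_lo, self.alpha,
                                  cutoff_z=cutoff_z, direction_rule=self.direction_rule)
            row = res.to_row()
            row["cutoff_z"] = cutoff_z
            row["class"] = label
            rows.append(row)
        if not rows:
            raise ValueError("no analyzable genes")

        per_gene = pd.DataFrame(rows)
        per_gene["p_bh"] = benjamini_hochberg(per_gene["p"].to_numpy())
        cols = ["gene", "cutoff", "cutoff_z", "Q", "p", "p_bh", "HR",
                "CI_low", "CI_high", "direction", "n_high", "n_low", "class"]
        per_gene = per_gene[cols]

        assoc = per_gene.loc[per_gene["p"] < self.alpha, "gene"]
        over = per_gene.loc[(per_gene["p"] < self.alpha)
                            & (per_gene["cutoff_z"] >= self.z_hi), "gene"]
        under = per_gene.loc[(per_gene["p"] < self.alpha)
                             & (per_gene["cutoff_z"] <= self.z_lo), "gene"]
        shorter = per_gene.loc[per_gene["class"].str.startswith("shorter"), "gene"]
        longer = per_gene.loc[per_gene["class"].str.startswith("longer"), "gene"]

        self.results_ = ScreenResult(
            per_gene=per_gene,
            skipped=skipped,
            alpha=self.alpha,
            z_hi=self.z_hi,
            z_lo=self.z_lo,
            survival_associated=sorted(assoc),
            overexpression_set=sorted(over),
            underexpression_set=sorted(under),
            shorter_survival_genes=sorted(shorter),
            longer_survival_genes=sorted(longer),
        )
        self.shorter_survival_genes_ = self.results_.shorter_survival_genes
        self.longer_survival_genes_ = self.results_.longer_survival_genes
        return self


def screen_genes(expr: pd.DataFrame, clin: pd.DataFrame, alpha: float = 0.05,
                 z_hi: float = 1.0, z_lo: float = -1.0,
                 min_group: int | None = None, standardize: bool = False,
                 direction_rule: str = "hr") -> ScreenResult:
    """Run the screen on a genes x samples matrix and an aligned clinical table."""
    if list(expr.columns) != list(clin.index):
        raise ValueError("expression and clinical samples are not aligned; "
                         "call io.align_samples first")
    screen = GenomeWideScreen(alpha=alpha, z_hi=z_hi, z_lo=z_lo,
                              min_group=min_group, standardize=standardize,
                              direction_rule=direction_rule)
    y = (clin["time"].to_numpy(dtype=float), clin["event"].to_numpy())
    screen.fit(expr.T, y)
    return screen.results_


@dataclass
class GeneReport:
    """Single-gene dichotomized survival report."""

    gene: str
    cutoff: float
    cutpoint: CutpointResult | None
    km_high: KMCurve
    km_low: KMCurve
    logrank_chi2: float
    logrank_p: float
    cox_univariate: CoxFit
    cox_multivariate: CoxFit | None
    mean_time_high: float
    mean_time_low: float


DEFAULT_COVARIATES = ("age", "gs", "t_category", "ipsa")


def gene_report(expr: pd.DataFrame, clin: pd.DataFrame, gene: str,
                cutoff: float | None = None, covariates=None,
                min_group: int | None = None) -> GeneReport:
    """KM curves, univariate and covariate-adjusted Cox fits for one gene.

    When ``cutoff`` is omitted the optimal cutpoint is computed; the
    multivariate model adjusts for the available clinical covariates
    (age, Gleason score, T category, initial PSA when present) with
    Bonferroni-adjusted Wald p-values across the model's covariates.
    """
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    if list(expr.columns) != list(clin.index):
        raise ValueError("expression and clinical samples are not aligned")
    x = expr.loc[gene].to_numpy(dtype=float)
    keep = np.isfinite(x)
    x = x[keep]
    clin = clin.loc[keep]
    time = clin["time"].to_numpy(dtype=float)
    event = clin["event"].to_numpy()

    cut_res = None
    if cutoff is None:
        cut_res = best_cutpoint(x, time, event, min_group=min_group, gene=gene)
        cutoff = cut_res.best_cutoff
    high = x > cutoff
    if high.all() or not high.any():
        raise ValueError(f"cutoff {cutoff} leaves an empty group")

    km_high = km_estimate(time[high], event[high])
    km_low = km_estimate(time[~high], event[~high])
    chi2, lr_p = logrank_test(time[high], event[high], time[~high], event[~high])

    uni = CoxPH().fit(pd.DataFrame({gene: high.astype(int)}, index=clin.index),
                      (time, event)).result_()

    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES
                      if c in clin.columns and clin[c].notna().all()
                      and clin[c].nunique() > 1]
    multi = None
    if covariates:
        design = pd.DataFrame({gene: high.astype(int)}, index=clin.index)
        for c in covariates:
            design[c] = pd.to_numeric(clin[c], errors="raise")
        multi = CoxPH().fit(design, (time, event)).result_()

    means = mean_time_to_event(time, event, high.astype(int))
    return GeneReport(
        gene=gene,
        cutoff=float(cutoff),
        cutpoint=cut_res,
        km_high=km_high,
        km_low=km_low,
        logrank_chi2=chi2,
        logrank_p=lr_p,
        cox_univariate=uni,
        cox_multivariate=multi,
        mean_time_high=means.get(1, float("nan")),
        mean_time_low=means.get(0, float("nan")),
    )
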