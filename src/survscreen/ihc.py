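"""H-score quantification of immunohistochemical staining.

Each high-power field is summarized by counts of cells in four staining
intensity categories (negative 0, low 1, positive 2, high 3). The H-score is
the intensity-weighted percentage sum, sum_k k * 100 * count_k / n_cells,
ranging 0-300. Per patient, several fields are scored and the field with the
highest H-score is carried forward to survival analysis (highest-field rule).
A simple grayscale-histogram binning is provided for workflows starting from
pixel intensity histograms rather than cell counts; its zone bounds are
configurable defaults, not a calibrated standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._validation import check_time_event
from .cutpoint import CutpointResult, best_cutpoint
from .survival import CoxFit, CoxPH, KMCurve, km_estimate

__all__ = [
    "FieldCounts",
    "HScoreResult",
    "HScoreSurvival",
    "compute_hscore",
    "bin_intensity_histogram",
    "select_field",
    "patient_hscores",
    "hscore_survival",
    "DEFAULT_ZONE_BOUNDS",
]

CATEGORIES = ("negative", "low", "positive", "high")

# Upper grayscale bound (inclusive) of the high / positive / low zones;
# darker pixels = stronger staining. Approximate, configurable defaults.
DEFAULT_ZONE_BOUNDS = (60, 120, 180)


@dataclass(frozen=True)
class FieldCounts:
    """Cell counts per staining intensity category in one field."""

    field_id: str
    counts: tuple[int, int, int, int]  # negative, low, positive, high

    def __post_init__(self):
        if len(self.counts) != 4:
            raise ValueError("counts must have 4 categories")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class HScoreResult:
    """Per-field H-scores with the highest-field selection."""

    field_ids: tuple
    h_per_field: tuple
    selected_field: str
    h_selected: float


def compute_hscore(counts) -> float:
    """H-score = sum_k k * 100 * count_k / n_cells, in [0, 300]."""
    if isinstance(counts, FieldCounts):
        counts = counts.counts
    c = np.asarray(counts, dtype=float)
    if c.shape != (4,):
        raise ValueError("expected 4 intensity-category counts")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    n = c.sum()
    if n == 0:
        raise ValueError("no cells counted")
    return float(np.dot(np.arange(4), c) * 100.0 / n)


def bin_intensity_histogram(gray_hist, zone_bounds=DEFAULT_ZONE_BOUNDS):
    """Assign a 256-bin grayscale histogram to the four intensity zones.

    ``zone_bounds`` = inclusive upper bounds of the (high, positive, low)
    zones; everything above the last bound is negative. Returns counts in
    category order (negative, low, positive, high).
    """
    hist = np.asarray(gray_hist, dtype=float)
    if hist.shape != (256,):
        raise ValueError("expected a 256-bin grayscale histogram")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    b = tuple(int(x) for x in zone_bounds)
    if len(b) != 3 or not (0 <= b[0] < b[1] < b[2] <= 255):
        raise ValueError("zone_bounds must be 3 strictly increasing values in [0, 255]")
    high = hist[: b[0] + 1].sum()
    positive = hist[b[0] + 1: b[1] + 1].sum()
    low = hist[b[1] + 1: b[2] + 1].sum()
    negative = hist[b[2] + 1:].sum()
    return np.array([negative, low, positive, high])


def select_field(hscores, field_ids=None) -> HScoreResult:
    """Highest-field rule: keep the maximum H-score; ties -> first field."""
    h = [float(v) for v in hscores]
    if not h:
        raise ValueError("no fields")
    if field_ids is None:
        field_ids = [str(i + 1) for i in range(len(h))]
    field_ids = [str(f) for f in field_ids]
    if len(field_ids) != len(h):
        raise ValueError("field_ids length mismatch")
    idx = int(np.argmax(h))  # argmax keeps the first maximum on ties
    return HScoreResult(tuple(field_ids), tuple(h), field_ids[idx], h[idx])


def patient_hscores(ihc_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-patient highest-field H-scores from an IHC count table.

    Input columns: patient_id, field_id, n_negative, n_low, n_positive,
    n_high (one row per field). Output: patient_id, h_selected,
    selected_field.
    """
    rows = []
    for pid, grp in ihc_counts.groupby("patient_id", sort=False):
        hs = [compute_hscore(r) for r in
              grp[["n_negative", "n_low", "n_positive", "n_high"]].to_numpy()]
        sel = select_field(hs, field_ids=grp["field_id"].tolist())
        rows.append({"patient_id": pid, "h_selected": sel.h_selected,
                     "selected_field": sel.selected_field})
    return pd.DataFrame(rows)


@dataclass
class HScoreSurvival:
    """Survival linkage of protein H-scores: optimal and fixed-z cutoffs."""

    cutpoint: CutpointResult
    cutoff_z: float  # optimal H-score cutoff on the cohort z-score scale
    km_high: KMCurve
    km_low: KMCurve
    fixed_z_cutoff: float  # H-score at cohort z = 1
    fixed_z_fraction_high: float
    fixed_z_cox: CoxFit | None
    fixed_z_km_high: KMCurve | None
    fixed_z_km_low: KMCurve | None


def hscore_survival(hscores, time, event, min_group: int | None = None) -> HScoreSurvival:
    """Optimal-cutpoint analysis of per-patient H-scores.

    Runs the maximally selected log-rank cutpoint on the raw H-scores and
    reports the selected cutoff also as a cohort z-score, since cutoffs on
    different measurement scales are compared on the z scale. A second,
    fixed dichotomy at cohort z = 1 (the conventional overexpression
    definition) is evaluated alongside.
    """
    h = np.asarray(hscores, dtype=float)
    time, event = check_time_event(time, event)
    if h.size != time.size:
        raise ValueError("H-scores and survival lengths differ")
    res = best_cutpoint(h, time, event, min_group=min_group, gene="H-score")
    mu, sd = h.mean(), h.std()
    if sd == 0:
        raise ValueError("constant H-scores")
    cutoff_z = (res.best_cutoff - mu) / sd

    high = h > res.best_cutoff
    km_hi = km_estimate(time[high], event[high])
    km_lo = km_estimate(time[~high], event[~high])

    z1_cutoff = mu + sd
    fx_high = h > z1_cutoff
    fx_cox = fx_hi = fx_lo = None
    if fx_high.any() and not fx_high.all():
        try:
            fx_cox = CoxPH().fit(fx_high.astype(int)[:, None], (time, event)).result_()
        except ValueError:
            fx_cox = None
        fx_hi = km_estimate(time[fx_high], event[fx_high])
        fx_lo = km_estimate(time[~fx_high], event[~fx_high])

    return HScoreSurvival(
        cutpoint=res,
        cutoff_z=float(cutoff_z),
        km_high=km_hi,
        km_low=km_lo,
        fixed_z_cutoff=float(z1_cutoff),
        fixed_z_fraction_high=float(fx_high.mean()),
        fixed_z_cox=fx_cox,
        fixed_z_km_high=fx_hi,
        fixed_z_km_low=fx_lo,
    )
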