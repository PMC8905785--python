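"""Segmentation metrics, severity-stratified cross-validation folds, and
agreement analysis for LDI volumetry.

Metric definitions (S = segmentation, GT = ground truth, |.| = voxel count):

    Dice      = 2|S n GT| / (|S| + |GT|)
    recall    = |S n GT| / |GT|
    precision = |S n GT| / |S|
    RVD       = (|S| - |GT|) / |GT|          (signed relative volume difference)
    VOE       = 1 - |S n GT| / |S u GT|      (volumetric overlap error)

Agreement between computed and reference LDI is summarised by ordinary
least squares (computed on reference) and Bland-Altman statistics: bias =
mean difference, limits of agreement = bias +/- 1.96 x sd(differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import BinaryMask, require_same_lattice

__all__ = [
    "SegMetrics",
    "AgreementReport",
    "seg_metrics",
    "make_cv_folds",
    "ldi_agreement",
    "stratified_summary",
    "DEFAULT_LDI_BINS",
]

#: Severity strata for reporting: [0, 2), [2, 5), [5, inf) percent LDI.
DEFAULT_LDI_BINS = (0.0, 2.0, 5.0, float("inf"))


@dataclass(frozen=True)
class SegMetrics:
    """Overlap metrics for one mask pair.

    ``defined`` is False when GT is empty (overlap metrics are not defined
    for cases without any trauma); values are then NaN.  ``flags`` records
    edge cases such as an empty segmentation against non-empty GT.
    """

    dice: float
    recall: float
    precision: float
    rvd: float
    voe: float
    defined: bool = True
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class AgreementReport:
    """OLS + Bland-Altman agreement between computed and reference LDI."""

    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    bias: float
    loa_low: float
    loa_high: float
    outlier_ids: tuple = ()
    degenerate: bool = False


def seg_metrics(S: BinaryMask, GT: BinaryMask) -> SegMetrics:
    """Dice/recall/precision/RVD/VOE between a segmentation and ground truth."""
    require_same_lattice(S, GT)
    n_s = S.count()
    n_gt = GT.count()
    if n_gt == 0:
        return SegMetrics(
            dice=float("nan"), recall=float("nan"), precision=float("nan"),
            rvd=float("nan"), voe=float("nan"), defined=False,
            flags=("empty ground truth: overlap metrics undefined",),
        )
    inter = int(np.count_nonzero(S.data & GT.data))
    union = n_s + n_gt - inter
    flags = []
    if n_s == 0:
        flags.append("empty segmentation: precision reported as 0")
        precision = 0.0
    else:
        precision = inter / n_s
    return SegMetrics(
        dice=2.0 * inter / (n_s + n_gt),
        recall=inter / n_gt,
        precision=precision,
        rvd=(n_s - n_gt) / n_gt,
        voe=1.0 - inter / union,
        defined=True,
        flags=tuple(flags),
    )


def make_cv_folds(cases, k: int, seed: int = 0) -> dict:
    """Severity-balanced patient-wise fold assignment.

    ``cases`` is a sequence of ``(case_id, reference_ldi)``.  Cases are
    sorted by reference LDI (case id breaking ties) and dealt round-robin
    into ``k`` folds with a seeded rotation, so each fold receives one case
    from every consecutive severity block — per-fold LDI distributions are
    balanced up to the dealing granularity.  The same assignment serves both
    the liver and trauma tasks.

    Returns ``{case_id: fold_index}``.
    """
    cases = list(cases)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(cases) < k:
        raise ValueError(f"need at least k={k} cases, got {len(cases)}")
    ids = [c[0] for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case_ids in cases")
    rng = np.random.default_rng(seed)
    rotation = int(rng.integers(k))
    ordered = sorted(cases, key=lambda c: (float(c[1]), str(c[0])))
    return {cid: (i + rotation) % k for i, (cid, _) in enumerate(ordered)}


def ldi_agreement(pairs, ids=None) -> AgreementReport:
    """Regression + Bland-Altman agreement from (computed, reference) pairs.

    OLS regresses computed on reference.  Outliers are the cases whose
    difference falls strictly outside the limits of agreement.  Zero
    variance in the reference makes the regression degenerate (flagged,
    coefficients NaN); Bland-Altman statistics are still reported.
    """
    arr = np.asarray([(float(c), float(r)) for c, r in pairs], dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 pairs for agreement analysis")
    computed, reference = arr[:, 0], arr[:, 1]
    if ids is None:
        ids = list(range(len(computed)))
    elif len(ids) != len(computed):
        raise ValueError("ids length must match pairs")

    diffs = computed - reference
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    outliers = tuple(
        ids[i] for i in range(len(diffs)) if diffs[i] < loa_low or diffs[i] > loa_high
    )

    if np.ptp(reference) == 0:
        return AgreementReport(
            slope=float("nan"), intercept=float("nan"),
            r_squared=float("nan"), pearson_r=float("nan"),
            bias=bias, loa_low=loa_low, loa_high=loa_high,
            outlier_ids=outliers, degenerate=True,
        )
    fit = sstats.linregress(reference, computed)
    return AgreementReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        pearson_r=float(fit.rvalue),
        bias=bias,
        loa_low=loa_low,
        loa_high=loa_high,
        outlier_ids=outliers,
    )


def stratified_summary(
    per_case: pd.DataFrame,
    bins=DEFAULT_LDI_BINS,
    ldi_column: str = "reference_ldi",
) -> pd.DataFrame:
    """Per-severity-stratum mean/sd of each metric column.

    ``per_case`` holds one row per case with a reference-LDI column and
    numeric metric columns.  Bins are right-open: a case with LDI exactly at
    an edge goes to the upper stratum.  Empty strata are reported with n=0
    and no statistics.
    """
    edges = list(bins)
    if per_case[ldi_column].max() >= edges[-1]:
        raise ValueError("bins do not cover the observed LDI range")
    metric_cols = [
        c for c in per_case.columns
        if c != ldi_column and np.issubdtype(per_case[c].dtype, np.number)
    ]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = per_case[(per_case[ldi_column] >= lo) & (per_case[ldi_column] < hi)]
        label = f"[{lo:g}, {hi:g})" if np.isfinite(hi) else f">= {lo:g}"
        row = {"stratum": label, "n": len(sel)}
        for c in metric_cols:
            if len(sel):
                row[f"{c}_mean"] = float(sel[c].mean())
                row[f"{c}_sd"] = float(sel[c].std(ddof=1)) if len(sel) > 1 else 0.0
            else:
                row[f"{c}_mean"] = float("nan")
                row[f"{c}_sd"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
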