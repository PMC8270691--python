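"""Cohort cleaning, normalization and the discovery/test split.

Pipeline order (exclude → quantile normalize → SD filter → duplicate
merge → split): normalizing before the variance filter keeps the SD
threshold on a common scale across samples; the order of the two matrix
filters is order-insensitive for the default thresholds but the SD filter
can be moved ahead of normalization via ``sd_filter_first``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "exclude_patients",
    "quantile_normalize",
    "filter_low_variance",
    "collapse_duplicates",
    "split_cohort",
    "SplitAssignment",
    "run_preprocess",
]


# ---------------------------------------------------------------------------
# patient exclusion
# ---------------------------------------------------------------------------

def exclude_patients(clinical: pd.DataFrame):
    """Remove unusable SLE patients; healthy controls are always kept.

    A patient is excluded when (a) any visit has a missing SLEDAI or
    required field, (b) any drug flag changes across visits, or (c) the
    SLEDAI is exactly constant over ≥2 visits (no disease-activity
    variation to correlate against).  Single-visit patients with complete
    data are kept.  Returns ``(filtered_table, report)`` where ``report``
    is a DataFrame of (patient_id, reason).
    """
    from .io import DRUG_COLUMNS

    reasons = []
    keep_patients = []
    for pid, grp in clinical.groupby("patient_id", sort=False):
        if (grp["state"] == "healthy").all():
            keep_patients.append(pid)
            continue
        required = grp.drop(columns=["sledai"])
        if grp["sledai"].isna().any() or required.isna().any().any():
            reasons.append((pid, "missing data"))
            continue
        if any(grp[c].nunique() > 1 for c in DRUG_COLUMNS):
            reasons.append((pid, "drug change"))
            continue
        if len(grp) >= 2 and grp["sledai"].nunique() == 1:
            reasons.append((pid, "stable SLEDAI"))
            continue
        keep_patients.append(pid)
    report = pd.DataFrame(reasons, columns=["patient_id", "reason"])
    out = clinical[clinical["patient_id"].isin(keep_patients)].reset_index(drop=True)
    return out, report


# ---------------------------------------------------------------------------
# matrix operations
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples (columns) to a common distribution.

    The reference distribution is the per-rank mean over column-sorted
    values.  Ties within a column receive the mean of the reference
    values over their rank span (average-rank convention), so the output
    preserves within-column rank order and is idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    n_genes, _ = values.shape
    reference = np.mean(np.sort(values, axis=0), axis=1)
    out = np.empty_like(values)
    # cumulative means of the reference support fractional (tied) ranks:
    # a tie with average rank r spans ranks [r - (k-1)/2, r + (k-1)/2] and
    # gets the mean reference value over that span
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_genes)
        # group equal values: contiguous in sorted order
        sorted_vals = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0)
        starts = np.concatenate([[0], boundaries + 1])
        ends = np.concatenate([boundaries + 1, [n_genes]])
        for s, e in zip(starts, ends):
            mean_ref = (csum[e] - csum[s]) / (e - s)
            assigned[order[s:e]] = mean_ref
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_low_variance(matrix: pd.DataFrame, sd_min: float = 0.1) -> pd.DataFrame:
    """Keep genes whose across-sample SD (n−1 denominator) is ≥ ``sd_min``."""
    sds = matrix.std(axis=1, ddof=1)
    kept = matrix.loc[sds >= sd_min]
    if kept.shape[0] == 0:
        raise ValueError(
            f"no genes pass the SD filter at sd_min={sd_min}; lower the threshold"
        )
    return kept


def collapse_duplicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Merge duplicated gene symbols to their per-sample mean expression,
    preserving first-occurrence order."""
    if not matrix.index.duplicated().any():
        return matrix
    order = matrix.index[~matrix.index.duplicated()]
    collapsed = matrix.groupby(level=0, sort=False).mean()
    return collapsed.loc[order]


# ---------------------------------------------------------------------------
# discovery / test split
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    discovery_patients: list
    test_patients: list

    def to_dict(self):
        return {
            "discovery_patients": sorted(self.discovery_patients),
            "test_patients": sorted(self.test_patients),
        }


def split_cohort(clinical: pd.DataFrame, ratio=(2, 1), seed: int = 0) -> SplitAssignment:
    """Split SLE patients into discovery and test sets at the patient
    level (all visits of a patient stay together), stratified by the
    ``cohort`` field, with |discovery| = round(r1/(r1+r2) · n) per stratum."""
    sle = clinical[clinical["state"] == "SLE"]
    patients = sle[["patient_id", "cohort"]].drop_duplicates("patient_id")
    if len(patients) < 3:
        raise ValueError("need at least 3 SLE patients to split")
    frac = ratio[0] / (ratio[0] + ratio[1])
    rng = np.random.default_rng(seed)
    discovery, test = [], []
    for _, grp in patients.groupby("cohort", sort=True):
        ids = sorted(grp["patient_id"])
        rng.shuffle(ids)
        n_disc = int(round(frac * len(ids)))
        discovery.extend(ids[:n_disc])
        test.extend(ids[n_disc:])
    return SplitAssignment(sorted(discovery), sorted(test))


# ---------------------------------------------------------------------------
# pipeline convenience
# ---------------------------------------------------------------------------

def run_preprocess(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    sd_min: float = 0.1,
    split_seed: int = 0,
    sd_filter_first: bool = False,
    do_split: bool = True,
):
    """exclude → quantile normalize → SD filter → merge duplicates → split."""
    clinical, report = exclude_patients(clinical)
    matrix = matrix[[s for s in matrix.columns if s in set(clinical["sample_id"])]]
    if sd_filter_first:
        matrix = filter_low_variance(matrix, sd_min)
        matrix = quantile_normalize(matrix)
    else:
        matrix = quantile_normalize(matrix)
        matrix = filter_low_variance(matrix, sd_min)
    matrix = collapse_duplicates(matrix)
    split = split_cohort(clinical, seed=split_seed) if do_split else None
    return matrix, clinical, split, report
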