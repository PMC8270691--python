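"""Subtype-stratified treatment analysis.

Per-patient SLEDAI change is normalized to score units per month
(30.44 days) so rates are comparable across patients with different
follow-up.  Drug benefit contrasts exposed vs unexposed patients within
each subtype (patients are treated by combination, so the contrast is
per drug, everything else uncontrolled — as in the source design).  The
repositioning analysis attributes each inter-visit interval's rate to
the subtype of the interval's first sample, since a patient's samples
can change subtype over time.  Demographic associations use Fisher's
exact test (exact enumeration for r×c tables up to N = 200, seeded
Monte-Carlo beyond).
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DAYS_PER_MONTH",
    "sledai_deltas",
    "drug_benefit",
    "reposition_rates",
    "demographic_association",
    "fisher_exact_rxc",
    "patient_subtypes",
]

DAYS_PER_MONTH = 30.44


# ---------------------------------------------------------------------------
# per-patient deltas
# ---------------------------------------------------------------------------

def patient_subtypes(clinical: pd.DataFrame, assignments: pd.Series) -> pd.Series:
    """Patient-level subtype = majority label over the patient's samples;
    ties break toward the earliest sample's label."""
    merged = clinical.merge(
        assignments.rename("subtype"), left_on="sample_id", right_index=True, how="inner"
    )
    out = {}
    for pid, grp in merged.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_days", kind="stable")
        counts = grp["subtype"].value_counts()
        top = counts.max()
        tied = set(counts.index[counts == top])
        if len(tied) == 1:
            out[pid] = counts.idxmax()
        else:
            out[pid] = next(s for s in grp["subtype"] if s in tied)
    return pd.Series(out, name="subtype")


def sledai_deltas(clinical: pd.DataFrame, assignments: pd.Series) -> pd.DataFrame:
    """Per-patient SLEDAI change and per-month rate.

    delta = SLEDAI_last − SLEDAI_first over the patient's observed
    visits; months = elapsed days / 30.44; rate = delta / months.
    Single-visit patients and zero-elapsed-time patients are skipped with
    a warning.  The patient's subtype is the majority sample label.
    """
    subtype = patient_subtypes(clinical, assignments)
    sle = clinical[(clinical["state"] == "SLE") & clinical["sledai"].notna()]
    rows, skipped = [], []
    for pid, grp in sle.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_days", kind="stable")
        if len(grp) < 2:
            skipped.append((pid, "single visit"))
            continue
        days = grp["time_days"].iloc[-1] - grp["time_days"].iloc[0]
        if days <= 0:
            skipped.append((pid, "zero elapsed time"))
            continue
        months = days / DAYS_PER_MONTH
        delta = float(grp["sledai"].iloc[-1] - grp["sledai"].iloc[0])
        rows.append(
            dict(
                patient_id=pid,
                subtype=subtype.get(pid),
                drug_cs=bool(grp["drug_cs"].iloc[0]),
                drug_hc=bool(grp["drug_hc"].iloc[0]),
                drug_is=bool(grp["drug_is"].iloc[0]),
                drug_ifnk=bool(grp["drug_ifnk"].iloc[0]),
                delta_total=delta,
                months=float(months),
                rate=delta / months,
            )
        )
    for pid, reason in skipped:
        warnings.warn(f"patient {pid}: {reason}; excluded from deltas")
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "subtype",
            "drug_cs",
            "drug_hc",
            "drug_is",
            "drug_ifnk",
            "delta_total",
            "months",
            "rate",
        ],
    )


# ---------------------------------------------------------------------------
# drug benefit
# ---------------------------------------------------------------------------

def drug_benefit(
    deltas: pd.DataFrame,
    drugs: Iterable[str] = ("cs", "hc", "is"),
    value: str = "rate",
) -> pd.DataFrame:
    """Exposed-vs-unexposed SLEDAI-rate contrast per (subtype, drug).

    difference = mean(exposed) − mean(unexposed); Wilcoxon rank-sum p,
    BH-adjusted across the table.  Cells with < 2 patients on either
    side are reported with counts but no test.  Within each subtype,
    ``rank`` orders drugs by ascending difference (most beneficial, i.e.
    most negative, first).
    """
    if value not in ("rate", "delta_total"):
        raise ValueError("value must be 'rate' or 'delta_total'")
    rows = []
    for subtype in sorted(deltas["subtype"].dropna().unique()):
        sub = deltas[deltas["subtype"] == subtype]
        for drug in drugs:
            flag = sub[f"drug_{drug}"]
            exposed = sub.loc[flag, value]
            unexposed = sub.loc[~flag, value]
            row = dict(
                subtype=subtype,
                drug=drug,
                n_exposed=int(len(exposed)),
                n_unexposed=int(len(unexposed)),
                mean_exposed=float(exposed.mean()) if len(exposed) else np.nan,
                mean_unexposed=float(unexposed.mean()) if len(unexposed) else np.nan,
            )
            if len(exposed) >= 2 and len(unexposed) >= 2:
                row["difference"] = row["mean_exposed"] - row["mean_unexposed"]
                row["p_value"] = float(
                    stats.mannwhitneyu(exposed, unexposed, alternative="two-sided").pvalue
                )
            else:
                row["difference"] = np.nan
                row["p_value"] = np.nan
            rows.append(row)
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["q_value"] = np.nan
    if ok.any():
        out.loc[ok, "q_value"] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    out["rank"] = (
        out.groupby("subtype")["difference"].rank(method="first", ascending=True)
    )
    return out


# ---------------------------------------------------------------------------
# repositioning rates
# ---------------------------------------------------------------------------

def reposition_rates(clinical: pd.DataFrame, assignments: pd.Series, drug: str = "ifnk"):
    """Per-subtype mean SLEDAI rate over inter-visit intervals of treated
    patients.

    Each interval contributes ΔSLEDAI/Δmonths attributed to the subtype
    of the interval's FIRST sample.  Returns a DataFrame indexed by
    subtype with ``rate`` (mean over intervals, NaN when a subtype has no
    interval), ``n_intervals`` and ``n_samples`` (treated samples
    assigned to the subtype).
    """
    flag = f"drug_{drug}"
    treated = clinical[(clinical["state"] == "SLE") & clinical[flag] & clinical["sledai"].notna()]
    merged = treated.merge(
        assignments.rename("subtype"), left_on="sample_id", right_index=True, how="inner"
    )
    records = {}
    sample_counts = merged["subtype"].value_counts().to_dict()
    for pid, grp in merged.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_days", kind="stable")
        times = grp["time_days"].to_numpy(dtype=float)
        sledai = grp["sledai"].to_numpy(dtype=float)
        subs = grp["subtype"].to_numpy()
        for i in range(len(grp) - 1):
            d_months = (times[i + 1] - times[i]) / DAYS_PER_MONTH
            if d_months <= 0:
                continue
            rate = (sledai[i + 1] - sledai[i]) / d_months
            records.setdefault(subs[i], []).append(rate)
    subtypes = sorted(set(sample_counts) | set(records))
    rows = []
    for s in subtypes:
        rates = records.get(s, [])
        rows.append(
            dict(
                subtype=s,
                rate=float(np.mean(rates)) if rates else np.nan,
                n_intervals=len(rates),
                n_samples=int(sample_counts.get(s, 0)),
            )
        )
    out = pd.DataFrame(rows, columns=["subtype", "rate", "n_intervals", "n_samples"])
    return out.set_index("subtype")


# ---------------------------------------------------------------------------
# Fisher's exact test (2×2 and r×c)
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray, lgamma=math.lgamma) -> float:
    """log P(table | margins) under the multivariate hypergeometric."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    lp = sum(lgamma(r + 1) for r in rows) + sum(lgamma(c + 1) for c in cols)
    lp -= lgamma(n + 1)
    lp -= sum(lgamma(v + 1) for v in table.ravel())
    return lp


def _enumerate_tables(rows, cols):
    """Yield every nonnegative integer table with the given margins."""
    r, c = len(rows), len(cols)

    def rec(i, remaining_cols, acc):
        if i == r - 1:
            last = np.asarray(remaining_cols)
            if (last >= 0).all():
                yield acc + [list(last)]
            return
        # enumerate row i cell by cell
        def cells(j, left_row, rem_cols, row_acc):
            if j == c - 1:
                v = left_row
                if 0 <= v <= rem_cols[j]:
                    new_rem = list(rem_cols)
                    new_rem[j] -= v
                    yield row_acc + [v], new_rem
                return
            hi = min(left_row, rem_cols[j])
            for v in range(hi + 1):
                new_rem = list(rem_cols)
                new_rem[j] -= v
                yield from cells(j + 1, left_row - v, new_rem, row_acc + [v])

        for row, rem in cells(0, rows[i], remaining_cols, []):
            yield from rec(i + 1, rem, acc + [row])

    yield from rec(0, list(cols), [])


def fisher_exact_rxc(
    table,
    seed: int = 0,
    n_mc: int = 100000,
    exact_limit: int = 200,
):
    """Two-sided Fisher's exact p for an r×c contingency table.

    2×2 tables delegate to the hypergeometric tail (scipy).  Larger
    tables are handled by exact enumeration of all tables with the
    observed margins when the total count is ≤ ``exact_limit``, summing
    the probability of every table no more probable than the observed
    one; beyond that a seeded Monte-Carlo over margin-preserving random
    tables is used.  Returns ``(p, method)``.
    """
    table = np.asarray(table, dtype=int)
    if table.min() < 0:
        raise ValueError("table entries must be nonnegative")
    # drop all-zero rows/columns
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0, "degenerate"
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1]), "hypergeometric"
    rows = list(table.sum(axis=1))
    cols = list(table.sum(axis=0))
    lp_obs = _log_table_prob(table)
    tol = 1e-10
    if table.sum() <= exact_limit:
        total = 0.0
        for t in _enumerate_tables(rows, cols):
            lp = _log_table_prob(np.asarray(t))
            if lp <= lp_obs + tol:
                total += math.exp(lp)
        return min(float(total), 1.0), "exact-enumeration"
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(rows, cols)
    draws = sampler.rvs(n_mc, method="patefield", random_state=rng)
    hits = sum(1 for t in draws if _log_table_prob(np.asarray(t, dtype=int)) <= lp_obs + tol)
    return (1 + hits) / (n_mc + 1), "monte-carlo"


def demographic_association(
    assignments: pd.Series,
    clinical: pd.DataFrame,
    variable: str,
    seed: int = 0,
) -> dict:
    """Subtype × demographic-level association (Fisher's exact).

    Patients get one subtype by majority rule; the contingency table
    counts patients.  Levels with zero patients are dropped with a
    warning.  Returns a dict with the table, p-value and test method.
    """
    if variable not in ("age_group", "sex", "race"):
        raise ValueError("variable must be one of age_group, sex, race")
    sle = clinical[clinical["state"] == "SLE"]
    subtype = patient_subtypes(sle, assignments)
    per_patient = (
        sle.sort_values(["patient_id", "time_days"]).groupby("patient_id", sort=True)[variable].first()
    )
    df = pd.concat([subtype, per_patient], axis=1, join="inner").dropna()
    table = pd.crosstab(df["subtype"], df[variable])
    empty_cols = [c for c in table.columns if table[c].sum() == 0]
    if empty_cols:
        warnings.warn(f"levels with 0 patients dropped: {empty_cols}")
        table = table.drop(columns=empty_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 subtypes and >= 2 levels for the association test")
    p, method = fisher_exact_rxc(table.to_numpy(), seed=seed)
    return {"table": table, "p_value": float(p), "method": method}
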