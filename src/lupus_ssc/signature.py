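"""Disease-activity gene-signature screen.

Two filters define the signature: (1) a one-way ANOVA between SLE and
healthy samples with Benjamini–Hochberg FDR control, and (2) a
patient-weighted longitudinal correlation score

    score(g) = Σ_p w_p · |r_p(g)|,     Σ_p w_p = 1,

where ``r_p(g)`` is the within-patient correlation (Spearman by default —
SLEDAI is ordinal) between gene ``g``'s expression across patient ``p``'s
visits and the SLEDAI score, and ``w_p ∝ n_visits_p`` weights patients by
the information they contribute.  Because the weights sum to one the
score lives in [0, 1] and the selection cutoff (score > 0.6) is on an
absolute scale.  The score is calibrated by a permutation null (shuffling
gene and sample labels of the expression matrix) and contrasted against
random non-differential gene sets of matched size.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "anova_screen",
    "patient_weights",
    "activity_score",
    "permutation_calibration",
    "random_geneset_comparison",
    "select_signature",
    "SignatureScreen",
]


# ---------------------------------------------------------------------------
# differential screen
# ---------------------------------------------------------------------------

def anova_screen(matrix: pd.DataFrame, clinical: pd.DataFrame, q_max: float = 0.05) -> pd.DataFrame:
    """Per-gene one-way ANOVA between SLE and healthy samples.

    Samples are treated as independent observations.  Returns a DataFrame
    indexed by gene with columns ``f_stat``, ``p_value``, ``q_value``
    (Benjamini–Hochberg) and ``deg`` (q < q_max).  Genes with zero total
    variance get F = 0, p = 1.
    """
    meta = clinical.set_index("sample_id")["state"]
    samples = [s for s in matrix.columns if s in meta.index]
    states = meta.loc[samples]
    sle = [s for s in samples if states[s] == "SLE"]
    healthy = [s for s in samples if states[s] == "healthy"]
    if len(sle) < 2 or len(healthy) < 2:
        raise ValueError("each state group needs at least 2 samples for the ANOVA screen")
    a = matrix[sle].to_numpy(dtype=float)
    b = matrix[healthy].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(a, b, axis=1)
    # zero within- and between-group variance -> 0/0; define as no effect
    degenerate = ~np.isfinite(f) & (np.ptp(np.concatenate([a, b], axis=1), axis=1) == 0)
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"f_stat": f, "p_value": p, "q_value": q, "deg": q < q_max}, index=matrix.index
    )


# ---------------------------------------------------------------------------
# patient weights and activity score
# ---------------------------------------------------------------------------

def patient_weights(clinical: pd.DataFrame, min_visits: int = 3) -> pd.Series:
    """Weights ∝ visit count for patients informative about activity.

    A patient is scoreable when they have ≥ ``min_visits`` visits with
    observed SLEDAI and nonzero SLEDAI variance.  Weights are normalized
    to sum to 1; non-scoreable patients are omitted (weight 0).
    """
    sle = clinical[(clinical["state"] == "SLE") & clinical["sledai"].notna()]
    weights = {}
    for pid, grp in sle.groupby("patient_id", sort=True):
        if len(grp) >= min_visits and grp["sledai"].nunique() > 1:
            weights[pid] = float(len(grp))
    if not weights:
        raise ValueError(
            f"no patient has >= {min_visits} visits with varying SLEDAI; cannot score"
        )
    w = pd.Series(weights, name="weight")
    return w / w.sum()


def _patient_blocks(matrix: pd.DataFrame, clinical: pd.DataFrame, weights: pd.Series):
    """Per weighted patient: (column indices into matrix, SLEDAI vector)."""
    cols = {s: i for i, s in enumerate(matrix.columns)}
    blocks = []
    grouped = clinical[clinical["patient_id"].isin(weights.index)]
    for pid, grp in grouped.groupby("patient_id", sort=True):
        grp = grp[grp["sample_id"].isin(cols) & grp["sledai"].notna()]
        idx = np.array([cols[s] for s in grp["sample_id"]])
        blocks.append((pid, idx, grp["sledai"].to_numpy(dtype=float)))
    return blocks


def _corr_rows(values: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    """Correlation of each row of ``values`` with ``y``; zero-variance
    rows give r = 0."""
    if method == "spearman":
        values = stats.rankdata(values, axis=1, method="average")
        y = stats.rankdata(y, method="average")
    xc = values - values.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    return np.where(np.isfinite(r), r, 0.0)


def activity_score(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    genes: Optional[Iterable[str]] = None,
    weights: Optional[pd.Series] = None,
    method: str = "spearman",
):
    """Patient-weighted |correlation| score of genes against SLEDAI.

    Returns ``(per_patient_r, score)``: a genes × patients DataFrame of
    within-patient correlations and a Series of weighted scores in [0, 1].
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if weights is None:
        weights = patient_weights(clinical)
    if genes is not None:
        genes = list(genes)
        missing = [g for g in genes if g not in matrix.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        matrix = matrix.loc[genes]
    blocks = _patient_blocks(matrix, clinical, weights)
    values = matrix.to_numpy(dtype=float)
    r_cols = {}
    for pid, idx, sledai in blocks:
        r_cols[pid] = _corr_rows(values[:, idx], sledai, method)
    per_patient_r = pd.DataFrame(r_cols, index=matrix.index)
    w = weights.loc[per_patient_r.columns]
    score = per_patient_r.abs() @ w
    score.name = "score"
    return per_patient_r, score


def permutation_calibration(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    genes: Optional[Iterable[str]] = None,
    weights: Optional[pd.Series] = None,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "spearman",
    scheme: str = "both",
):
    """Permutation null for the activity score.

    Each of ``n_perm`` iterations independently shuffles the gene (row)
    labels and the sample (column) labels of the expression matrix
    (``scheme``: 'both' | 'rows' | 'columns') and recomputes every score.
    Returns ``(perm_p, null_scores)`` with the add-one estimator
    perm_p(g) = (1 + #{b : score_b(g) ≥ score_obs(g)}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if weights is None:
        weights = patient_weights(clinical)
    if genes is not None:
        genes = list(genes)
    else:
        genes = list(matrix.index)
    _, obs = activity_score(matrix, clinical, genes, weights, method)
    gene_pos = np.array([matrix.index.get_loc(g) for g in genes])
    values = matrix.to_numpy(dtype=float)
    blocks = _patient_blocks(matrix, clinical, weights)
    w = weights.to_numpy()
    w_order = list(weights.index)
    block_map = {pid: (idx, sledai) for pid, idx, sledai in blocks}
    rng = np.random.default_rng(seed)
    n_genes_total, n_samples = values.shape
    null_scores = np.empty((n_perm, len(genes)))
    for b in range(n_perm):
        rows = (
            rng.permutation(n_genes_total) if scheme in ("both", "rows") else np.arange(n_genes_total)
        )
        cols = (
            rng.permutation(n_samples) if scheme in ("both", "columns") else np.arange(n_samples)
        )
        permuted = values[np.ix_(rows, cols)][gene_pos]
        acc = np.zeros(len(genes))
        for pid, wi in zip(w_order, w):
            idx, sledai = block_map[pid]
            r = _corr_rows(permuted[:, idx], sledai, method)
            acc += wi * np.abs(r)
        null_scores[b] = acc
    obs_v = obs.loc[genes].to_numpy()
    perm_p = (1 + (null_scores >= obs_v[None, :]).sum(axis=0)) / (n_perm + 1)
    return pd.Series(perm_p, index=genes, name="perm_p"), null_scores


def random_geneset_comparison(
    scores: pd.Series,
    deg_genes: Iterable[str],
    n_random: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical p comparing the mean score of the differential genes to
    random equally-sized sets of non-differential genes.

    ``scores`` must cover both the differential genes and the background.
    p = (1 + #{draws : mean_random ≥ mean_DEG}) / (n_random + 1).
    """
    deg_genes = list(deg_genes)
    non_deg = scores.index.difference(deg_genes)
    if len(non_deg) < len(deg_genes):
        raise ValueError(
            f"need >= {len(deg_genes)} non-differential genes, have {len(non_deg)}"
        )
    rng = np.random.default_rng(seed)
    mean_deg = scores.loc[deg_genes].mean()
    pool = scores.loc[non_deg].to_numpy()
    hits = 0
    for _ in range(n_random):
        draw = rng.choice(pool, size=len(deg_genes), replace=False)
        if draw.mean() >= mean_deg:
            hits += 1
    return (1 + hits) / (n_random + 1)


def select_signature(result: pd.DataFrame, q_max: float = 0.05, score_min: float = 0.6) -> list:
    """Genes with q < q_max AND score > score_min (both strict), sorted by
    descending score.  Returns an empty list (with a warning) if nothing
    passes."""
    sel = result[(result["q_value"] < q_max) & (result["score"] > score_min)]
    if sel.empty:
        warnings.warn("signature selection is empty at these thresholds")
        return []
    return list(sel.sort_values("score", ascending=False).index)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class SignatureScreen(BaseEstimator):
    """Screen genes for a disease-activity signature.

    Parameters
    ----------
    q_max : float
        BH-FDR cutoff for the differential (ANOVA) filter.
    score_min : float
        Strict lower cutoff on the weighted |correlation| score.
    method : {"spearman", "pearson"}
        Within-patient correlation estimator.
    min_visits : int
        Minimum visits for a patient to contribute to the score.
    n_perm : int
        Permutations for score calibration; 0 skips the permutation step.
    random_state : int
        Seed for the permutation null.

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : DataFrame indexed by gene with ``f_stat``, ``p_value``,
        ``q_value``, ``score`` and (if ``n_perm``) ``perm_p``.
    weights_ : Series of patient weights.
    per_patient_r_ : genes × patients correlation DataFrame.
    signature_ : selected gene list, descending score.
    """

    def __init__(
        self,
        q_max: float = 0.05,
        score_min: float = 0.6,
        method: str = "spearman",
        min_visits: int = 3,
        n_perm: int = 0,
        random_state: int = 0,
    ):
        self.q_max = q_max
        self.score_min = score_min
        self.method = method
        self.min_visits = min_visits
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, matrix: pd.DataFrame, clinical: pd.DataFrame) -> "SignatureScreen":
        anova = anova_screen(matrix, clinical, self.q_max)
        self.weights_ = patient_weights(clinical, self.min_visits)
        self.per_patient_r_, score = activity_score(
            matrix, clinical, None, self.weights_, self.method
        )
        results = anova.copy()
        results["score"] = score
        if self.n_perm:
            perm_p, _ = permutation_calibration(
                matrix,
                clinical,
                None,
                self.weights_,
                n_perm=self.n_perm,
                seed=self.random_state,
                method=self.method,
            )
            results["perm_p"] = perm_p
        results["selected"] = (results["q_value"] < self.q_max) & (
            results["score"] > self.score_min
        )
        self.results_ = results
        self.signature_ = select_signature(results, self.q_max, self.score_min)
        return self

    def get_signature(self) -> list:
        return list(self.signature_)
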