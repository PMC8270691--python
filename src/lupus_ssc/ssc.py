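"""Single-sample subtype classifier (SSC).

The subtype model is learned in three stages on the standardized
signature-gene space (per-gene z-scores from the training samples):

1. **k selection** — three independent criteria (average silhouette
   width and Calinski–Harabasz index on PAM k-medoids partitions, and
   the gap statistic on k-means partitions with uniform reference draws)
   each vote for a k; the majority wins, ties break toward smaller k.
2. **Consensus partition** — three base clusterings (k-medoids with
   Euclidean distance, k-medoids with correlation distance 1−r, Ward
   agglomerative) are combined through a sample × sample co-association
   matrix; average-linkage clustering of 1 − co-association cut at k
   gives the consensus labels.
3. **Iterative centroid correction** — alternate nearest-centroid
   reassignment and centroid recomputation until fewer than ``tol``
   (default 1%) of labels change, or ``max_iter`` iterations.  The
   within-cluster sum of squares is non-increasing across iterations.

A new sample is assigned to the nearest centroid (Euclidean distance in
the standardized space); a softmax over negative distances serves as the
assignment likelihood.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SubtypeModel",
    "SubtypeClassifier",
    "choose_k",
    "consensus_partition",
    "fit_centroids",
    "iterative_correction",
    "classify",
    "name_subtypes",
    "sledai_by_subtype",
    "kmedoids",
]


# ---------------------------------------------------------------------------
# k-medoids (PAM-style Voronoi iteration)
# ---------------------------------------------------------------------------

def kmedoids(distance: np.ndarray, k: int, rng, max_iter: int = 100, n_init: int = 5) -> np.ndarray:
    """Partition around medoids on a precomputed distance matrix.

    k-medoids++ seeding followed by Voronoi iteration (assign to nearest
    medoid, move each medoid to its cluster's distance-sum minimizer),
    best of ``n_init`` restarts by total within-cluster distance.
    Returns integer labels 0..k-1.
    """
    best_labels, best_cost = None, np.inf
    for _ in range(max(n_init, 1)):
        labels, cost = _kmedoids_once(distance, k, rng, max_iter)
        if cost < best_cost:
            best_labels, best_cost = labels, cost
    return best_labels


def _kmedoids_once(distance: np.ndarray, k: int, rng, max_iter: int):
    n = distance.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of samples")
    medoids = [int(rng.integers(n))]
    for _ in range(k - 1):
        d = distance[:, medoids].min(axis=1) ** 2
        total = d.sum()
        if total <= 0:
            candidates = np.setdiff1d(np.arange(n), medoids)
            medoids.append(int(rng.choice(candidates)))
        else:
            medoids.append(int(rng.choice(n, p=d / total)))
    medoids = np.asarray(medoids)
    for _ in range(max_iter):
        labels = np.argmin(distance[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size:
                sub = distance[np.ix_(members, members)]
                new[c] = members[int(np.argmin(sub.sum(axis=0)))]
        if np.array_equal(new, medoids):
            break
        medoids = new
    labels = np.argmin(distance[:, medoids], axis=1)
    cost = float(distance[np.arange(n), medoids[labels]].sum())
    return labels, cost


# ---------------------------------------------------------------------------
# k selection
# ---------------------------------------------------------------------------

def _gap_vote(X: np.ndarray, ks, b_ref: int, rng) -> int:
    """Gap-statistic vote with a PCA-aligned uniform reference (the
    rotation-respecting null of the original method, appropriate for
    correlated features); the one-standard-error rule, falling back to
    argmax gap."""
    ks = list(ks)
    centered = X - X.mean(axis=0)
    # rotate into the principal axes; reference draws are uniform over the
    # bounding box there, then rotated back
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    Xp = centered @ vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)

    def log_wk(data, k, seed):
        km = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(data)
        return np.log(max(km.inertia_, 1e-300))

    gaps, sks = [], []
    for k in ks:
        obs = log_wk(X, k, int(rng.integers(2**31 - 1)))
        refs = np.empty(b_ref)
        for b in range(b_ref):
            ref = (lo + rng.random(X.shape) * span) @ vt
            refs[b] = log_wk(ref, k, int(rng.integers(2**31 - 1)))
        gaps.append(refs.mean() - obs)
        sks.append(refs.std(ddof=0) * np.sqrt(1 + 1 / b_ref))
    for i in range(len(ks) - 1):
        if gaps[i] >= gaps[i + 1] - sks[i + 1]:
            return ks[i]
    return ks[int(np.argmax(gaps))]


def _parsimonious_vote(ks, values, rel_tol: float = 0.05) -> int:
    """Smallest k whose criterion is within ``rel_tol`` of the best value
    (a one-SE-style parsimony rule: near-ties resolve to fewer clusters)."""
    values = np.asarray(values, dtype=float)
    best = values.max()
    cutoff = best - rel_tol * abs(best)
    return ks[int(np.argmax(values >= cutoff))]


def choose_k(X, k_range=(2, 6), seed: int = 0, gap_b: int = 50):
    """Select the number of subtypes by majority vote of three criteria.

    ``X`` is samples × features (standardized signature space).  Returns
    ``(k, votes)`` where ``votes`` maps criterion name to its chosen k.
    Ties in the majority break toward the smaller k.
    """
    X = np.asarray(X, dtype=float)
    ks = list(range(k_range[0], k_range[1] + 1))
    if X.shape[0] <= max(ks):
        raise ValueError("need more samples than max(k_range)")
    D = squareform(pdist(X))
    if not D.any():
        raise ValueError("all samples identical; clustering is degenerate")
    rng = np.random.default_rng(seed)
    sil, ch = [], []
    for k in ks:
        pam = kmedoids(D, k, rng)
        km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31 - 1))).fit_predict(X)
        # CH on an independent partition family (k-means) so that the two
        # votes do not share one partition's sampling noise
        sil.append(
            silhouette_score(D, pam, metric="precomputed")
            if len(np.unique(pam)) > 1
            else -np.inf
        )
        ch.append(calinski_harabasz_score(X, km) if len(np.unique(km)) > 1 else -np.inf)
    votes = {
        "silhouette": _parsimonious_vote(ks, sil),
        "calinski_harabasz": _parsimonious_vote(ks, ch),
        "gap": _gap_vote(X, ks, gap_b, rng),
    }
    counts = Counter(votes.values())
    best = max(counts.values())
    k = min(kk for kk, c in counts.items() if c == best)
    return k, votes


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------

def consensus_partition(X, k: int, seed: int = 0):
    """Co-association consensus of three base partitions.

    Base partitions: k-medoids on Euclidean distance, k-medoids on
    correlation distance (1 − Pearson r between samples), and Ward
    agglomerative clustering.  The co-association matrix (fraction of
    partitions co-clustering each pair) is clustered with average
    linkage on 1 − co-association and cut at k.  Returns
    ``(labels, coassociation)``.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    d_eucl = squareform(pdist(X))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    d_corr = 1.0 - corr
    np.fill_diagonal(d_corr, 0.0)
    partitions = [
        kmedoids(d_eucl, k, rng),
        kmedoids(d_corr, k, rng),
        AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X),
    ]
    n = X.shape[0]
    coassoc = np.zeros((n, n))
    for labels in partitions:
        coassoc += (labels[:, None] == labels[None, :]).astype(float)
    coassoc /= len(partitions)
    diss = 1.0 - coassoc
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    if len(np.unique(labels)) < k:
        # re-cut at decreasing merge heights until k non-empty clusters appear
        heights = np.unique(Z[:, 2])[::-1]
        for h in heights:
            labels = fcluster(Z, t=h - 1e-12, criterion="distance") - 1
            if len(np.unique(labels)) == k:
                break
        else:
            raise ValueError(f"cannot cut the consensus dendrogram into {k} clusters")
    return _canonical_labels(labels), coassoc


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (deterministic)."""
    mapping = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# centroids and iterative correction
# ---------------------------------------------------------------------------

def fit_centroids(X, labels) -> np.ndarray:
    """Per-cluster mean of the (standardized) expression: k × features."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    ks = np.unique(labels)
    if len(ks) != ks.max() + 1:
        raise ValueError("labels must be 0..k-1 with every cluster non-empty")
    return np.vstack([X[labels == c].mean(axis=0) for c in range(ks.max() + 1)])


def _wcss(X, labels, centroids) -> float:
    return float(((X - centroids[labels]) ** 2).sum())


def iterative_correction(
    centroids: np.ndarray,
    X,
    labels=None,
    max_iter: int = 50,
    tol: float = 0.01,
):
    """Correct a partition by alternating nearest-centroid assignment and
    centroid recomputation until < ``tol`` of labels change.

    A centroid whose cluster empties keeps its previous value (with a
    warning).  Returns ``(centroids, labels, n_iter, wcss_trace)``.
    """
    X = np.asarray(X, dtype=float)
    centroids = np.asarray(centroids, dtype=float).copy()
    prev = np.asarray(labels) if labels is not None else None
    trace = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d = cdist(X, centroids)
        new_labels = np.argmin(d, axis=1)  # ties -> lowest cluster index
        for c in range(centroids.shape[0]):
            members = new_labels == c
            if members.any():
                centroids[c] = X[members].mean(axis=0)
            else:
                warnings.warn(f"cluster {c} lost all members; keeping previous centroid")
        trace.append(_wcss(X, new_labels, centroids))
        if prev is not None:
            changed = float(np.mean(new_labels != prev))
            if changed < tol:
                prev = new_labels
                break
        prev = new_labels
    return centroids, prev, n_iter, trace


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class SubtypeModel:
    """Persistent state of the single-sample classifier."""

    k: int
    signature_genes: list
    gene_means: list
    gene_sds: list
    centroids: list  # k × genes, standardized units
    subtype_names: dict = field(default_factory=dict)  # cluster index (str) -> name
    training_labels: dict = field(default_factory=dict)  # sample -> cluster

    def __post_init__(self):
        if any(s <= 0 for s in self.gene_sds):
            raise ValueError("gene_sds must all be > 0")
        c = np.asarray(self.centroids)
        if c.shape != (self.k, len(self.signature_genes)):
            raise ValueError("centroid matrix shape mismatch")
        if len(np.unique(c, axis=0)) != self.k:
            raise ValueError("centroid rows must be distinct")

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "signature_genes": list(self.signature_genes),
            "gene_means": [float(v) for v in self.gene_means],
            "gene_sds": [float(v) for v in self.gene_sds],
            "centroids": [[float(v) for v in row] for row in np.asarray(self.centroids)],
            "subtype_names": {str(k): v for k, v in self.subtype_names.items()},
            "training_labels": {s: int(l) for s, l in self.training_labels.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SubtypeModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def classify(model: SubtypeModel, samples: pd.DataFrame) -> pd.DataFrame:
    """Assign each sample (column) of a genes × samples matrix.

    Standardizes with the TRAINING means/SDs, computes Euclidean
    distances to each centroid, labels by the nearest (ties to the lowest
    cluster index) and reports softmax(−distance) likelihoods.
    """
    missing = [g for g in model.signature_genes if g not in samples.index]
    if missing:
        raise KeyError(f"samples are missing signature genes: {missing[:10]}")
    X = samples.loc[model.signature_genes].to_numpy(dtype=float).T
    mu = np.asarray(model.gene_means)
    sd = np.asarray(model.gene_sds)
    Xz = (X - mu) / sd
    centroids = np.asarray(model.centroids)
    d = cdist(Xz, centroids)
    labels = np.argmin(d, axis=1)
    # softmax of negative distances, numerically stabilized
    z = -d
    z = z - z.max(axis=1, keepdims=True)
    lik = np.exp(z)
    lik /= lik.sum(axis=1, keepdims=True)
    out = pd.DataFrame(
        {
            "sample_id": list(samples.columns),
            "label": labels,
        }
    )
    names = {int(k): v for k, v in model.subtype_names.items()}
    out["subtype"] = [names.get(int(l), str(l)) for l in labels]
    for c in range(model.k):
        out[f"dist_{c}"] = d[:, c]
    for c in range(model.k):
        out[f"lik_{c}"] = lik[:, c]
    return out


# ---------------------------------------------------------------------------
# subtype naming and severity
# ---------------------------------------------------------------------------

def name_subtypes(
    model: SubtypeModel,
    term_activity: pd.DataFrame,
    genesets,
    clinical: pd.DataFrame,
) -> dict:
    """Name clusters from their IFN- and NE-module activity.

    For each cluster the mean activity over IFN-module terms and over
    NE-module terms (bacterial + fungal) is compared to the healthy
    baseline; "high" means above healthy mean + 2·healthy SD.
    high/high → mixed, IFN only → IFN-high, NE only → NE-high.  A cluster
    elevated in neither module, or two clusters mapping to the same name,
    is an error (the model is not interpretable under this scheme).
    """
    ifn_terms = [t.term_id for t in genesets.by_module("IFN") if t.term_id in term_activity.index]
    ne_terms = [
        t.term_id
        for t in list(genesets.by_module("bacterial")) + list(genesets.by_module("fungal"))
        if t.term_id in term_activity.index
    ]
    if not ifn_terms or not ne_terms:
        raise ValueError("gene sets must define IFN and NE (bacterial/fungal) modules")
    healthy = set(clinical.loc[clinical["state"] == "healthy", "sample_id"])
    healthy_cols = [s for s in term_activity.columns if s in healthy]
    if len(healthy_cols) < 2:
        raise ValueError("need >= 2 healthy samples in the term activity matrix")

    def module_level(term_ids, cols):
        return term_activity.loc[term_ids, cols].mean(axis=0)

    thresholds = {}
    for mod, terms in (("IFN", ifn_terms), ("NE", ne_terms)):
        h = module_level(terms, healthy_cols)
        thresholds[mod] = h.mean() + 2 * h.std(ddof=1)

    names = {}
    for c in range(model.k):
        cols = [s for s, l in model.training_labels.items() if l == c and s in term_activity.columns]
        if not cols:
            raise ValueError(f"cluster {c} has no samples in the activity matrix")
        ifn_high = module_level(ifn_terms, cols).mean() > thresholds["IFN"]
        ne_high = module_level(ne_terms, cols).mean() > thresholds["NE"]
        if ifn_high and ne_high:
            names[c] = "mixed"
        elif ifn_high:
            names[c] = "IFN-high"
        elif ne_high:
            names[c] = "NE-high"
        else:
            raise ValueError(f"cluster {c} is elevated in neither module; cannot name")
    if len(set(names.values())) != len(names):
        raise ValueError(f"subtype naming is not one-to-one: {names}")
    return names


def sledai_by_subtype(labels: pd.Series, clinical: pd.DataFrame, trim: bool = True):
    """Kruskal–Wallis comparison of SLEDAI across subtypes.

    ``labels`` maps sample_id → subtype label.  With ``trim`` the SLEDAI
    values outside the Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
    (computed over all SLE samples) are removed first.  Pairwise
    Wilcoxon rank-sum tests are BH-adjusted.  Returns a dict with
    ``statistic``, ``p_value``, ``groups`` and a ``pairwise`` DataFrame.
    """
    sle = clinical[(clinical["state"] == "SLE") & clinical["sledai"].notna()]
    df = sle.set_index("sample_id")[["sledai"]].join(labels.rename("subtype"), how="inner")
    df = df.dropna(subset=["subtype"])
    if trim and len(df):
        q1, q3 = df["sledai"].quantile([0.25, 0.75])
        iqr = q3 - q1
        df = df[(df["sledai"] >= q1 - 1.5 * iqr) & (df["sledai"] <= q3 + 1.5 * iqr)]
    groups = {g: sub["sledai"].to_numpy() for g, sub in df.groupby("subtype")}
    usable = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need >= 2 subtypes with >= 2 samples each")
    stat, p = stats.kruskal(*usable.values())
    pairs = []
    keys = sorted(usable)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = usable[keys[i]], usable[keys[j]]
            mw = stats.mannwhitneyu(a, b, alternative="two-sided")
            pairs.append((keys[i], keys[j], mw.pvalue))
    pairwise = pd.DataFrame(pairs, columns=["group_a", "group_b", "p_value"])
    if len(pairwise):
        pairwise["q_value"] = multipletests(pairwise["p_value"], method="fdr_bh")[1]
    skipped = sorted(set(groups) - set(usable))
    if skipped:
        warnings.warn(f"subtypes with <2 samples skipped in pairwise tests: {skipped}")
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "groups": {g: len(v) for g, v in usable.items()},
        "pairwise": pairwise,
    }


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class SubtypeClassifier(BaseEstimator, ClassifierMixin):
    """Consensus-clustering nearest-centroid subtype classifier.

    Fit on a samples × genes table of signature-gene expression (training
    discovers the subtypes); predict assigns any new sample, one at a
    time if need be, to the nearest subtype centroid in the standardized
    training space.

    Parameters
    ----------
    k : int or "auto"
        Number of subtypes; "auto" selects by the three-criterion vote.
    k_range : tuple
        Candidate range for k selection.
    max_iter, tol : iterative-correction controls (stop when < tol of
        labels change).
    gap_b : reference draws for the gap statistic.
    random_state : seed driving every stochastic step of fitting.

    Attributes
    ----------
    k_ : selected number of subtypes; ``k_votes_`` the per-criterion votes.
    genes_ : feature (gene) order; ``mean_``, ``scale_`` standardization.
    centroids_ : k × genes standardized centroids.
    labels_ : corrected training labels; ``consensus_labels_`` the
        pre-correction consensus; ``n_iter_``, ``wcss_trace_``.
    subtype_names_ : optional cluster → name map (see
        :func:`name_subtypes`), used by :meth:`predict` output labels.
    """

    def __init__(
        self,
        k="auto",
        k_range=(2, 6),
        max_iter: int = 50,
        tol: float = 0.01,
        gap_b: int = 50,
        random_state: int = 0,
    ):
        self.k = k
        self.k_range = k_range
        self.max_iter = max_iter
        self.tol = tol
        self.gap_b = gap_b
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))

    def fit(self, X, y=None) -> "SubtypeClassifier":
        frame = self._as_frame(X)
        values = frame.to_numpy(dtype=float)
        if values.shape[0] < 3:
            raise ValueError("need at least 3 training samples")
        self.genes_ = list(frame.columns)
        self.sample_ids_ = list(frame.index)
        self.mean_ = values.mean(axis=0)
        sd = values.std(axis=0, ddof=1)
        if (sd <= 0).any():
            bad = [g for g, s in zip(self.genes_, sd) if s <= 0]
            raise ValueError(f"zero-variance training genes: {bad[:10]}")
        self.scale_ = sd
        Xz = (values - self.mean_) / self.scale_
        if self.k == "auto":
            self.k_, self.k_votes_ = choose_k(
                Xz, self.k_range, seed=self.random_state, gap_b=self.gap_b
            )
        else:
            self.k_ = int(self.k)
            self.k_votes_ = {}
        consensus, self.coassociation_ = consensus_partition(
            Xz, self.k_, seed=self.random_state
        )
        self.consensus_labels_ = consensus
        centroids = fit_centroids(Xz, consensus)
        centroids, labels, self.n_iter_, self.wcss_trace_ = iterative_correction(
            centroids, Xz, labels=consensus, max_iter=self.max_iter, tol=self.tol
        )
        self.centroids_ = centroids
        self.labels_ = labels
        self.classes_ = np.arange(self.k_)
        self.subtype_names_ = {}
        return self

    def _standardize(self, X) -> np.ndarray:
        frame = self._as_frame(X)
        if list(frame.columns) != self.genes_:
            missing = [g for g in self.genes_ if g not in frame.columns]
            if missing:
                raise KeyError(f"missing signature genes: {missing[:10]}")
            frame = frame[self.genes_]
        return (frame.to_numpy(dtype=float) - self.mean_) / self.scale_

    def distances(self, X) -> np.ndarray:
        return cdist(self._standardize(X), self.centroids_)

    def predict(self, X) -> np.ndarray:
        return np.argmin(self.distances(X), axis=1)

    def predict_proba(self, X) -> np.ndarray:
        z = -self.distances(X)
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def predict_names(self, X) -> list:
        names = self.subtype_names_ or {}
        return [names.get(int(l), str(l)) for l in self.predict(X)]

    # -- persistence -----------------------------------------------------
    def to_model(self) -> SubtypeModel:
        return SubtypeModel(
            k=int(self.k_),
            signature_genes=list(self.genes_),
            gene_means=[float(v) for v in self.mean_],
            gene_sds=[float(v) for v in self.scale_],
            centroids=np.asarray(self.centroids_).tolist(),
            subtype_names={str(k): v for k, v in self.subtype_names_.items()},
            training_labels={s: int(l) for s, l in zip(self.sample_ids_, self.labels_)},
        )

    @classmethod
    def from_model(cls, model: SubtypeModel) -> "SubtypeClassifier":
        est = cls(k=model.k)
        est.k_ = model.k
        est.genes_ = list(model.signature_genes)
        est.mean_ = np.asarray(model.gene_means, dtype=float)
        est.scale_ = np.asarray(model.gene_sds, dtype=float)
        est.centroids_ = np.asarray(model.centroids, dtype=float)
        est.labels_ = np.asarray(
            [model.training_labels[s] for s in model.training_labels], dtype=int
        )
        est.sample_ids_ = list(model.training_labels)
        est.classes_ = np.arange(model.k)
        est.subtype_names_ = {int(k): v for k, v in model.subtype_names.items()}
        est.k_votes_ = {}
        return est
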