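"""Gene-set activity (GED), enrichment, module profiles and the term
co-expression network.

The gene expression deviation (GED) statistic measures how far a
sample's expression of a term's genes deviates from a healthy reference:
with z_gs = (x_gs − mean_healthy_g) / sd_healthy_g, the activity of term
T in sample s is mean_{g∈T} |z_gs| (a signed-mean variant is available).
Under a Gaussian null a healthy sample's expected activity is
E|Z| = √(2/π) ≈ 0.798.  When a healthy sample is itself scored, the
reference mean/SD are computed leave-one-out to avoid self-reference
bias.

Term similarity is the Spearman correlation of term-activity vectors
across a chosen sample subset (the mixed-subtype samples, in the
intended use); edges require both |r| ≥ r_min and a BH-adjusted
correlation-test q below q_max.  Communities come from greedy modularity
maximization; bridge terms are ranked by betweenness restricted to
shortest paths between different communities.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .signature import anova_screen

__all__ = [
    "GEDActivity",
    "ged_activity",
    "enrich_terms",
    "subtype_deg",
    "module_profile",
    "term_similarity",
    "build_network",
    "detect_communities",
    "bridge_nodes",
]


# ---------------------------------------------------------------------------
# GED activity
# ---------------------------------------------------------------------------

class GEDActivity(BaseEstimator, TransformerMixin):
    """Transform samples × genes expression into samples × terms activity.

    Parameters
    ----------
    genesets : GeneSetCollection
        Terms to score; terms with fewer than ``min_genes`` genes mapped
        to the fitted gene space are dropped with a warning.
    min_genes : int
        Minimum mapped genes per term.
    signed : bool
        If True use the signed mean z instead of mean |z|.

    ``fit`` takes the healthy reference samples (samples × genes) and
    stores per-gene means and SDs; genes with zero reference variance are
    dropped from every term (with a warning).  ``transform`` scores any
    samples × genes table sharing the fitted gene space.
    """

    def __init__(self, genesets: GeneSetCollection, min_genes: int = 3, signed: bool = False):
        self.genesets = genesets
        self.min_genes = min_genes
        self.signed = signed

    def fit(self, X: pd.DataFrame, y=None) -> "GEDActivity":
        if X.shape[0] < 2:
            raise ValueError("need >= 2 healthy reference samples")
        self.genes_ = list(X.columns)
        values = X.to_numpy(dtype=float)
        self.ref_n_ = values.shape[0]
        self.ref_mean_ = values.mean(axis=0)
        self.ref_sd_ = values.std(axis=0, ddof=1)
        usable = self.ref_sd_ > 0
        if not usable.all():
            dropped = [g for g, u in zip(self.genes_, usable) if not u]
            warnings.warn(
                f"{len(dropped)} genes have zero healthy variance and are dropped from all terms"
            )
        gene_pos = {g: i for i, g in enumerate(self.genes_) if usable[i]}
        self.term_ids_, self.term_index_ = [], []
        for term in self.genesets:
            idx = [gene_pos[g] for g in sorted(term.genes) if g in gene_pos]
            if len(idx) < self.min_genes:
                warnings.warn(
                    f"term {term.term_id!r} has < {self.min_genes} mapped genes; dropped"
                )
                continue
            self.term_ids_.append(term.term_id)
            self.term_index_.append(np.asarray(idx))
        if not self.term_ids_:
            raise ValueError("no term has enough mapped genes")
        return self

    def _z(self, values: np.ndarray, mean, sd) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return (values - mean) / sd

    def _activities(self, z: np.ndarray) -> np.ndarray:
        dev = z if self.signed else np.abs(z)
        return np.column_stack([dev[:, idx].mean(axis=1) for idx in self.term_index_])

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [g for g in self.genes_ if g not in X.columns]
        if missing:
            raise KeyError(f"samples missing fitted genes: {missing[:10]}")
        values = X[self.genes_].to_numpy(dtype=float)
        z = self._z(values, self.ref_mean_, self.ref_sd_)
        act = self._activities(np.nan_to_num(z, nan=0.0, posinf=0.0, neginf=0.0))
        return pd.DataFrame(act, index=X.index, columns=self.term_ids_)

    def transform_loo(self, X_healthy: pd.DataFrame) -> pd.DataFrame:
        """Score the *reference* samples with leave-one-out means/SDs."""
        if list(X_healthy.columns) != self.genes_:
            X_healthy = X_healthy[self.genes_]
        values = X_healthy.to_numpy(dtype=float)
        n = values.shape[0]
        if n < 3:
            raise ValueError("leave-one-out reference needs >= 3 healthy samples")
        mean = values.mean(axis=0)
        m2 = ((values - mean) ** 2).sum(axis=0)
        rows = []
        # prediction SD: a held-out sample deviates from the mean of the
        # n-1 reference samples with variance sigma^2 * (1 + 1/(n-1))
        pred_factor = np.sqrt(1.0 + 1.0 / (n - 1))
        for i in range(n):
            loo_mean = (n * mean - values[i]) / (n - 1)
            loo_m2 = m2 - (values[i] - mean) ** 2 * n / (n - 1)
            loo_sd = np.sqrt(np.maximum(loo_m2, 0.0) / (n - 2)) * pred_factor
            z = self._z(values[i : i + 1], loo_mean, loo_sd)
            rows.append(self._activities(np.nan_to_num(z, nan=0.0, posinf=0.0, neginf=0.0))[0])
        return pd.DataFrame(rows, index=X_healthy.index, columns=self.term_ids_)


def ged_activity(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    genesets: GeneSetCollection,
    min_genes: int = 3,
    signed: bool = False,
) -> pd.DataFrame:
    """Term × sample GED activity with a healthy reference.

    Healthy samples are scored against a leave-one-out reference (so the
    null level is unbiased); patient samples use the plug-in reference of
    all healthy samples.
    """
    healthy_ids = [
        s
        for s in matrix.columns
        if s in set(clinical.loc[clinical["state"] == "healthy", "sample_id"])
    ]
    if len(healthy_ids) < 2:
        raise ValueError("need >= 2 healthy samples for the GED reference")
    other_ids = [s for s in matrix.columns if s not in set(healthy_ids)]
    ged = GEDActivity(genesets, min_genes=min_genes, signed=signed)
    healthy_X = matrix[healthy_ids].T
    ged.fit(healthy_X)
    parts = []
    if other_ids:
        parts.append(ged.transform(matrix[other_ids].T))
    if len(healthy_ids) >= 3:
        parts.append(ged.transform_loo(healthy_X))
    else:
        parts.append(ged.transform(healthy_X))
    activity = pd.concat(parts, axis=0).T
    return activity[matrix.columns.intersection(activity.columns)][
        [s for s in matrix.columns if s in activity.columns]
    ]


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrich_terms(
    genes: Iterable[str],
    genesets: GeneSetCollection,
    background: Iterable[str],
    q_max: float = 0.01,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a query gene list.

    For each term: overlap k of the query (size n) with the term's genes
    restricted to the background (size m, universe N); p = P(X ≥ k).
    BH q-values across terms; ``significant`` flags q < q_max.
    """
    background = list(dict.fromkeys(background))
    if not background:
        raise ValueError("empty background")
    bg = set(background)
    query = [g for g in dict.fromkeys(genes)]
    outside = [g for g in query if g not in bg]
    if outside:
        raise ValueError(f"query genes outside background: {outside[:5]}")
    N, n = len(bg), len(query)
    qset = set(query)
    rows = []
    for term in genesets:
        term_bg = term.genes & bg
        m = len(term_bg)
        k = len(term_bg & qset)
        p = stats.hypergeom.sf(k - 1, N, m, n) if m else 1.0
        rows.append((term.term_id, term.module, m, k, min(float(p), 1.0)))
    out = pd.DataFrame(rows, columns=["term_id", "module", "term_size", "overlap", "p_value"])
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["q_value"] < q_max
    return out.set_index("term_id")


# ---------------------------------------------------------------------------
# per-subtype differential genes and module dysregulation
# ---------------------------------------------------------------------------

def subtype_deg(
    matrix: pd.DataFrame,
    labels: pd.Series,
    clinical: pd.DataFrame,
    q_max: float = 0.05,
) -> dict:
    """Per-subtype differential genes versus the healthy controls.

    ``labels`` maps sample_id → subtype.  Each subtype's samples are
    screened against the healthy samples with the ANOVA machinery of the
    signature module; subtypes with < 2 samples are skipped.
    Returns {subtype: result DataFrame}.
    """
    healthy = clinical[clinical["state"] == "healthy"]
    results = {}
    for subtype in sorted(labels.dropna().unique()):
        members = [s for s in labels.index[labels == subtype] if s in matrix.columns]
        if len(members) < 2:
            warnings.warn(f"subtype {subtype!r} has < 2 samples; skipped")
            continue
        cols = members + [s for s in healthy["sample_id"] if s in matrix.columns]
        sub_clin = clinical[clinical["sample_id"].isin(cols)]
        results[subtype] = anova_screen(matrix[cols], sub_clin, q_max)
    return results


def module_profile(
    term_activity: pd.DataFrame,
    genesets: GeneSetCollection,
    labels: pd.Series,
    clinical: pd.DataFrame,
) -> pd.DataFrame:
    """Per (subtype, module) dysregulation relative to healthy.

    Δ = mean activity over the subtype's samples − mean over healthy
    samples, where a sample's module activity is the mean over the
    module's surviving terms.  A Wilcoxon rank-sum test compares the
    subtype's per-sample module activities to healthy, BH-adjusted over
    the whole profile.  Modules with no surviving terms are reported with
    NaN.
    """
    healthy_ids = [
        s
        for s in term_activity.columns
        if s in set(clinical.loc[clinical["state"] == "healthy", "sample_id"])
    ]
    if not healthy_ids:
        raise ValueError("no healthy samples in the activity matrix")
    modules = sorted({t.module for t in genesets if t.module != "none"})
    rows = []
    for subtype in sorted(labels.dropna().unique()):
        members = [s for s in labels.index[labels == subtype] if s in term_activity.columns]
        for module in modules:
            terms = [
                t.term_id for t in genesets.by_module(module) if t.term_id in term_activity.index
            ]
            if not terms or not members:
                rows.append((subtype, module, np.nan, np.nan, 0))
                continue
            sub = term_activity.loc[terms, members].mean(axis=0)
            ref = term_activity.loc[terms, healthy_ids].mean(axis=0)
            delta = float(sub.mean() - ref.mean())
            p = float(stats.mannwhitneyu(sub, ref, alternative="two-sided").pvalue)
            rows.append((subtype, module, delta, p, len(terms)))
    out = pd.DataFrame(rows, columns=["subtype", "module", "delta", "p_value", "n_terms"])
    ok = out["p_value"].notna()
    out["q_value"] = np.nan
    if ok.any():
        out.loc[ok, "q_value"] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# term network
# ---------------------------------------------------------------------------

def term_similarity(term_activity: pd.DataFrame, samples: Optional[Iterable[str]] = None):
    """Pairwise Spearman correlation of term-activity vectors.

    ``samples`` restricts the columns (e.g. to mixed-subtype samples).
    Constant-activity terms get correlation 0 with a warning.  Returns
    ``(similarity DataFrame, n_samples)``.
    """
    if samples is not None:
        cols = [s for s in samples if s in term_activity.columns]
    else:
        cols = list(term_activity.columns)
    if len(cols) < 10:
        raise ValueError("need >= 10 samples for term similarity")
    values = term_activity[cols].to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    ranks = stats.rankdata(values, axis=1, method="average")
    with np.errstate(invalid="ignore"):
        sim = np.corrcoef(ranks)
    sim = np.nan_to_num(sim, nan=0.0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant-activity terms; correlations set to 0"
        )
        sim[constant, :] = 0.0
        sim[:, constant] = 0.0
    np.fill_diagonal(sim, 1.0)
    frame = pd.DataFrame(sim, index=term_activity.index, columns=term_activity.index)
    return frame, len(cols)


def build_network(
    similarity: pd.DataFrame,
    n_samples: int,
    r_min: float = 0.6,
    q_max: float = 0.05,
) -> nx.Graph:
    """Weighted term graph: edge (a, b) iff |r| ≥ r_min and the BH-adjusted
    correlation-test q < q_max (t approximation with the recorded sample
    count); weight = |r|.  Isolated nodes are retained."""
    terms = list(similarity.index)
    G = nx.Graph()
    G.add_nodes_from(terms)
    iu = np.triu_indices(len(terms), k=1)
    r = similarity.to_numpy()[iu]
    df = n_samples - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2 * stats.t.sf(t, df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    for (i, j), rv, qv in zip(zip(*iu), r, q):
        if abs(rv) >= r_min and qv < q_max:
            G.add_edge(terms[i], terms[j], weight=float(abs(rv)))
    return G


def detect_communities(G: nx.Graph):
    """Greedy modularity communities on the weighted graph.

    Returns ``(communities, modularity)`` where ``communities`` maps term
    → community index (ordered by decreasing community size).
    """
    if G.number_of_edges() == 0:
        raise ValueError("graph has no edges; cannot detect communities")
    H = G.subgraph([n for n in G if G.degree(n) > 0])
    comms = nx.algorithms.community.greedy_modularity_communities(H, weight="weight")
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c))
    q = nx.algorithms.community.modularity(H, comms, weight="weight")
    mapping = {}
    for i, c in enumerate(comms):
        for node in c:
            mapping[node] = i
    return mapping, float(q)


def bridge_nodes(G: nx.Graph, communities: dict, top_n: int = 5) -> list:
    """Terms ranked by betweenness over shortest paths whose endpoints lie
    in different communities (edge length = 1/weight).  Returns up to
    ``top_n`` (term, score) pairs with score > 0; a single community
    yields an empty list with a warning."""
    groups = {}
    for node, c in communities.items():
        groups.setdefault(c, []).append(node)
    if len(groups) < 2:
        warnings.warn("only one community; no bridge nodes")
        return []
    H = G.copy()
    for u, v, d in H.edges(data=True):
        d["length"] = 1.0 / max(d.get("weight", 1.0), 1e-12)
    scores = {n: 0.0 for n in H}
    keys = sorted(groups)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            bc = nx.betweenness_centrality_subset(
                H, sources=groups[keys[i]], targets=groups[keys[j]], weight="length"
            )
            for n, v in bc.items():
                scores[n] += v
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(n, s) for n, s in ranked[:top_n] if s > 0]
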