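"""Synthetic longitudinal SLE cohorts with planted ground truth.

The generator emulates the data structure the downstream analysis assumes:
repeated visits per patient with varying visit counts, integer SLEDAI
trajectories, a block of *activity genes* whose expression tracks SLEDAI
within each patient at a calibrated correlation, three latent subtypes
defined by elevation of an IFN gene module, an NE (neutrophil) gene
module, or both ("mixed"), healthy controls, and per-drug effects on the
SLEDAI slope.  Every downstream stage has a parameter-recovery test
against the emitted :class:`GroundTruth`.

The defaults encode the study conditions used throughout the test suite
and the acceptance script; see ``docs/methods.md`` for the rationale of
each value and for what the generator deliberately does **not** emulate
(probe-level structure, batch effects, SLEDAI components).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io import CLINICAL_COLUMNS, GeneSet, GeneSetCollection

__all__ = [
    "SUBTYPES",
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_trial",
    "default_trial_config",
    "planted_genesets",
    "module_panel",
    "generate_module_factor_design",
    "DAYS_PER_MONTH",
]

#: canonical subtype order: most to least severe
SUBTYPES = ("mixed", "IFN-high", "NE-high")

DAYS_PER_MONTH = 30.44


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Conditions of a simulated cohort.

    The primary fields mirror the quantities the analysis is sensitive
    to; the secondary fields below them fix the remaining degrees of
    freedom of the generative model.
    """

    n_patients: int = 60
    visits_min: int = 4
    visits_max: int = 8
    n_healthy: int = 30
    n_genes: int = 2000
    n_activity_genes: int = 50
    ifn_module_size: int = 30
    ne_module_size: int = 30
    #: proportions of (mixed, IFN-high, NE-high) patients
    subtype_props: tuple = (0.34, 0.33, 0.33)
    #: mean log2 shift of an active module's genes in samples of an
    #: elevated subtype
    effect_size: float = 1.5
    #: target within-patient |correlation| of activity genes with SLEDAI
    activity_cor: float = 0.8
    #: fixed log2 offset of activity genes in SLE vs healthy samples (the
    #: disease-state component; the SLEDAI-tracking component is centered
    #: within each patient)
    activity_offset: float = 1.0
    #: per-gene Gaussian noise SD (log2 units)
    noise_sd: float = 0.5
    sledai_range: tuple = (0, 105)
    #: drug -> {subtype -> SLEDAI slope shift per month} for exposed patients
    drug_effects: dict = field(default_factory=dict)
    seed: int = 0

    # --- secondary conditions -------------------------------------------
    #: subtype SLEDAI means, ordered by severity (mixed > IFN-high > NE-high)
    subtype_sledai_mean: dict = field(
        default_factory=lambda: {"mixed": 12.0, "IFN-high": 9.0, "NE-high": 6.0}
    )
    sledai_between_sd: float = 1.5   # patient-level baseline spread
    sledai_within_sd: float = 3.0    # visit-to-visit disease-activity swing
    visit_interval_days: float = 45.0
    visit_jitter_days: float = 5.0
    #: per-sample module activation variability, relative to effect_size
    module_factor_rel_sd: float = 0.2
    #: multiplier on effect_size for the mixed subtype (the mixed type is
    #: the most dysregulated group in every module)
    mixed_boost: float = 1.3
    #: fraction of activity genes drawn from inside the IFN module
    activity_ifn_overlap: float = 0.3
    #: fraction of activity genes drawn from inside the NE module (the
    #: signature is enriched in bacterial/fungal terms as well; without
    #: NE-module members the signature could not separate NE-driven
    #: subtypes)
    activity_ne_overlap: float = 0.2
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    drug_exposure_prob: dict = field(
        default_factory=lambda: {"cs": 0.5, "hc": 0.4, "is": 0.3}
    )

    def validate(self) -> None:
        if abs(sum(self.subtype_props) - 1.0) > 1e-9:
            raise ConfigurationError("subtype_props must sum to 1")
        if len(self.subtype_props) != 3:
            raise ConfigurationError("subtype_props must have 3 entries (mixed, IFN-high, NE-high)")
        if self.ifn_module_size + self.ne_module_size > self.n_genes:
            raise ConfigurationError("module gene sets exceed n_genes")
        if self.n_activity_genes > self.n_genes:
            raise ConfigurationError("n_activity_genes exceeds n_genes")
        if self.visits_min < 1 or self.visits_max < self.visits_min:
            raise ConfigurationError("need 1 <= visits_min <= visits_max")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.n_activity_genes > 0:
            if not 0.0 <= self.activity_cor < 1.0:
                raise ConfigurationError(
                    "activity_cor infeasible: with noise_sd "
                    f"{self.noise_sd} > 0 the attainable range is [0, 1)"
                )


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    subtype_of_patient: dict
    activity_genes: list
    ifn_genes: list
    ne_genes: list
    planted_drug_effects: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# ---------------------------------------------------------------------------
# core generator
# ---------------------------------------------------------------------------

def _allocate_subtypes(n: int, props, rng) -> np.ndarray:
    """Largest-remainder allocation of n patients over the 3 subtypes,
    shuffled so subtype is independent of patient order."""
    raw = np.asarray(props, dtype=float) * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.arange(3), counts)
    rng.shuffle(labels)
    return np.array([SUBTYPES[i] for i in labels])


def _gene_layout(cfg: SimulationConfig):
    width = max(5, len(str(cfg.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(cfg.n_genes)]
    ifn = genes[: cfg.ifn_module_size]
    ne = genes[cfg.ifn_module_size : cfg.ifn_module_size + cfg.ne_module_size]
    n_ov_ifn = min(int(round(cfg.activity_ifn_overlap * cfg.n_activity_genes)), cfg.ifn_module_size)
    n_ov_ne = min(int(round(cfg.activity_ne_overlap * cfg.n_activity_genes)), cfg.ne_module_size)
    n_outside = cfg.n_activity_genes - n_ov_ifn - n_ov_ne
    pool = genes[cfg.ifn_module_size + cfg.ne_module_size :]
    if n_outside > len(pool):
        raise ConfigurationError("not enough genes outside modules for activity genes")
    activity = ifn[:n_ov_ifn] + ne[:n_ov_ne] + pool[:n_outside]
    return genes, ifn, ne, activity


def _generate(cfg: SimulationConfig, *, force_ifnk: bool) -> tuple:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, ifn, ne, activity = _gene_layout(cfg)
    ifn_set, ne_set = set(ifn), set(ne)
    ifn_idx = np.array([g in ifn_set for g in genes])
    ne_idx = np.array([g in ne_set for g in genes])
    act_idx = np.array([g in set(activity) for g in genes])
    act_ifn_idx = act_idx & ifn_idx
    act_ne_idx = act_idx & ne_idx
    act_out_idx = act_idx & ~ifn_idx & ~ne_idx

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    # fixed per-gene correlation sign for activity genes; genes inside a
    # planted module always track positively (module activation and
    # disease activity pull the same way)
    act_signs = np.where(rng.random(cfg.n_genes) < 0.5, 1.0, -1.0)
    act_signs[ifn_idx | ne_idx] = 1.0

    subtype_of = _allocate_subtypes(cfg.n_patients, cfg.subtype_props, rng)
    lo, hi = cfg.sledai_range
    if cfg.n_activity_genes > 0 and cfg.activity_cor > 0:
        cor_ratio = cfg.activity_cor / np.sqrt(1.0 - cfg.activity_cor**2)
    else:
        cor_ratio = 0.0

    def _beta(subtype: str, in_active_module: bool) -> float:
        """Tracking slope so that cor(x, SLEDAI) -> activity_cor given the
        gene's total non-SLEDAI variance (noise + module factor)."""
        var = cfg.noise_sd**2
        if in_active_module:
            boost = cfg.mixed_boost if subtype == "mixed" else 1.0
            var += (cfg.effect_size * boost * cfg.module_factor_rel_sd) ** 2
        return cor_ratio * np.sqrt(var)

    rows = []
    columns = []
    sample_meta = []
    pat_width = max(3, len(str(max(cfg.n_patients, 1))))
    for p in range(cfg.n_patients):
        pid = f"P{p:0{pat_width}d}"
        subtype = subtype_of[p]
        n_v = int(rng.integers(cfg.visits_min, cfg.visits_max + 1))
        if cfg.visit_jitter_days > 0:
            intervals = cfg.visit_interval_days + rng.uniform(
                -cfg.visit_jitter_days, cfg.visit_jitter_days, n_v - 1
            )
        else:
            intervals = np.full(n_v - 1, cfg.visit_interval_days)
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        months = times / DAYS_PER_MONTH

        drugs = {
            d: bool(rng.random() < prob) for d, prob in sorted(cfg.drug_exposure_prob.items())
        }
        drugs.setdefault("cs", False)
        drugs.setdefault("hc", False)
        drugs.setdefault("is", False)
        drugs["ifnk"] = bool(force_ifnk)
        slope = 0.0
        for d, exposed in drugs.items():
            if exposed:
                slope += cfg.drug_effects.get(d, {}).get(subtype, 0.0)

        b_p = rng.normal(0.0, cfg.sledai_between_sd)
        latent = (
            cfg.subtype_sledai_mean[subtype]
            + b_p
            + slope * months
            + rng.normal(0.0, cfg.sledai_within_sd, n_v)
        )
        latent = np.clip(latent, lo, hi)
        sledai = np.rint(latent).astype(int)

        # per-patient slopes calibrated so cor(expression, SLEDAI) -> activity_cor
        sd_p = latent.std(ddof=1) if n_v > 1 else 0.0
        inv_sd = 1.0 / max(sd_p, 0.5)
        active = cfg.effect_size != 0.0
        b_out = _beta(subtype, False) * inv_sd
        b_ifn = _beta(subtype, active and subtype in ("mixed", "IFN-high")) * inv_sd
        b_ne = _beta(subtype, active and subtype in ("mixed", "NE-high")) * inv_sd
        latent_centered = latent - latent.mean()

        for v in range(n_v):
            sid = f"{pid}V{v:02d}"
            x = baseline + rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
            boost = cfg.mixed_boost if subtype == "mixed" else 1.0
            if subtype in ("mixed", "IFN-high") and cfg.effect_size != 0.0:
                shift = cfg.effect_size * boost * (1.0 + rng.normal(0.0, cfg.module_factor_rel_sd))
                x[ifn_idx] += shift
            if subtype in ("mixed", "NE-high") and cfg.effect_size != 0.0:
                shift = cfg.effect_size * boost * (1.0 + rng.normal(0.0, cfg.module_factor_rel_sd))
                x[ne_idx] += shift
            if cfg.n_activity_genes:
                dc = latent_centered[v]
                for mask, b in ((act_out_idx, b_out), (act_ifn_idx, b_ifn), (act_ne_idx, b_ne)):
                    x[mask] += (act_signs * (cfg.activity_offset + b * dc))[mask]
            rows.append(x)
            columns.append(sid)
            sample_meta.append(
                dict(
                    patient_id=pid,
                    sample_id=sid,
                    visit_index=v,
                    time_days=round(float(times[v]), 4),
                    sledai=int(sledai[v]),
                    state="SLE",
                    age_group="pediatric" if rng.random() < 0.5 else "adult",
                    sex="female" if rng.random() < 0.85 else "male",
                    race=["black", "white", "other"][int(rng.integers(0, 3))],
                    drug_cs=drugs["cs"],
                    drug_hc=drugs["hc"],
                    drug_is=drugs["is"],
                    drug_ifnk=drugs["ifnk"],
                    cohort="sim",
                )
            )

    heal_width = max(3, len(str(max(cfg.n_healthy, 1))))
    for h in range(cfg.n_healthy):
        hid = f"H{h:0{heal_width}d}"
        x = baseline + rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
        rows.append(x)
        columns.append(hid + "V00")
        sample_meta.append(
            dict(
                patient_id=hid,
                sample_id=hid + "V00",
                visit_index=0,
                time_days=0.0,
                sledai=0,
                state="healthy",
                age_group="pediatric" if rng.random() < 0.5 else "adult",
                sex="female" if rng.random() < 0.6 else "male",
                race=["black", "white", "other"][int(rng.integers(0, 3))],
                drug_cs=False,
                drug_hc=False,
                drug_is=False,
                drug_ifnk=False,
                cohort="sim",
            )
        )

    if rows:
        values = np.column_stack(rows)
    else:
        values = np.empty((cfg.n_genes, 0))
    expression = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=columns)
    clinical = pd.DataFrame(sample_meta, columns=CLINICAL_COLUMNS)
    truth = GroundTruth(
        subtype_of_patient={
            f"P{p:0{pat_width}d}": subtype_of[p] for p in range(cfg.n_patients)
        },
        activity_genes=list(activity),
        ifn_genes=list(ifn),
        ne_genes=list(ne),
        planted_drug_effects={d: dict(e) for d, e in cfg.drug_effects.items()},
    )
    return expression, clinical, truth


def generate_cohort(config: SimulationConfig):
    """Generate an observational longitudinal cohort.

    Returns ``(expression, clinical, truth)`` where ``expression`` is a
    genes × samples :class:`~pandas.DataFrame`, ``clinical`` a per-visit
    table with the canonical schema, and ``truth`` the planted structure.
    Fully reproducible from ``config.seed``.
    """
    return _generate(config, force_ifnk=False)


def generate_trial(config: SimulationConfig, treatment_effects: Mapping[str, float]):
    """Generate a treated longitudinal trial (IFN-K-style design).

    Every patient is flagged ``drug_ifnk`` and followed at exact monthly
    visits; ``treatment_effects`` maps each subtype to the planted SLEDAI
    slope (score units per month).  Other drug exposures are disabled.
    """
    missing = set(SUBTYPES) - set(treatment_effects)
    if missing:
        raise ConfigurationError(f"treatment_effects missing subtypes: {sorted(missing)}")
    cfg = replace(
        config,
        drug_effects={"ifnk": dict(treatment_effects)},
        visit_interval_days=DAYS_PER_MONTH,
        visit_jitter_days=0.0,
        drug_exposure_prob={"cs": 0.0, "hc": 0.0, "is": 0.0},
    )
    return _generate(cfg, force_ifnk=True)


def default_trial_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Conditions of the repositioning trial: 6 treated patients followed
    over 6 exact monthly visits with damped visit-to-visit SLEDAI swings
    (a controlled trial, unlike the observational cohort)."""
    base = dict(
        n_patients=6,
        visits_min=6,
        visits_max=6,
        n_healthy=0,
        n_genes=60,
        n_activity_genes=0,
        ifn_module_size=10,
        ne_module_size=10,
        subtype_props=(1 / 3, 1 / 3, 1 / 3),
        sledai_within_sd=0.5,
        sledai_between_sd=1.5,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# gene sets over the planted structure
# ---------------------------------------------------------------------------

def module_panel(truth: GroundTruth) -> list:
    """The subtype feature panel: planted module genes excluding the
    activity-tracking genes (the module *program*, whose expression is
    subtype-determined; tracking genes ride disease activity in every
    subtype and only blur the subtype axes)."""
    act = set(truth.activity_genes)
    return [g for g in list(truth.ifn_genes) + list(truth.ne_genes) if g not in act]


def planted_genesets(
    truth: GroundTruth,
    n_terms_per_module: int = 3,
    n_decoys: int = 5,
    genes_per_decoy: int = 10,
    include_bridge: bool = False,
    seed: int = 0,
) -> GeneSetCollection:
    """Build a term collection over the planted modules.

    IFN-module genes are split into ``n_terms_per_module`` terms labelled
    module ``IFN``; NE-module genes into terms labelled alternately
    ``bacterial`` and ``fungal``.  Module terms exclude the
    activity-tracking genes: term activity is meant to read module
    activation, whereas tracking genes ride disease activity in every
    subtype (they appear in decoy terms instead).  Decoy terms draw
    random genes from the remaining pool (module ``none``).  With
    ``include_bridge`` an extra term mixes genes from both planted
    modules (a cross-mechanism term).
    """
    rng = np.random.default_rng(seed)
    terms = []
    act = set(truth.activity_genes)
    ifn_clean = [g for g in truth.ifn_genes if g not in act]
    ne_clean = [g for g in truth.ne_genes if g not in act]

    def split(genes, n):
        genes = list(genes)
        chunks = np.array_split(np.arange(len(genes)), n)
        return [[genes[i] for i in c] for c in chunks if len(c) >= 2]

    for i, chunk in enumerate(split(ifn_clean, n_terms_per_module)):
        terms.append(GeneSet(f"IFN_T{i}", f"interferon response {i}", frozenset(chunk), "IFN"))
    for i, chunk in enumerate(split(ne_clean, n_terms_per_module)):
        module = "bacterial" if i % 2 == 0 else "fungal"
        terms.append(GeneSet(f"NE_T{i}", f"neutrophil response {i}", frozenset(chunk), module))
    if include_bridge:
        k = max(2, min(len(ifn_clean), len(ne_clean), 8) // 2)
        bridge = list(ifn_clean[:k]) + list(ne_clean[:k])
        terms.append(GeneSet("BRIDGE_T", "cross-mechanism term", frozenset(bridge), "immune"))
    planted = set(truth.ifn_genes) | set(truth.ne_genes)
    pool = sorted(set(truth.activity_genes) - planted)
    # decoys may also use genes outside every planted set; caller's matrix
    # restricts what is scoreable, missing genes are dropped downstream
    all_pool = pool + [g for g in truth.activity_genes if g not in pool]
    for j in range(n_decoys):
        if len(all_pool) >= 3:
            sel = list(rng.choice(all_pool, size=min(genes_per_decoy, len(all_pool)), replace=False))
        else:
            sel = list(truth.ifn_genes[:3])
        terms.append(GeneSet(f"DECOY_T{j}", f"decoy term {j}", frozenset(sel), "none"))
    return GeneSetCollection(terms)


# ---------------------------------------------------------------------------
# two-factor term design (co-expression network conditions)
# ---------------------------------------------------------------------------

def generate_module_factor_design(
    n_samples: int = 400,
    n_healthy: int = 40,
    n_terms_per_factor: int = 8,
    genes_per_term: int = 24,
    effect_size: float = 2.0,
    factor_sd: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
):
    """Planted two-factor design for the term co-expression network.

    Emulates the mixed-subtype sample population in which two independent
    pathogenic programs fluctuate from sample to sample: an IFN factor and
    an NE factor, each ``N(0, factor_sd)`` per sample, shift the genes of
    their terms by ``effect_size + factor``.  One bridge term carries genes
    from both factors.  Returns ``(expression, clinical, genesets, truth)``
    where ``truth`` maps each term to its factor ('IFN', 'NE', 'bridge').
    """
    rng = np.random.default_rng(seed)
    n_factor_genes = n_terms_per_factor * genes_per_term
    n_genes = 2 * n_factor_genes
    genes = [f"G{i:05d}" for i in range(n_genes)]
    ifn_genes = genes[:n_factor_genes]
    ne_genes = genes[n_factor_genes:]
    baseline = rng.normal(7.0, 1.0, n_genes)

    # exactly orthogonal factor realizations: the factors are planted as
    # independent, so the design removes their sampling correlation
    f_ifn = rng.normal(0.0, 1.0, n_samples)
    f_ne = rng.normal(0.0, 1.0, n_samples)
    f_ifn = f_ifn - f_ifn.mean()
    f_ne = f_ne - f_ne.mean()
    f_ne = f_ne - (f_ifn @ f_ne) / (f_ifn @ f_ifn) * f_ifn
    f_ifn = f_ifn / f_ifn.std() * factor_sd
    f_ne = f_ne / f_ne.std() * factor_sd
    cols, meta = [], []
    values = []
    for s in range(n_samples):
        x = baseline + rng.normal(0.0, noise_sd, n_genes)
        x[:n_factor_genes] += effect_size + f_ifn[s]
        x[n_factor_genes:] += effect_size + f_ne[s]
        sid = f"M{s:04d}V00"
        values.append(x)
        cols.append(sid)
        meta.append((f"M{s:04d}", sid, "SLE", 8))
    for h in range(n_healthy):
        x = baseline + rng.normal(0.0, noise_sd, n_genes)
        sid = f"H{h:04d}V00"
        values.append(x)
        cols.append(sid)
        meta.append((f"H{h:04d}", sid, "healthy", 0))

    expression = pd.DataFrame(
        np.column_stack(values), index=pd.Index(genes, name="gene"), columns=cols
    )
    clinical = pd.DataFrame(
        [
            dict(
                patient_id=pid,
                sample_id=sid,
                visit_index=0,
                time_days=0.0,
                sledai=sledai,
                state=state,
                age_group="adult",
                sex="female",
                race="white",
                drug_cs=False,
                drug_hc=False,
                drug_is=False,
                drug_ifnk=False,
                cohort="factor",
            )
            for pid, sid, state, sledai in meta
        ],
        columns=CLINICAL_COLUMNS,
    )

    terms, truth = [], {}
    for i in range(n_terms_per_factor):
        chunk = ifn_genes[i * genes_per_term : (i + 1) * genes_per_term]
        terms.append(GeneSet(f"IFN_T{i}", f"interferon term {i}", frozenset(chunk), "IFN"))
        truth[f"IFN_T{i}"] = "IFN"
    for i in range(n_terms_per_factor):
        chunk = ne_genes[i * genes_per_term : (i + 1) * genes_per_term]
        module = "bacterial" if i % 2 == 0 else "fungal"
        terms.append(GeneSet(f"NE_T{i}", f"neutrophil term {i}", frozenset(chunk), module))
        truth[f"NE_T{i}"] = "NE"
    half = genes_per_term // 2
    bridge = ifn_genes[:half] + ne_genes[:half]
    terms.append(GeneSet("BRIDGE_T", "cross-mechanism term", frozenset(bridge), "immune"))
    truth["BRIDGE_T"] = "bridge"
    return expression, clinical, GeneSetCollection(terms), truth
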