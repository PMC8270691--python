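"""Pipeline configuration: one YAML file holds every tunable threshold.

Defaults reproduce the documented analysis settings; any subset can be
overridden from a user YAML passed to the CLI via ``--config``.
"""

from __future__ import annotations

import copy

import yaml

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS = {
    "preprocess": {
        "sd_min": 0.1,
        "sd_filter_first": False,
        "split_ratio": [2, 1],
    },
    "signature": {
        "q_max": 0.05,
        "score_min": 0.6,
        "method": "spearman",  # or "pearson"
        "min_visits": 3,
        "n_perm": 1000,
        "perm_scheme": "both",  # rows | columns | both
        "n_random": 1000,
        "weighting": "visits",  # visits | uniform | sqrt
    },
    "ssc": {
        "k": "auto",
        "k_range": [2, 6],
        "max_iter": 50,
        "tol": 0.01,
        "gap_b": 50,
    },
    "functional": {
        "min_genes": 3,
        "signed": False,
        "enrich_q_max": 0.01,
        "r_min": 0.6,
        "edge_q_max": 0.05,
        "top_bridges": 5,
    },
    "treatment": {
        "value": "rate",  # rate | delta_total
        "drugs": ["cs", "hc", "is"],
    },
}


def load_config(path=None) -> dict:
    """Merge a user YAML over the defaults (two-level deep merge)."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if section in cfg and isinstance(values, dict):
                cfg[section].update(values)
            else:
                cfg[section] = values
    return cfg
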