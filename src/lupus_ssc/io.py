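"""Readers, writers and validated in-memory containers.

Conventions
-----------
* Expression matrices are **gene-major** on disk and in memory (genes as
  rows, samples as columns), matching the GEO series-matrix layout.  They
  are held as :class:`pandas.DataFrame` with the gene symbol as index and
  the sample identifier as column.  Values are log2-scale intensities.
* The clinical table is a plain CSV with one row per visit and the fixed
  schema in :data:`CLINICAL_COLUMNS`.  Missing SLEDAI is an empty cell,
  never 0 (0 is a valid score).
* Gene sets use the tab-delimited GMT format; an optional two-column
  ``term_id<TAB>module`` map attaches each term to one of the five
  functional modules (viral, bacterial, fungal, IFN, immune).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CLINICAL_COLUMNS",
    "MODULES",
    "GeneSet",
    "GeneSetCollection",
    "ParseError",
    "SchemaError",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "validate_clinical",
    "read_gmt",
    "write_gmt",
]

#: required columns of the clinical CSV, in canonical order
CLINICAL_COLUMNS = [
    "patient_id",
    "sample_id",
    "visit_index",
    "time_days",
    "sledai",
    "state",
    "age_group",
    "sex",
    "race",
    "drug_cs",
    "drug_hc",
    "drug_is",
    "drug_ifnk",
    "cohort",
]

DRUG_COLUMNS = ["drug_cs", "drug_hc", "drug_is", "drug_ifnk"]

#: the five functional modules plus the unassigned sentinel
MODULES = ("viral", "bacterial", "fungal", "IFN", "immune", "none")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class SchemaError(ValueError):
    """A table violates the documented schema or an invariant."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _check_sample_header(samples, path) -> None:
    cleaned = [s.strip('"') for s in samples]
    seen = set()
    for s in cleaned:
        if s in seen:
            raise ParseError(f"{path}: duplicated sample column {s!r} in header")
        seen.add(s)
    if not cleaned:
        raise ParseError(f"{path}: malformed header (no sample columns)")


def _finalize_expression(frame: pd.DataFrame, path) -> pd.DataFrame:
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicated sample column {dup!r}")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        # locate the first offending cell for the error message
        for j, col in enumerate(frame.columns):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ParseError(
                    f"{path}: non-numeric value {frame.iloc[i, j]!r} at "
                    f"gene row {frame.index[i]!r}, sample column {col!r}"
                ) from exc
        raise ParseError(f"{path}: non-numeric values in matrix") from exc
    if not np.isfinite(values).all():
        raise ParseError(f"{path}: non-finite values in matrix")
    out = pd.DataFrame(values, index=frame.index.astype(str), columns=frame.columns.astype(str))
    out.index.name = "gene"
    return out


def read_expression(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a genes × samples expression matrix.

    Parameters
    ----------
    path : path-like
        File to read.
    dialect : {"tsv", "series_matrix"}
        ``tsv``: first column gene symbols, header row sample ids.
        ``series_matrix``: GEO-like text; lines starting with ``!`` are
        metadata and the table sits between the ``!series_matrix_table_begin``
        and ``!series_matrix_table_end`` markers (markers optional — any
        non-``!`` block is accepted).

    Duplicate *gene* rows are preserved (merging duplicates is a
    preprocessing step); duplicate *sample* columns are an error.
    """
    path = Path(path)
    if dialect == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        _check_sample_header(header[1:], path)
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif dialect == "series_matrix":
        lines = []
        with open(path) as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line or line.startswith("!"):
                    continue
                lines.append(line)
        if not lines:
            raise ParseError(f"{path}: no table found between metadata lines")
        _check_sample_header(lines[0].split("\t")[1:], path)
        from io import StringIO

        frame = pd.read_csv(StringIO("\n".join(lines)), sep="\t", index_col=0, dtype=str)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if frame.columns.size == 0:
        raise ParseError(f"{path}: malformed header (no sample columns)")
    # strip GEO-style quoting
    frame.index = frame.index.astype(str).str.strip('"')
    frame.columns = frame.columns.astype(str).str.strip('"')
    return _finalize_expression(frame, path)


def write_expression(frame: pd.DataFrame, path) -> None:
    """Write a genes × samples matrix as TSV (gene symbols in column 1)."""
    frame = frame.copy()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a clinical table.

    Rows are re-sorted by ``time_days`` within each patient and
    ``visit_index`` reassigned 0..n-1; healthy rows must carry SLEDAI 0
    (or missing); ``sample_id`` must be unique.
    """
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"clinical table missing required columns: {missing}")
    table = table[CLINICAL_COLUMNS].copy()
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"duplicate sample_id {dup!r}")
    table["sledai"] = pd.to_numeric(table["sledai"], errors="coerce")
    table["time_days"] = pd.to_numeric(table["time_days"], errors="raise")
    bad_state = set(table["state"]) - {"SLE", "healthy"}
    if bad_state:
        raise SchemaError(f"unknown state values: {sorted(bad_state)}")
    healthy = table["state"] == "healthy"
    bad = healthy & table["sledai"].notna() & (table["sledai"] != 0)
    if bad.any():
        sid = table.loc[bad, "sample_id"].iloc[0]
        raise SchemaError(f"healthy sample {sid!r} has nonzero SLEDAI")
    ok = table["sledai"].isna() | ((table["sledai"] >= 0) & (table["sledai"] <= 105))
    if not ok.all():
        sid = table.loc[~ok, "sample_id"].iloc[0]
        raise SchemaError(f"sample {sid!r} has SLEDAI outside [0, 105]")
    for col in DRUG_COLUMNS:
        table[col] = table[col].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False,
             "1": True, "0": False, "true": True, "false": False}
        )
        if table[col].isna().any():
            raise SchemaError(f"column {col} must be boolean")
        table[col] = table[col].astype(bool)
    if (table.loc[healthy, DRUG_COLUMNS].to_numpy() != False).any():  # noqa: E712
        raise SchemaError("healthy samples must not carry drug flags")
    # canonical per-patient ordering
    table = table.sort_values(["patient_id", "time_days"], kind="stable").reset_index(drop=True)
    table["visit_index"] = table.groupby("patient_id", sort=False).cumcount()
    return table


def read_clinical(path) -> pd.DataFrame:
    """Read and validate the per-visit clinical CSV.

    Unparseable SLEDAI cells become NaN (missing); exclusion of patients
    with missing fields is handled in :mod:`lupus_ssc.preprocess`.
    """
    table = pd.read_csv(path, dtype={"patient_id": str, "sample_id": str, "cohort": str})
    return validate_clinical(table)


def write_clinical(table: pd.DataFrame, path) -> None:
    table = table[CLINICAL_COLUMNS]
    table.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    term_id: str
    term_name: str
    genes: frozenset
    module: str = "none"

    def __post_init__(self):
        if not self.genes:
            raise ParseError(f"term {self.term_id!r} has an empty gene set")
        if self.module not in MODULES:
            raise SchemaError(f"term {self.term_id!r}: unknown module {self.module!r}")


@dataclass
class GeneSetCollection:
    """An ordered collection of functional terms with module labels."""

    terms: list = field(default_factory=list)

    def __post_init__(self):
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate term_id in gene-set collection")

    def __iter__(self):
        return iter(self.terms)

    def __len__(self):
        return len(self.terms)

    def __getitem__(self, term_id: str) -> GeneSet:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)

    @property
    def term_ids(self) -> list:
        return [t.term_id for t in self.terms]

    def by_module(self, module: str) -> list:
        return [t for t in self.terms if t.module == module]

    def subset(self, term_ids: Iterable[str]) -> "GeneSetCollection":
        keep = set(term_ids)
        return GeneSetCollection([t for t in self.terms if t.term_id in keep])

    def with_modules(self, module_map: Mapping[str, str]) -> "GeneSetCollection":
        return GeneSetCollection(
            [
                GeneSet(t.term_id, t.term_name, t.genes, module_map.get(t.term_id, t.module))
                for t in self.terms
            ]
        )


def read_gmt(path, module_map=None) -> GeneSetCollection:
    """Read a GMT file; ``module_map`` is an optional two-column TSV
    (``term_id<TAB>module``) attaching functional-module labels."""
    terms = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs ≥3 tab-separated fields")
            term_id, name, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: term {term_id!r} has no genes")
            terms.append(GeneSet(term_id, name, frozenset(genes)))
    coll = GeneSetCollection(terms)
    if module_map is not None:
        mapping = {}
        with open(module_map) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError(f"{module_map}:{lineno}: expected term_id<TAB>module")
                mapping[parts[0]] = parts[1]
        coll = coll.with_modules(mapping)
    return coll


def write_gmt(collection: GeneSetCollection, path, module_map_path=None) -> None:
    with open(path, "w") as fh:
        for t in collection:
            fh.write("\t".join([t.term_id, t.term_name, *sorted(t.genes)]) + "\n")
    if module_map_path is not None:
        with open(module_map_path, "w") as fh:
            for t in collection:
                fh.write(f"{t.term_id}\t{t.module}\n")


# ---------------------------------------------------------------------------
# small JSON helpers (model persistence lives in lupus_ssc.ssc)
# ---------------------------------------------------------------------------

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
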