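"""Readers and writers for the tab-delimited interchange formats.

Formats
-------
expression matrix   TSV, first column ``probe_set``, remaining columns samples
sample map          TSV ``sample<TAB>tissue[<TAB>replicate]``
vocabulary          TSV ``source_term<TAB>group_term`` (empty group = drop)
probe map           TSV ``probe_set<TAB>gene``
training set        TSV ``gene<TAB>class`` with class ``specific:<tissue>``
                    or ``ubiquitous``
results             TSV summary + long-format per-tissue companion table
parameters          YAML with the flat keys h_max, spm1, spm2, g_min, sp_min,
                    d_min, c, bf1, bf2, n_draws, seed
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    Call,
    Category,
    DataError,
    ExpressionDataset,
    GeneResult,
    ProbeGeneMap,
    TrainingSet,
    ValidationError,
    VocabularyMap,
    normalize_term,
)

__all__ = [
    "read_expression_dataset",
    "write_expression_dataset",
    "read_vocabulary",
    "read_probe_gene_map",
    "write_probe_gene_map",
    "read_training_set",
    "write_training_set",
    "group_tissues",
    "write_results",
    "read_call_table",
    "write_call_table",
    "load_params",
    "save_params",
]

PARAM_KEYS = (
    "h_max",
    "spm1",
    "spm2",
    "g_min",
    "sp_min",
    "d_min",
    "c",
    "bf1",
    "bf2",
    "n_draws",
    "seed",
)


# ---------------------------------------------------------------------------
# expression data
# ---------------------------------------------------------------------------

def read_expression_dataset(
    matrix_path: str | Path,
    sample_map_path: str | Path,
    dataset_id: str | None = None,
) -> ExpressionDataset:
    """Read a log2 expression matrix plus its sample->tissue map.

    Samples present in the matrix but absent from the map are dropped with a
    warning; duplicate probe sets and non-numeric cells raise ``DataError``.
    """
    matrix_path = Path(matrix_path)
    raw = pd.read_csv(matrix_path, sep="\t", dtype=str)
    if raw.columns[0] != "probe_set":
        raise DataError(
            f"{matrix_path}: first column must be 'probe_set', got {raw.columns[0]!r}"
        )
    raw = raw.set_index("probe_set")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise DataError(f"{matrix_path}: duplicate probe set id {dup!r}")
    try:
        matrix = raw.astype(float)
    except ValueError:
        for col in raw.columns:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            if coerced.isna().any():
                probe = raw.index[coerced.isna().to_numpy().nonzero()[0][0]]
                raise DataError(
                    f"{matrix_path}: non-numeric value at probe {probe!r}, sample {col!r}"
                ) from None
        raise  # pragma: no cover - unreachable

    sample_map = pd.read_csv(
        sample_map_path, sep="\t", dtype=str, header=0
    )
    if sample_map.shape[1] < 2:
        raise DataError(f"{sample_map_path}: expected columns sample, tissue[, replicate]")
    sample_tissue = dict(
        zip(sample_map.iloc[:, 0].astype(str), sample_map.iloc[:, 1].astype(str))
    )
    unmapped = [c for c in matrix.columns if str(c) not in sample_tissue]
    if unmapped:
        warnings.warn(
            f"{matrix_path.name}: dropping {len(unmapped)} sample(s) absent from "
            f"the sample map: {unmapped}",
            stacklevel=2,
        )
        matrix = matrix.drop(columns=unmapped)
    if dataset_id is None:
        dataset_id = matrix_path.stem
    return ExpressionDataset(dataset_id, matrix, sample_tissue)


def write_expression_dataset(dataset: ExpressionDataset, matrix_path, sample_map_path):
    """Write a dataset back to the TSV pair (round-trips bit-exactly)."""
    out = dataset.matrix.copy()
    out.index.name = "probe_set"
    out.to_csv(matrix_path, sep="\t", float_format="%.17g")
    rows = [
        {"sample": str(c), "tissue": dataset.sample_tissue[str(c)]}
        for c in dataset.matrix.columns
    ]
    pd.DataFrame(rows).to_csv(sample_map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# vocabulary grouping
# ---------------------------------------------------------------------------

def read_vocabulary(path: str | Path) -> VocabularyMap:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected columns source_term, group_term")
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    return VocabularyMap(mapping)


def group_tissues(dataset: ExpressionDataset, vocab: VocabularyMap) -> ExpressionDataset:
    """Merge tissues sharing a group term; drop out-of-scope tissues.

    For a replicate-free dataset the merged column is the element-wise
    maximum over the grouped columns (the grouped tissue is represented by
    its strongest signal).  For a replicate-bearing dataset the samples of
    grouped tissues are pooled under the group term, preserving the
    replicate structure.
    """
    replicated = any(n >= 2 for n in dataset.replicates_per_tissue.values())

    # group term (normative spelling) per original tissue; None = drop
    grouped_term: dict[str, str | None] = {}
    group_spelling: dict[str, str] = {}
    for t in dataset.tissue_panel:
        g = vocab.apply(t)
        if g is not None:
            g = group_spelling.setdefault(normalize_term(g), g)
        grouped_term[t] = g

    new_sample_tissue: dict[str, str] = {}
    if replicated:
        keep_cols: list[str] = []
        for col in dataset.matrix.columns:
            tissue = dataset.sample_tissue[str(col)]
            g = grouped_term.get(tissue, vocab.apply(tissue))
            if g is None:
                continue
            keep_cols.append(col)
            new_sample_tissue[str(col)] = g
        new_matrix = dataset.matrix[keep_cols]
    else:
        cols_by_group: dict[str, list[str]] = {}
        for t in dataset.tissue_panel:
            g = grouped_term[t]
            if g is None:
                continue
            cols_by_group.setdefault(g, []).extend(dataset._cols_by_tissue[t])
        data = {}
        for g, cols in cols_by_group.items():
            data[g] = dataset.matrix[cols].max(axis=1)
            new_sample_tissue[g] = g
        new_matrix = pd.DataFrame(data, index=dataset.matrix.index)

    n_tissues = len({normalize_term(t) for t in new_sample_tissue.values()})
    if n_tissues < 3:
        raise ValidationError(
            f"grouping leaves {n_tissues} tissue(s) in {dataset.dataset_id!r}; "
            "at least 3 are required"
        )
    return ExpressionDataset(dataset.dataset_id, new_matrix, new_sample_tissue)


# ---------------------------------------------------------------------------
# probe maps and training sets
# ---------------------------------------------------------------------------

def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected columns probe_set, gene")
    probes = df.iloc[:, 0].astype(str)
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise DataError(f"{path}: probe set {dup!r} maps to more than one gene")
    return ProbeGeneMap(dict(zip(probes, df.iloc[:, 1].astype(str))))


def write_probe_gene_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    rows = sorted(pmap.probe_to_gene.items())
    pd.DataFrame(rows, columns=["probe_set", "gene"]).to_csv(path, sep="\t", index=False)


def read_training_set(path: str | Path, name: str | None = None) -> TrainingSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected columns gene, class")
    positives: dict[str, str] = {}
    negatives: set[str] = set()
    for gene, cls in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        cls = cls.strip()
        if cls.startswith("specific:"):
            positives[gene] = cls.split(":", 1)[1].strip()
        elif cls == "ubiquitous":
            negatives.add(gene)
        else:
            raise DataError(
                f"{path}: class for gene {gene!r} must be 'specific:<tissue>' "
                f"or 'ubiquitous', got {cls!r}"
            )
    return TrainingSet(positives, negatives, name=name or Path(path).stem)


def write_training_set(training: TrainingSet, path: str | Path) -> None:
    rows = [(g, f"specific:{t}") for g, t in sorted(training.positives.items())]
    rows += [(g, "ubiquitous") for g in sorted(training.negatives)]
    pd.DataFrame(rows, columns=["gene", "class"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# call tables and results
# ---------------------------------------------------------------------------

def write_call_table(calls: Mapping[str, Call], path: str | Path) -> None:
    """Per-probe-set call table: probe_set, source, category, tissue1, tissue2."""
    rows = []
    for probe in sorted(calls):
        call = calls[probe]
        t1 = call.tissues[0] if call.tau >= 1 else "."
        t2 = call.tissues[1] if call.tau >= 2 else "."
        rows.append((probe, call.source, call.category.value, t1, t2))
    pd.DataFrame(
        rows, columns=["probe_set", "source", "category", "tissue1", "tissue2"]
    ).to_csv(path, sep="\t", index=False)


def read_call_table(path: str | Path) -> dict[str, Call]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, Call] = {}
    for _, row in df.iterrows():
        cat = Category(row["category"])
        tissues = tuple(t for t in (row["tissue1"], row["tissue2"]) if t != ".")
        out[row["probe_set"]] = Call(cat, tissues, row.get("source", ""))
    return out


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def write_results(results: Sequence[GeneResult], path: str | Path) -> None:
    """Write the gene summary table plus a long-format per-tissue companion.

    Rows are sorted by gene name; the companion file (``<stem>_tissue_scores``)
    holds one row per (gene, tissue) with the total score, sorted by gene then
    tissue.
    """
    if not results:
        raise ValidationError("write_results requires a non-empty result list")
    path = Path(path)
    rows = []
    for r in sorted(results, key=lambda r: r.gene):
        t1 = r.tissues[0] if len(r.tissues) >= 1 else "."
        t2 = r.tissues[1] if len(r.tissues) >= 2 else "."
        rows.append(
            (
                r.gene,
                r.category.value,
                t1,
                t2,
                _fmt(r.score),
                r.support,
                r.coverage[0],
                r.coverage[1],
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "gene",
            "category",
            "tissue1",
            "tissue2",
            "score",
            "support",
            "coverage_present",
            "coverage_total",
        ],
    ).to_csv(path, sep="\t", index=False)

    long_rows = []
    for r in sorted(results, key=lambda r: r.gene):
        for tissue in sorted(r.total_scores):
            long_rows.append((r.gene, tissue, _fmt(r.total_scores[tissue])))
    companion = path.with_name(path.stem + "_tissue_scores" + path.suffix)
    pd.DataFrame(long_rows, columns=["gene", "tissue", "total_score"]).to_csv(
        companion, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# parameter files
# ---------------------------------------------------------------------------

def save_params(params: Mapping[str, object], path: str | Path) -> None:
    """Serialize a flat parameter mapping (the canonical key set) to YAML."""
    unknown = set(params) - set(PARAM_KEYS)
    if unknown:
        raise ValidationError(f"unknown parameter keys: {sorted(unknown)}")
    with open(path, "w") as fh:
        yaml.safe_dump({k: params[k] for k in PARAM_KEYS if k in params}, fh)


def load_params(path: str | Path) -> dict[str, object]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise DataError(f"{path}: expected a mapping of parameter keys")
    unknown = set(data) - set(PARAM_KEYS)
    if unknown:
        raise DataError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return data
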