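"""Domain types shared across the pipeline.

The vocabulary follows the tissue-specificity literature: a gene is
*specific* when preferentially expressed in exactly one tissue,
*2-selective* when preferentially expressed in exactly two, and
*ubiquitous* otherwise.  A microarray platform measures genes through one
or more *probe sets*, which may disagree with each other.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "DataError",
    "Category",
    "Call",
    "ExpressionDataset",
    "VocabularyMap",
    "ProbeGeneMap",
    "TissueScore",
    "GeneResult",
    "TrainingSet",
    "normalize_term",
]


class ValidationError(ValueError):
    """Inputs violate a structural precondition (bad config, bad shapes)."""


class DataError(ValueError):
    """Data content is unusable (duplicates, non-numeric, missing values)."""


def normalize_term(term: str) -> str:
    """Canonical comparison key for a tissue term: trimmed, case-folded."""
    return str(term).strip().casefold()


class Category(str, enum.Enum):
    SPECIFIC = "SPECIFIC"
    TWO_SELECTIVE = "TWO_SELECTIVE"
    UBIQUITOUS = "UBIQUITOUS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Call:
    """One verdict for one probe set (or one consolidated verdict).

    ``tissues`` holds 1 tissue for a SPECIFIC call, 2 distinct tissues for a
    TWO_SELECTIVE call and none for UBIQUITOUS.  ``tau`` (the number of
    tissues identified) is the quantity penalised during training.
    """

    category: Category
    tissues: tuple[str, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        expected = {
            Category.SPECIFIC: 1,
            Category.TWO_SELECTIVE: 2,
            Category.UBIQUITOUS: 0,
        }[self.category]
        if len(self.tissues) != expected:
            raise ValidationError(
                f"{self.category.value} call must name {expected} tissue(s), "
                f"got {self.tissues!r}"
            )
        if self.category is Category.TWO_SELECTIVE:
            a, b = (normalize_term(t) for t in self.tissues)
            if a == b:
                raise ValidationError(
                    f"2-selective call must name two distinct tissues, got {self.tissues!r}"
                )

    @property
    def tau(self) -> int:
        return len(self.tissues)

    @property
    def tissue_keys(self) -> tuple[str, ...]:
        return tuple(normalize_term(t) for t in self.tissues)

    # -- constructors ----------------------------------------------------
    @staticmethod
    def specific(tissue: str, source: str = "") -> "Call":
        return Call(Category.SPECIFIC, (tissue,), source)

    @staticmethod
    def two_selective(t1: str, t2: str, source: str = "") -> "Call":
        return Call(Category.TWO_SELECTIVE, (t1, t2), source)

    @staticmethod
    def ubiquitous(source: str = "") -> "Call":
        return Call(Category.UBIQUITOUS, (), source)


class ExpressionDataset:
    """One platform's log2-intensity matrix with a tissue assignment.

    Parameters
    ----------
    dataset_id
        Short name of the data source.
    matrix
        probe_set x sample DataFrame of finite log2-scale intensities.
    sample_tissue
        Mapping sample id -> tissue term; every matrix column must appear.
    """

    def __init__(
        self,
        dataset_id: str,
        matrix: pd.DataFrame,
        sample_tissue: Mapping[str, str],
    ) -> None:
        self.dataset_id = str(dataset_id)
        self.matrix = matrix.rename_axis(index=None)
        self.sample_tissue = {str(k): str(v).strip() for k, v in sample_tissue.items()}
        self._validate()
        # tissue_panel preserves first-seen column order; it also defines the
        # deterministic tie-break order used by the detectors.
        panel: list[str] = []
        seen: set[str] = set()
        for col in matrix.columns:
            t = self.sample_tissue[str(col)]
            key = normalize_term(t)
            if key not in seen:
                seen.add(key)
                panel.append(t)
        self.tissue_panel: list[str] = panel
        self._cols_by_tissue: dict[str, list[str]] = {t: [] for t in panel}
        key_to_term = {normalize_term(t): t for t in panel}
        for col in matrix.columns:
            term = key_to_term[normalize_term(self.sample_tissue[str(col)])]
            self._cols_by_tissue[term].append(col)
        if len(self.tissue_panel) < 3:
            raise ValidationError(
                f"dataset {self.dataset_id!r} has {len(self.tissue_panel)} tissues; "
                "at least 3 are required"
            )

    def _validate(self) -> None:
        if self.matrix.index.has_duplicates:
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise DataError(f"duplicate probe set id {dup!r} in dataset {self.dataset_id!r}")
        missing = [c for c in self.matrix.columns if str(c) not in self.sample_tissue]
        if missing:
            raise ValidationError(
                f"samples without tissue assignment in {self.dataset_id!r}: {missing}"
            )
        values = self.matrix.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError(f"non-numeric values in dataset {self.dataset_id!r}")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite intensity at probe {self.matrix.index[bad[0]]!r}, "
                f"sample {self.matrix.columns[bad[1]]!r} in {self.dataset_id!r}"
            )

    # -- derived structure ------------------------------------------------
    @property
    def replicates_per_tissue(self) -> dict[str, int]:
        return {t: len(cols) for t, cols in self._cols_by_tissue.items()}

    @property
    def has_replicates(self) -> bool:
        """True when every tissue carries >= 2 samples (Bayes requirement)."""
        return all(n >= 2 for n in self.replicates_per_tissue.values())

    @property
    def probe_sets(self) -> list[str]:
        return [str(p) for p in self.matrix.index]

    def tissue_means(self, probe_set: str) -> np.ndarray:
        """Per-tissue mean log2 intensity, ordered as ``tissue_panel``."""
        row = self.matrix.loc[probe_set]
        return np.array(
            [row[self._cols_by_tissue[t]].mean() for t in self.tissue_panel], dtype=float
        )

    def replicate_values(self, probe_set: str) -> dict[str, np.ndarray]:
        row = self.matrix.loc[probe_set]
        return {
            t: row[cols].to_numpy(dtype=float) for t, cols in self._cols_by_tissue.items()
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionDataset({self.dataset_id!r}, {self.matrix.shape[0]} probe sets, "
            f"{len(self.tissue_panel)} tissues, {self.matrix.shape[1]} samples)"
        )


@dataclass
class VocabularyMap:
    """Tissue-vocabulary grouping: source term -> group term.

    Terms without an entry pass through unchanged; an empty group term marks
    the source tissue as out of scope (dropped).
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized: dict[str, str] = {}
        for src, grp in self.mapping.items():
            key = normalize_term(src)
            grp = str(grp).strip()
            if key in normalized and normalized[key] != grp:
                raise ValidationError(
                    f"vocabulary maps {src!r} to both {normalized[key]!r} and {grp!r}"
                )
            normalized[key] = grp
        self._norm = normalized

    def apply(self, term: str) -> str | None:
        """Group term for ``term`` (None = out of scope, dropped)."""
        grp = self._norm.get(normalize_term(term), term)
        return grp if grp != "" else None


@dataclass
class ProbeGeneMap:
    """probe set -> gene symbol for one platform."""

    probe_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        self.probe_to_gene = {str(p): str(g) for p, g in self.probe_to_gene.items()}

    @property
    def gene_to_probes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for p, g in self.probe_to_gene.items():
            out.setdefault(g, []).append(p)
        for g in out:
            out[g].sort()
        return out

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.probe_to_gene.values()))


@dataclass
class TissueScore:
    """Per-tissue evidence scores for one gene (inner or total scope)."""

    gene: str
    scope: str  # "inner:<dataset>" or "total"
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, s in self.scores.items():
            if not (0.0 <= s <= 1.0 + 1e-12):
                raise ValidationError(f"score {s} for tissue {t!r} outside [0, 1]")

    def top(self, k: int = 1) -> list[tuple[str, float]]:
        """Top-k (tissue, score) pairs; ties broken alphabetically."""
        ordered = sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return ordered[:k]


@dataclass
class GeneResult:
    """Final verdict for one gene across all datasets."""

    gene: str
    category: Category
    tissues: tuple[str, ...]
    total_scores: dict[str, float]
    score: float
    support: str
    coverage: tuple[int, int]

    def __post_init__(self) -> None:
        present, total = self.coverage
        if present > total:
            raise ValidationError(
                f"coverage {present}/{total} invalid for gene {self.gene!r}"
            )


@dataclass
class TrainingSet:
    """Annotated training genes: specific (gene -> tissue) and ubiquitous."""

    positives: dict[str, str]
    negatives: set[str] = field(default_factory=set)
    name: str = "training"

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValidationError(
                f"genes in both positive and negative sets: {sorted(overlap)}"
            )

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.positives) | set(self.negatives))

    def truth(self, gene: str) -> str:
        if gene in self.positives:
            return "specific"
        if gene in self.negatives:
            return "ubiquitous"
        raise KeyError(gene)
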