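"""Parameter optimisation on training genes and cross-set evaluation.

The objective is the penalty sum over annotated training genes: a method
should identify exactly one tissue for each specific training gene and no
tissue for each ubiquitous one.  A grid search over the method's thresholds
minimises the sum; robustness is assessed by training on one gene set and
testing on the others (an all-against-all agreement matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .consensus import consensus_vote
from .datatypes import (
    Call,
    Category,
    ExpressionDataset,
    ProbeGeneMap,
    TrainingSet,
    ValidationError,
    normalize_term,
)
from .detectors import BayesDetector, make_detector
from .pipeline import run_study
from .scoring import SUPPORT_BELOW, dataset_call

__all__ = ["penalty", "OptimizationResult", "grid_search", "cross_evaluate"]


def penalty(call: Call, truth: str) -> int:
    """Per-gene penalty: |tau - 1| for specific genes, tau for ubiquitous.

    tau is the number of tissues the method identified; the objective is
    zero exactly when every specific training gene receives one tissue and
    every ubiquitous gene receives none.
    """
    if truth == "specific":
        return abs(call.tau - 1)
    if truth == "ubiquitous":
        return call.tau
    raise ValidationError(f"truth must be 'specific' or 'ubiquitous', got {truth!r}")


@dataclass
class OptimizationResult:
    """Outcome of a grid search for one method on one dataset."""

    method: str
    dataset_id: str
    params: object
    objective: float
    per_gene_penalty: dict[str, int] = field(default_factory=dict)
    grid_size: int = 0

    def report(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "penalty": p} for g, p in sorted(self.per_gene_penalty.items())
        ]
        return pd.DataFrame(rows)


def _gene_call(calls: Sequence[Call]) -> Call:
    """Consolidate a training gene's probe-set calls into one call."""
    if len(calls) == 1:
        return calls[0]
    if 2 <= len(calls) <= 3:
        return consensus_vote(calls)
    return dataset_call(calls)


def grid_search(
    method,
    dataset: ExpressionDataset,
    probe_map: ProbeGeneMap,
    training: TrainingSet,
    grid: Sequence[object] | None = None,
    spm_scale: str = "linear",
    seed: int = 0,
) -> OptimizationResult:
    """Minimise the penalty sum over a finite parameter grid.

    ``method`` is a detector name or detector object.  Every training gene
    must have at least one probe set in the dataset.  Ties keep the first
    minimum in grid order (default grids list stricter settings first, so
    the most permissive tying setting is never preferred).
    """
    detector = make_detector(method, spm_scale=spm_scale, seed=seed) if isinstance(
        method, str
    ) else method

    gene_probes: dict[str, list[str]] = {}
    index = set(dataset.probe_sets)
    g2p = probe_map.gene_to_probes
    missing = []
    for gene in training.genes:
        probes = [p for p in g2p.get(gene, []) if p in index]
        if not probes:
            missing.append(gene)
        gene_probes[gene] = probes
    if missing:
        raise ValidationError(
            f"training genes absent from dataset {dataset.dataset_id!r}: {missing}"
        )

    sub = ExpressionDataset(
        dataset.dataset_id,
        dataset.matrix.loc[sorted({p for ps in gene_probes.values() for p in ps})],
        dataset.sample_tissue,
    )
    if grid is None:
        grid = detector.default_grid(len(dataset.tissue_panel))
    grid = list(grid)
    if not grid:
        raise ValidationError("grid_search requires a non-empty grid")

    if isinstance(detector, BayesDetector):
        stats = detector.prepare(sub, c_values=sorted({p.c for p in grid}))
    else:
        stats = detector.prepare(sub)

    best_params = None
    best_objective = float("inf")
    best_penalties: dict[str, int] = {}
    for params in grid:
        penalties: dict[str, int] = {}
        for gene in training.genes:
            calls = [detector.classify(stats[p], params) for p in gene_probes[gene]]
            penalties[gene] = penalty(_gene_call(calls), training.truth(gene))
        objective = float(sum(penalties.values()))
        if objective < best_objective:
            best_objective = objective
            best_params = params
            best_penalties = penalties
    return OptimizationResult(
        method=detector.name,
        dataset_id=dataset.dataset_id,
        params=best_params,
        objective=best_objective,
        per_gene_penalty=best_penalties,
        grid_size=len(grid),
    )


def _agreement(result, annotated_tissue: str | None) -> bool:
    """Annotated-vs-predicted agreement for one gene.

    A below-threshold prediction reports no tissue, matching the study's
    reading of empty cells as 'no tissue with strong support'.
    """
    effective = () if result is None or result.support == SUPPORT_BELOW else result.tissues
    keys = {normalize_term(t) for t in effective}
    if annotated_tissue is None:  # ubiquitous gene
        return not keys
    return normalize_term(annotated_tissue) in keys


def cross_evaluate(
    paramsets: Mapping[str, Mapping[str, Mapping[str, object]]],
    datasets: Sequence[ExpressionDataset],
    probe_maps: Mapping[str, ProbeGeneMap],
    training_sets: Mapping[str, TrainingSet],
    methods: Mapping[str, Sequence[str]] | str = "auto",
    spm_scale: str = "linear",
    rule2_frequency: str = "contribution",
    seed: int = 0,
) -> pd.DataFrame:
    """All-against-all train/test agreement matrix (percentages).

    Rows are the training sets whose fitted parameters are applied; columns
    are the gene sets tested.  A specific gene agrees when the predicted
    tissue set contains its annotated tissue; a ubiquitous gene agrees when
    no tissue is predicted.
    """
    for name, ts in training_sets.items():
        if not ts.genes:
            raise ValidationError(f"test set {name!r} is empty")

    # restrict the datasets to the probes of the evaluated genes
    wanted_genes = {g for ts in training_sets.values() for g in ts.genes}
    restricted: list[ExpressionDataset] = []
    for dataset in datasets:
        probes = [
            p
            for p in dataset.probe_sets
            if probe_maps[dataset.dataset_id].probe_to_gene.get(p) in wanted_genes
        ]
        if probes:
            restricted.append(
                ExpressionDataset(
                    dataset.dataset_id,
                    dataset.matrix.loc[probes],
                    dataset.sample_tissue,
                )
            )

    matrix: dict[str, dict[str, float]] = {}
    for train_name, params in paramsets.items():
        results, _ = run_study(
            restricted,
            probe_maps,
            params,
            methods=methods,
            spm_scale=spm_scale,
            rule2_frequency=rule2_frequency,
            seed=seed,
        )
        by_gene = {r.gene: r for r in results}
        row: dict[str, float] = {}
        for test_name, test_set in training_sets.items():
            agree = 0
            for gene in test_set.genes:
                annotated = test_set.positives.get(gene)
                if _agreement(by_gene.get(gene), annotated):
                    agree += 1
            row[test_name] = 100.0 * agree / len(test_set.genes)
        matrix[train_name] = row
    return pd.DataFrame(matrix).T[list(training_sets)]
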