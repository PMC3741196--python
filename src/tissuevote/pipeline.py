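"""End-to-end wiring: detect -> consensus -> inner/total score -> verdicts.

Each dataset is analysed separately by 2-3 detection methods; the consensus
vote merges the methods per probe set; the scoring layer merges probe sets
within a dataset (inner score) and datasets across the study (total score).
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .consensus import consensus_vote
from .datatypes import (
    Call,
    Category,
    ExpressionDataset,
    GeneResult,
    ProbeGeneMap,
    ValidationError,
)
from .detectors import BayesDetector, BayesParams, make_detector
from .scoring import dataset_call, final_call, inner_score, total_score

__all__ = [
    "resolve_methods",
    "detect_dataset",
    "consensus_calls",
    "score_study",
    "run_study",
]

DEFAULT_METHODS = ("roku", "decision", "bayes")


def resolve_methods(dataset: ExpressionDataset, methods) -> list[str]:
    """Expand ``"auto"`` and validate the Bayes replicate requirement."""
    if methods in (None, "auto"):
        out = ["roku", "decision"]
        if dataset.has_replicates:
            out.append("bayes")
        return out
    methods = list(methods)
    for m in methods:
        if m not in DEFAULT_METHODS:
            raise ValidationError(f"unknown method {m!r}")
    if "bayes" in methods and not dataset.has_replicates:
        raise ValidationError(
            f"dataset {dataset.dataset_id!r}: the Bayes factor method can only be "
            "applied to datasets with multiple samples per tissue"
        )
    if not (2 <= len(methods) <= 3):
        raise ValidationError("each dataset needs 2 or 3 methods for the consensus vote")
    return methods


def detect_dataset(
    dataset: ExpressionDataset,
    methods: Sequence[str],
    params_by_method: Mapping[str, object],
    spm_scale: str = "linear",
    seed: int = 0,
) -> dict[str, dict[str, Call]]:
    """Apply each method to every probe set; returns method -> probe -> Call."""
    out: dict[str, dict[str, Call]] = {}
    for name in methods:
        params = params_by_method[name]
        if name == "bayes":
            detector = BayesDetector(n_draws=params.n_draws, seed=seed)
            stats = detector.prepare(dataset, c_values=[params.c])
        else:
            detector = make_detector(name, spm_scale=spm_scale)
            stats = detector.prepare(dataset)
        out[name] = {p: detector.classify(s, params) for p, s in stats.items()}
    return out


def consensus_calls(method_calls: Mapping[str, Mapping[str, Call]]) -> dict[str, Call]:
    """Per-probe-set consensus over the 2-3 method call tables."""
    methods = list(method_calls)
    if not (2 <= len(methods) <= 3):
        raise ValidationError("consensus needs call tables from 2 or 3 methods")
    probes = set(method_calls[methods[0]])
    for m in methods[1:]:
        if set(method_calls[m]) != probes:
            raise ValidationError("method call tables cover different probe sets")
    return {
        probe: consensus_vote([method_calls[m][probe] for m in methods])
        for probe in probes
    }


def score_study(
    consensus_by_dataset: Mapping[str, Mapping[str, Call]],
    probe_maps: Mapping[str, ProbeGeneMap],
    rule2_frequency: str = "contribution",
    genes: Sequence[str] | None = None,
) -> list[GeneResult]:
    """Gene-level verdicts from per-dataset consensus call tables."""
    dataset_ids = list(consensus_by_dataset)
    calls_per_gene: dict[str, dict[str, list[Call]]] = {}
    for ds in dataset_ids:
        pmap = probe_maps[ds].probe_to_gene
        for probe, call in consensus_by_dataset[ds].items():
            gene = pmap.get(probe)
            if gene is None:
                continue
            calls_per_gene.setdefault(gene, {}).setdefault(ds, []).append(call)

    wanted = sorted(calls_per_gene) if genes is None else list(genes)
    results: list[GeneResult] = []
    for gene in wanted:
        per_ds = calls_per_gene.get(gene)
        if not per_ds:
            continue
        presence = {ds: ds in per_ds for ds in dataset_ids}
        inner = {
            ds: inner_score(calls, gene, ds, rule2_frequency)
            for ds, calls in per_ds.items()
        }
        ds_calls = {ds: dataset_call(calls, rule2_frequency) for ds, calls in per_ds.items()}
        total, coverage = total_score(inner, presence, gene)
        results.append(final_call(gene, ds_calls, total, coverage))
    return results


def run_study(
    datasets: Sequence[ExpressionDataset],
    probe_maps: Mapping[str, ProbeGeneMap],
    params: Mapping[str, Mapping[str, object]],
    methods: Mapping[str, Sequence[str]] | str = "auto",
    spm_scale: str = "linear",
    rule2_frequency: str = "contribution",
    seed: int = 0,
) -> tuple[list[GeneResult], dict[str, dict[str, Call]]]:
    """Run the full flow; returns gene results and per-dataset consensus calls.

    ``params[ds][method]`` holds the method parameters for each dataset;
    ``methods`` is "auto" or a mapping dataset -> method names.
    """
    consensus_by_dataset: dict[str, dict[str, Call]] = {}
    for dataset in datasets:
        ds = dataset.dataset_id
        ds_methods = resolve_methods(
            dataset, "auto" if methods == "auto" else methods[ds]
        )
        method_calls = detect_dataset(
            dataset, ds_methods, params[ds], spm_scale=spm_scale, seed=seed
        )
        consensus_by_dataset[ds] = consensus_calls(method_calls)
    results = score_study(consensus_by_dataset, probe_maps, rule2_frequency)
    return results, consensus_by_dataset
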