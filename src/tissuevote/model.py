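"""Model/Results interface over the detection-consensus-scoring pipeline.

``TissueSpecificityModel`` is built from one or more expression datasets
(plus probe-to-gene maps and optionally an annotated training set);
``fit()`` estimates each detector's thresholds by grid-searching the
training penalty and returns a ``TissueSpecificityResults`` carrying the
fitted parameters, their objectives and the gene-level predictions.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import pandas as pd

from .datatypes import (
    ExpressionDataset,
    GeneResult,
    ProbeGeneMap,
    TrainingSet,
    ValidationError,
)
from .detectors import BayesDetector, BayesParams, DecisionParams, RokuSpmParams
from .pipeline import resolve_methods, run_study
from .scoring import (
    SUPPORT_BELOW,
    SUPPORT_HIGH,
    SUPPORT_MEDIUM,
    SUPPORT_MEDIUM_HIGH,
    SUPPORT_STRONG,
)
from .training import OptimizationResult, grid_search
from . import io as tv_io

__all__ = ["TissueSpecificityModel", "TissueSpecificityResults"]

_DEFAULTS = {
    "roku": RokuSpmParams(),
    "decision": DecisionParams(),
    "bayes": BayesParams(),
}


class TissueSpecificityModel:
    """Consensus tissue-specificity prediction over several datasets.

    Parameters
    ----------
    datasets
        Expression datasets (grouped to a common vocabulary upstream).
    probe_maps
        dataset id -> probe-to-gene map.
    training_set
        Annotated specific/ubiquitous genes used by :meth:`fit`; without it
        the default thresholds are used unchanged.
    methods
        ``"auto"`` (ROKU-SPM + decision function everywhere, Bayes factor
        where every tissue has replicates) or a mapping dataset id -> names.
    """

    def __init__(
        self,
        datasets: Sequence[ExpressionDataset],
        probe_maps: Mapping[str, ProbeGeneMap],
        training_set: TrainingSet | None = None,
        methods: Mapping[str, Sequence[str]] | str = "auto",
        spm_scale: str = "linear",
        rule2_frequency: str = "contribution",
        bayes_n_draws: int = 10_000,
    ) -> None:
        if not datasets:
            raise ValidationError("at least one dataset is required")
        ids = [d.dataset_id for d in datasets]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate dataset ids: {ids}")
        missing = [i for i in ids if i not in probe_maps]
        if missing:
            raise ValidationError(f"probe maps missing for datasets: {missing}")
        self.datasets = list(datasets)
        self.probe_maps = dict(probe_maps)
        self.training_set = training_set
        self.spm_scale = spm_scale
        self.rule2_frequency = rule2_frequency
        self.bayes_n_draws = bayes_n_draws
        self.methods_by_dataset: dict[str, list[str]] = {
            d.dataset_id: resolve_methods(
                d, "auto" if methods == "auto" else methods[d.dataset_id]
            )
            for d in datasets
        }

    @classmethod
    def from_files(
        cls,
        dataset_specs: Sequence[Mapping[str, str]],
        vocabulary_path: str | None = None,
        training_path: str | None = None,
        **kwargs,
    ) -> "TissueSpecificityModel":
        """Build from TSV files; each spec has id/matrix/sample_map/probe_map."""
        vocab = tv_io.read_vocabulary(vocabulary_path) if vocabulary_path else None
        datasets = []
        probe_maps = {}
        for spec in dataset_specs:
            ds = tv_io.read_expression_dataset(
                spec["matrix"], spec["sample_map"], dataset_id=spec.get("id")
            )
            if vocab is not None:
                ds = tv_io.group_tissues(ds, vocab)
            datasets.append(ds)
            probe_maps[ds.dataset_id] = tv_io.read_probe_gene_map(spec["probe_map"])
        training = tv_io.read_training_set(training_path) if training_path else None
        return cls(datasets, probe_maps, training_set=training, **kwargs)

    # -- estimation -------------------------------------------------------
    def fit(
        self,
        grids: Mapping[str, Sequence[object]] | None = None,
        seed: int = 0,
    ) -> "TissueSpecificityResults":
        """Estimate per-dataset, per-method thresholds by grid search.

        Without a training set the defaults are returned as 'fitted' values
        with no objective.  ``grids`` optionally overrides the default grid
        per method name.
        """
        params: dict[str, dict[str, object]] = {}
        optimizations: dict[tuple[str, str], OptimizationResult] = {}
        for dataset in self.datasets:
            ds = dataset.dataset_id
            params[ds] = {}
            for method in self.methods_by_dataset[ds]:
                if self.training_set is None:
                    base = _DEFAULTS[method]
                    if method == "bayes":
                        base = BayesParams(
                            c=base.c,
                            bf1=base.bf1,
                            bf2=base.bf2,
                            n_draws=self.bayes_n_draws,
                            seed=seed,
                        )
                    params[ds][method] = base
                    continue
                if method == "bayes":
                    detector = BayesDetector(n_draws=self.bayes_n_draws, seed=seed)
                    grid = (
                        grids.get(method)
                        if grids and method in grids
                        else detector.default_grid(
                            len(dataset.tissue_panel),
                            n_replicates=min(dataset.replicates_per_tissue.values()),
                            seed=seed,
                        )
                    )
                    opt = grid_search(
                        detector,
                        dataset,
                        self.probe_maps[ds],
                        self.training_set,
                        grid=grid,
                        seed=seed,
                    )
                else:
                    grid = grids.get(method) if grids and method in grids else None
                    opt = grid_search(
                        method,
                        dataset,
                        self.probe_maps[ds],
                        self.training_set,
                        grid=grid,
                        spm_scale=self.spm_scale,
                        seed=seed,
                    )
                params[ds][method] = opt.params
                optimizations[(ds, method)] = opt
        return TissueSpecificityResults(self, params, optimizations, seed=seed)


class TissueSpecificityResults:
    """Fitted thresholds plus the study-wide predictions they imply."""

    def __init__(
        self,
        model: TissueSpecificityModel,
        params: Mapping[str, Mapping[str, object]],
        optimizations: Mapping[tuple[str, str], OptimizationResult],
        seed: int = 0,
    ) -> None:
        self.model = model
        self.params = {ds: dict(m) for ds, m in params.items()}
        self.optimizations = dict(optimizations)
        self.seed = seed
        self._results: list[GeneResult] | None = None

    # -- prediction -------------------------------------------------------
    def predict(self) -> list[GeneResult]:
        """Run detect -> consensus -> scoring for every gene (cached)."""
        if self._results is None:
            self._results, self._consensus = run_study(
                self.model.datasets,
                self.model.probe_maps,
                self.params,
                methods=self.model.methods_by_dataset,
                spm_scale=self.model.spm_scale,
                rule2_frequency=self.model.rule2_frequency,
                seed=self.seed,
            )
        return self._results

    def predict_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.predict():
            rows.append(
                {
                    "gene": r.gene,
                    "category": r.category.value,
                    "tissue1": r.tissues[0] if len(r.tissues) >= 1 else None,
                    "tissue2": r.tissues[1] if len(r.tissues) >= 2 else None,
                    "score": r.score,
                    "support": r.support,
                    "coverage_present": r.coverage[0],
                    "coverage_total": r.coverage[1],
                }
            )
        return pd.DataFrame(rows)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        """Text report: fitted parameters, objectives and support-band counts."""
        lines = ["Tissue-specificity consensus model", "=" * 40]
        for ds in self.params:
            lines.append(f"dataset {ds}: methods {', '.join(self.params[ds])}")
            for method, p in self.params[ds].items():
                opt = self.optimizations.get((ds, method))
                obj = f"  objective={opt.objective:g}" if opt else ""
                lines.append(f"  {method}: {p}{obj}")
        results = self.predict()
        lines.append("")
        lines.append(f"genes scored: {len(results)}")
        band_order = [
            SUPPORT_STRONG,
            SUPPORT_HIGH,
            SUPPORT_MEDIUM_HIGH,
            SUPPORT_MEDIUM,
            SUPPORT_BELOW,
        ]
        counts = Counter((r.category.value, r.support) for r in results)
        coverage = Counter(r.coverage for r in results)
        lines.append("support bands (category / band / genes):")
        for (cat, band), n in sorted(
            counts.items(), key=lambda kv: (kv[0][0], band_order.index(kv[0][1]))
        ):
            lines.append(f"  {cat:<14} {band:<15} {n}")
        lines.append("coverage (present/total / genes):")
        for (present, total), n in sorted(coverage.items(), reverse=True):
            lines.append(f"  {present} out of {total}: {n}")
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Histogram of top-tissue total scores, split by final category."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.predict_frame()
        for cat, sub in frame.groupby("category"):
            ax.hist(sub["score"], bins=20, range=(0, 1), alpha=0.5, label=cat)
        ax.set_xlabel("top-tissue total score")
        ax.set_ylabel("genes")
        ax.legend()
        return ax
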