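"""Synthetic multi-dataset expression studies with planted ground truth.

The generator emulates the structure of a multi-platform tissue atlas
study: several datasets with partially overlapping tissue panels, 1-3 probe
sets per gene, optional per-tissue replicates, and genes planted as
specific (one elevated tissue), 2-selective (two elevated tissues) or
ubiquitous (no elevation).  Noise is Gaussian on the log2 scale
(multiplicative on the linear scale), the standard model for microarray
intensities.  A configurable fraction of probe sets is *discordant* - it
carries no elevation although its gene does - to exercise the
non-informative-probe rule of the inner score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    Call,
    ExpressionDataset,
    ProbeGeneMap,
    TrainingSet,
    ValidationError,
)

__all__ = [
    "TISSUE_TERMS",
    "StudyConfig",
    "SyntheticStudy",
    "generate_study",
    "generate_worked_example",
    "training_set_from_truth",
]

# fixed 60-term tissue list the per-dataset panels are drawn from
TISSUE_TERMS = [
    "liver", "kidney", "heart", "lung", "brain", "muscle", "pancreas",
    "spleen", "thymus", "prostate", "testis", "ovary", "placenta", "skin",
    "stomach", "small intestine", "colon", "adrenal gland", "thyroid",
    "salivary gland", "bone marrow", "lymph node", "tonsil", "appendix",
    "bladder", "uterus", "cervix", "esophagus", "trachea", "breast",
    "adipose tissue", "spinal cord", "cerebellum", "hippocampus",
    "hypothalamus", "pituitary gland", "retina", "cornea", "tongue",
    "gallbladder", "duodenum", "jejunum", "ileum", "rectum", "skeletal muscle",
    "smooth muscle", "cardiac muscle", "aorta", "vein", "artery",
    "peripheral nerve", "dorsal root ganglion", "olfactory bulb",
    "substantia nigra", "amygdala", "caudate nucleus", "corpus callosum",
    "fetal brain", "fetal liver", "fetal lung",
]

CLASS_SPECIFIC = "specific"
CLASS_TWO_SELECTIVE = "two_selective"
CLASS_UBIQUITOUS = "ubiquitous"


@dataclass(frozen=True)
class StudyConfig:
    """Study design: panels, gene classes, effect and noise levels.

    Defaults describe the standard test study: four platforms, 500 genes,
    a 3-log2-unit elevation against unit Gaussian noise, 10% discordant
    probe sets, 20-tissue panels sharing a 12-tissue core, and replicate
    structure (1, 3, 1, 3) so that two datasets support the Bayes detector.
    """

    n_datasets: int = 4
    n_genes: int = 500
    class_proportions: tuple[float, float, float] = (0.45, 0.15, 0.40)
    probe_sets_per_gene: tuple[int, int] = (1, 3)
    panel_size: int = 20
    core_size: int = 12
    replicates_per_dataset: tuple[int, ...] = (1, 3, 1, 3)
    baseline: float = 8.0
    noise_sd: float = 1.0
    effect_size: float = 3.0
    discordant_rate: float = 0.10
    targets_from_core: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValidationError("class proportions must sum to 1")
        if self.effect_size <= 0:
            raise ValidationError("effect size must be > 0")
        if self.panel_size < 3 or self.core_size < 2:
            raise ValidationError("panels need >= 3 tissues and a core of >= 2")
        if self.core_size > self.panel_size:
            raise ValidationError("core_size cannot exceed panel_size")
        if self.panel_size > len(TISSUE_TERMS):
            raise ValidationError(f"panel_size cannot exceed {len(TISSUE_TERMS)}")
        if len(self.replicates_per_dataset) != self.n_datasets:
            raise ValidationError("one replicate count per dataset is required")
        if any(r < 1 for r in self.replicates_per_dataset):
            raise ValidationError("replicate counts must be >= 1")
        lo, hi = self.probe_sets_per_gene
        if not (1 <= lo <= hi):
            raise ValidationError("probe_sets_per_gene must be a valid range from >= 1")
        if not (0.0 <= self.discordant_rate <= 1.0):
            raise ValidationError("discordant_rate must lie in [0, 1]")


@dataclass
class SyntheticStudy:
    datasets: list[ExpressionDataset]
    probe_maps: dict[str, ProbeGeneMap]
    truth: pd.DataFrame
    config: StudyConfig


def _assign_classes(n_genes: int, proportions: Sequence[float]) -> list[str]:
    counts = [int(round(p * n_genes)) for p in proportions]
    counts[-1] = n_genes - sum(counts[:-1])
    labels = [CLASS_SPECIFIC, CLASS_TWO_SELECTIVE, CLASS_UBIQUITOUS]
    out: list[str] = []
    for label, count in zip(labels, counts):
        out.extend([label] * count)
    return out


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate the multi-dataset study; fully reproducible under the seed.

    Planted genes receive the log2 elevation on their target tissue(s) in
    every dataset whose panel contains the tissue; discordant probe sets
    carry no elevation.  Target tissues are drawn from the shared core so
    every platform can in principle see them.
    """
    rng = np.random.default_rng(config.seed)

    terms = list(TISSUE_TERMS)
    rng.shuffle(terms)
    core = terms[: config.core_size]
    extras_pool = terms[config.core_size :]
    panels: list[list[str]] = []
    n_extra = config.panel_size - config.core_size
    for _ in range(config.n_datasets):
        extras = list(rng.choice(extras_pool, size=n_extra, replace=False))
        panels.append(core + extras)

    classes = _assign_classes(config.n_genes, config.class_proportions)
    width = len(str(config.n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    # target tissues come from the shared core by default (every platform can
    # see them); with targets_from_core=False they are drawn from the union of
    # the panels, so a gene's tissue may be absent from some datasets
    pool = core if config.targets_from_core else sorted({t for p in panels for t in p})
    targets: dict[str, tuple[str, ...]] = {}
    for gene, cls in zip(genes, classes):
        if cls == CLASS_SPECIFIC:
            targets[gene] = (str(rng.choice(pool)),)
        elif cls == CLASS_TWO_SELECTIVE:
            targets[gene] = tuple(rng.choice(pool, size=2, replace=False))
        else:
            targets[gene] = ()

    datasets: list[ExpressionDataset] = []
    probe_maps: dict[str, ProbeGeneMap] = {}
    lo, hi = config.probe_sets_per_gene
    for d in range(config.n_datasets):
        ds_id = f"DS{d + 1}"
        panel = panels[d]
        reps = config.replicates_per_dataset[d]
        samples = [f"{t}|r{k + 1}" for t in panel for k in range(reps)]
        sample_tissue = {s: s.split("|")[0] for s in samples}
        tissue_cols = {
            t: [i for i, s in enumerate(samples) if sample_tissue[s] == t]
            for t in panel
        }

        probe_rows: list[str] = []
        probe_to_gene: dict[str, str] = {}
        elevation_rows: list[tuple[int, tuple[str, ...]]] = []
        for gene in genes:
            n_probes = int(rng.integers(lo, hi + 1))
            for p in range(n_probes):
                probe = f"{gene}_{ds_id}_p{p + 1}"
                probe_rows.append(probe)
                probe_to_gene[probe] = gene
                discordant = (
                    bool(targets[gene]) and rng.random() < config.discordant_rate
                )
                planted = () if discordant else targets[gene]
                elevation_rows.append((len(probe_rows) - 1, planted))

        values = rng.normal(
            config.baseline, config.noise_sd, size=(len(probe_rows), len(samples))
        )
        for row_idx, planted in elevation_rows:
            for tissue in planted:
                if tissue in tissue_cols:
                    values[row_idx, tissue_cols[tissue]] += config.effect_size

        matrix = pd.DataFrame(values, index=probe_rows, columns=samples)
        matrix.index.name = "probe_set"
        datasets.append(ExpressionDataset(ds_id, matrix, sample_tissue))
        probe_maps[ds_id] = ProbeGeneMap(probe_to_gene)

    truth = pd.DataFrame(
        {
            "gene": genes,
            "class": classes,
            "tissue1": [targets[g][0] if len(targets[g]) >= 1 else "" for g in genes],
            "tissue2": [targets[g][1] if len(targets[g]) >= 2 else "" for g in genes],
        }
    )
    return SyntheticStudy(datasets, probe_maps, truth, config)


def training_set_from_truth(
    truth: pd.DataFrame,
    n_specific: int = 20,
    n_ubiquitous: int = 10,
    seed: int = 0,
    name: str = "synthetic-training",
) -> TrainingSet:
    """Sample an annotated training set (specific + ubiquitous genes).

    Mirrors the design of the study's curated gene sets: a handful of
    specific genes with known tissue plus ubiquitously expressed genes.
    """
    rng = np.random.default_rng(seed)
    spec = truth[truth["class"] == CLASS_SPECIFIC]
    ubiq = truth[truth["class"] == CLASS_UBIQUITOUS]
    if len(spec) < n_specific or len(ubiq) < n_ubiquitous:
        raise ValidationError(
            f"truth table holds {len(spec)} specific / {len(ubiq)} ubiquitous genes; "
            f"requested {n_specific} / {n_ubiquitous}"
        )
    spec_rows = spec.iloc[rng.choice(len(spec), size=n_specific, replace=False)]
    ubiq_rows = ubiq.iloc[rng.choice(len(ubiq), size=n_ubiquitous, replace=False)]
    return TrainingSet(
        positives=dict(zip(spec_rows["gene"], spec_rows["tissue1"])),
        negatives=set(ubiq_rows["gene"]),
        name=name,
    )


# ---------------------------------------------------------------------------
# worked-example fixtures
# ---------------------------------------------------------------------------

def generate_worked_example(name: str) -> tuple[dict[str, list[Call]], int]:
    """Per-dataset probe-set consensus calls for the two worked examples.

    ``GRHPR``: three probe sets in GNF1H/GeAZr/GSE7307 and one in GDS3113;
    ``ASS1``: one probe set in GNF1H, two in GeAZr and GSE7307, none in
    GDS3113 (for ASS1's GeAZr probe sets - whose individual calls the
    description leaves open, stating only that Liver and Kidney scores are
    averaged over them - the fixture uses two 2-selective(Liver, Kidney)
    calls).  Returns the calls keyed by dataset plus the study size (4).
    """
    S, P, U = Call.specific, Call.two_selective, Call.ubiquitous
    if name == "GRHPR":
        calls = {
            "GNF1H": [P("Liver", "Lymph"), P("Liver", "Lymph"), U()],
            "GeAZr": [S("Liver"), S("Liver"), S("Liver")],
            "GSE7307": [S("Liver"), P("Liver", "Kidney"), U()],
            "GDS3113": [U()],
        }
        return calls, 4
    if name == "ASS1":
        calls = {
            "GNF1H": [P("Liver", "Kidney")],
            "GeAZr": [P("Liver", "Kidney"), P("Liver", "Kidney")],
            "GSE7307": [P("Liver", "Kidney"), U()],
        }
        return calls, 4
    raise ValidationError(f"unknown worked example {name!r} (expected 'GRHPR' or 'ASS1')")
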