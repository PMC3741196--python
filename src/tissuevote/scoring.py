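"""Inner score per dataset, cross-dataset total score and support bands.

The inner score condenses the consensus calls of a gene's probe sets within
one dataset into per-tissue evidence in [0, 1]; the total score averages
inner scores over the datasets in which the gene is represented.  Support
bands translate the top tissue's total score into the categorical labels
used for reporting (strong / high / medium-high / medium / below-threshold).
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

from .datatypes import (
    Call,
    Category,
    GeneResult,
    TissueScore,
    ValidationError,
    normalize_term,
)

__all__ = [
    "inner_score",
    "dataset_call",
    "total_score",
    "support_category",
    "final_call",
    "SUPPORT_STRONG",
    "SUPPORT_HIGH",
    "SUPPORT_MEDIUM_HIGH",
    "SUPPORT_MEDIUM",
    "SUPPORT_BELOW",
]

SUPPORT_STRONG = "strong"
SUPPORT_HIGH = "high"
SUPPORT_MEDIUM_HIGH = "medium-high"
SUPPORT_MEDIUM = "medium"
SUPPORT_BELOW = "below-threshold"

_EPS = 1e-9


def _display_names(calls: Sequence[Call]) -> dict[str, str]:
    names: dict[str, str] = {}
    for call in calls:
        for t in call.tissues:
            names.setdefault(normalize_term(t), t)
    return names


def _retain(calls: Sequence[Call]) -> list[Call]:
    """Rule 1: drop non-informative ubiquitous calls when >= 50% of the
    probe sets are specific/2-selective and share a tissue."""
    informative = [c for c in calls if c.category is not Category.UBIQUITOUS]
    support = Counter(k for c in informative for k in c.tissue_keys)
    if support and max(support.values()) * 2 >= len(calls):
        return informative
    return list(calls)


def _rule2_candidates(retained: Sequence[Call]) -> list[tuple[str, object]]:
    """Conditions reaching the >= 50% homogeneity bar among retained calls.

    A candidate is either ("specific", tissue_key) or ("pair",
    frozenset{key1, key2}).  Several tied candidates mean the evidence is
    split and scoring falls back to contribution averaging.
    """
    n = len(retained)
    spec_counts = Counter(
        c.tissue_keys[0] for c in retained if c.category is Category.SPECIFIC
    )
    pair_counts = Counter(
        frozenset(c.tissue_keys)
        for c in retained
        if c.category is Category.TWO_SELECTIVE
    )
    out: list[tuple[str, object]] = []
    for key, count in spec_counts.items():
        if count * 2 >= n:
            out.append(("specific", key))
    for pair, count in pair_counts.items():
        if count * 2 >= n:
            out.append(("pair", pair))
    return out


def _contribution_scores(
    retained: Sequence[Call], rule2_frequency: str
) -> dict[str, float]:
    """Fallback averaging: per-tissue mean contribution over retained calls.

    ``contribution``: a specific call adds 1 to its tissue, a 2-selective
    call adds 0.5 to each of its two tissues.  ``mention``: every call
    containing the tissue adds 1.
    """
    if rule2_frequency not in ("contribution", "mention"):
        raise ValidationError(
            f"rule2_frequency must be 'contribution' or 'mention', got {rule2_frequency!r}"
        )
    n = len(retained)
    acc: dict[str, float] = {}
    for call in retained:
        weight = 1.0 if rule2_frequency == "mention" else 1.0 / max(call.tau, 1)
        for key in call.tissue_keys:
            acc[key] = acc.get(key, 0.0) + weight
    return {k: v / n for k, v in acc.items()}


def _inner(calls: Sequence[Call], rule2_frequency: str) -> tuple[dict[str, float], Call]:
    retained = _retain(calls)
    names = _display_names(retained)
    informative = [c for c in retained if c.category is not Category.UBIQUITOUS]
    if not informative:
        return {}, Call.ubiquitous(source="inner")

    candidates = _rule2_candidates(retained)
    if len(candidates) == 1:
        kind, key = candidates[0]
        if kind == "specific":
            return {names[key]: 1.0}, Call.specific(names[key], source="inner")
        pair = sorted(key)  # type: ignore[arg-type]
        scores = {names[k]: 0.5 for k in pair}
        return scores, Call.two_selective(names[pair[0]], names[pair[1]], source="inner")

    scores = {names[k]: v for k, v in _contribution_scores(retained, rule2_frequency).items()}
    # dataset-level verdict for the split case: majority category among the
    # informative calls (tie -> specific), tissues by top contribution
    n_spec = sum(1 for c in informative if c.category is Category.SPECIFIC)
    n_pair = len(informative) - n_spec
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if n_spec >= n_pair or len(ordered) < 2:
        verdict = Call.specific(ordered[0][0], source="inner")
    else:
        verdict = Call.two_selective(ordered[0][0], ordered[1][0], source="inner")
    return scores, verdict


def inner_score(
    probe_calls: Sequence[Call],
    gene: str = "",
    dataset_id: str = "",
    rule2_frequency: str = "contribution",
) -> TissueScore:
    """Per-tissue evidence for one gene in one dataset (Rules 1-2).

    Rule 1 drops ubiquitous probe sets when at least half of the probe sets
    are informative for a shared tissue.  Rule 2 assigns 1 (specific) or
    0.5/0.5 (2-selective) when a single tissue/pair reaches the 50% bar
    among retained calls; split evidence falls back to averaging the
    per-probe-set contributions.  All-ubiquitous input yields an empty map.
    """
    if not probe_calls:
        raise ValidationError("inner_score requires at least one call")
    scores, _ = _inner(probe_calls, rule2_frequency)
    return TissueScore(gene=gene, scope=f"inner:{dataset_id}", scores=scores)


def dataset_call(
    probe_calls: Sequence[Call], rule2_frequency: str = "contribution"
) -> Call:
    """Dataset-level verdict implied by the inner-score rules."""
    if not probe_calls:
        raise ValidationError("dataset_call requires at least one call")
    _, verdict = _inner(probe_calls, rule2_frequency)
    return verdict


def total_score(
    inner: Mapping[str, TissueScore],
    presence: Mapping[str, bool],
    gene: str = "",
) -> tuple[TissueScore, tuple[int, int]]:
    """Average the inner scores over the datasets where the gene is present.

    Datasets where the gene is represented but called ubiquitous contribute
    zero to every tissue; datasets without any probe set for the gene do not
    enter the denominator (they only reduce coverage).
    """
    present = [ds for ds, p in presence.items() if p]
    if not present:
        raise ValidationError(f"gene {gene!r} absent from every dataset")
    missing = [ds for ds in inner if ds not in presence]
    if missing:
        raise ValidationError(f"inner scores for unknown datasets: {missing}")
    acc: dict[str, float] = {}
    for ds in present:
        ts = inner.get(ds)
        if ts is None:
            continue
        for tissue, s in ts.scores.items():
            acc[tissue] = acc.get(tissue, 0.0) + s
    scores = {t: v / len(present) for t, v in acc.items()}
    coverage = (len(present), len(presence))
    return TissueScore(gene=gene, scope="total", scores=scores), coverage


def support_category(category: Category, score: float) -> str:
    """Support band for a top-tissue total score.

    Specific genes: strong (=1), high (0.75 <= s < 1), medium-high
    (0.5 < s < 0.75), medium (=0.5).  2-selective genes: strong (s >= 0.5,
    the pair maximum), medium-high (0.3 <= s < 0.5).  Anything lower is
    below-threshold, as is any ubiquitous verdict.
    """
    if not (-_EPS <= score <= 1.0 + _EPS):
        raise ValidationError(f"score {score} outside [0, 1]")
    if category is Category.SPECIFIC:
        if abs(score - 1.0) <= _EPS:
            return SUPPORT_STRONG
        if score >= 0.75 - _EPS:
            return SUPPORT_HIGH
        if score > 0.5 + _EPS:
            return SUPPORT_MEDIUM_HIGH
        if abs(score - 0.5) <= _EPS:
            return SUPPORT_MEDIUM
        return SUPPORT_BELOW
    if category is Category.TWO_SELECTIVE:
        if score >= 0.5 - _EPS:
            return SUPPORT_STRONG
        if score >= 0.3 - _EPS:
            return SUPPORT_MEDIUM_HIGH
        return SUPPORT_BELOW
    return SUPPORT_BELOW


def final_call(
    gene: str,
    dataset_calls: Mapping[str, Call],
    total: TissueScore,
    coverage: tuple[int, int],
) -> GeneResult:
    """Gene-level verdict from dataset verdicts and the total score.

    The category is the majority among the informative dataset verdicts
    (ties go to specific); the reported tissue is the top-scoring one (or the
    top two for 2-selective genes); the support label is the band of the top
    tissue's total score.
    """
    informative = [
        c for c in dataset_calls.values() if c.category is not Category.UBIQUITOUS
    ]
    if not informative:
        top = total.top(1)
        score = top[0][1] if top else 0.0
        return GeneResult(
            gene, Category.UBIQUITOUS, (), dict(total.scores), score, SUPPORT_BELOW, coverage
        )
    n_spec = sum(1 for c in informative if c.category is Category.SPECIFIC)
    n_pair = len(informative) - n_spec
    category = Category.SPECIFIC if n_spec >= n_pair else Category.TWO_SELECTIVE

    k = 1 if category is Category.SPECIFIC else 2
    top = total.top(k)
    if len(top) < k:
        # scored tissues cannot fill the category (e.g. a 2-selective verdict
        # with a single scored tissue): degrade to specific
        category = Category.SPECIFIC
        top = total.top(1)
    if not top:
        return GeneResult(
            gene, Category.UBIQUITOUS, (), dict(total.scores), 0.0, SUPPORT_BELOW, coverage
        )
    tissues = tuple(t for t, _ in top)
    score = top[0][1]
    support = support_category(category, score)
    return GeneResult(gene, category, tissues, dict(total.scores), score, support, coverage)
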