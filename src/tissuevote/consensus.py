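"""Consensus vote combining the verdicts of 2-3 detection methods.

The rule table treats method order as irrelevant (the vote is over an
unordered multiset of calls) and tissue identity as meaningful: a specific
call T is only reinforced by other calls that *contain* T.  When no tissue
gains majority support the consensus is ubiquitous ("no tissue with strong
support").
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

from .datatypes import Call, Category, ValidationError, normalize_term

__all__ = ["consensus_vote"]


def _tissue_support(calls: Sequence[Call]) -> Counter:
    support: Counter = Counter()
    for call in calls:
        for key in call.tissue_keys:
            support[key] += 1
    return support


def _display_name(calls: Sequence[Call], key: str) -> str:
    for call in calls:
        for t in call.tissues:
            if normalize_term(t) == key:
                return t
    raise KeyError(key)  # pragma: no cover - defensive


def consensus_vote(calls: Sequence[Call]) -> Call:
    """Combine 2 or 3 method calls for one probe set into a consensus call.

    Rules (with n methods voting):

    * ubiquitous calls outnumbering informative calls -> ubiquitous;
    * all informative calls 2-selective: a pair named by >= 50% of them wins;
      otherwise a tissue supported by >= 2 calls wins as specific, else
      ubiquitous;
    * informative calls with at least as many specific as 2-selective
      members: the tissue with the uniquely largest support wins as
      specific; a tie between distinct tissues yields ubiquitous;
    * more 2-selective than specific members: a majority pair wins as
      2-selective, otherwise as in the specific branch but requiring
      support >= 2.
    """
    calls = list(calls)
    if not (2 <= len(calls) <= 3):
        raise ValidationError(f"consensus vote needs 2 or 3 calls, got {len(calls)}")

    informative = [c for c in calls if c.category is not Category.UBIQUITOUS]
    n_uq = len(calls) - len(informative)
    if not informative or n_uq > len(informative):
        return Call.ubiquitous(source="consensus")

    specifics = [c for c in informative if c.category is Category.SPECIFIC]
    pairs = [c for c in informative if c.category is Category.TWO_SELECTIVE]
    support = _tissue_support(informative)

    def majority_pair() -> Call | None:
        pair_counts = Counter(frozenset(c.tissue_keys) for c in pairs)
        if not pair_counts:
            return None
        ranked = pair_counts.most_common()
        top_pair, count = ranked[0]
        if count * 2 < len(informative):
            return None
        if len(ranked) > 1 and ranked[1][1] == count:
            return None  # tied distinct pairs: fall back to tissue support
        source = next(c for c in pairs if frozenset(c.tissue_keys) == top_pair)
        return Call.two_selective(*source.tissues, source="consensus")

    def best_tissue(min_support: int) -> Call | None:
        ranked = support.most_common()
        top_key, top_count = ranked[0]
        if top_count < min_support:
            return None
        if len(ranked) > 1 and ranked[1][1] == top_count:
            return None  # tie between distinct tissues: no strong support
        return Call.specific(_display_name(informative, top_key), source="consensus")

    if not specifics:
        winner = majority_pair()
        if winner is not None:
            return winner
        single = best_tissue(min_support=2)
        return single if single is not None else Call.ubiquitous(source="consensus")

    if len(pairs) > len(specifics):
        winner = majority_pair()
        if winner is not None:
            return winner
        single = best_tissue(min_support=2)
        return single if single is not None else Call.ubiquitous(source="consensus")

    # specific calls dominate (or tie): a uniquely best-supported tissue wins
    single = best_tissue(min_support=1)
    return single if single is not None else Call.ubiquitous(source="consensus")
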