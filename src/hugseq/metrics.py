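"""Evaluation measures: gene popularity and harmonic-mean composites.

Popularity scores a pattern against a ranked list of disease genes
(rank 1 = most associated).  A listed gene at rank ``r`` in a list of
``R`` weighs ``R - r + 1``; unlisted genes weigh 1; up- and
down-regulation items of a gene share its weight; the pattern score is
the mean weight over all its items (repeats counted).  The harmonic
means GU-Pop and Sup-Pop fold utility or support together with
popularity.  A support-ranked top-k (exhaustive within a length cap)
serves as the frequency-based comparator.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Pattern, SequentialDataset
from .oracle import PatternStats, enumerate_patterns, DEFAULT_CAP

__all__ = [
    "PopularGeneRanking",
    "popularity",
    "composite_scores",
    "top_k_frequent",
]


@dataclass(frozen=True)
class PopularGeneRanking:
    """An ordered disease-gene list; rank 1 first.  Typically 20 genes."""

    genes: tuple[str, ...]
    unlisted_weight: float = 1.0

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked genes must be unique")

    @classmethod
    def from_text(cls, text: str) -> "PopularGeneRanking":
        """One gene per line, best rank first; blank/'#' lines ignored."""
        genes = [
            ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        return cls(tuple(genes))

    def weight(self, gene: str) -> float:
        try:
            rank = self.genes.index(gene) + 1
        except ValueError:
            return self.unlisted_weight
        return len(self.genes) - rank + 1


def popularity(pattern: Pattern, ranking: PopularGeneRanking) -> float:
    """Mean rank weight over all items of the pattern.

    Invariant to item order and regulation direction; bounded by
    [unlisted weight, list length] for non-degenerate rankings.
    """
    items = list(pattern.items())
    if not items:
        raise ValueError("popularity of an empty pattern is undefined")
    return sum(ranking.weight(gene) for gene, _ in items) / len(items)


def composite_scores(gu: float, pop: float, sup: float) -> tuple[float, float]:
    """Harmonic means (GU-Pop, Sup-Pop); a zero denominator yields 0."""
    if min(gu, pop, sup) < 0:
        raise ValueError("inputs must be non-negative")
    gu_pop = 2.0 * gu * pop / (gu + pop) if gu + pop > 0 else 0.0
    sup_pop = 2.0 * sup * pop / (sup + pop) if sup + pop > 0 else 0.0
    return gu_pop, sup_pop


def top_k_frequent(
    dataset: SequentialDataset,
    k: int,
    max_size: int,
    cap: int = DEFAULT_CAP,
) -> list[PatternStats]:
    """Top-k patterns by support (ties by utility, then pattern order).

    An exhaustive frequency-ranked comparator for contrasting
    utility-driven with frequency-driven pattern selection.
    """
    stats = enumerate_patterns(dataset, max_size, cap)
    stats.sort(key=lambda s: (-s.support, -s.utility, s.pattern))
    return stats[:k]
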