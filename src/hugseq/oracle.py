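"""Exhaustive ground truth for desk-scale datasets.

The oracle enumerates every distinct pattern occurring in a dataset by
direct subsequence generation — per patient, every choice of strictly
increasing time samples and, per chosen geneset, every non-empty item
subset — and accumulates per-pattern per-patient maxima.  It shares only
the basic utility arithmetic with the tree miner (never the sequence
utility-list joins), so it is a genuine second implementation suitable
for verifying completeness of the search and soundness of the
rest-utility bound.

Scalability is deliberately absent: a work cap guards against
accidentally enumerating anything beyond toy size.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .model import (
    Combiner,
    Element,
    ParameterError,
    Pattern,
    SequentialDataset,
    product_combiner,
    quantize,
)

__all__ = ["EnumerationCapError", "PatternStats", "enumerate_patterns", "brute_topk"]

DEFAULT_CAP = 2_000_000


class EnumerationCapError(RuntimeError):
    """The projected enumeration effort exceeds the configured cap."""


@dataclass(frozen=True)
class PatternStats:
    pattern: Pattern
    utility: float
    support: int


def _element_subsets(items: tuple, utils: dict) -> list[tuple[Element, float]]:
    out = []
    for r in range(1, len(items) + 1):
        for combo in combinations(items, r):
            out.append((combo, sum(utils[i] for i in combo)))
    return out


def enumerate_patterns(
    dataset: SequentialDataset,
    max_size: int,
    cap: int = DEFAULT_CAP,
    combiner: Combiner = product_combiner,
) -> list[PatternStats]:
    """Every distinct pattern of size <= ``max_size`` with an occurrence.

    ``max_size`` caps the total item count of a pattern (its *size*),
    so both element growth and sequence growth are bounded uniformly.

    Patterns come back sorted by (descending utility, lexicographic
    pattern), the ranking convention shared with the miner.  Raises
    :class:`EnumerationCapError` once the number of visited embeddings
    exceeds ``cap``.
    """
    if max_size < 1:
        raise ParameterError(f"max_size must be >= 1, got {max_size}")
    imp = dataset.importance
    best: dict[tuple, dict[int, float]] = {}  # elements -> patient idx -> max util
    work = {"n": 0}

    for pi, patient in enumerate(dataset.patients):
        subset_lists = []
        for gs in patient.genesets:
            utils = {
                item: combiner(imp.score(item[0]), iu)
                for item, iu in gs.items.items()
            }
            subset_lists.append(_element_subsets(gs.item_ids(), utils))

        def rec(start: int, elements: tuple, util: float, size: int) -> None:
            for gi in range(start, len(subset_lists)):
                for subset, subutil in subset_lists[gi]:
                    if size + len(subset) > max_size:
                        continue
                    work["n"] += 1
                    if work["n"] > cap:
                        raise EnumerationCapError(
                            f"enumeration exceeded the cap of {cap} embeddings"
                        )
                    new_elements = elements + (subset,)
                    new_util = util + subutil
                    new_size = size + len(subset)
                    per_patient = best.setdefault(new_elements, {})
                    if new_util > per_patient.get(pi, float("-inf")):
                        per_patient[pi] = new_util
                    if new_size < max_size:
                        rec(gi + 1, new_elements, new_util, new_size)

        rec(0, (), 0.0, 0)

    stats = [
        PatternStats(
            Pattern(elements),
            quantize(sum(per_patient.values())),
            len(per_patient),
        )
        for elements, per_patient in best.items()
    ]
    stats.sort(key=lambda s: (-s.utility, s.pattern))
    return stats


def brute_topk(
    dataset: SequentialDataset,
    k: int,
    max_size: int,
    cap: int = DEFAULT_CAP,
    combiner: Combiner = product_combiner,
) -> tuple[list[PatternStats], float]:
    """Top-k patterns by exhaustive enumeration, plus the optimal threshold.

    Returns ``(ranked, min_util_opt)`` where ``min_util_opt`` is the
    utility of the k-th (or last, if fewer) pattern — the threshold a
    fixed-threshold run would need to recover the same set.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    stats = enumerate_patterns(dataset, max_size, cap, combiner)
    top = stats[:k]
    min_util_opt = top[-1].utility if top else 0.0
    return top, min_util_opt
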