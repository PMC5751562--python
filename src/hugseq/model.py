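"""Core utility model for gene-regulation sequence mining.

A time-course expression experiment is reduced to a *sequence database*:
each patient is an ordered list of *genesets*, and each geneset holds the
gene-regulation items (gene up- or down-regulated) active at one time
sample, annotated with the magnitude of the fold change (the *internal
utility*).  A disease-specific gene-importance table supplies the
*external utility*.  The utility of an item is the combination of the
two (by default their product); pattern utilities build on that:

* the utility of a pattern occurrence is the sum of its matched geneset
  utilities,
* the utility of a pattern in a patient is the **maximum** over its
  occurrences,
* the utility of a pattern in the dataset is the **sum** over patients.

The *rest utility* ``psi`` of a pattern adds to its utility the total
item utility of the patient's suffix starting at the last geneset of
the pattern's first (earliest-ending) occurrence.  ``psi`` upper-bounds
the utility of every extension of the pattern and therefore drives both
search-order heuristics and sound pruning in :mod:`hugseq.miner`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

UP = "+"
DOWN = "-"
DIRECTIONS = (UP, DOWN)

#: Global tolerance for utility equality / ordering decisions.
UTIL_TOL = 1e-9

#: Decimal places used when quantizing utilities for ranking.
UTIL_DECIMALS = 9

ItemId = tuple[str, str]
Element = tuple[ItemId, ...]

#: Default combiner of external (importance) and internal (fold-change
#: magnitude) utility: their product.
def product_combiner(importance: float, internal: float) -> float:
    return importance * internal


Combiner = Callable[[float, float], float]


def quantize(utility: float) -> float:
    """Round a utility to the global comparison precision."""
    return round(utility, UTIL_DECIMALS)


class NoOccurrenceError(LookupError):
    """A pattern has no occurrence where one was required."""


class ContainmentError(ValueError):
    """An item identity is absent from the geneset it should match."""


class ParameterError(ValueError):
    """An invalid user-facing parameter (k, gamma, delta, ...)."""


def _parse_item_token(token: str) -> ItemId:
    token = token.strip()
    if len(token) < 2 or token[-1] not in DIRECTIONS:
        raise ValueError(f"malformed item token {token!r}; expected e.g. 'G1+'")
    return (token[:-1], token[-1])


def _canonical_element(items: Iterable[ItemId]) -> Element:
    seen = sorted(set(items))
    return tuple(seen)


@dataclass(frozen=True, order=True)
class Pattern:
    """A gene-regulation sequential pattern: an ordered tuple of elements.

    Each element is a canonically sorted tuple of ``(gene, direction)``
    identities; no utilities are stored.  Patterns are hashable and
    totally ordered (element-tuple lexicographic order), which fixes all
    tie-breaking throughout the package.
    """

    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("a pattern needs at least one element")
        for el in self.elements:
            if not el:
                raise ValueError("pattern elements must be non-empty")
            if list(el) != sorted(set(el)):
                raise ValueError(f"element {el!r} is not canonical")

    @classmethod
    def of(cls, elements: Iterable[Iterable[str | ItemId]]) -> "Pattern":
        """Build from e.g. ``[["G1+", "G2-"], ["G1-"]]`` or item tuples."""
        built = []
        for el in elements:
            ids = [
                it if isinstance(it, tuple) else _parse_item_token(it) for it in el
            ]
            built.append(_canonical_element(ids))
        return cls(tuple(built))

    @classmethod
    def parse(cls, text: str) -> "Pattern":
        """Parse the display form ``(G1+ G2-)(G1-)``."""
        groups = re.findall(r"\(([^()]*)\)", text)
        if not groups or "".join(groups).strip() == "":
            raise ValueError(f"cannot parse pattern {text!r}")
        return cls.of([g.split() for g in groups])

    @property
    def length(self) -> int:
        """Number of elements (genesets) in the pattern."""
        return len(self.elements)

    @property
    def size(self) -> int:
        """Total number of items over all elements."""
        return sum(len(el) for el in self.elements)

    def items(self) -> Iterator[ItemId]:
        for el in self.elements:
            yield from el

    def __str__(self) -> str:
        return "".join(
            "(" + " ".join(f"{g}{d}" for g, d in el) + ")" for el in self.elements
        )


@dataclass(frozen=True)
class Item:
    """One gene-regulation event: a gene moving up or down by some magnitude."""

    gene: str
    direction: str
    internal_utility: float

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not (self.internal_utility >= 0 and math.isfinite(self.internal_utility)):
            raise ValueError("internal utility must be finite and >= 0")

    @property
    def item_id(self) -> ItemId:
        return (self.gene, self.direction)


@dataclass
class GeneImportanceTable:
    """Disease-specific gene scores (external utility).

    A gene absent from the table scores ``default`` (0 by default, so
    unlisted genes contribute nothing to mining utilities).
    """

    scores: dict[str, float] = field(default_factory=dict)
    default: float = 0.0

    def __post_init__(self) -> None:
        for gene, s in self.scores.items():
            if not (math.isfinite(s) and s >= 0):
                raise ValueError(f"importance of {gene!r} must be finite and >= 0")

    def score(self, gene: str) -> float:
        return self.scores.get(gene, self.default)


@dataclass
class Geneset:
    """The set of regulation items active at one time sample."""

    time_sample_id: int
    items: dict[ItemId, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (gene, direction), iu in self.items.items():
            if direction not in DIRECTIONS:
                raise ValueError(f"bad direction in item ({gene}, {direction})")
            if not (math.isfinite(iu) and iu >= 0):
                raise ValueError("internal utilities must be finite and >= 0")
        # canonical storage order (gene, then up before down)
        ordered = {k: self.items[k] for k in sorted(self.items)}
        self.items.clear()
        self.items.update(ordered)

    def contains(self, element: Element) -> bool:
        return all(item in self.items for item in element)

    def item_ids(self) -> tuple[ItemId, ...]:
        return tuple(self.items)


@dataclass
class PatientSequence:
    """A patient's ordered genesets (strictly increasing time samples)."""

    patient_id: str
    genesets: list[Geneset] = field(default_factory=list)

    def __post_init__(self) -> None:
        tids = [gs.time_sample_id for gs in self.genesets]
        if any(b <= a for a, b in zip(tids, tids[1:])):
            raise ValueError(
                f"time samples of patient {self.patient_id!r} must strictly increase"
            )


@dataclass
class SequentialDataset:
    """The mined object: patients + importance table + the gamma used to build it."""

    patients: list[PatientSequence]
    importance: GeneImportanceTable
    gamma: float = 1.0

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")

    def item_ids(self) -> list[ItemId]:
        """All distinct item identities, in canonical order."""
        seen: set[ItemId] = set()
        for p in self.patients:
            for gs in p.genesets:
                seen.update(gs.items)
        return sorted(seen)

    def patient(self, patient_id: str) -> PatientSequence:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


@dataclass(frozen=True)
class Occurrence:
    """One embedding of a pattern in a patient, with its summed utility."""

    patient_id: str
    time_sample_ids: tuple[int, ...]
    utility: float


# ---------------------------------------------------------------------------
# utility operations
# ---------------------------------------------------------------------------

def item_utility(
    item: Item,
    importance: GeneImportanceTable,
    combiner: Combiner = product_combiner,
) -> float:
    """Utility of one regulation event: combine importance with fold magnitude."""
    return combiner(importance.score(item.gene), item.internal_utility)


def _cell_utility(
    item_id: ItemId,
    internal: float,
    importance: GeneImportanceTable,
    combiner: Combiner,
) -> float:
    return combiner(importance.score(item_id[0]), internal)


def geneset_utility(
    element: Element,
    geneset: Geneset,
    importance: GeneImportanceTable,
    combiner: Combiner = product_combiner,
) -> float:
    """Sum of item utilities of ``element``'s items matched inside ``geneset``.

    Only the matched items count; other items of the geneset are ignored.
    """
    total = 0.0
    for item_id in element:
        if item_id not in geneset.items:
            raise ContainmentError(
                f"item {item_id} not in geneset at time sample {geneset.time_sample_id}"
            )
        total += _cell_utility(item_id, geneset.items[item_id], importance, combiner)
    return total


def find_occurrences(
    pattern: Pattern,
    patient: PatientSequence,
    importance: GeneImportanceTable,
    combiner: Combiner = product_combiner,
) -> list[Occurrence]:
    """Every embedding of ``pattern`` with strictly increasing time samples.

    Returned sorted lexicographically by the time-sample-id vector.
    """
    genesets = patient.genesets
    n = len(genesets)
    out: list[Occurrence] = []
    elements = pattern.elements

    def rec(ei: int, start: int, tids: list[int], acc: float) -> None:
        if ei == len(elements):
            out.append(Occurrence(patient.patient_id, tuple(tids), acc))
            return
        for gi in range(start, n):
            gs = genesets[gi]
            if gs.contains(elements[ei]):
                u = geneset_utility(elements[ei], gs, importance, combiner)
                tids.append(gs.time_sample_id)
                rec(ei + 1, gi + 1, tids, acc + u)
                tids.pop()

    rec(0, 0, [], 0.0)
    return out


def pattern_utility_in_patient(
    pattern: Pattern,
    patient: PatientSequence,
    importance: GeneImportanceTable,
    combiner: Combiner = product_combiner,
) -> float:
    """Maximum occurrence utility in this patient; 0 if the pattern is absent."""
    occs = find_occurrences(pattern, patient, importance, combiner)
    return max((o.utility for o in occs), default=0.0)


def pattern_utility(
    pattern: Pattern,
    dataset: SequentialDataset,
    combiner: Combiner = product_combiner,
) -> float:
    """Dataset utility: per-patient maxima summed over all patients."""
    return sum(
        pattern_utility_in_patient(pattern, p, dataset.importance, combiner)
        for p in dataset.patients
    )


def support(pattern: Pattern, dataset: SequentialDataset) -> int:
    """Number of patients containing at least one occurrence."""
    count = 0
    for p in dataset.patients:
        if find_occurrences(pattern, p, dataset.importance):
            count += 1
    return count


def first_occurrence(
    pattern: Pattern,
    patient: PatientSequence,
    importance: GeneImportanceTable,
    combiner: Combiner = product_combiner,
) -> Occurrence:
    """The occurrence whose last geneset is earliest.

    Ties (several embeddings sharing the minimal final time sample) go to
    the lexicographically smallest time-sample-id vector, which makes the
    rest sequence — and hence the rest-utility bound — deterministic.
    """
    occs = find_occurrences(pattern, patient, importance, combiner)
    if not occs:
        raise NoOccurrenceError(
            f"pattern {pattern} does not occur in patient {patient.patient_id}"
        )
    return min(occs, key=lambda o: (o.time_sample_ids[-1], o.time_sample_ids))


def rest_sequence(
    patient: PatientSequence,
    pattern: Pattern,
    importance: GeneImportanceTable,
    combiner: Combiner = product_combiner,
) -> PatientSequence:
    """Suffix of the patient from (and including) the last geneset of the
    first occurrence of ``pattern``."""
    occ = first_occurrence(pattern, patient, importance, combiner)
    last_tid = occ.time_sample_ids[-1]
    idx = next(
        i for i, gs in enumerate(patient.genesets) if gs.time_sample_id == last_tid
    )
    return PatientSequence(patient.patient_id, patient.genesets[idx:])


def sequence_total_utility(
    patient: PatientSequence,
    importance: GeneImportanceTable,
    combiner: Combiner = product_combiner,
) -> float:
    """Sum of all item utilities over all genesets of the patient."""
    total = 0.0
    for gs in patient.genesets:
        for item_id, iu in gs.items.items():
            total += _cell_utility(item_id, iu, importance, combiner)
    return total


def upper_utility(
    pattern: Pattern,
    patient: PatientSequence,
    importance: GeneImportanceTable,
    combiner: Combiner = product_combiner,
) -> float:
    """Rest utility ``psi`` in one patient: pattern utility plus the total
    utility of the suffix from the first occurrence's last geneset.

    0 when the pattern does not occur.  Upper-bounds the in-patient
    utility of every extension of ``pattern``.
    """
    occs = find_occurrences(pattern, patient, importance, combiner)
    if not occs:
        return 0.0
    gu = max(o.utility for o in occs)
    rest = rest_sequence(patient, pattern, importance, combiner)
    return gu + sequence_total_utility(rest, importance, combiner)


def upper_utility_dataset(
    pattern: Pattern,
    dataset: SequentialDataset,
    combiner: Combiner = product_combiner,
) -> float:
    """Rest utility ``psi`` summed over all patients."""
    return sum(
        upper_utility(pattern, p, dataset.importance, combiner)
        for p in dataset.patients
    )
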