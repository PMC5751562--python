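"""Top-k high-utility sequence mining over a lexicographic pattern tree.

The search maintains, per pattern, a *sequence utility list*: tuples
``(patient, last time sample, occurrence utility)`` keeping only the
maximal occurrence utility per (patient, last time sample) — a dominated
partial occurrence can never yield the per-patient maximum after an
extension, because every extension adds the same suffix utility to all
occurrences ending at the same time sample.  Children are produced by
two joins:

* **I-step** — add an item to the last element (same time sample join);
  only items lexicographically greater than the current last item are
  tried, so every pattern is generated exactly once;
* **S-step** — open a new element after the last one (strictly later
  time sample join, keeping the best predecessor utility).

A fixed-capacity :class:`TKList` holds the current best k patterns and
the dynamic threshold ``min_util`` (the k-th utility once full, never
decreasing).  A subtree is pruned when the rest utility ``psi`` of its
root falls below ``min_util`` — sound because ``psi`` upper-bounds the
utility of every extension.  Two optional strategies accelerate the
threshold's rise without changing the output:

* **PES** (pre-evaluation) seeds the TKList with all single-item
  utilities and all whole-patient-sequence utilities before the tree is
  built, so ``min_util`` starts above zero;
* **RSO** (rest-utility-sorted order) expands sibling extensions in
  descending ``psi`` order, so promising subtrees are visited first.

A fixed-threshold mode mines every pattern whose utility reaches a
given ``delta`` instead of the top k.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import (
    Combiner,
    ItemId,
    ParameterError,
    Pattern,
    PatientSequence,
    SequentialDataset,
    product_combiner,
    quantize,
    sequence_total_utility,
    support as pattern_support,
)

__all__ = [
    "ItemUtilList",
    "SeqUtilListEntry",
    "TreeNode",
    "TKList",
    "MinerContext",
    "MiningResult",
    "build_item_util_lists",
    "pes_initialize",
    "i_step",
    "s_step",
    "rso_order",
    "update_tklist",
    "mine_topk",
    "mine_with_threshold",
]


@dataclass(frozen=True)
class SeqUtilListEntry:
    patient_id: str
    last_time_sample_id: int
    utility: float


@dataclass
class ItemUtilList:
    """Inverted index of one item: (patient, time sample, utility) rows."""

    item: ItemId
    rows: list[tuple[str, int, float]] = field(default_factory=list)


@dataclass
class TreeNode:
    """A node of the lexicographic pattern tree.

    ``entries`` maps patient index -> {last time sample -> maximal
    occurrence utility of the node's pattern ending there}.
    """

    pattern: Pattern
    kind: str  # "I" or "S"
    entries: dict[int, dict[int, float]]
    utility: float
    psi: float

    def seq_util_list(self, patients: Sequence[PatientSequence]) -> list[SeqUtilListEntry]:
        out = []
        for pi in sorted(self.entries):
            pid = patients[pi].patient_id
            for tid in sorted(self.entries[pi]):
                out.append(SeqUtilListEntry(pid, tid, self.entries[pi][tid]))
        return out


class TKList:
    """Fixed-capacity ranked store of the best k patterns seen so far.

    Entries are deduplicated by pattern (keeping the larger utility).
    ``min_util`` equals the k-th utility once the list is full, is 0
    before that, and never decreases.  Ranking ties are broken by
    lexicographic pattern order, smallest kept.
    """

    def __init__(self, k: int):
        if k < 1:
            raise ParameterError(f"k must be >= 1, got {k}")
        self.k = k
        self.entries: dict[Pattern, float] = {}
        self._min_util = 0.0
        self.trajectory: list[float] = [0.0]

    @property
    def min_util(self) -> float:
        return self._min_util

    def insert(self, pattern: Pattern, utility: float) -> bool:
        qu = quantize(utility)
        cur = self.entries.get(pattern)
        if cur is not None:
            if qu > cur:
                self.entries[pattern] = qu
                self._update_threshold()
            return True
        if len(self.entries) < self.k:
            self.entries[pattern] = qu
            self._update_threshold()
            return True
        if qu >= self._min_util:
            self.entries[pattern] = qu
            for pat, _ in self.ranked()[self.k:]:
                del self.entries[pat]
            self._update_threshold()
            return True
        return False

    def _update_threshold(self) -> None:
        if len(self.entries) >= self.k:
            kth = min(self.entries.values())
            if kth > self._min_util:
                self._min_util = kth
                self.trajectory.append(kth)

    def ranked(self) -> list[tuple[Pattern, float]]:
        return sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))


def update_tklist(tklist: TKList, pattern: Pattern, utility: float) -> tuple[TKList, float]:
    """Insert one (pattern, utility) candidate; returns (list, new min_util)."""
    if utility < 0:
        raise ParameterError("utilities are non-negative")
    tklist.insert(pattern, utility)
    return tklist, tklist.min_util


class MinerContext:
    """Dataset-derived indexes shared by all nodes of one mining run."""

    def __init__(self, dataset: SequentialDataset, combiner: Combiner = product_combiner):
        self.dataset = dataset
        self.combiner = combiner
        imp = dataset.importance
        self.items: list[ItemId] = dataset.item_ids()
        # item -> patient index -> {time sample -> item utility}
        self.item_rows: dict[ItemId, dict[int, dict[int, float]]] = {}
        # per patient: {time sample -> total item utility from there to the end}
        self.suffix: list[dict[int, float]] = []
        for pi, patient in enumerate(dataset.patients):
            acc = 0.0
            suf: dict[int, float] = {}
            for gs in reversed(patient.genesets):
                acc += sum(
                    combiner(imp.score(g), iu) for (g, _), iu in gs.items.items()
                )
                suf[gs.time_sample_id] = acc
            self.suffix.append(suf)
            for gs in patient.genesets:
                for item_id, iu in gs.items.items():
                    util = combiner(imp.score(item_id[0]), iu)
                    self.item_rows.setdefault(item_id, {}).setdefault(pi, {})[
                        gs.time_sample_id
                    ] = util

    # -- node construction ---------------------------------------------------

    def _make_node(self, pattern: Pattern, kind: str,
                   entries: dict[int, dict[int, float]]) -> TreeNode:
        utility = sum(max(d.values()) for d in entries.values())
        psi = sum(
            max(d.values()) + self.suffix[pi][min(d)] for pi, d in entries.items()
        )
        return TreeNode(pattern, kind, entries, utility, psi)

    def singleton_node(self, item: ItemId) -> TreeNode | None:
        rows = self.item_rows.get(item)
        if not rows:
            return None
        entries = {pi: dict(tids) for pi, tids in rows.items()}
        return self._make_node(Pattern(((item,),)), "S", entries)


def build_item_util_lists(
    dataset: SequentialDataset, combiner: Combiner = product_combiner
) -> dict[ItemId, ItemUtilList]:
    """Complete inverted index of every item's (patient, time sample, utility)."""
    ctx = MinerContext(dataset, combiner)
    out: dict[ItemId, ItemUtilList] = {}
    for item in ctx.items:
        rows = []
        for pi in sorted(ctx.item_rows[item]):
            pid = dataset.patients[pi].patient_id
            for tid in sorted(ctx.item_rows[item][pi]):
                rows.append((pid, tid, ctx.item_rows[item][pi][tid]))
        out[item] = ItemUtilList(item, rows)
    return out


def i_step(ctx: MinerContext, node: TreeNode, item: ItemId) -> TreeNode | None:
    """Extend the last element with ``item`` (same-time-sample join).

    Returns ``None`` when the extension has no occurrence.  Callers must
    respect the canonical order (``item`` greater than the last item of
    the node's last element); violations simply aren't generated.
    """
    rows = ctx.item_rows.get(item)
    if not rows:
        return None
    entries: dict[int, dict[int, float]] = {}
    for pi, tid_map in node.entries.items():
        prow = rows.get(pi)
        if not prow:
            continue
        d = {}
        for tid, u in tid_map.items():
            iu = prow.get(tid)
            if iu is not None:
                d[tid] = u + iu
        if d:
            entries[pi] = d
    if not entries:
        return None
    elements = node.pattern.elements
    pattern = Pattern(elements[:-1] + (elements[-1] + (item,),))
    return ctx._make_node(pattern, "I", entries)


def s_step(ctx: MinerContext, node: TreeNode, item: ItemId) -> TreeNode | None:
    """Open a new element ``{item}`` after the last one (later-time join).

    For each (patient, new last time sample) the maximal extended
    occurrence utility is kept.
    """
    rows = ctx.item_rows.get(item)
    if not rows:
        return None
    entries: dict[int, dict[int, float]] = {}
    for pi, tid_map in node.entries.items():
        prow = rows.get(pi)
        if not prow:
            continue
        ptids = sorted(tid_map)
        prefix_max: list[float] = []
        best = float("-inf")
        for t in ptids:
            best = max(best, tid_map[t])
            prefix_max.append(best)
        d = {}
        for tid_i in sorted(prow):
            idx = bisect_left(ptids, tid_i)
            if idx > 0:
                d[tid_i] = prefix_max[idx - 1] + prow[tid_i]
        if d:
            entries[pi] = d
    if not entries:
        return None
    pattern = Pattern(node.pattern.elements + ((item,),))
    return ctx._make_node(pattern, "S", entries)


@dataclass
class Extension:
    item: ItemId
    kind: str  # "I" or "S"
    node: TreeNode


def _extensions(ctx: MinerContext, node: TreeNode, max_size: int | None) -> list[Extension]:
    """All non-empty one-step extensions, in canonical (I then S) order.

    ``max_size`` caps the total item count; each step adds exactly one
    item, so a node at the cap generates nothing.
    """
    if max_size is not None and node.pattern.size >= max_size:
        return []
    exts: list[Extension] = []
    last_item = node.pattern.elements[-1][-1]
    for item in ctx.items:
        if item > last_item:
            child = i_step(ctx, node, item)
            if child is not None:
                exts.append(Extension(item, "I", child))
    for item in ctx.items:
        child = s_step(ctx, node, item)
        if child is not None:
            exts.append(Extension(item, "S", child))
    return exts


def rso_order(extensions: Iterable[Extension]) -> list[Extension]:
    """Sort sibling extensions by descending rest utility ``psi``.

    Ties break S-extensions before I-extensions, then by item identity —
    an arbitrary but fixed rule that keeps runs deterministic.
    """
    return sorted(
        extensions,
        key=lambda e: (-quantize(e.node.psi), 0 if e.kind == "S" else 1, e.item),
    )


def _full_sequence_pattern(patient: PatientSequence) -> Pattern | None:
    if not patient.genesets:
        return None
    return Pattern(tuple(gs.item_ids() for gs in patient.genesets))


def pes_initialize(
    dataset: SequentialDataset,
    k: int,
    max_size: int | None = None,
    combiner: Combiner = product_combiner,
) -> tuple[TKList, float]:
    """Pre-evaluation seeding of the TKList.

    The candidate pool is every single-item pattern with its exact
    dataset utility, plus every patient's whole sequence with the sum of
    all its item utilities (a lower bound of that pattern's dataset
    utility — safe as a seed because the tree will revisit the pattern
    with its true, not-smaller utility).  When a ``max_size`` cap is in
    force, whole sequences with more items than the cap are not seeded
    (their patterns would be unreachable by the capped search).
    """
    tk = TKList(k)
    ctx = MinerContext(dataset, combiner)
    for item in ctx.items:
        node = ctx.singleton_node(item)
        if node is not None:
            tk.insert(node.pattern, node.utility)
    for patient in dataset.patients:
        pattern = _full_sequence_pattern(patient)
        if pattern is None:
            continue
        if max_size is not None and pattern.size > max_size:
            continue
        tk.insert(pattern, sequence_total_utility(patient, dataset.importance, combiner))
    return tk, tk.min_util


@dataclass
class MiningResult:
    """Ranked patterns plus run diagnostics."""

    patterns: list[tuple[Pattern, float, int]]  # (pattern, utility, support)
    min_util: float
    candidate_count: int
    threshold_trajectory: list[float]
    k: int | None = None
    delta: float | None = None
    strategies: dict | None = None
    max_size: int | None = None
    expanded: list[tuple[Pattern, float]] | None = None
    pruned: list[tuple[Pattern, float]] | None = None


def mine_topk(
    dataset: SequentialDataset,
    k: int,
    use_pes: bool = True,
    use_rso: bool = True,
    max_size: int | None = None,
    combiner: Combiner = product_combiner,
    collect_diagnostics: bool = False,
) -> MiningResult:
    """Mine exactly the k highest-utility patterns of the dataset.

    The result is independent of the strategy flags; they only change
    how fast the dynamic threshold rises (and hence the candidate-node
    count).  Rank-boundary utility ties resolve to the lexicographically
    smallest patterns.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    ctx = MinerContext(dataset, combiner)
    if use_pes:
        tk, _ = pes_initialize(dataset, k, max_size, combiner)
    else:
        tk = TKList(k)
    state = {"candidates": 0}
    expanded: list[tuple[Pattern, float]] = []
    pruned: list[tuple[Pattern, float]] = []

    def visit(node: TreeNode) -> None:
        if collect_diagnostics:
            expanded.append((node.pattern, node.psi))
        exts = _extensions(ctx, node, max_size)
        state["candidates"] += len(exts)
        for ext in exts:
            tk.insert(ext.node.pattern, ext.node.utility)
        ordered = rso_order(exts) if use_rso else exts
        for ext in ordered:
            if quantize(ext.node.psi) >= tk.min_util:
                visit(ext.node)
            elif collect_diagnostics:
                pruned.append((ext.node.pattern, ext.node.psi))

    roots = []
    for item in ctx.items:
        node = ctx.singleton_node(item)
        if node is not None:
            roots.append(Extension(item, "S", node))
    state["candidates"] += len(roots)
    for ext in roots:
        tk.insert(ext.node.pattern, ext.node.utility)
    for ext in rso_order(roots) if use_rso else roots:
        if quantize(ext.node.psi) >= tk.min_util:
            visit(ext.node)
        elif collect_diagnostics:
            pruned.append((ext.node.pattern, ext.node.psi))

    result_patterns = [
        (pat, qu, pattern_support(pat, dataset)) for pat, qu in tk.ranked()
    ]
    return MiningResult(
        patterns=result_patterns,
        min_util=tk.min_util,
        candidate_count=state["candidates"],
        threshold_trajectory=list(tk.trajectory),
        k=k,
        strategies={"pes": use_pes, "rso": use_rso},
        max_size=max_size,
        expanded=expanded if collect_diagnostics else None,
        pruned=pruned if collect_diagnostics else None,
    )


def mine_with_threshold(
    dataset: SequentialDataset,
    delta: float,
    max_size: int | None = None,
    combiner: Combiner = product_combiner,
) -> MiningResult:
    """Mine every pattern whose dataset utility is at least ``delta``.

    The threshold is fixed (inclusive), so the expansion order is
    irrelevant; subtrees are pruned when their rest utility falls below
    ``delta``.
    """
    if delta < 0:
        raise ParameterError(f"delta must be >= 0, got {delta}")
    qdelta = quantize(delta)
    ctx = MinerContext(dataset, combiner)
    found: dict[Pattern, float] = {}
    state = {"candidates": 0}

    def visit(node: TreeNode) -> None:
        exts = _extensions(ctx, node, max_size)
        state["candidates"] += len(exts)
        for ext in exts:
            if quantize(ext.node.utility) >= qdelta:
                found[ext.node.pattern] = quantize(ext.node.utility)
            if quantize(ext.node.psi) >= qdelta:
                visit(ext.node)

    for item in ctx.items:
        node = ctx.singleton_node(item)
        if node is None:
            continue
        state["candidates"] += 1
        if quantize(node.utility) >= qdelta:
            found[node.pattern] = quantize(node.utility)
        if quantize(node.psi) >= qdelta:
            visit(node)

    ranked = sorted(found.items(), key=lambda kv: (-kv[1], kv[0]))
    return MiningResult(
        patterns=[(p, u, pattern_support(p, dataset)) for p, u in ranked],
        min_util=qdelta,
        candidate_count=state["candidates"],
        threshold_trajectory=[qdelta],
        delta=delta,
        max_size=max_size,
    )
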