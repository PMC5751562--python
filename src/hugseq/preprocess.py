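"""Convert raw time-course expression values into a utility sequence database.

The pipeline has two steps.  First, every expression trajectory is turned
into *signed fold changes* against the first time sample (the baseline):
a ratio ``r = v(t) / v(0)`` is reported as ``r`` when ``r >= 1`` and as
``-1/r`` otherwise, so induction and repression are symmetric around
``+/-1`` and the baseline column is exactly 1.  Second, fold changes are
discretized with a regulation threshold ``gamma > 1``: a cell with fold
change ``f`` becomes an up-item when ``f > gamma``, a down-item (with
internal utility ``|f|``) when ``f < -gamma``, and is treated as "normal"
and dropped otherwise.  The comparison is strict, so a fold change of
exactly ``+/-gamma`` is normal.  The baseline time sample never emits
items.  Sub-threshold items are removed *before* any utility is
computed, so downstream utilities never see them.

Expression input is a long-format table (patient_id, gene, time_index,
value) or a wide CSV; the discretized database round-trips through a
one-patient-per-line text format (grammar below).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .model import (
    DOWN,
    UP,
    GeneImportanceTable,
    Geneset,
    ItemId,
    ParameterError,
    PatientSequence,
    SequentialDataset,
)

__all__ = [
    "ExpressionMatrix",
    "FoldChangeMatrix",
    "ParseError",
    "compute_fold_changes",
    "discretize_to_sequences",
    "parse_sequence_file",
    "write_sequence_file",
    "read_expression_long",
    "read_expression_wide_csv",
    "read_importance_table",
    "write_importance_table",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""


_FORBIDDEN_IN_NAME = re.compile(r"[\s{};,()]")


def _check_name(name: str, what: str) -> str:
    if not name or _FORBIDDEN_IN_NAME.search(name):
        raise ValueError(f"{what} {name!r} contains forbidden characters")
    return name


@dataclass
class ExpressionMatrix:
    """Patients x genes x ordered time samples of non-negative intensities.

    ``values`` is indexed by (patient_id, gene) with integer time-index
    columns sorted ascending; column 0 is the baseline.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.reindex(columns=sorted(self.values.columns))
        arr = self.values.to_numpy(dtype=float)
        if not (np.isfinite(arr).all() and (arr >= 0).all()):
            raise ValueError("expression values must be finite and >= 0")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        required = {"patient_id", "gene", "time_index", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"long-format table needs columns {sorted(required)}")
        wide = df.pivot_table(
            index=["patient_id", "gene"],
            columns="time_index",
            values="value",
            sort=False,
        )
        wide.columns = [int(c) for c in wide.columns]
        return cls(wide)

    @property
    def time_indices(self) -> list[int]:
        return list(self.values.columns)


@dataclass
class FoldChangeMatrix:
    """Signed fold changes, same shape as the expression matrix.

    Every cell satisfies ``|f| >= 1`` and the baseline column is 1.
    """

    values: pd.DataFrame

    @property
    def time_indices(self) -> list[int]:
        return list(self.values.columns)


def read_expression_long(path: str) -> ExpressionMatrix:
    """Read the long-format TSV (patient_id, gene, time_index, value)."""
    df = pd.read_csv(path, sep="\t")
    return ExpressionMatrix.from_long(df)


def read_expression_wide_csv(path: str) -> ExpressionMatrix:
    """Read a wide CSV: columns patient_id, gene, then time indices 0..T-1."""
    df = pd.read_csv(path)
    wide = df.set_index(["patient_id", "gene"])
    wide.columns = [int(c) for c in wide.columns]
    return ExpressionMatrix(wide)


def read_importance_table(path: str) -> GeneImportanceTable:
    """Two-column TSV (gene, score); a header line 'gene\\tscore' is optional."""
    scores: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: expected 'gene<TAB>score'")
            if lineno == 1 and parts == ["gene", "score"]:
                continue
            try:
                scores[parts[0]] = float(parts[1])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad score {parts[1]!r}") from exc
    return GeneImportanceTable(scores)


def write_importance_table(table: GeneImportanceTable, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tscore\n")
        for gene in sorted(table.scores):
            fh.write(f"{gene}\t{table.scores[gene]!r}\n")


def _signed_fold_change(value: float, baseline: float) -> float:
    r = value / baseline
    return r if r >= 1.0 else -1.0 / r


def compute_fold_changes(
    expr: ExpressionMatrix,
    baseline_policy: str = "drop",
    epsilon: float = 1e-6,
) -> FoldChangeMatrix:
    """Signed fold change of every cell against the baseline time sample.

    ``baseline_policy`` handles non-positive values (a zero baseline or a
    zero measurement, for which a ratio is undefined):

    - ``"drop"`` (default): remove the (patient, gene) trajectory;
    - ``"epsilon"``: substitute ``epsilon`` for the offending value;
    - ``"fail"``: raise :class:`ValueError`.
    """
    if baseline_policy not in {"drop", "epsilon", "fail"}:
        raise ParameterError(f"unknown baseline policy {baseline_policy!r}")
    df = expr.values.copy()
    bad = (df <= 0).any(axis=1)
    if bad.any():
        if baseline_policy == "fail":
            rows = ", ".join(map(str, df.index[bad][:5]))
            raise ValueError(f"non-positive expression values for {rows}")
        if baseline_policy == "drop":
            df = df.loc[~bad]
        else:
            df = df.mask(df <= 0, epsilon)
    cols = sorted(df.columns)
    baseline = df[cols[0]]
    out = pd.DataFrame(index=df.index, columns=cols, dtype=float)
    for c in cols:
        ratio = df[c] / baseline
        out[c] = ratio.where(ratio >= 1.0, -1.0 / ratio)
    return FoldChangeMatrix(out)


def discretize_to_sequences(
    fc: FoldChangeMatrix,
    gamma: float,
    importance: GeneImportanceTable,
) -> SequentialDataset:
    """Turn signed fold changes into the gamma-filtered sequence database.

    A cell with fold change ``f`` at a non-baseline time sample emits an
    up-item ``(gene, +, f)`` when ``f > gamma`` and a down-item
    ``(gene, -, |f|)`` when ``f < -gamma``; everything else is dropped.
    Empty genesets are dropped; patients left without any geneset are
    kept as empty sequences.
    """
    if not gamma > 1.0:
        raise ParameterError(f"gamma must be > 1, got {gamma}")
    cols = sorted(fc.values.columns)
    patients: list[PatientSequence] = []
    patient_order = list(dict.fromkeys(fc.values.index.get_level_values(0)))
    for pid in patient_order:
        block = fc.values.loc[pid]
        genesets: list[Geneset] = []
        for t in cols[1:]:  # baseline excluded
            items: dict[ItemId, float] = {}
            for gene, f in block[t].items():
                if f > gamma:
                    items[(str(gene), UP)] = float(f)
                elif f < -gamma:
                    items[(str(gene), DOWN)] = float(-f)
            if items:
                genesets.append(Geneset(int(t), items))
        patients.append(PatientSequence(str(pid), genesets))
    return SequentialDataset(patients, importance, gamma=gamma)


# ---------------------------------------------------------------------------
# sequence-database text format
# ---------------------------------------------------------------------------
#
# Grammar (UTF-8, one patient per line, '#'-prefixed header/comment lines):
#
#   file     := header* record*
#   header   := '# gamma: ' FLOAT
#   record   := patient_id ( TAB geneset ( SP geneset )* )?
#   geneset  := 't:' INT '{' item ( ';' item )* '}'
#   item     := gene ',' ('+'|'-') ',' FLOAT
#
# Items appear in canonical order (gene, then up before down); time
# indices strictly increase along a record.  Floats are written with
# repr() so that parse(write(D)) == D exactly.

_GENESET_RE = re.compile(r"^t:(\d+)\{(.*)\}$")


def write_sequence_file(dataset: SequentialDataset) -> str:
    lines = [f"# gamma: {dataset.gamma!r}"]
    for p in dataset.patients:
        _check_name(p.patient_id, "patient id")
        tokens = []
        for gs in p.genesets:
            items = ";".join(
                f"{_check_name(g, 'gene')},{d},{iu!r}" for (g, d), iu in gs.items.items()
            )
            tokens.append(f"t:{gs.time_sample_id}{{{items}}}")
        lines.append(p.patient_id + ("\t" + " ".join(tokens) if tokens else ""))
    return "\n".join(lines) + "\n"


def parse_sequence_file(
    text: str,
    importance: GeneImportanceTable | None = None,
) -> SequentialDataset:
    gamma = 1.0
    patients: list[PatientSequence] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*gamma:\s*(\S+)", line)
            if m:
                gamma = float(m.group(1))
            continue
        parts = line.split("\t")
        pid = parts[0].strip()
        if not pid:
            raise ParseError(f"line {lineno}: missing patient id")
        genesets: list[Geneset] = []
        if len(parts) > 2:
            raise ParseError(f"line {lineno}: expected at most one TAB")
        if len(parts) == 2 and parts[1].strip():
            for token in parts[1].split(" "):
                m = _GENESET_RE.match(token.strip())
                if not m:
                    raise ParseError(f"line {lineno}: malformed geneset {token!r}")
                tid = int(m.group(1))
                items: dict[ItemId, float] = {}
                for item_txt in m.group(2).split(";"):
                    fields = item_txt.split(",")
                    if len(fields) != 3 or fields[1] not in (UP, DOWN):
                        raise ParseError(
                            f"line {lineno}: malformed item {item_txt!r}"
                        )
                    key: ItemId = (fields[0], fields[1])
                    if key in items:
                        raise ParseError(
                            f"line {lineno}: duplicate item {fields[0]}{fields[1]}"
                        )
                    try:
                        items[key] = float(fields[2])
                    except ValueError as exc:
                        raise ParseError(
                            f"line {lineno}: bad utility {fields[2]!r}"
                        ) from exc
                genesets.append(Geneset(tid, items))
        try:
            patients.append(PatientSequence(pid, genesets))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    return SequentialDataset(
        patients, importance if importance is not None else GeneImportanceTable(),
        gamma=gamma,
    )
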