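"""Seeded synthetic data and the packaged worked-example fixture.

The generator emulates a time-course expression study: per (patient,
gene) a log-normal baseline intensity, multiplicative log-normal noise
around the baseline at later time samples, and *planted* regulation
patterns realized by multiplying (up) or dividing (down) the baseline by
a configured magnitude at chosen time samples — so that discretization
at the configured gamma recovers the planted items exactly, noise or
not.  Planted genes receive a high importance score; background genes a
low one.  A truth record lists every realized injection site.

Each planted pattern is injected into its own block of patients by
default.  Patterns sharing patients would compose into higher-utility
super-patterns (the union of their items outranks either pattern), which
is realistic but makes "the planted patterns are the top k" false by
construction; disjoint blocks keep recovery experiments well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    GeneImportanceTable,
    ParameterError,
    Pattern,
    SequentialDataset,
)
from .preprocess import (
    ExpressionMatrix,
    FoldChangeMatrix,
    compute_fold_changes,
    discretize_to_sequences,
)

__all__ = [
    "PlantedPattern",
    "SynthConfig",
    "generate_dataset",
    "default_benchmark_config",
    "toy_fixture",
    "toy_fold_changes",
    "toy_importance",
]


@dataclass(frozen=True)
class PlantedPattern:
    """One pattern to inject, with its injection policy.

    ``patients`` selects the patient indices eligible for injection
    (``None`` = all); each eligible patient receives the pattern with
    ``probability``, at uniformly drawn increasing time samples unless
    ``time_positions`` pins them.  ``magnitude`` is the planted fold
    change (must exceed the mining gamma to survive discretization).
    """

    pattern: Pattern
    probability: float = 1.0
    magnitude: float = 3.0
    patients: tuple[int, ...] | None = None
    time_positions: tuple[int, ...] | None = None


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the package's standard benchmark: 10 patients,
    20 genes, 8 time samples, two planted two-element patterns on
    disjoint genes and disjoint patient blocks, log-normal baselines
    around e^5.5 ≈ 245 intensity units, and per-time-sample log-noise of
    0.25 (≈10% of background cells cross gamma = 1.5 in either
    direction).  Planted genes score 0.9 importance; background genes
    draw uniformly from [0.05, 0.3].
    """

    n_patients: int = 10
    n_genes: int = 20
    n_time_samples: int = 8
    baseline_log_mean: float = 5.5
    baseline_log_sd: float = 0.6
    noise_sd: float = 0.25
    planted: tuple[PlantedPattern, ...] = ()
    planted_importance: float = 0.9
    background_importance_range: tuple[float, float] = (0.05, 0.3)
    gamma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_genes, self.n_time_samples) < 1:
            raise ParameterError("all counts must be >= 1")
        for pp in self.planted:
            if not 0.0 <= pp.probability <= 1.0:
                raise ParameterError("injection probabilities must be in [0, 1]")
            if pp.pattern.length > self.n_time_samples - 1:
                raise ParameterError(
                    f"planted pattern {pp.pattern} is longer than the "
                    f"{self.n_time_samples - 1} non-baseline time samples"
                )
            if pp.magnitude <= self.gamma:
                raise ParameterError("planted magnitude must exceed gamma")


def _gene_name(i: int) -> str:
    return f"G{i + 1:02d}"


def default_benchmark_config(seed: int = 0, noise_sd: float = 0.25) -> SynthConfig:
    """The standard two-pattern benchmark configuration."""
    p1 = Pattern.of([["G01+", "G02+"], ["G03-"]])
    p2 = Pattern.of([["G04-"], ["G05+", "G06-"]])
    return SynthConfig(
        noise_sd=noise_sd,
        planted=(
            PlantedPattern(p1, patients=(0, 1, 2, 3, 4)),
            PlantedPattern(p2, patients=(5, 6, 7, 8, 9)),
        ),
        seed=seed,
    )


def generate_dataset(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, GeneImportanceTable, list[dict]]:
    """Draw one synthetic expression study; reproducible under ``config.seed``.

    Returns the expression matrix, the importance table, and the truth
    record: one dict per realized injection with the pattern, patient id
    and time samples used.
    """
    rng = np.random.default_rng(config.seed)
    genes = [_gene_name(i) for i in range(config.n_genes)]
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    T = config.n_time_samples

    baselines = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd,
        size=(config.n_patients, config.n_genes),
    )
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_patients, config.n_genes, T))
    values = baselines[:, :, None] * np.exp(noise)
    values[:, :, 0] = baselines  # baseline column is noise-free by construction

    planted_genes = {
        g for pp in config.planted for g, _ in pp.pattern.items()
    }
    unknown = planted_genes - set(genes)
    if unknown:
        raise ParameterError(f"planted genes {sorted(unknown)} outside the gene panel")
    gene_idx = {g: i for i, g in enumerate(genes)}

    truth: list[dict] = []
    for pp in config.planted:
        eligible = (
            range(config.n_patients) if pp.patients is None else pp.patients
        )
        for pi in eligible:
            if rng.random() >= pp.probability:
                continue
            if pp.time_positions is not None:
                positions = list(pp.time_positions)
            else:
                positions = sorted(
                    rng.choice(np.arange(1, T), size=pp.pattern.length, replace=False)
                )
            for element, t in zip(pp.pattern.elements, positions):
                for gene, direction in element:
                    gi = gene_idx[gene]
                    b = baselines[pi, gi]
                    values[pi, gi, t] = (
                        b * pp.magnitude if direction == "+" else b / pp.magnitude
                    )
            truth.append(
                {
                    "pattern": str(pp.pattern),
                    "patient_id": patients[pi],
                    "time_samples": [int(t) for t in positions],
                }
            )

    index = pd.MultiIndex.from_product(
        [patients, genes], names=["patient_id", "gene"]
    )
    frame = pd.DataFrame(
        values.reshape(config.n_patients * config.n_genes, T),
        index=index,
        columns=range(T),
    )
    scores = {
        g: (
            config.planted_importance
            if g in planted_genes
            else float(rng.uniform(*config.background_importance_range))
        )
        for g in genes
    }
    return ExpressionMatrix(frame), GeneImportanceTable(scores), truth


def generate_sequential_dataset(
    config: SynthConfig,
) -> tuple[SequentialDataset, list[dict]]:
    """Convenience: generate, fold-change, and discretize in one call."""
    expr, importance, truth = generate_dataset(config)
    fc = compute_fold_changes(expr)
    return discretize_to_sequences(fc, config.gamma, importance), truth


# ---------------------------------------------------------------------------
# the packaged three-patient worked example
# ---------------------------------------------------------------------------

# Signed fold changes of three genes over four time samples (baseline
# first) for three patients; the worked example used across the docs.
_TOY_FOLD_CHANGES: dict[str, dict[str, list[float]]] = {
    "P1": {
        "G1": [1.0, 2.2, -2.4, -4.8],
        "G2": [1.0, -3.2, 1.4, 3.0],
        "G3": [1.0, -1.1, -1.6, -1.6],
    },
    "P2": {
        "G1": [1.0, 6.1, 1.0, 2.6],
        "G2": [1.0, 3.2, 1.9, -2.8],
        "G3": [1.0, -1.9, -1.1, 2.9],
    },
    "P3": {
        "G1": [1.0, -3.1, -6.6, -15.0],
        "G2": [1.0, 1.1, 1.0, -6.2],
        "G3": [1.0, 2.0, 1.7, 2.2],
    },
}

_TOY_IMPORTANCE = {"G1": 0.8, "G2": 0.6, "G3": 0.1}


def toy_fold_changes() -> FoldChangeMatrix:
    """Signed fold-change matrix of the three-patient worked example."""
    rows = []
    index = []
    for pid, genes in _TOY_FOLD_CHANGES.items():
        for gene, vals in genes.items():
            index.append((pid, gene))
            rows.append(vals)
    frame = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["patient_id", "gene"]),
        columns=range(4),
        dtype=float,
    )
    return FoldChangeMatrix(frame)


def toy_importance() -> GeneImportanceTable:
    return GeneImportanceTable(dict(_TOY_IMPORTANCE))


def toy_fixture(gamma: float = 1.5) -> tuple[SequentialDataset, GeneImportanceTable]:
    """The gamma-filtered worked-example sequence database.

    Three patients, three genes, four time samples, importance scores
    {G1: 0.8, G2: 0.6, G3: 0.1}; byte-stable across releases.
    """
    importance = toy_importance()
    dataset = discretize_to_sequences(toy_fold_changes(), gamma, importance)
    return dataset, importance
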