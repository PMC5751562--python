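# hugseq

Top-k high-utility gene-regulation sequential pattern mining from
time-course expression data.

## What it does

Given a time-course expression study (patients × genes × ordered time
samples) and a disease-specific gene-importance table, `hugseq` finds the
k sequences of gene-regulation events — e.g. *"G1 up together with G2 down,
later followed by G1 down"* — that maximize a utility combining how
disease-relevant the genes are with how strongly they moved. Frequency-based
sequence mining surfaces common but uninformative patterns; utility-based
mining targets the ones that matter for a disease of interest.

The pipeline:

1. **Fold changes** — each trajectory is divided by its first (baseline)
   sample; a ratio r is reported as r if r ≥ 1 and as −1/r otherwise.
2. **Discretization** — with a threshold γ > 1 (default 1.5), a fold change
   f becomes an up-item `g+` when f > γ, a down-item `g−` (internal utility
   |f|) when f < −γ, and is dropped otherwise.
3. **Mining** — the utility of item g at a time sample is
   `GI(g) · IGU(g)` (gene importance × fold magnitude); an occurrence of a
   pattern sums its matched geneset utilities; a pattern scores the
   *maximum* occurrence utility per patient, *summed* over patients
   (`GU(α, D)`). The miner returns exactly the top-k patterns by `GU`, or
   all patterns above a fixed threshold δ.

The search walks a lexicographic pattern tree with per-node sequence
utility lists, raises a dynamic threshold through a fixed-capacity top-k
list, and prunes subtrees with the rest-utility bound Ψ (pattern utility
plus the remaining suffix utility — an upper bound on every extension).
Two strategies, PES (pre-evaluation seeding) and RSO (rest-utility-sorted
expansion), speed the threshold's rise without changing the output; a
brute-force oracle verifies that on desk-scale data. See
`docs/methods.md` for the full model.

## Worked example

The package ships a three-patient, three-gene, four-sample fixture with
importance scores {G1: 0.8, G2: 0.6, G3: 0.1}:

```python
from hugseq import toy_fixture, mine_topk, Pattern, pattern_utility

dataset, importance = toy_fixture(gamma=1.5)
print(pattern_utility(Pattern.parse("(G1-)"), dataset))
for pattern, utility, support in mine_topk(dataset, k=3, max_size=3).patterns:
    print(f"{pattern}  utility={utility}  support={support}")
```

prints

```
15.84
(G1-)(G1-)  utility=23.04  support=2
(G1-)(G1- G2-)  utility=21.0  support=1
(G1-)(G1-)(G1-)  utility=19.76  support=1
```

`15.84` is the dataset utility of "G1 down-regulated": its best occurrence
is worth 3.84 in patient 1 and 12.0 in patient 3 (and it never occurs in
patient 2). With at most three items per pattern (`max_size=3`), the top
pattern is "G1 down, later G1 down again", worth 5.76 in patient 1 plus
17.28 in patient 3; `support` counts the patients containing each pattern.

Command line, end to end:

```
hugseq synth --seed 5 --out study/
hugseq mine --expression study/expression.tsv --importance study/importance.tsv \
            --k 4 --max-size 2 --out run/
hugseq evaluate --results run/patterns.tsv --ranking disease_genes.txt
```

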