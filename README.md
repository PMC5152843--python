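# glyccomp

Replicate comparison, adduct-group merging and relative quantification for
GlycReSoft-style composition match tables from top-down LC-MS analysis of
glycosaminoglycans (e.g. low-molecular-weight heparins such as enoxaparin).

GlycReSoft assigns a bracketed *Compound Key* — a composition 5-tuple like
`[1,4,5,2,7]` for `[ΔHexA, HexA, GlcN, Ac, SO3]` — to every deconvoluted
mass it matches, along with a *Score* and a summed ion *Total Volume*.
Because one chain appears as many ammonium-adduct states and distinct
compositions can be indistinguishable at 5 ppm, single-run match lists are
full of false positives. This toolkit automates the screening workflow:

1. **Read** one tab-delimited table per sample/replicate, drop rows with
   empty compound keys (noise), and pool the tables with per-row
   provenance labels.
2. **Screen** by the all-presence principle: a composition is kept only if
   its extracted key occurs in *every* sample being compared.
3. **Merge** surviving rows per (key, sample): maximum score, exact summed
   total volume across adduct-split rows.
4. **Quantify** by normalizing each sample's volumes to the summed volume
   of its 10 most abundant components, and evaluate retained sets against
   manual truth annotations (false-positive rate, false negatives).
5. **Enumerate** the intact-chain composition hypothesis (constraint-
   coupled counts, ammonium adducts 0–14, MW window 500–6000 Da, dp ≤ 18)
   and match observed masses within a ppm tolerance.
6. **Simulate** replicate tables with planted ground truth for testing.

## CLI

```sh
# screen three replicate tables and merge adduct groups
glyccomp compare lot1.txt lot2.txt lot3.txt -o merged.tsv [--min-score 0.1] \
    [--labels a,b,c] [--profile default|pnp] [--anhydro]

# relative quantification normalized to the top-10 most abundant components
glyccomp quantify merged.tsv -o abundances.tsv [--top-n 10]

# false-positive rate against a manual truth annotation
glyccomp fdr merged.tsv --truth truth.txt

# enumerate the composition/adduct hypothesis
glyccomp hypothesis -o hypothesis.tsv [--mw-min 500 --mw-max 6000 ...]

# generate replicate fixtures with planted ground truth
glyccomp simulate --k 3 --true 10 --decoy 15 --seed 7 --out fixtures/
```

Input tables are tab-delimited with a header; the `Compound Key`, `Score`
and `Total Volume` columns are resolved case-insensitively and can be
remapped with `--column role=HeaderName`. All other columns pass through.
Per-stage row counts (raw → keyed → pooled → retained → merged) are logged
on stderr.

Two key dialects are supported: the intact-chain order
`[ΔHexA, HexA, GlcN, Ac, SO3]` (default) and the synthesized-standard
order `[HexA, GlcN, PNP=1, SO3, Ac]` (`--profile pnp`).

## Library

```python
from glyccomp import compare, top_n_normalize, fdr_evaluate, read_truth

results = compare(["lot1.txt", "lot2.txt", "lot3.txt"])
abundances = top_n_normalize(results, n=10)
report = fdr_evaluate(results, read_truth("truth.txt"))
```

Monoisotopic mass constants are hard-coded from standard atomic masses;
`scripts/derive_masses.py` reproduces the derivation. The 1,6-anhydro
reducing-end variant of the terminal residue is exactly one H2O lighter.

## Tests

```sh
python -m pytest tests/
```

The suite checks the pipeline against independent oracles: a naive
set-intersection + group-by comparator, a literal row-by-row simulator of
the original spreadsheet merging loop, a quintuple-loop hypothesis
enumerator and an element-sum mass calculator.

One acceptance test (`tests/test_acceptance.py::test_criterion_1_fdr_worked_example`)
requires the published supplementary matching-result workbook for four
synthesized heparin oligosaccharides, which cannot be redistributed here;
it fails with instructions unless the workbook is placed at
`data/fdr_workbook.xlsx` (sheets `A-1` … `D-3`) with truth annotations at
`data/truth_<oligo>.txt`, or pointed to via `GLYCCOMP_FDR_WORKBOOK`.

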