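# allerkit

Computational prediction of protein allergens, for people assessing the
allergenic potential of novel or transgenic proteins and for method
developers who need a self-contained, testable implementation of the three
classic approaches:

1. **FAO/WHO sequence rules.** Rule 1 flags a query that shares an exact
   stretch of ≥ 6 consecutive identical residues (a *word*) with any known
   allergen; the word length *w* is configurable (6–14 is the interesting
   range). Rule 2 slides an 80-residue window along the query one residue at
   a time, locally aligns every window against every known allergen
   (Smith–Waterman, BLOSUM62, gap open 11 / extend 1), and flags the query
   if any window reaches ≥ 35% identity. Both the identity threshold and the
   denominator convention (alignment length vs. fixed window length) are
   configurable, and the two rules can be combined by conjunction or
   disjunction ("rule-both").

2. **Iterative motif elicitation.** A MEME/MAST-style loop: discover the
   most significant ungapped motif in the current allergen set by EM under a
   ZOOPS site model (zero or one occurrence per sequence), scan the
   allergens with the motif's position weight matrix, remove the matching
   sequences, and repeat until no motif with E-value < 0.01 remains.
   Prediction scans a query against the elicited library; per-position match
   p-values come from the exact distribution of PWM scores under the
   background, and a query is called an allergen when its best combined
   E-value falls below the scan threshold. Removing matched sequences
   between rounds is what lets minority families surface: a single
   discovery pass describes only the dominant family and its sensitivity
   collapses on mixed data.

3. **SVM on amino-acid composition.** Each protein is a 20-vector of
   residue fractions, fᵢ = count(i) / length, in fixed alphabetical order;
   an RBF-kernel SVM with Platt probability calibration separates allergens
   from non-allergens in composition space. Composition is permutation
   invariant, so shuffled or reversed variants of a sequence are
   indistinguishable to this feature set — a documented blind spot.

Around the engines: dataset curation (same-species redundancy removal at
99% global identity, negative pools purged of anything ≥ 30% locally
identical to an allergen or shorter than 50 residues, seeded negative
sampling, reversed-allergen negatives), stratified 10-fold cross-validation
with sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/total, ROC/AUC by threshold sweep, parameter sweeps over word size /
identity threshold / scan E-value, seeded synthetic fixtures, and a CLI.

## Worked example

```python
import allerkit as ak

# build a labeled synthetic benchmark: two allergen families sharing planted
# 10-mers, plus random negatives
ds = ak.generate(ak.FixtureSpec(n_families=2, family_size=15, seq_length=100,
                                motif_consensi=["WWHHWWHHWW", "CCYYCCYYCC"],
                                n_negatives=30, seed=8))
allergens = ds.filter_label(ak.Label.ALLERGEN)

# FAO/WHO rule 1: exact 6-mer match against the allergen set
index = ak.build_word_index(allergens, wordsize=6)
query = ds[0]
verdict = ak.rule1_predict(query, index)
print(f"rule 1: {query.id} -> {'allergen' if verdict.is_allergen else 'non-allergen'} "
      f"({len(verdict.evidence)} word hits)")

# iterative motif elicitation
library = ak.elicit_motifs(allergens, ak.ElicitParams(seed=11))
for motif in library:
    print(f"motif {motif.iteration}: {motif.consensus}  E = {motif.evalue:.2e}")

# 10-fold CV of the composition SVM on the separable benchmark
bench = ak.generate_composition_benchmark(n_per_class=100, seed=42)
result = ak.cross_validate(bench, lambda: ak.SvmPredictor(ak.SvmParams(seed=1)), k=10, seed=2)
m = result.overall
print(f"SVM 10-fold CV: sensitivity {m.sensitivity:.1%}, "
      f"specificity {m.specificity:.1%}, accuracy {m.accuracy:.1%}")
```

Output:

```
rule 1: fam1_1 -> allergen (201 word hits)
motif 1: WWHHWWHHWW  E = 2.71e-42
motif 2: CCYYCCYYCC  E = 2.23e-32
SVM 10-fold CV: sensitivity 100.0%, specificity 100.0%, accuracy 100.0%
```

The query is a member of family 1, so rule 1 finds its planted word (and
many incidental short matches) in the training allergens. The elicitation
loop recovers both planted consensi in order — family 1's motif is found
first, its sequences are removed, and family 2's motif surfaces in round
two. The composition benchmark is separable by construction, so the SVM is
perfect on it; real allergen/non-allergen composition overlaps far more.

The same operations are available from the shell:

```bash
allerkit fixtures --seed 8 --out data/
allerkit predict --method rule1 --db data/positives.fasta \
    --query data/negatives.fasta --out report.tsv
allerkit motifs elicit --in data/positives.fasta --seed 11 --out lib.meme
allerkit predict --method motif --lib lib.meme --query data/positives.fasta --out motif.tsv
allerkit evaluate --pos data/positives.fasta --neg data/negatives.fasta \
    --method rule1 --out metrics.json
allerkit sweep --pos data/positives.fasta --neg data/negatives.fasta \
    --method rule1 --grid 6,8,10,12,14 --out sweep.tsv
```

Several `--method` flags on one `predict` call produce per-method rows plus
a combined verdict (`--mode any|all|majority`).

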