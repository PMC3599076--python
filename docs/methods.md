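# Methods

This note documents the models implemented in allerkit, the choices made
where the published descriptions of these methods are silent, and what the
synthetic benchmarks do and do not establish.

## Sequence rules

**Rule 1 (exact word match).** A shared identical stretch of length ≥ *w*
exists between two sequences iff a shared *w*-mer exists, so the rule is
implemented as exact *w*-mer lookup: every *w*-mer of every reference
allergen is indexed with its (allergen, position) occurrences, and a query
is positive iff any of its *w*-mers is in the index. All overlapping hits
are reported with 1-based positions. Default *w* = 6; the positive set
shrinks monotonically as *w* grows, which drives the sensitivity/specificity
trade-off along the 6–14 sweep.

**Rule 2 (window identity).** Windows of length min(80, |query|) are taken
at step 1 (a query shorter than the window is one whole-sequence window —
short queries are evaluated, not skipped). Each window is aligned to each
reference allergen by exact Smith–Waterman with BLOSUM62 and affine gaps
(open 11, extend 1) — a deterministic stand-in for per-window BLAST that
avoids heuristic seeding variability. Identity is taken from the
best-*scoring* alignment, not the best-identity one, matching how search
tools report percent identity.

Two conventions are configurable because published statements of the
35%-in-80-aa criterion never fix them:

- *Denominator.* Default: identical columns / alignment length (the BLAST
  convention). Alternative: identical columns / window length. The default
  saturates at 100% for short perfect local matches (any shared hexamer
  gives a 6/6 alignment), which makes it extremely sensitive and almost
  non-specific; the window denominator requires genuinely extended
  similarity. Both are reported by the acceptance script on the
  reversed-negative design, where the contrast is stark (≈100%/0% vs
  ≈100%/100% sensitivity/specificity).
- *Comparison.* Default ≥ threshold ("identity of 35%"); strict >
  ("more than 35%") selectable. A constructed 80-column pair with exactly
  28 identities (every column positively scoring, so the full-length
  gapless alignment is the unique optimum) sits exactly on the 35% boundary
  and flips verdict between the conventions.

**Rule-both** is the boolean OR (default) or AND of the two verdicts with
both evidence sets attached.

## Motif elicitation

The loop: discover the best motif in the current allergen set; if its
E-value is below the stopping threshold (default 0.01), accept it, scan the
remaining sequences with it, remove every sequence whose combined E-value is
at or below the scan threshold (default 0.01 — the same knob used at
prediction time, since no separate removal criterion is standard), and
iterate. The loop also stops when an iteration removes nothing, fewer than
two sequences remain, or `max_iterations` is hit. The non-iterative
comparison arm runs discovery once on the full set.

**Discovery** is EM under a ZOOPS model (each sequence holds zero or one
motif occurrence; the occurrence prior γ is re-estimated each step) over a
width grid (default 6–20). Starting points per width (default 10) are half
the most recurrent *w*-mers (counted as number of distinct sequences
containing the word — this points EM straight at conserved elements) and
half seeded random substrings. Letter frequencies carry a 0.25-per-cell
pseudocount; the background is the input set's residue frequencies
(uniform 0.05 selectable) and is estimated once per elicitation on the full
input set so that all motifs in one library share a single background —
required for the library to round-trip through the MEME minimal text
format, which stores one background block.

**Motif significance** is approximated, not MEME-exact: with expected site
counts c and fitted frequencies f, the log-likelihood ratio
LLR = Σ c·log(f/b) is first reduced by the position-selection cost
Σᵢ zᵢ·log mᵢ (each sequence chose its site among mᵢ positions), and the
E-value is the χ² upper tail of 2·LLR_adj at 19·width degrees of freedom,
Bonferroni-scaled by the number of EM starting points tested across the
grid. Widths are ranked by the normal-approximate χ² z-score
(2·LLR_adj − df)/√(2df): raw p-values underflow for strong motifs, and an
unnormalized statistic is width-neutral on random flanking columns, which
overshoots the true motif width. The approximation is calibrated by null
simulation: on i.i.d. uniform-composition datasets (20 sequences × 100
residues), elicitation accepts no motif in ≥ 9/10 seeds, while planted
exact 10-mers in the same geometry score E ≲ 10⁻⁴⁰.

**Scanning.** PWM log-odds (log₂, background-relative) are scaled to
integers (100 units per bit) and the exact distribution of window scores
under the background is built by convolving per-column score distributions;
a window score's p-value is a table lookup. A sequence's combined E-value is
(best per-position p-value) × (positions scanned) × (number of motifs) — a
conservative Bonferroni stand-in for MAST's QFAST product, chosen because it
is exactly testable against brute-force enumeration (verified on reduced
alphabets at widths 3–5). Sequences shorter than every motif are negative
with a warning.

## Composition SVM

Features are the 20 residue fractions in fixed alphabetical order
(A, C, D, …, Y); the order is fingerprinted into saved models so a
feature-order mismatch fails loudly rather than silently. The classifier is
an RBF-kernel SVM (C = 1, gamma = "scale") with Platt-calibrated
probabilities, seeded for determinism; the verdict threshold on P(allergen)
defaults to 0.5 and the ROC is generated by sweeping that probability, so
reported AUCs match the probability interface. No kernel or regularization
is standard for this task; these are ordinary defaults, all configurable.
Note that Platt calibration targets depend on class counts, so duplicating
every training record leaves the decision function (in the separable
regime) but not the calibrated probabilities bit-identical; invariance
tests therefore assert on decision values.

## Curation rules

Positives: within each species (records without a species annotation are
never removed), records at ≥ 99% global-alignment identity
(Needleman–Wunsch, BLOSUM62, 11/1, identity = identical / alignment
columns) collapse to the longest member, ties to the smallest id. Negative
pools: drop records shorter than 50 residues or with best local identity
≥ 30% to any allergen, counted only over alignments of ≥ 50 columns
(mirroring BLAST-style screening); survivors are relabeled non-allergens
and sampled uniformly with an explicit integer seed. Reversed-allergen
negatives keep length and composition while destroying alignable order —
the unbiased negative design for window-identity evaluation, and
deliberately adversarial for the composition SVM, whose features cannot
distinguish a sequence from its reversal.

## Evaluation

Folds are stratified (per-fold class counts within 1 of equal); the overall
cross-validated figure is the unweighted mean of fold metrics, with pooled
confusion counts available as an alternative. Ratios with empty
denominators are reported as missing, never as zero. The similarity rules
have no trained state, but their allergen reference is still restricted to
the training folds of each split — otherwise held-out allergens match
themselves and sensitivity is trivially perfect. Parameter sweeps reuse one
fold plan across the whole grid so curves are comparable point by point.
ROC/AUC uses a tie-grouped threshold sweep with trapezoid integration,
which equals the Mann–Whitney pairwise-concordance statistic exactly.

## Synthetic study conditions

The generators are the package's benchmarks; their scales were chosen to
make each effect unambiguous at desk scale:

- word-match / sweep fixture: 2 families × 15 members, length 100, planted
  10-mers, 30 random negatives;
- reversed-negative design: 5 families × 10 members, length 80, a
  40-residue shared domain (half the window, so related pairs reach ~50%
  window identity), 50 reversed negatives;
- motif recovery: 20 sequences × 100 residues with one exact planted
  10-mer each (single family), or 15 + 15 across two families; nulls are
  i.i.d. uniform-composition sequences of the same geometry;
- composition benchmark: 100 + 100 sequences of length 100 drawing 80% of
  residues from {A,L,V} (positives) or {D,E,K} (negatives).

Backgrounds default to uniform 0.05 (a Swiss-Prot-like composition preset
is provided); planted elements sit at uniform random positions at least 5
residues from either end; everything is reproducible per seed down to
byte-identical FASTA.

What passing these benchmarks shows: the algorithms are implemented
correctly — exact-match equivalence to brute force, monotone threshold
behavior, planted-signal recovery, correct null calibration, exact metric
arithmetic. What it does not show: performance on real allergen data. Real
proteins have indels, domain shuffling, shared evolutionary history between
positives and negatives, and composition structure far richer than these
i.i.d. backgrounds; published headline numbers for these methods come from
curated allergen databases that are not redistributable, and nothing here
claims numeric parity with them.

## Known limitations

- Motif E-values are a χ²/Bonferroni approximation, not MEME's objective;
  combined scan E-values are a Bonferroni product, not QFAST. Absolute
  E-values are therefore conservative and comparable within allerkit, not
  across tools.
- Rule 2 is exact Smith–Waterman per window: O(window × |allergen|) per
  pair, fine for curated reference sets, slow for proteome-scale databases.
- Motifs are ungapped PWMs; no profile HMMs, no indel handling.
- The composition feature set is blind to residue order by construction.
- The redundancy and negative-pool filters do all-pairs alignment; for very
  large pools a prefilter (e.g. k-mer screening) would be needed.
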