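# Methods

## The discovery problem and the model

The pipeline treats riboswitch discovery as positive-unlabeled (PU)
binary classification. Known riboswitch sequences are positives with a
selection flag s = 1; candidate 5'UTRs are unlabeled (s = 0, class
unknown). Under the selected-completely-at-random assumption — a
positive's chance of being *labeled* does not depend on its features —
a probabilistic classifier g(x) trained to predict s satisfies
p(y=1 | x) = g(x) / c with c = p(s=1 | y=1). The package estimates c as
the mean of g over a held-out fraction of the labeled positives
(`holdout_ratio`, default 0.1, seeded) and scores candidates with the
adjusted output g(x)/c clipped into [0, 1]. Because the adjustment is a
fixed positive rescaling, candidate *ranking* is inherited from the base
classifier; the adjustment matters for thresholding, which the pipeline
does at 0.95 per classifier.

The base classifier is an unweighted RBF-kernel SVC (C = 10, γ = 0.4)
with Platt-scaled probability outputs, and is pluggable: any estimator
with `predict_proba` drops in (the test suite uses constant stubs and an
unregularized logistic model where calibration matters).

### Ligand-holdout validation

Because the scientific target is *extrapolation* — detecting riboswitch
families absent from training — validation withholds entire ligand
classes. `build_splits` produces one split per major class
(representation ≥ 2%), one per configured class pair, and one pooled
split of all rare classes. Under the reference corpus census shipped in
`riboscout.reference` (ten major classes, nine pairs) this yields the
20-classifier design; on the synthetic corpus (three classes, no pairs)
it yields three. Validation accuracy is the fraction of withheld-class
positives whose adjusted score reaches the threshold.

### Ensemble scoring and hit selection

Per candidate, each classifier contributes its adjusted output PUᵢ(x);
the ensemble score is the mean of PUᵢ(x)/maxᵢ, where maxᵢ is classifier
i's maximum adjusted output over the full positive corpus. Hits are
selected by per-classifier agreement on the non-normalized output
(default: all classifiers at 0.95) and ranked by the normalized mean,
ties broken by record id. Since adjusted outputs are clipped to [0, 1],
maxᵢ ≤ 1 and each normalized term is additionally capped at 1, keeping
the score in [0, 1] even for candidates that outscore every positive.

## Secondary structure

All downstream computation consumes only a `(dotbracket, mfe)` pair, so
folding is a backend choice recorded in provenance:

* `maxpair` (default): a maximum-base-pairing dynamic program
  (Watson–Crick + GU wobble, minimum hairpin loop 3, energy −1 per
  pair), numba-accelerated, with deterministic tie-breaking (prefer the
  5'-most position unpaired, then the 5'-most partner). It is exact for
  its objective — verified against exhaustive enumeration on short
  sequences — and bit-reproducible with no external dependency.
* `vienna`: ViennaRNA's thermodynamic MFE fold when the RNAlib bindings
  are importable.
* file-backed: precomputed structures pass through a cache, so any
  external folder can feed the pipeline.

The structural grammar parsed from dot-bracket: a *stack* is a maximal
run of consecutively nested pairs with no unpaired interruption on
either strand; a *hairpin* is an unpaired run closed by a single pair;
between stacks along a helix an unpaired run of length 1 is a *bulge*
and ≥ 2 an *internal loop*, sided left (opening strand) or right
(closing strand), each side counted independently; a stack is *branched*
when the loop it closes holds ≥ 2 child helices; multiloop and external
unpaired NT count as *unpaired*, hairpin/bulge/loop NT do not. A lone
pair is a stack of length 1. Pseudoknots are not representable and
unbalanced input is rejected with its position. Every parse satisfies
the conservation identity
`n_paired + nt_hairpin + nt_bulge + nt_loop + n_unpaired = L`, and the
parser agrees with an independent recursive-descent decomposition on all
~180,000 balanced strings up to length 14.

## Feature normalization

Structural counts are max-normalized and the MFE min-normalized
(mfe / min mfe, so the most negative energy maps to 1) over the
*combined* positive + unlabeled corpus, fit once and persisted as JSON.
New sequences — truncated sub-sequences, negatives, fresh candidates —
are scored under the stored context without refitting, with values
clipped into [0, 1]; this keeps the trained ensemble's feature scale
intact. A count never observed in the fitting corpus gets maximum 1 to
avoid 0/0; an all-unstructured corpus maps every normalized MFE to 0.
The minimum featurizable length is 25 NT, the corpus length floor.

## Similarity ranking

J_Sim combines three distances, each normalized and clipped at 1:
length difference over (L_max − L_min) (reference 476 − 25 = 451,
recomputable from any corpus); dot-bracket Levenshtein distance over
max((L_max − L_min) − L_UTR, L_UTR) — a length *bound* rather than a
true maximum, hence the clipping; and the squared difference of the
structural block (slots S66–S74) over the candidate's maximum structural
distance to any positive. Whether the structural block should enter
normalized or raw is not fully determined by the defining indices; the
package uses the normalized (assembled) values, the only option under
which the slot indices refer to a concrete vector. Edit distance is
computed with edlib; an independent memoized transcription of the
defining recursion serves as the test oracle.

## Truncation scan

Each candidate window is re-scored as 20 suffixes whose start offsets
are evenly spaced (rounded, duplicates collapsed) from 30 NT to
L − 26, so every suffix keeps the 3'-terminal 25 NT (start codon + 22).
The full-length window is scored separately, not as a bin. Profiles are
classed `robust` (full detected, ≥ half the bins detected), `fragile`
(full detected only), `emergent` (full missed but ≥ 5 bins detected) or
`negative`. Per-suffix failures are recorded as missing scores without
aborting the scan.

## The synthetic corpus

The generator emulates the data classes the analysis assumes, with
ground truth recorded for every record:

* **Positives** (default ~2,000 in three classes) are structure-poor
  backbones (alphabet skewed to A and C, whose pairing partners are
  scarce, so the max-pairing folder finds little opportunistic
  structure) carrying three planted stem-loops each: a GC-rich stem, a
  4–7 NT loop, the stem's reverse complement, optionally interrupted by
  a 1 NT bulge or a 2–3 NT internal loop. Classes differ in stem length
  (8–11 vs 8–11 vs 9–12) and in bulge-versus-loop character along a
  graded continuum (p_bulge/p_loop 0.7/0.1, 0.4/0.4, 0.1/0.7). The
  grading is deliberate: a withheld class then lies within the span of
  the remaining classes, making holdout validation an interpolation
  task — which is what real riboswitch families, sharing core
  architectural motifs, present. Early disjoint-character designs
  (e.g. classes differing in hairpin *count*) made holdout an
  extrapolation task the RBF classifier rightly failed; that behavior
  is a property of the classifier, not a bug, and the default design
  avoids it on purpose.
* **Background** records are backbone-only random sequences;
  a `spike_fraction` (default 5%) of the unlabeled pool are positives
  with labels stripped, recorded in a manifest.
* **Random negatives** are uniform ACGU with lengths resampled from the
  positive set; **exon-like negatives** carry a single weak stem-loop,
  between background and positives in structure.
* The `separation` knob scales the planted signal; at 0, positives are
  drawn from the background distribution — a negative control for the
  entire pipeline.

Default lengths are 115–170 NT (set by the space three planted
stem-loops need plus backbone; real corpora span 25–476 NT and the
length distribution is configurable). All draws derive from one seed
via per-stage child streams; identical configs reproduce byte-identical
corpora.

What the generator does *not* emulate: thermodynamic folding ensembles
(the default backend maximizes pairing rather than minimizing free
energy), sequence homology within a ligand class, genomic base
composition, and the heavy class imbalance of real riboswitch corpora.
Passing tests therefore demonstrate that the machinery recovers planted
structure-defined classes under its own folding model — not that the
published biological accuracies transfer.

## Negative control and the zero-separation pathology

The negative control retrains the ensemble with uniform-random
negatives added to the 0-labeled pool (a seeded 2,000-record subsample
at training; all 10,000 scored), mirroring how the published control
labeled random and exonic sequences 0. Scoring such negatives under an
ensemble that never saw their kind would instead measure behavior on
out-of-distribution input — under the max-pairing folder, uniform
random sequences are out-of-distribution on the *structured* side.

With `separation = 0` the Elkan–Noto construction exhibits its known
pathology: g(x) is nearly constant, c is estimated at that constant,
and *every* record's adjusted score approaches 1 — withheld-class
"accuracy" is high because everything is accepted. The meaningful
collapse statistic is therefore the discrimination gap — withheld-class
detection rate minus background acceptance rate — which falls from
≈ 0.9 under default separation to ≈ 0.

## Numerical and design choices

* Study scale: 2,000 positives / 2,000 unlabeled / 10,000 negatives per
  seed, ten seeds for distributional claims; chosen as the package's
  desk-scale study conditions. Full-scale corpora run through the same
  code paths unchanged.
* SVC seeds: each split's classifier uses `seed + split_index`;
  Platt scaling inherits the same seed.
* Degenerate guards: c ≤ 0 or non-finite aborts with advice to enlarge
  the holdout; an empty validation set, an empty positive corpus, or a
  split leaving no training positives are errors, not warnings.
* Ties: hit ranking breaks J_Ensemble ties by id; match ranking breaks
  J_Sim ties by positive id; both are input-order invariant.
* Known limitations: the Elkan–Noto estimate biases c downward when the
  unlabeled pool is positive-rich; permutation importance on correlated
  features splits credit (MFE and GC dominate on the synthetic corpus);
  and the max-pairing energy proxy makes absolute MFE values
  incomparable with thermodynamic folds — only their normalized ranks
  matter inside one corpus.
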