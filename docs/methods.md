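# Methods

This note documents the models, numerical choices and limitations behind
snoscout. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## Box models

Each box (H: `ANANNA`, 6 nt; ACA: 3 nt; C: `RUGAUGA`, 7 nt; D: `CUGA`,
4 nt) is modelled as a position-specific weight matrix over {A, C, G, U}
with probabilities `(count + pseudocount) / (n + 4·pseudocount)`. A window
scores `Σ log2(p_i(x_i) / bg(x_i))` bits; the background defaults to
uniform 0.25 and can be refit from training-sequence composition. The
default pseudocount of 0.25 keeps scores finite for motifs sampled from
small training sets; degenerate consensus positions (R, N) are represented
by the probability rows themselves, never by special-casing characters.

Score thresholds are the equal-error point between the score densities of
true boxes and of non-box windows: Gaussian-KDE estimates of both samples
are intersected between the two sample means; when no crossing exists there
(or a sample is degenerate) the midpoint of the means is used. The shipped
default PWMs are rebuilt from consensus-sampled instances with thresholds
against uniform random windows; `snorna-scout train` re-estimates both from
the user's positives (non-box windows drawn from dinucleotide-shuffled
copies of the training sequences). Published PWM parameters for this
method family are not available, so rebuilt matrices necessarily differ
from any original tool's.

## Folding

The reference engine is the ViennaRNA thermodynamic model (`RNAfold`
semantics; energies in kcal/mol). Hard constraints mark positions that must
stay unpaired; windowed local folding (`RNALfold` semantics, maximal base
pair span = window size) locates locally stable segments. A second,
deliberately simple engine — maximum base pairing, Watson–Crick + G·U,
minimum hairpin loop 3, energy −1 per pair, ties broken by the
lexicographically smallest structure under '(' < '.' < ')' — exists so
that tests can verify folding behaviour against exhaustive enumeration; it
is never used for shipped models.

Loop decomposition classifies every position of a nested structure exactly
once: paired, hairpin loop, interior element (interior loops and bulges,
i.e. single-child pairs with unpaired gaps), or external; unpaired
positions of the rare multibranch loop are counted as external. "Single
stem-loop" means exactly one hairpin loop, at least `min_stem_bp` pairs
(default 3) and no multibranch loop.

Thermodynamic z-scores are computed from an explicit ensemble of
mononucleotide-shuffled copies (default 100, reducible per run):
`z = (MFE − mean)/sd`, 0 when sd = 0. A regression-based z-score
approximation was deliberately not used: the explicit ensemble is exact for
its definition, seeded, and engine-agnostic, at the cost of `n_shuffles`
extra folds per candidate.

## Candidate workflows

**H/ACA** (all tunables in `PipelineConfig`): H boxes above threshold are
scanned; per H box, windowed local folding over the 120 nt upstream
(`haca.upstream_window`) proposes the candidate 5' end as the start of the
locally stable segment whose 3' end lies within `haca.gap_tol = 3` nt of
the H box (the longest qualifying segment wins); the region from that start
to the H box, and the region between the H box and an ACA box at most 120
nt downstream (`haca.max_h_aca_distance`), must each fold into a single
stem-loop with the 14th base upstream of the respective box
(`haca.constraint_offset`, counting the adjacent base as 1st; regions
shorter than 14 nt are left unconstrained) forced unpaired. The candidate
ends at the ACA box end; no extra 3' tail is appended, and the boxes
themselves are excluded from the folded hairpin regions. The full-candidate
constrained MFE (`mfeC`) applies both box constraints simultaneously.

**C/D**: C boxes above threshold are paired with D boxes whose end lies
within 200 nt of the C box start (`cd.max_c_d_span`; the span reading, not
the gap, was chosen for the 200 nt limit). Box pairs must pass the
kink-turn sequence test: G,A at C box positions 3–4 and D box positions
3–4; at least one U over (C box position 5, D box position 2); a strict
Watson–Crick pair (wobble excluded) between C box position 6 and D box
position 1. The candidate region is the boxed span plus 20 nt flanks
(`cd.flank`; the amount of flanking context folded with a candidate is a
free choice of this implementation) folded twice — free, and with every
position from the C box start to the D box end forced unpaired — and the
constrained structure must contain a terminal stem of ≥ `cd.min_stem_bp`
pairs enclosing the boxed region.

Feature vectors are fixed-order 15-vectors per class; the H/ACA
"recognition loop" features read the interior element containing the
constrained position (falling back to the largest interior element, and to
size 0 / symmetry 1 when the hairpin has none), with loop symmetry
`S = 1 − |left − right| / (left + right)`.

## Classification

Negatives are dinucleotide-shuffled copies of the positives
(Altschul–Erickson Euler-path construction: exact conservation of the
dinucleotide multiset, hence of length, composition and terminal residues;
sampled uniformly over realizations via Wilson's algorithm). Because
shuffles generally fail the structure filters, they are featurized in
*relaxed* mode: box thresholds ignored (best-scoring windows within a valid
geometry are used) and structure filters disabled. This choice — how
negative sequences acquire feature vectors at all — is an open design
point of the method family; relaxed mode was chosen because it asks the
classifier to separate real architecture from the best impersonation a
composition-matched sequence can offer. One shuffle per positive gives
balanced classes.

Scaling maps each feature to [−1, 1] by training min/max without clipping
(svm-scale behaviour); constant features map to 0. The grid search
evaluates every `(C, γ) = (2^a, 2^b)` over the exponent range by
stratified k-fold cross-validated accuracy, breaking ties toward smaller
`C` then smaller `γ` (smoother models). Final models are RBF C-SVMs with
Platt-style probability estimates. On small, perfectly separated training
sets the Platt fit can come out anti-correlated with the SVM decision
function (a known pathology of the internal calibration CV); training
therefore checks the orientation of the probabilities against the decision
values on the training set and records a correction flag in the model.
Predicted labels always come from the C-SVM decision; probabilities feed
the ranking metrics and the reporting cutoff.

Metrics: accuracy, F-score, average precision (area under
precision–recall), ROC AUC, and RSS defined as the *mean* squared
difference between the 0/1 label and the predicted probability — the mean
(Brier-style) form is the one consistent with the magnitudes this protocol
produces (~0.01–0.1), whereas a raw sum would scale with n.

The train/test protocol splits positives by single-linkage clustering on
6-mer Jaccard similarity ≥ 0.5 (clusters assigned alternately to the two
partitions by descending size, so near-duplicates never straddle the
boundary — a lightweight stand-in for phylogeny-based dataset
construction), then repeatedly (default 10×) trains on one partition and
tests on the other with fresh negatives per repeat, reporting per-direction
means and standard deviations.

## Synthetic data

The generator emulates canonical anatomy only: H/ACA records are
flank + hairpin + H box + hairpin + ACA + 3 nt tail, each hairpin an outer
helix (4–7 bp), a recognition loop (4–10 nt per side), an inner helix
(3–6 bp, ≤ 10 bp total) and a terminal loop, with a U planted 14 nt
upstream of each box inside the recognition loop (total helix sizes start
at 7 bp because the planted U must fall inside a ≤ 10 nt loop side beyond
an outer helix of ≥ 4 bp, and an inner helix below 3 bp is not reliably
stable). C/D records are flank + stem arm + C box + spacer (30–80 nt,
purine-rich to bias against self-pairing) + D box + complementary arm +
flank, with terminal stems of 4–8 bp: under the thermodynamic model a 3 bp
helix closing the 40–90 nt boxed loop has positive net energy and would
never appear in the constrained MFE structure, so generated stems start at
4 bp. Stem arms are drawn from {G, C} so that short designed helices
dominate the MFE structure; loops and flanks are A/C-rich (non-pairing).

Decoy families: (a) boxes kept, stems scrambled; (b) dinucleotide-shuffled
positives; (c) uniform random sequences with matched length and GC.

What passing tests on this data do **not** show: performance on real
genomes (introns, repeats, composition heterogeneity, non-canonical boxes),
robustness to sequencing errors, or discrimination against structured
non-snoRNA ncRNAs. Family-(c) decoys measure one specific failure mode —
random composition-matched sequence — and at the default filter settings
about 9 % of such ~100 nt decoys pass the pre-SVM H/ACA structure filters
(0 % for C/D); the SVM stage reduces the end-to-end false-positive rate to
a few percent (measured by `scripts/acceptance.py`). Leishmania-style
AGA-box variants and C'/D' internal boxes are out of scope.

## Determinism and degenerate inputs

Every stochastic stage (shuffling, ensembles, negative generation, CV
shuffling, the generator) takes an explicit seed; sub-seeds are derived
with `numpy.random.SeedSequence` and stay below 2³¹. Degenerate cases are
defined, not errors: zero-variance ensembles give z = 0; structures with
no interior elements give loop size 0 and symmetry 1; constant features
scale to 0; sequences shorter than the constraint offset fold
unconstrained; records with alphabet violations are skipped with a warning
at FASTA input.
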