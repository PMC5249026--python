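# snoscout

Detection of the two main classes of small nucleolar RNAs — **H/ACA box**
and **C/D box snoRNAs** — in nucleotide sequences, combining position-specific
weight matrix (PWM) box scanning, constrained minimum-free-energy RNA
secondary-structure prediction, and an RBF C-SVM classifier. It is aimed at
researchers annotating non-coding RNAs in genomic or transcriptomic
sequence who want snoRNA calls that do not depend on knowing the target
rRNA/snRNA modification site (so orphan snoRNAs are found too).

## The method

snoRNAs (60–300 nt) are recognized by short conserved sequence *boxes*
embedded in a characteristic secondary structure:

* **H/ACA box snoRNAs** fold into two hairpins joined by a single-stranded
  hinge carrying box H (consensus `ANANNA`) and a 3' tail carrying the
  trinucleotide `ACA`. Each hairpin has a large interior *recognition loop*
  whose target uridine sits 13–16 nt upstream of the downstream box.
* **C/D box snoRNAs** carry box C (`RUGAUGA`) near the 5' end and box D
  (`CUGA`) near the 3' end; the flanks fold into a short *terminal stem*,
  and the boxed junction forms a *kink-turn* (tandem G·A pairs, a U·U
  interaction, and a closing Watson–Crick pair).

The pipeline per class:

1. **Box scan.** PWMs score every window as log₂-odds against background;
   windows at or above a threshold (the equal-error crossing of
   true-box vs. non-box score densities) become box candidates.
2. **Structure filters.** For H/ACA: the candidate 5' end is the locally
   stable hairpin (RNALfold-style windowed folding) ending just upstream of
   the H box, and both hairpin regions must fold into single stem-loops with
   the 14th base upstream of each box constrained unpaired — this opens the
   recognition loop that in vivo is held open by proteins. For C/D: boxes at
   most 200 nt apart must pass the kink-turn sequence test, and the region
   from the start of box C to the end of box D is forced unpaired while the
   flanks must still close a terminal stem of ≥ 3 bp.
3. **Features.** Each surviving candidate yields a fixed-order
   15-attribute vector (constrained MFE, composition, box scores, loop
   sizes and symmetries for H/ACA; free/constrained MFE, shuffled-ensemble
   energy statistics, stem geometry for C/D), including a thermodynamic
   z-score `z = (MFE − mean)/sd` over mononucleotide-shuffled ensembles.
4. **Classification.** Features are scaled to [−1, 1] (svm-scale
   semantics), `C` and `γ` are chosen by exhaustive grid search over
   exponentially growing values (2⁻¹⁵…2¹⁵ by default) with stratified
   10-fold cross-validated accuracy, and an RBF C-SVM with probability
   estimates is trained on positives versus dinucleotide-shuffled negatives
   (Altschul–Erickson exact-conservation shuffling).

A seeded synthetic-data module generates canonical records of both classes,
decoy families, and ground-truth annotations, so the entire pipeline is
trainable and testable without any external data.

## Worked example

```bash
# generate 30 canonical C/D box snoRNAs with ground-truth boxes
snorna-scout simulate --sno-class cd --n 30 --seed 4 --out cdpos

# train: PWMs from the annotated boxes, similarity-aware split,
# repeated train/test protocol, final refit
snorna-scout train cdpos.fasta --sno-class cd --bed cdpos.bed \
    --out cd.model --metrics-out cd_metrics.tsv \
    --seed 2 --repeats 1 --grid-min -3 --grid-max 3 --folds 5 --n-shuffles 20

# predict on new sequences
snorna-scout simulate --sno-class cd --n 10 --seed 99 --out cdtest
snorna-scout predict cdtest.fasta --model cd.model --out pred --seed 1
```

The train step prints:

```
model written to cd.model (C=2^0, gamma=2^-3, 30 positives, 30 negatives)
```

and `pred.tsv` starts:

```
record_id  sno_class  strand  start  end  box1_name  box1_start  box1_end  box1_score  box2_name  box2_start  box2_end  box2_score  probability  label
cd_0000    CD         +       5      118  C          25          32        12.8562     D           97         101       7.8587      0.966846     1
cd_0001    CD         +       5      105  C          25          32        12.8562     D           86         90        7.8587      0.962505     1
```

Each row is one candidate: its region (0-based half-open), the located C
and D boxes with their PWM bit scores, and the SVM probability that the
candidate is a real C/D box snoRNA (`label` = probability ≥ 0.5). A GFF3
file with 1-based coordinates, probability in the score column and all 15
features in the attributes is written alongside. `cd_metrics.tsv` holds the
repeated-protocol accuracy, F-score, average precision, ROC AUC and RSS
(mean and SD, both train/test directions).

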