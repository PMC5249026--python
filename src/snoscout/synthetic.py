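"""Seeded generator of canonical snoRNA sequences, decoys and annotations.

Everything the pipeline needs — training positives, shuffled negatives and
decoy controls — is generated programmatically from the canonical anatomy of
the two snoRNA classes, so no external data is required.

H/ACA records are built as: 5' flank, hairpin 1, H box (an ANANNA
instance), hairpin 2, ACA, 3 nt tail. Each hairpin is an outer helix, an
interior (recognition) loop, an inner helix and a terminal loop; a uridine
is planted 14 nt upstream of the downstream box, inside the 3' side of the
recognition loop, mirroring the target uridine found 13–16 nt before the
boxes in real molecules.

C/D records are built as: 5' flank, 5' stem arm, C box (an RUGAUGA
instance), an unstructured spacer, D box (CUGA), the reverse-complement 3'
stem arm, 3' flank. Sampled boxes always satisfy the kink-turn test.

Loops, spacers and flanks are sampled from weak-pairing alphabets (A/C for
loops and flanks, purine-rich spacers) so that the designed helices dominate
the MFE structure; stem arms are G/C-rich so short helices are stable
enough to appear in thermodynamic folds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Tuple

import numpy as np

from .pwm import PWM, build_pwm, estimate_threshold, score_window
from .seqio import COMPLEMENT, SequenceRecord, dinucleotide_shuffle, write_fasta


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GeneratorConfig:
    seed: int = 0
    n: int = 200
    # H/ACA anatomy
    haca_outer_stem: Tuple[int, int] = (4, 7)    # outer helix bp
    haca_inner_stem: Tuple[int, int] = (3, 6)    # inner helix bp (total <= 10)
    haca_loop_side: Tuple[int, int] = (4, 10)    # recognition loop nt per side
    haca_hairpin_loop: Tuple[int, int] = (4, 7)
    # C/D anatomy
    cd_stem: Tuple[int, int] = (4, 8)            # terminal stem bp
    cd_spacer: Tuple[int, int] = (30, 80)        # nt between the boxes
    # shared
    flank5: Tuple[int, int] = (8, 20)
    flank3_haca: int = 3
    flank3_cd: Tuple[int, int] = (8, 20)
    u_offset: int = 14                           # planted U upstream of each box

    def validate(self) -> None:
        for name in ("haca_outer_stem", "haca_inner_stem", "haca_loop_side",
                     "haca_hairpin_loop", "cd_stem", "cd_spacer", "flank5",
                     "flank3_cd"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.n < 1 or self.seed < 0:
            raise ValueError("n must be >= 1 and seed >= 0")


@dataclass
class HacaGroundTruth:
    h_box: Tuple[int, int]
    aca_box: Tuple[int, int]
    hairpin1: Tuple[int, int]
    hairpin2: Tuple[int, int]


@dataclass
class CdGroundTruth:
    c_box: Tuple[int, int]
    d_box: Tuple[int, int]
    stem5: Tuple[int, int]
    stem3: Tuple[int, int]


def _rand(rng: np.random.Generator, length: int, letters: str, probs) -> str:
    return "".join(rng.choice(list(letters), size=length, p=probs))


def _stem_arm(rng: np.random.Generator, length: int, gc_only: bool = False) -> str:
    if gc_only:
        return _rand(rng, length, "GC", [0.5, 0.5])
    return _rand(rng, length, "GCAU", [0.35, 0.35, 0.15, 0.15])


def _loop_seq(rng: np.random.Generator, length: int) -> str:
    return _rand(rng, length, "AC", [0.7, 0.3])


def sample_h_box(rng: np.random.Generator) -> str:
    """An instance of the H box consensus ANANNA."""
    n = list("ACGU")
    return ("A" + rng.choice(n) + "A" + rng.choice(n) + rng.choice(n) + "A")


def sample_c_box(rng: np.random.Generator) -> str:
    """An instance of the C box consensus RUGAUGA (R is a purine)."""
    return rng.choice(["A", "G"]) + "UGAUGA"


D_BOX = "CUGA"
ACA_BOX = "ACA"


def _uniform_int(rng, bounds: Tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def _make_haca_hairpin(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    """One hairpin whose 3' end abuts a box: the planted U sits u_offset nt
    from the hairpin's 3' end, inside the recognition loop."""
    s_out = _uniform_int(rng, cfg.haca_outer_stem)
    s_in = _uniform_int(rng, (cfg.haca_inner_stem[0],
                              min(cfg.haca_inner_stem[1], 10 - s_out)))
    ll = _uniform_int(rng, cfg.haca_loop_side)
    lr_min = max(cfg.haca_loop_side[0], cfg.u_offset - s_out)
    lr = _uniform_int(rng, (lr_min, max(lr_min, cfg.haca_loop_side[1])))
    hloop = _uniform_int(rng, cfg.haca_hairpin_loop)

    arm_out = _stem_arm(rng, s_out, gc_only=True)
    arm_in = _stem_arm(rng, s_in, gc_only=True)
    loop_l = _loop_seq(rng, ll)
    loop_r = list(_loop_seq(rng, lr))
    # plant the target uridine u_offset nt upstream of the box
    loop_r[lr - (cfg.u_offset - s_out)] = "U"
    terminal = _loop_seq(rng, hloop)
    return (arm_out + loop_l + arm_in + terminal
            + revcomp(arm_in) + "".join(loop_r) + revcomp(arm_out))


def gen_haca(config: GeneratorConfig) -> list[Tuple[SequenceRecord, HacaGroundTruth]]:
    """Generate canonical H/ACA box snoRNA records with ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(config.n):
        flank5 = _loop_seq(rng, _uniform_int(rng, config.flank5))
        hp1 = _make_haca_hairpin(rng, config)
        h_box = sample_h_box(rng)
        hp2 = _make_haca_hairpin(rng, config)
        flank3 = _loop_seq(rng, config.flank3_haca)
        residues = flank5 + hp1 + h_box + hp2 + ACA_BOX + flank3
        h_start = len(flank5) + len(hp1)
        aca_start = h_start + len(h_box) + len(hp2)
        truth = HacaGroundTruth(
            h_box=(h_start, h_start + len(h_box)),
            aca_box=(aca_start, aca_start + 3),
            hairpin1=(len(flank5), h_start),
            hairpin2=(h_start + len(h_box), aca_start),
        )
        out.append((SequenceRecord(id=f"haca_{i:04d}", residues=residues,
                                   description="synthetic H/ACA box snoRNA"),
                    truth))
    return out


def _purine_rich(rng: np.random.Generator, length: int) -> str:
    # biased against self-pairing: mostly A/G, little C/U
    return _rand(rng, length, "AGCU", [0.55, 0.25, 0.12, 0.08])


def gen_cd(config: GeneratorConfig) -> list[Tuple[SequenceRecord, CdGroundTruth]]:
    """Generate canonical C/D box snoRNA records with ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    out = []
    for i in range(config.n):
        flank5 = _loop_seq(rng, _uniform_int(rng, config.flank5))
        arm = _stem_arm(rng, _uniform_int(rng, config.cd_stem), gc_only=True)
        c_box = sample_c_box(rng)
        spacer = _purine_rich(rng, _uniform_int(rng, config.cd_spacer))
        flank3 = _loop_seq(rng, _uniform_int(rng, config.flank3_cd))
        residues = flank5 + arm + c_box + spacer + D_BOX + revcomp(arm) + flank3
        c_start = len(flank5) + len(arm)
        d_start = c_start + 7 + len(spacer)
        truth = CdGroundTruth(
            c_box=(c_start, c_start + 7),
            d_box=(d_start, d_start + 4),
            stem5=(len(flank5), c_start),
            stem3=(d_start + 4, d_start + 4 + len(arm)),
        )
        out.append((SequenceRecord(id=f"cd_{i:04d}", residues=residues,
                                   description="synthetic C/D box snoRNA"),
                    truth))
    return out


def gen_decoys(config: GeneratorConfig, sno_class: str) -> list[SequenceRecord]:
    """Decoy sequences of three families, ``config.n`` of each.

    (a) boxes present at their annotated positions but the stem arms
    replaced by independent random sequence (no complementarity);
    (b) dinucleotide-shuffled positives;
    (c) uniform random sequences with length and GC content matched to the
    positives.

    The family is recorded in the record id (``famA``/``famB``/``famC``) and
    description.
    """
    config.validate()
    if sno_class not in ("haca", "cd"):
        raise ValueError("sno_class must be 'haca' or 'cd'")
    rng = np.random.default_rng(config.seed + 2)
    positives = gen_haca(config) if sno_class == "haca" else gen_cd(config)

    decoys: list[SequenceRecord] = []
    # family (a): boxes kept, pairing destroyed
    scrambled = _gen_scrambled(config, sno_class, rng)
    decoys.extend(scrambled)
    # family (b): dinucleotide-shuffled positives
    for i, (rec, _) in enumerate(positives):
        shuf = dinucleotide_shuffle(rec.residues, int(rng.integers(2**31)))
        decoys.append(SequenceRecord(
            id=f"decoy_{sno_class}_famB_{i:04d}", residues=shuf,
            description="decoy family=b dinucleotide-shuffled positive"))
    # family (c): uniform random, matched length and GC
    for i, (rec, _) in enumerate(positives):
        gc = (rec.residues.count("G") + rec.residues.count("C")) / len(rec.residues)
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G U
        seq = _rand(rng, len(rec.residues), "ACGU", probs)
        decoys.append(SequenceRecord(
            id=f"decoy_{sno_class}_famC_{i:04d}", residues=seq,
            description="decoy family=c uniform random matched length/GC"))
    return decoys


def _gen_scrambled(config: GeneratorConfig, sno_class: str,
                   rng: np.random.Generator) -> list[SequenceRecord]:
    """Family (a): same layout as positives but non-complementary stems."""
    out = []
    for i in range(config.n):
        flank5 = _loop_seq(rng, _uniform_int(rng, config.flank5))
        if sno_class == "cd":
            s = _uniform_int(rng, config.cd_stem)
            arm5 = _rand(rng, s, "ACGU", [0.25] * 4)
            arm3 = _rand(rng, s, "ACGU", [0.25] * 4)
            spacer = _rand(rng, _uniform_int(rng, config.cd_spacer), "ACGU", [0.25] * 4)
            flank3 = _loop_seq(rng, _uniform_int(rng, config.flank3_cd))
            residues = flank5 + arm5 + sample_c_box(rng) + spacer + D_BOX + arm3 + flank3
        else:
            hp1 = "".join(rng.permutation(list(_make_haca_hairpin(rng, config))))
            hp2 = "".join(rng.permutation(list(_make_haca_hairpin(rng, config))))
            residues = (flank5 + hp1 + sample_h_box(rng) + hp2 + ACA_BOX
                        + _loop_seq(rng, config.flank3_haca))
        out.append(SequenceRecord(
            id=f"decoy_{sno_class}_famA_{i:04d}", residues=residues,
            description="decoy family=a boxes kept, stems scrambled"))
    return out


# ---------------------------------------------------------------------------
# default PWMs rebuilt from consensus instances
# ---------------------------------------------------------------------------


def default_pwms(seed: int = 0, n_instances: int = 300,
                 n_background: int = 2000) -> dict[str, PWM]:
    """PWMs for the four boxes, built from sampled consensus instances.

    Thresholds are the equal-error crossing between the score distribution
    of true box instances and that of random uniform windows of the same
    length.
    """
    rng = np.random.default_rng(seed)
    pwms: dict[str, PWM] = {}
    samplers = {
        "H": lambda: sample_h_box(rng),
        "ACA": lambda: ACA_BOX,
        "C": lambda: sample_c_box(rng),
        "D": lambda: D_BOX,
    }
    for name, sampler in samplers.items():
        instances = [sampler() for _ in range(n_instances)]
        pwm = build_pwm(instances, pseudocount=0.25, box_name=name)
        pos_scores = [score_window(pwm, inst) for inst in instances]
        neg_scores = [
            score_window(pwm, _rand(rng, pwm.length, "ACGU", [0.25] * 4))
            for _ in range(n_background)
        ]
        pwm.threshold = estimate_threshold(pos_scores, neg_scores)
        pwms[name] = pwm
    return pwms


# ---------------------------------------------------------------------------
# file output used by the simulate CLI
# ---------------------------------------------------------------------------


def write_simulation(records, truths, config: GeneratorConfig, prefix) -> None:
    """Write FASTA + BED (0-based half-open ground truth) + JSON config echo."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_fasta(records, prefix.with_suffix(".fasta"))
    with open(prefix.with_suffix(".bed"), "w") as fh:
        if truths is not None:
            for rec, truth in zip(records, truths):
                for name, (s, e) in asdict(truth).items():
                    fh.write(f"{rec.id}\t{s}\t{e}\t{name}\t0\t+\n")
        else:
            for rec in records:
                family = rec.description.split("family=")[1][0] if "family=" in rec.description else "."
                fh.write(f"{rec.id}\t0\t{len(rec)}\tdecoy_{family}\t0\t+\n")
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(asdict(config), fh, indent=2)
        fh.write("\n")
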