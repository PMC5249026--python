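"""C/D box snoRNA candidate search, kink-turn test and feature extraction.

A C/D box snoRNA carries box C (consensus RUGAUGA) near its 5' end and box D
(consensus CUGA) near its 3' end; the flanking sequences fold together into a
short terminal stem, and the boxed region forms a kink-turn: tandem G·A
pairs, a U·U interaction and a closing Watson–Crick pair. The search is
box-first: PWM scans for C then D boxes within the allowed span, a sequence
kink-turn test, and a constrained fold in which the whole region from the
start of box C to the end of box D is kept unpaired so that only the
terminal stem can form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .config import PipelineConfig
from .folding import (
    FoldResult,
    ensemble_stats,
    fold,
    make_constraint,
    pair_table,
)
from .pwm import PWM, BoxMatch, scan, score_window
from .seqio import SequenceRecord, composition

#: canonical feature order of the C/D 15-attribute vector
CD_FEATURE_NAMES = [
    "mfe", "mfeC", "E_avg", "E_stdv", "ls", "Dcd", "Cscore", "Dscore",
    "GC", "zscore", "bpStem", "lu5", "lu3", "stemUnpCbox", "stemUnpDbox",
]

#: Watson–Crick pairs only — the kink-turn closing pair excludes wobble
WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


@dataclass
class KinkTurnResult:
    passed: bool
    rule_ga_c: bool
    rule_ga_d: bool
    rule_uu: bool
    rule_wc: bool


@dataclass
class CdCandidate:
    record_id: str
    start: int   # fold region start (with flanks), 0-based
    end: int     # fold region end, half-open
    c_box: BoxMatch
    d_box: BoxMatch
    kink_turn: KinkTurnResult
    fold_free: FoldResult
    fold_constrained: FoldResult


@dataclass
class CdFeatures:
    mfe: float
    mfeC: float
    E_avg: float
    E_stdv: float
    ls: int
    Dcd: int
    Cscore: float
    Dscore: float
    GC: float
    zscore: float
    bpStem: int
    lu5: int
    lu3: int
    stemUnpCbox: int
    stemUnpDbox: int

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in CD_FEATURE_NAMES], dtype=float)


def kink_turn_test(cbox_seq: str, dbox_seq: str) -> KinkTurnResult:
    """Sequence test for the C/D kink-turn motif.

    Rules (1-based positions within the boxes): G,A at C box positions 3–4
    and at D box positions 3–4 (the tandem G·A pairs); a U at C box position
    5 or D box position 2 (the U·U interaction needs at least one uridine);
    and a Watson–Crick pair between C box position 6 and D box position 1
    (wobble G·U is not accepted).
    """
    if len(cbox_seq) != 7:
        raise ValueError(f"C box must have length 7, got {len(cbox_seq)}")
    if len(dbox_seq) != 4:
        raise ValueError(f"D box must have length 4, got {len(dbox_seq)}")
    rule_ga_c = cbox_seq[2] == "G" and cbox_seq[3] == "A"
    rule_ga_d = dbox_seq[2] == "G" and dbox_seq[3] == "A"
    rule_uu = cbox_seq[4] == "U" or dbox_seq[1] == "U"
    rule_wc = (cbox_seq[5], dbox_seq[0]) in WATSON_CRICK
    return KinkTurnResult(
        passed=rule_ga_c and rule_ga_d and rule_uu and rule_wc,
        rule_ga_c=rule_ga_c,
        rule_ga_d=rule_ga_d,
        rule_uu=rule_uu,
        rule_wc=rule_wc,
    )


def terminal_stem_features(
    structure: str,
    cbox_range: Tuple[int, int],
    dbox_range: Tuple[int, int],
) -> Tuple[int, int, int, int, int, int]:
    """(bpStem, ls, lu5, lu3, stemUnpCbox, stemUnpDbox) of a fold region.

    Stem pairs are the pairs enclosing the boxed region: (i, j) with i
    before the C box and j at or beyond the D box end (region-local
    half-open box coordinates). With no stem pairs all outputs are 0.
    ``ls`` is the 5' arm span, ``lu5``/``lu3`` count unpaired positions
    inside the two arm spans, and ``stemUnpCbox``/``stemUnpDbox`` count the
    unpaired gap between each arm and its box.
    """
    pairs = pair_table(structure)
    paired = {i for p in pairs for i in p}
    stem = [(i, j) for (i, j) in pairs if i < cbox_range[0] and j >= dbox_range[1]]
    if not stem:
        return 0, 0, 0, 0, 0, 0
    i_min = min(i for i, _ in stem)
    i_max = max(i for i, _ in stem)
    j_min = min(j for _, j in stem)
    j_max = max(j for _, j in stem)
    bp_stem = len(stem)
    ls = i_max - i_min + 1
    lu5 = sum(1 for p in range(i_min, i_max + 1) if p not in paired)
    lu3 = sum(1 for p in range(j_min, j_max + 1) if p not in paired)
    stem_unp_cbox = cbox_range[0] - i_max - 1
    stem_unp_dbox = j_min - dbox_range[1]
    return bp_stem, ls, lu5, lu3, stem_unp_cbox, stem_unp_dbox


def _fold_candidate(residues: str, c: BoxMatch, d: BoxMatch,
                    config: PipelineConfig, engine):
    """Free and constrained folds of the flanked candidate region."""
    start = max(0, c.start - config.cd_flank)
    end = min(len(residues), d.end + config.cd_flank)
    region = residues[start:end]
    fold_free = fold(engine, region)
    constraint = make_constraint(len(region),
                                 range(c.start - start, d.end - start))
    fold_con = fold(engine, region, constraint)
    return start, end, fold_free, fold_con


def find_cd_candidates(
    seq: SequenceRecord,
    pwm_c: PWM,
    pwm_d: PWM,
    config: PipelineConfig,
    engine,
) -> list[CdCandidate]:
    """Locate C/D box snoRNA candidates in one sequence.

    Steps: (1) PWM scan for C boxes; (2) per C box, PWM scan for D boxes
    with box span (C start to D end) within the allowed maximum; (3) the
    kink-turn sequence test; (4) fold the candidate with flanks, free and
    with the boxed region forced unpaired, and require a terminal stem of at
    least ``cd_min_stem_bp`` pairs in the constrained structure.
    """
    if not (math.isfinite(pwm_c.threshold) and math.isfinite(pwm_d.threshold)):
        raise ValueError("PWMs must have finite thresholds; run estimate_threshold")
    residues = seq.residues
    candidates: list[CdCandidate] = []
    for c in scan(residues, pwm_c):
        d_hi = min(len(residues), c.start + config.cd_max_c_d_span)
        for d in scan(residues, pwm_d, search_range=(c.end, d_hi)):
            if d.end - c.start > config.cd_max_c_d_span:
                continue
            kt = kink_turn_test(c.matched_seq, d.matched_seq)
            if not kt.passed:
                continue
            start, end, fold_free, fold_con = _fold_candidate(
                residues, c, d, config, engine)
            bp_stem, *_ = terminal_stem_features(
                fold_con.structure,
                (c.start - start, c.end - start),
                (d.start - start, d.end - start),
            )
            if bp_stem < config.cd_min_stem_bp:
                continue
            candidates.append(CdCandidate(
                record_id=seq.id, start=start, end=end,
                c_box=c, d_box=d, kink_turn=kt,
                fold_free=fold_free, fold_constrained=fold_con,
            ))
    candidates.sort(key=lambda cd: (cd.start, cd.c_box.start, cd.d_box.start))
    return candidates


def extract_cd_features(
    cand: CdCandidate,
    seq: SequenceRecord,
    engine,
    config: PipelineConfig,
    seed: Optional[int] = None,
) -> CdFeatures:
    """The 15-attribute C/D feature vector of a candidate."""
    if seed is None:
        seed = config.seed
    region = seq.residues[cand.start:cand.end]
    _, _, gc = composition(region)
    stats = ensemble_stats(engine, region, config.n_shuffles, seed)
    bp_stem, ls, lu5, lu3, unp_c, unp_d = terminal_stem_features(
        cand.fold_constrained.structure,
        (cand.c_box.start - cand.start, cand.c_box.end - cand.start),
        (cand.d_box.start - cand.start, cand.d_box.end - cand.start),
    )
    return CdFeatures(
        mfe=cand.fold_free.mfe,
        mfeC=cand.fold_constrained.mfe,
        E_avg=stats.e_avg,
        E_stdv=stats.e_stdv,
        ls=ls,
        Dcd=cand.d_box.start - cand.c_box.end,
        Cscore=cand.c_box.score,
        Dscore=cand.d_box.score,
        GC=gc,
        zscore=stats.zscore,
        bpStem=bp_stem,
        lu5=lu5,
        lu3=lu3,
        stemUnpCbox=unp_c,
        stemUnpDbox=unp_d,
    )


def relaxed_cd_features(
    seq: SequenceRecord,
    pwm_c: PWM,
    pwm_d: PWM,
    config: PipelineConfig,
    engine,
    seed: int,
) -> Optional[CdFeatures]:
    """Force one feature vector out of an arbitrary sequence.

    Used to featurize shuffled negatives: box thresholds are ignored (the
    best-scoring C and D windows within a valid geometry are used) and the
    kink-turn and terminal-stem filters are dropped. Returns None when no
    geometrically valid (C, D) placement exists.
    """
    residues = seq.residues
    Lc, Ld = pwm_c.length, pwm_d.length
    best_c = None
    for start in range(0, len(residues) - Lc - Ld + 1):
        s = score_window(pwm_c, residues[start:start + Lc])
        if best_c is None or s > best_c[1]:
            best_c = (start, s)
    if best_c is None:
        return None
    c = BoxMatch(pwm_c.box_name, best_c[0], best_c[0] + Lc, best_c[1],
                 residues[best_c[0]:best_c[0] + Lc])
    d_hi = min(len(residues), c.start + config.cd_max_c_d_span)
    best_d = None
    for start in range(c.end, d_hi - Ld + 1):
        s = score_window(pwm_d, residues[start:start + Ld])
        if best_d is None or s > best_d[1]:
            best_d = (start, s)
    if best_d is None:
        return None
    d = BoxMatch(pwm_d.box_name, best_d[0], best_d[0] + Ld, best_d[1],
                 residues[best_d[0]:best_d[0] + Ld])
    start, end, fold_free, fold_con = _fold_candidate(residues, c, d, config, engine)
    cand = CdCandidate(
        record_id=seq.id, start=start, end=end,
        c_box=c, d_box=d,
        kink_turn=kink_turn_test(c.matched_seq, d.matched_seq),
        fold_free=fold_free, fold_constrained=fold_con,
    )
    return extract_cd_features(cand, seq, engine, config, seed=seed)
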