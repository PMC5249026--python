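"""H/ACA box snoRNA candidate search and feature extraction.

An H/ACA box snoRNA folds into two hairpins separated by a single-stranded
hinge carrying box H (consensus ANANNA) and closed by a short tail carrying
the ACA trinucleotide. The search proceeds box-first: candidate H boxes come
from a PWM scan, the 5' end of the molecule is located as the locally stable
hairpin ending just upstream of the H box, and both hairpin regions must
fold into single stem-loops under a constraint that keeps the recognition
loop open (the 14th base upstream of each box is forced unpaired — in the
cell the target uridine, 13–16 nt before the boxes, sits in a large
interior loop held open by proteins that plain MFE folding does not model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import PipelineConfig
from .folding import (
    FoldResult,
    LoopDecomposition,
    UNPAIRED,
    ensemble_stats,
    fold,
    is_single_stemloop,
    local_fold,
    make_constraint,
    parse_structure,
)
from .pwm import PWM, BoxMatch, scan, score_window
from .seqio import SequenceRecord, composition

#: canonical feature order of the H/ACA 15-attribute vector
HACA_FEATURE_NAMES = [
    "mfeC", "AC", "GU", "GC", "zscore", "Hscore", "ACAscore",
    "LseqSize", "RseqSize", "LloopSC", "RloopSC",
    "LloopYC", "RloopYC", "LloopSym", "RloopSym",
]


@dataclass
class HacaCandidate:
    record_id: str
    start: int
    end: int
    h_box: BoxMatch
    aca_box: BoxMatch
    left_structure: FoldResult
    right_structure: FoldResult
    full_mfe_constrained: float


@dataclass
class HacaFeatures:
    mfeC: float
    AC: float
    GU: float
    GC: float
    zscore: float
    Hscore: float
    ACAscore: float
    LseqSize: int
    RseqSize: int
    LloopSC: int
    RloopSC: int
    LloopYC: float
    RloopYC: float
    LloopSym: float
    RloopSym: float

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in HACA_FEATURE_NAMES], dtype=float)


def build_haca_constraint(region_len: int, box_at_3prime: bool = True,
                          offset: int = 14) -> list[int]:
    """Constraint keeping the base ``offset`` positions upstream of a box open.

    The base immediately adjacent to the box counts as the 1st. For a region
    whose 3' end abuts the box this is index ``region_len - offset``; regions
    shorter than ``offset`` get no constraint.
    """
    if region_len < 1:
        raise ValueError("region_len must be >= 1")
    if region_len < offset:
        return make_constraint(region_len)
    pos = region_len - offset if box_at_3prime else offset - 1
    return make_constraint(region_len, [pos])


def _full_candidate_constraint(start: int, h_start: int, aca_start: int,
                               length: int, offset: int) -> list[int]:
    positions = []
    for box_start in (h_start, aca_start):
        p = box_start - offset - start
        if p >= 0:
            positions.append(p)
    return make_constraint(length, positions)


def _candidate_start(seq: str, h_start: int, config: PipelineConfig, engine) -> Optional[int]:
    """5' end of the candidate: start of the locally stable segment whose 3'
    end lies within ``gap_tol`` nt of the H box; the longest such segment
    (smallest start) wins."""
    win_start = max(0, h_start - config.haca_upstream_window)
    window = seq[win_start:h_start]
    if len(window) < 8:
        return None
    hits = local_fold(engine, window, config.haca_upstream_window)
    starts = [
        win_start + s
        for (s, e, _struct, _en) in hits
        if h_start - (win_start + e) <= config.haca_gap_tol
    ]
    return min(starts) if starts else None


def find_haca_candidates(
    seq: SequenceRecord,
    pwm_h: PWM,
    pwm_aca: PWM,
    config: PipelineConfig,
    engine,
) -> list[HacaCandidate]:
    """Locate H/ACA box snoRNA candidates in one sequence.

    Steps: (1) PWM scan for H boxes; (2) locate the candidate 5' end by
    local folding upstream of each H box and require the region up to the H
    box to fold into a single stem-loop under the recognition-loop
    constraint; (3) PWM scan for ACA boxes within the allowed distance
    downstream of the H box; (4) require the H-to-ACA region to fold into a
    single stem-loop under the same kind of constraint. One candidate per
    surviving (H, ACA) pair, ascending by start.
    """
    if not (math.isfinite(pwm_h.threshold) and math.isfinite(pwm_aca.threshold)):
        raise ValueError("PWMs must have finite thresholds; run estimate_threshold")
    residues = seq.residues
    offset = config.haca_constraint_offset
    min_region = 2 * config.haca_min_stem_bp + 3
    candidates: list[HacaCandidate] = []
    for h in scan(residues, pwm_h):
        cand_start = _candidate_start(residues, h.start, config, engine)
        if cand_start is None:
            continue
        left_region = residues[cand_start:h.start]
        if len(left_region) < min_region:
            continue
        left_fold = fold(
            engine, left_region,
            build_haca_constraint(len(left_region), offset=offset),
        )
        if not is_single_stemloop(parse_structure(left_fold.structure),
                                  config.haca_min_stem_bp):
            continue
        aca_hi = min(len(residues),
                     h.end + config.haca_max_h_aca_distance + pwm_aca.length)
        for aca in scan(residues, pwm_aca, search_range=(h.end, aca_hi)):
            if aca.start - h.end > config.haca_max_h_aca_distance:
                continue
            right_region = residues[h.end:aca.start]
            if len(right_region) < min_region:
                continue
            right_fold = fold(
                engine, right_region,
                build_haca_constraint(len(right_region), offset=offset),
            )
            if not is_single_stemloop(parse_structure(right_fold.structure),
                                      config.haca_min_stem_bp):
                continue
            cand_region = residues[cand_start:aca.end]
            full = fold(
                engine, cand_region,
                _full_candidate_constraint(cand_start, h.start, aca.start,
                                           len(cand_region), offset),
            )
            candidates.append(HacaCandidate(
                record_id=seq.id,
                start=cand_start,
                end=aca.end,
                h_box=h,
                aca_box=aca,
                left_structure=left_fold,
                right_structure=right_fold,
                full_mfe_constrained=full.mfe,
            ))
    candidates.sort(key=lambda c: (c.start, c.h_box.start, c.aca_box.start))
    return candidates


def _loop_features(decomp: LoopDecomposition, constrained_pos: int) -> tuple[int, float, float]:
    """(loop size, loop symmetry, mean symmetry) for one hairpin region.

    The recognition loop is the interior element containing the constrained
    position; if none contains it, the largest interior element; if the
    structure has no interior elements at all, size 0 and symmetries 1.
    """
    elements = decomp.interior_elements
    if not elements:
        return 0, 1.0, 1.0

    def symmetry(el) -> float:
        _, _, left, right = el
        total = left + right
        return 1.0 if total == 0 else 1.0 - abs(left - right) / total

    chosen = None
    for el in elements:
        if constrained_pos in decomp.interior_positions(el):
            chosen = el
            break
    if chosen is None:
        chosen = max(elements, key=lambda el: el[2] + el[3])
    size = chosen[2] + chosen[3]
    mean_sym = float(np.mean([symmetry(el) for el in elements]))
    return size, symmetry(chosen), mean_sym


def extract_haca_features(
    cand: HacaCandidate,
    seq: SequenceRecord,
    engine,
    config: PipelineConfig,
    seed: Optional[int] = None,
) -> HacaFeatures:
    """The 15-attribute H/ACA feature vector of a candidate."""
    if seed is None:
        seed = config.seed
    residues = seq.residues[cand.start:cand.end]
    ac, gu, gc = composition(residues)
    stats = ensemble_stats(engine, residues, config.n_shuffles, seed)
    offset = config.haca_constraint_offset

    left_decomp = parse_structure(cand.left_structure.structure)
    right_decomp = parse_structure(cand.right_structure.structure)
    left_len = cand.h_box.start - cand.start
    right_len = cand.aca_box.start - cand.h_box.end
    l_sc, l_yc, l_sym = _loop_features(left_decomp, left_len - offset)
    r_sc, r_yc, r_sym = _loop_features(right_decomp, right_len - offset)

    return HacaFeatures(
        mfeC=cand.full_mfe_constrained,
        AC=ac, GU=gu, GC=gc,
        zscore=stats.zscore,
        Hscore=cand.h_box.score,
        ACAscore=cand.aca_box.score,
        LseqSize=left_len,
        RseqSize=right_len,
        LloopSC=l_sc, RloopSC=r_sc,
        LloopYC=l_yc, RloopYC=r_yc,
        LloopSym=l_sym, RloopSym=r_sym,
    )


def relaxed_haca_features(
    seq: SequenceRecord,
    pwm_h: PWM,
    pwm_aca: PWM,
    config: PipelineConfig,
    engine,
    seed: int,
) -> Optional[HacaFeatures]:
    """Force one feature vector out of an arbitrary sequence.

    Used to featurize shuffled negatives, which usually fail the structure
    filters: box thresholds are ignored (the best-scoring windows are used)
    and the single-stem-loop requirements are dropped. Returns None when the
    sequence offers no geometrically valid (H, ACA) placement at all.
    """
    residues = seq.residues
    Lh, La = pwm_h.length, pwm_aca.length
    min_left = 8
    min_right = 2 * config.haca_min_stem_bp + 3
    best_h = None
    for start in range(min_left, len(residues) - Lh - La - min_right + 1):
        s = score_window(pwm_h, residues[start:start + Lh])
        if best_h is None or s > best_h[1]:
            best_h = (start, s)
    if best_h is None:
        return None
    h_start, h_score = best_h
    h = BoxMatch(pwm_h.box_name, h_start, h_start + Lh, h_score,
                 residues[h_start:h_start + Lh])
    best_aca = None
    aca_hi = min(len(residues) - La,
                 h.end + config.haca_max_h_aca_distance)
    for start in range(h.end + min_right, aca_hi + 1):
        s = score_window(pwm_aca, residues[start:start + La])
        if best_aca is None or s > best_aca[1]:
            best_aca = (start, s)
    if best_aca is None:
        return None
    aca = BoxMatch(pwm_aca.box_name, best_aca[0], best_aca[0] + La,
                   best_aca[1], residues[best_aca[0]:best_aca[0] + La])

    cand_start = _candidate_start(residues, h.start, config, engine)
    if cand_start is None or h.start - cand_start < min_left:
        cand_start = max(0, h.start - config.haca_upstream_window)
    offset = config.haca_constraint_offset
    left_region = residues[cand_start:h.start]
    right_region = residues[h.end:aca.start]
    left_fold = fold(engine, left_region,
                     build_haca_constraint(len(left_region), offset=offset))
    right_fold = fold(engine, right_region,
                      build_haca_constraint(len(right_region), offset=offset))
    cand_region = residues[cand_start:aca.end]
    full = fold(engine, cand_region,
                _full_candidate_constraint(cand_start, h.start, aca.start,
                                           len(cand_region), offset))
    cand = HacaCandidate(
        record_id=seq.id, start=cand_start, end=aca.end,
        h_box=h, aca_box=aca,
        left_structure=left_fold, right_structure=right_fold,
        full_mfe_constrained=full.mfe,
    )
    return extract_haca_features(cand, seq, engine, config, seed=seed)
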