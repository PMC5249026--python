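"""RNA secondary-structure prediction and dot-bracket loop analytics.

Two folding engines satisfy the same behavioural contract:

* :class:`ViennaEngine` — thermodynamic MFE folding (RNAfold semantics) with
  hard unpaired constraints and windowed local folding (RNALfold semantics),
  via the ViennaRNA bindings. This is the engine used for real predictions.
* :class:`MaxPairEngine` — a deterministic maximum base-pairing folder
  (Watson–Crick plus G·U wobble, minimum hairpin loop 3, energy −1 per
  pair, ties broken by the lexicographically smallest structure under the
  order '(' < '.' < ')'). Its optimum is checkable by exhaustive
  enumeration, so it serves as the oracle engine in tests; it is never used
  for shipped models.

Both honour per-position UNPAIRED constraints and return balanced
structures. Structures are plain dot-bracket strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np

from .seqio import mononucleotide_shuffle

FREE = 0
UNPAIRED = 1

Constraint = Sequence[int]

#: pairs allowed when folding (wobble included)
CANONICAL_PAIRS = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}

MIN_HAIRPIN = 3


def make_constraint(length: int, unpaired_positions: Sequence[int] = ()) -> list[int]:
    """All-FREE constraint with the given positions forced UNPAIRED."""
    c = [FREE] * length
    for p in unpaired_positions:
        if 0 <= p < length:
            c[p] = UNPAIRED
    return c


@dataclass
class FoldResult:
    structure: str
    mfe: float  # kcal/mol for Vienna; -1 per pair for the max-pair engine


@dataclass
class LoopDecomposition:
    """Full element classification of a nested dot-bracket structure."""

    pairs: list[Tuple[int, int]]
    helices: list[list[Tuple[int, int]]]
    # (closing pair, loop length)
    hairpin_loops: list[Tuple[Tuple[int, int], int]]
    # (outer pair, inner pair, left unpaired count, right unpaired count);
    # covers interior loops and bulges (left+right > 0); pure stacks excluded
    interior_elements: list[Tuple[Tuple[int, int], Tuple[int, int], int, int]]
    external_unpaired: int
    length: int
    # number of directly nested child pairs per pair (multiloop detection)
    children: dict[Tuple[int, int], int] = field(default_factory=dict)

    def interior_positions(
        self, element: Tuple[Tuple[int, int], Tuple[int, int], int, int]
    ) -> set[int]:
        (i, j), (k, l), _, _ = element
        return set(range(i + 1, k)) | set(range(l + 1, j))


class StructureParseError(ValueError):
    pass


def pair_table(dotbracket: str) -> list[Tuple[int, int]]:
    """Base pairs of a balanced single-family dot-bracket string."""
    stack: list[int] = []
    pairs: list[Tuple[int, int]] = []
    for pos, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureParseError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise StructureParseError(f"unexpected character {ch!r} at position {pos}")
    if stack:
        raise StructureParseError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def parse_structure(dotbracket: str) -> LoopDecomposition:
    """Decompose a dot-bracket structure into helices and loop elements.

    Every position is classified exactly once: paired, inside a hairpin
    loop, inside an interior element (loop or bulge), or external (which by
    convention also covers the rare multiloop interior).
    """
    n = len(dotbracket)
    pairs = pair_table(dotbracket)
    pair_set = set(pairs)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    # direct children of each pair
    children: dict[Tuple[int, int], list[Tuple[int, int]]] = {p: [] for p in pairs}
    roots: list[Tuple[int, int]] = []
    stack: list[Tuple[int, int]] = []
    for pos, ch in enumerate(dotbracket):
        if ch == "(":
            p = (pos, partner[pos])
            if stack:
                children[stack[-1]].append(p)
            else:
                roots.append(p)
            stack.append(p)
        elif ch == ")":
            stack.pop()

    # helices: maximal stacks of directly nested pairs with no gap
    helices: list[list[Tuple[int, int]]] = []
    in_helix: set[Tuple[int, int]] = set()
    for p in pairs:
        if p in in_helix:
            continue
        helix = [p]
        cur = p
        while True:
            kids = children[cur]
            if len(kids) == 1:
                (k, l) = kids[0]
                if k == cur[0] + 1 and l == cur[1] - 1:
                    helix.append((k, l))
                    cur = (k, l)
                    continue
            break
        in_helix.update(helix)
        helices.append(helix)

    hairpin_loops = []
    interior_elements = []
    classified: set[int] = set(partner)  # paired positions
    for p, kids in children.items():
        i, j = p
        if len(kids) == 0:
            loop_len = j - i - 1
            hairpin_loops.append((p, loop_len))
            classified.update(range(i + 1, j))
        elif len(kids) == 1:
            k, l = kids[0]
            left = k - i - 1
            right = j - l - 1
            if left + right > 0:
                interior_elements.append((p, (k, l), left, right))
            classified.update(range(i + 1, k))
            classified.update(range(l + 1, j))
        # multiloop unpaired positions fall through to external below

    external_unpaired = n - len(classified)
    return LoopDecomposition(
        pairs=pairs,
        helices=helices,
        hairpin_loops=sorted(hairpin_loops),
        interior_elements=sorted(interior_elements),
        external_unpaired=external_unpaired,
        length=n,
        children={p: len(k) for p, k in children.items()},
    )


def is_single_stemloop(decomp: LoopDecomposition, min_bp: int) -> bool:
    """True iff the structure is one hairpin with at least ``min_bp`` pairs
    and no multibranch loop."""
    if len(decomp.hairpin_loops) != 1:
        return False
    if len(decomp.pairs) < min_bp:
        return False
    return all(c <= 1 for c in decomp.children.values())


@dataclass
class EnergyStats:
    e_avg: float
    e_stdv: float
    zscore: float
    n_shuffles: int
    seed: int


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------


class FoldingEngineError(RuntimeError):
    pass


class ViennaEngine:
    """Thermodynamic MFE folding through the ViennaRNA bindings."""

    name = "vienna"

    def fold(self, seq: str, constraint: Optional[Constraint] = None) -> FoldResult:
        import RNA

        if constraint is not None and len(constraint) != len(seq):
            raise ValueError("constraint length must equal sequence length")
        try:
            fc = RNA.fold_compound(seq)
            if constraint is not None:
                for pos, flag in enumerate(constraint):
                    if flag == UNPAIRED:
                        fc.hc_add_up(pos + 1, RNA.CONSTRAINT_CONTEXT_ALL_LOOPS)
            structure, mfe = fc.mfe()
        except Exception as exc:  # pragma: no cover - engine failure wrapping
            raise FoldingEngineError(f"ViennaRNA failed on {seq[:30]}...: {exc}") from exc
        return FoldResult(structure=structure, mfe=round(float(mfe), 2))

    def local_fold(self, seq: str, max_span: int) -> list[Tuple[int, int, str, float]]:
        import RNA

        if max_span < 8:
            raise ValueError("max_span must be >= 8")
        if len(seq) < 8:
            return []
        md = RNA.md()
        span = min(max_span, len(seq))
        md.window_size = span
        md.max_bp_span = span
        fc = RNA.fold_compound(seq, md, RNA.OPTION_WINDOW)
        hits: list[Tuple[int, int, str, float]] = []

        def _cb(start, end, structure, energy, data=None):
            # callback coordinates are 1-based inclusive
            hits.append((start - 1, end, structure, float(energy)))

        fc.mfe_window_cb(_cb)
        return sorted(hits)


class MaxPairEngine:
    """Deterministic maximum base-pairing folder used as a test oracle.

    Energy is −1 per pair (unit-free); among all maximum-pairing nested
    structures the lexicographically smallest one under '(' < '.' < ')' is
    returned. Minimum hairpin loop length is 3; Watson–Crick and G·U pairs
    are allowed.
    """

    name = "maxpair"

    @staticmethod
    def _solve(seq: str, constraint: Optional[Constraint], max_span: Optional[int]):
        n = len(seq)
        free = [True] * n
        if constraint is not None:
            free = [flag != UNPAIRED for flag in constraint]

        def can_pair(i: int, j: int) -> bool:
            if j - i <= MIN_HAIRPIN:
                return False
            if max_span is not None and j - i > max_span:
                return False
            return free[i] and free[j] and (seq[i], seq[j]) in CANONICAL_PAIRS

        M = np.zeros((n + 1, n + 1), dtype=int)  # M[i][j] over [i, j)
        for span in range(MIN_HAIRPIN + 2, n + 1):
            for i in range(0, n - span + 1):
                j = i + span
                best = M[i + 1][j]
                for k in range(i + MIN_HAIRPIN + 1, j):
                    if can_pair(i, k):
                        v = 1 + M[i + 1][k] + M[k + 1][j]
                        if v > best:
                            best = v
                M[i][j] = best

        # lexicographically smallest traceback; '0'<'1'<'2' encodes '('<'.'<')'
        @lru_cache(maxsize=None)
        def best_struct(i: int, j: int) -> str:
            if j - i <= 0:
                return ""
            target = M[i][j]
            candidates = []
            for k in range(i + MIN_HAIRPIN + 1, j):
                if can_pair(i, k) and 1 + M[i + 1][k] + M[k + 1][j] == target:
                    candidates.append("0" + best_struct(i + 1, k) + "2" + best_struct(k + 1, j))
            if M[i + 1][j] == target:
                candidates.append("1" + best_struct(i + 1, j))
            return min(candidates)

        encoded = best_struct(0, n)
        best_struct.cache_clear()
        structure = encoded.translate(str.maketrans("012", "(.)"))
        return structure, int(M[0][n])

    def fold(self, seq: str, constraint: Optional[Constraint] = None) -> FoldResult:
        if constraint is not None and len(constraint) != len(seq):
            raise ValueError("constraint length must equal sequence length")
        structure, npairs = self._solve(seq, constraint, None)
        return FoldResult(structure=structure, mfe=float(-npairs))

    def local_fold(self, seq: str, max_span: int) -> list[Tuple[int, int, str, float]]:
        if max_span < 8:
            raise ValueError("max_span must be >= 8")
        structure, _ = self._solve(seq, None, max_span)
        pairs = pair_table(structure)
        hits = []
        # outermost pairs delimit locally folded segments
        covered_end = -1
        for i, j in pairs:
            if i > covered_end:
                seg = structure[i:j + 1]
                hits.append((i, j + 1, seg, -float(seg.count("("))))
                covered_end = j
        return hits


_ENGINES = {"vienna": ViennaEngine, "maxpair": MaxPairEngine}


def get_engine(name: str):
    try:
        return _ENGINES[name]()
    except KeyError:
        raise ValueError(f"unknown folding engine {name!r}; choose from {sorted(_ENGINES)}")


# ---------------------------------------------------------------------------
# module-level operations over an engine
# ---------------------------------------------------------------------------


def fold(engine, seq: str, constraint: Optional[Constraint] = None) -> FoldResult:
    """MFE structure of ``seq`` subject to ``constraint``.

    Positions flagged UNPAIRED are guaranteed to be '.' in the result.
    """
    result = engine.fold(seq, constraint)
    if constraint is not None:
        for pos, flag in enumerate(constraint):
            if flag == UNPAIRED and result.structure[pos] != ".":
                raise FoldingEngineError(
                    f"engine {engine.name} violated UNPAIRED constraint at {pos}"
                )
    return result


def local_fold(engine, seq: str, max_span: int) -> list[Tuple[int, int, str, float]]:
    """Locally stable folded segments with base-pair span <= max_span.

    Returns (start, end, structure, energy) tuples, 0-based half-open,
    sorted by start. May be empty.
    """
    return engine.local_fold(seq, max_span)


def ensemble_stats(engine, seq: str, n_shuffles: int, seed: int) -> EnergyStats:
    """Folding-energy statistics of a mononucleotide-shuffled ensemble.

    Folds ``n_shuffles`` random permutations of ``seq`` (identical
    nucleotide frequency) and returns their mean and standard deviation
    together with the z-score of the true sequence's MFE:
    z = (mfe − mean) / sd, or 0 when sd = 0. Reproducible under ``seed``.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    rng = np.random.default_rng(seed)
    energies = np.empty(n_shuffles)
    for i in range(n_shuffles):
        energies[i] = engine.fold(mononucleotide_shuffle(seq, rng)).mfe
    mfe0 = engine.fold(seq).mfe
    e_avg = float(energies.mean())
    e_stdv = float(energies.std(ddof=1)) if n_shuffles > 1 else 0.0
    z = (mfe0 - e_avg) / e_stdv if e_stdv > 0 else 0.0
    return EnergyStats(e_avg=e_avg, e_stdv=e_stdv, zscore=float(z),
                       n_shuffles=n_shuffles, seed=seed)
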