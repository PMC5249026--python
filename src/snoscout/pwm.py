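"""Position-specific weight matrices for the H, ACA, C and D boxes.

A PWM stores per-position nucleotide probabilities (with pseudocount) and
scores windows as log2-odds against a background composition. Box scans keep
every window at or above a score threshold; thresholds are estimated as the
equal-error crossing point of Gaussian kernel density estimates of true-box
versus non-box score samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import gaussian_kde

ALPHABET = "ACGU"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
UNIFORM_BACKGROUND = np.full(4, 0.25)

#: canonical motif lengths
BOX_LENGTHS = {"H": 6, "ACA": 3, "C": 7, "D": 4}


@dataclass
class PWM:
    box_name: str
    probs: np.ndarray          # L x 4, columns ordered A, C, G, U
    background: np.ndarray     # length 4
    pseudocount: float
    threshold: float = math.nan

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("probs must be an L x 4 matrix with L >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every PWM row must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        if (self.background < 0).any() or (self.probs < 0).any():
            raise ValueError("probabilities must be non-negative")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


@dataclass
class BoxMatch:
    box_name: str
    start: int            # 0-based
    end: int              # half-open, start + L
    score: float          # bits
    matched_seq: str


def build_pwm(
    instances: Sequence[str],
    pseudocount: float = 0.25,
    background: Optional[np.ndarray] = None,
    box_name: str = "box",
) -> PWM:
    """Build a PWM from equal-length box instances.

    probs[i][b] = (count(b at i) + pseudocount) / (n + 4 * pseudocount).
    The score threshold is left unset (NaN) until :func:`estimate_threshold`.
    """
    if not instances:
        raise ValueError("need at least one instance")
    L = len(instances[0])
    for inst in instances:
        if len(inst) != L:
            raise ValueError(
                f"ragged instance lengths: {inst!r} has length {len(inst)}, expected {L}"
            )
        if set(inst) - set(ALPHABET):
            raise ValueError(f"instance {inst!r} contains non-ACGU residues")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    counts = np.zeros((L, 4))
    for inst in instances:
        for i, ch in enumerate(inst):
            counts[i, _INDEX[ch]] += 1
    n = len(instances)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    return PWM(box_name=box_name, probs=probs, background=bg, pseudocount=pseudocount)


def score_window(pwm: PWM, window: str) -> float:
    """Log2-odds score of a window against the PWM background, in bits.

    A zero probability yields -inf, which never reaches a finite threshold.
    """
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} does not match PWM length {pwm.length}"
        )
    score = 0.0
    for i, ch in enumerate(window):
        p = pwm.probs[i, _INDEX[ch]]
        if p == 0.0:
            return -math.inf
        score += math.log2(p / pwm.background[_INDEX[ch]])
    return score


def scan(
    seq: str,
    pwm: PWM,
    threshold: Optional[float] = None,
    search_range: Optional[Tuple[int, int]] = None,
) -> list[BoxMatch]:
    """All windows scoring >= threshold, in ascending start order.

    ``search_range`` is a half-open interval of the sequence; only windows
    lying entirely inside it are reported. Ranges extending past the sequence
    are clipped, never an error. Overlapping matches are all kept.
    """
    if threshold is None:
        threshold = pwm.threshold
    if not math.isfinite(threshold):
        raise ValueError("scan requires a finite threshold")
    L = pwm.length
    lo, hi = (0, len(seq)) if search_range is None else search_range
    lo = max(0, lo)
    hi = min(len(seq), hi)
    matches = []
    for start in range(lo, hi - L + 1):
        window = seq[start:start + L]
        s = score_window(pwm, window)
        if s >= threshold:
            matches.append(
                BoxMatch(pwm.box_name, start, start + L, s, window)
            )
    return matches


def estimate_threshold(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Equal-error score threshold between true-box and non-box score samples.

    Returns the score at which Gaussian-KDE density estimates of the two
    samples cross, searched between the two sample means; if no crossing
    exists there (or a KDE is degenerate), the midpoint of the means.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score samples must be non-empty")
    m_pos, m_neg = float(pos.mean()), float(neg.mean())
    lo, hi = sorted((m_pos, m_neg))
    mid = 0.5 * (m_pos + m_neg)
    if hi - lo < 1e-12:
        return mid
    try:
        kde_pos = gaussian_kde(pos)
        kde_neg = gaussian_kde(neg)
    except Exception:  # singular samples (zero variance)
        return mid
    grid = np.linspace(lo, hi, 513)
    diff = kde_pos(grid) - kde_neg(grid)
    crossings = []
    for i in range(len(grid) - 1):
        if diff[i] == 0.0:
            crossings.append(grid[i])
        elif diff[i] * diff[i + 1] < 0:
            # linear interpolation of the root
            x = grid[i] + (grid[i + 1] - grid[i]) * diff[i] / (diff[i] - diff[i + 1])
            crossings.append(x)
    if not crossings:
        return mid
    return float(min(crossings, key=lambda x: abs(x - mid)))


def save_pwm(pwm: PWM, path) -> None:
    """Persist a PWM as a plain-text tab-separated matrix (bit-exact)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#box\t{pwm.box_name}\n")
        fh.write(f"#length\t{pwm.length}\n")
        fh.write(f"#pseudocount\t{pwm.pseudocount!r}\n")
        fh.write("#background\t" + "\t".join(repr(x) for x in pwm.background.tolist()) + "\n")
        fh.write(f"#threshold\t{pwm.threshold!r}\n")
        fh.write("#pos\t" + "\t".join(ALPHABET) + "\n")
        for i in range(pwm.length):
            fh.write(str(i) + "\t" + "\t".join(repr(x) for x in pwm.probs[i].tolist()) + "\n")


def load_pwm(path) -> PWM:
    path = Path(path)
    meta: dict[str, str] = {}
    background = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if line.startswith("#background"):
                background = np.array([float(x) for x in fields[1:]])
            elif line.startswith("#pos"):
                continue
            elif line.startswith("#"):
                meta[fields[0][1:]] = fields[1]
            else:
                rows.append([float(x) for x in fields[1:]])
    probs = np.array(rows)
    return PWM(
        box_name=meta["box"],
        probs=probs,
        background=background,
        pseudocount=float(meta["pseudocount"]),
        threshold=float(meta["threshold"]),
    )
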