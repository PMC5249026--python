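"""SVM training and evaluation for snoRNA classification.

Positives are feature vectors extracted from known snoRNAs by the class
pipelines; negatives come from dinucleotide-shuffled copies of the positives
pushed through the same pipeline in relaxed mode. Features are scaled to
[-1, 1] (svm-scale semantics: no clipping of out-of-range values), the RBF
C-SVM parameters C and gamma are chosen by exhaustive grid search over
exponentially growing values with stratified k-fold cross-validated
accuracy, and models are trained with Platt-style probability estimates.
"""

from __future__ import annotations

import logging
import math
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cdbox import CD_FEATURE_NAMES, extract_cd_features, find_cd_candidates, relaxed_cd_features
from .config import PipelineConfig
from .haca import HACA_FEATURE_NAMES, extract_haca_features, find_haca_candidates, relaxed_haca_features
from .pwm import PWM
from .seqio import SequenceRecord, dinucleotide_shuffle

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

FEATURE_NAMES = {"HACA": HACA_FEATURE_NAMES, "CD": CD_FEATURE_NAMES}


def _child_seed(*parts: int) -> int:
    """Deterministic sub-seed below 2**31 derived from integer parts."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# scaling (svm-scale semantics)
# ---------------------------------------------------------------------------


@dataclass
class ScalingParams:
    min_: np.ndarray
    max_: np.ndarray


def scale_fit(X) -> ScalingParams:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("scale_fit needs at least one feature vector")
    return ScalingParams(min_=X.min(axis=0), max_=X.max(axis=0))


def scale_apply(params: ScalingParams, X) -> np.ndarray:
    """Map features to [-1, 1] by the training min/max.

    Values outside the training range map outside [-1, 1] (no clipping);
    constant training features map to 0.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != params.min_.shape[0]:
        raise ValueError(
            f"dimension mismatch: {X.shape[1]} features, scaler has {params.min_.shape[0]}"
        )
    span = params.max_ - params.min_
    out = np.zeros_like(X)
    nz = span > 0
    out[:, nz] = -1.0 + 2.0 * (X[:, nz] - params.min_[nz]) / span[nz]
    return out


# ---------------------------------------------------------------------------
# model, grid search, metrics
# ---------------------------------------------------------------------------


@dataclass
class SvmModel:
    clf: SVC
    scaling: ScalingParams
    feature_names: list[str]
    sno_class: str                # "CD" or "HACA"
    C: float
    gamma: float
    seed: int
    n_pos: int
    n_neg: int
    pwms: dict[str, PWM] = field(default_factory=dict)
    # Platt calibration on small, perfectly separated training sets can come
    # out anti-correlated with the SVM decision function; detected at
    # training time and corrected here.
    proba_flipped: bool = False

    def predict_scaled(self, X_scaled) -> Tuple[np.ndarray, np.ndarray]:
        X_scaled = np.asarray(X_scaled, dtype=float)
        if X_scaled.shape[1] != len(self.feature_names):
            raise ValueError("feature order/length mismatch with trained model")
        proba = self.clf.predict_proba(X_scaled)
        pos_col = list(self.clf.classes_).index(1)
        p_pos = proba[:, pos_col]
        if self.proba_flipped:
            p_pos = 1.0 - p_pos
        labels = self.clf.predict(X_scaled).astype(int)
        return labels, p_pos


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f_score: float
    apr: float
    auc: float
    rss: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("accuracy", "precision", "recall", "f_score", "apr", "auc", "rss")}


def grid_search(
    X,
    y,
    exponents: Sequence[int] = range(-15, 16),
    folds: int = 10,
    seed: int = 0,
) -> Tuple[float, float, float]:
    """Exhaustive (C, gamma) = (2^a, 2^b) search by stratified k-fold CV accuracy.

    Returns (C, gamma, cv_accuracy) of the maximizer; ties are broken toward
    smaller C, then smaller gamma. Deterministic under ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("grid_search needs both classes present")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = [(tr, te) for tr, te in skf.split(X, y)]
    best: Optional[Tuple[float, float, float]] = None
    for a in exponents:
        for b in exponents:
            C, gamma = 2.0 ** a, 2.0 ** b
            accs = []
            for tr, te in splits:
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(X[tr], y[tr])
                accs.append(accuracy_score(y[te], clf.predict(X[te])))
            acc = float(np.mean(accs))
            if best is None or acc > best[2] + 1e-12:
                best = (C, gamma, acc)
    return best


def train(X, y, C: float, gamma: float, seed: int = 0,
          scaling: Optional[ScalingParams] = None,
          sno_class: str = "CD",
          pwms: Optional[dict[str, PWM]] = None) -> SvmModel:
    """Train an RBF C-SVM with Platt probability estimates on scaled data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isfinite(X).all():
        raise ValueError("training matrix contains NaN/inf; scale and clean first")
    clf = SVC(C=C, gamma=gamma, kernel="rbf", probability=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(X, y)
    # orientation check of the Platt probabilities against the decision values
    decision = clf.decision_function(X)
    pos_col = list(clf.classes_).index(1)
    p = clf.predict_proba(X)[:, pos_col]
    flipped = False
    if np.std(decision) > 0 and np.std(p) > 0:
        flipped = bool(np.corrcoef(decision, p)[0, 1] < 0)
    names = FEATURE_NAMES[sno_class]
    if len(names) != X.shape[1]:  # non-pipeline feature spaces keep generic names
        names = [f"f{i}" for i in range(X.shape[1])]
    if scaling is None:
        scaling = ScalingParams(min_=np.full(X.shape[1], -1.0),
                                max_=np.full(X.shape[1], 1.0))
    return SvmModel(
        clf=clf, scaling=scaling, feature_names=list(names),
        sno_class=sno_class, C=C, gamma=gamma, seed=seed,
        n_pos=int((y == 1).sum()), n_neg=int((y == 0).sum()),
        pwms=pwms or {}, proba_flipped=flipped,
    )


def predict(model: SvmModel, X_scaled) -> Tuple[np.ndarray, np.ndarray]:
    """Labels and P(positive) for already-scaled feature vectors."""
    return model.predict_scaled(X_scaled)


def evaluate(y_true, y_pred, p_pos=None) -> MetricsReport:
    """Classification metrics.

    accuracy = (TP+TN)/n, f_score = 2TP/(2TP+FP+FN); apr and auc are the
    areas under the precision-recall and ROC curves over the predicted
    probabilities; rss = mean squared (label - probability), a Brier-style
    mean. With no probabilities, or a single-class truth, the
    probability-based metrics are NaN sentinels.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    acc = accuracy_score(y_true, y_pred)
    prec = precision_score(y_true, y_pred, zero_division=0.0)
    rec = recall_score(y_true, y_pred, zero_division=0.0)
    f = f1_score(y_true, y_pred, zero_division=0.0)
    apr = auc = rss = math.nan
    if p_pos is not None:
        p_pos = np.asarray(p_pos, dtype=float)
        rss = float(np.mean((y_true - p_pos) ** 2))
        if len(np.unique(y_true)) == 2:
            apr = float(average_precision_score(y_true, p_pos))
            auc = float(roc_auc_score(y_true, p_pos))
    return MetricsReport(accuracy=float(acc), precision=float(prec),
                         recall=float(rec), f_score=float(f),
                         apr=apr, auc=auc, rss=rss)


def metrics_from_confusion(tp: int, fn: int, fp: int, tn: int) -> MetricsReport:
    """Metrics computed from confusion-matrix counts via :func:`evaluate`."""
    y_true = np.concatenate([np.ones(tp + fn, int), np.zeros(fp + tn, int)])
    y_pred = np.concatenate([np.ones(tp, int), np.zeros(fn, int),
                             np.ones(fp, int), np.zeros(tn, int)])
    return evaluate(y_true, y_pred)


# ---------------------------------------------------------------------------
# feature extraction and negative-set construction
# ---------------------------------------------------------------------------


def extract_positive_features(
    records: Sequence[SequenceRecord],
    sno_class: str,
    pwms: dict[str, PWM],
    config: PipelineConfig,
    engine,
    seed: int = 0,
) -> np.ndarray:
    """Feature matrix of the first surviving candidate of each record.

    Records yielding no candidate are dropped with a warning.
    """
    vectors = []
    dropped = 0
    for i, rec in enumerate(records):
        s = _child_seed(seed, 11, i)
        if sno_class == "HACA":
            cands = find_haca_candidates(rec, pwms["H"], pwms["ACA"], config, engine)
            if cands:
                vectors.append(extract_haca_features(
                    cands[0], rec, engine, config, seed=s).as_vector())
            else:
                dropped += 1
        else:
            cands = find_cd_candidates(rec, pwms["C"], pwms["D"], config, engine)
            if cands:
                vectors.append(extract_cd_features(
                    cands[0], rec, engine, config, seed=s).as_vector())
            else:
                dropped += 1
    if dropped:
        logger.warning("%d of %d positives yielded no candidate and were dropped",
                       dropped, len(records))
    return np.array(vectors)


def make_negatives(
    positives: Sequence[SequenceRecord],
    sno_class: str,
    pwms: dict[str, PWM],
    config: PipelineConfig,
    engine,
    seed: int = 0,
    per_positive: int = 1,
) -> np.ndarray:
    """Feature vectors of dinucleotide-shuffled copies of the positives.

    Each shuffle is pushed through the class pipeline in relaxed mode (box
    thresholds ignored, structure filters disabled, best-scoring box
    positions used) to force one feature vector; shuffles offering no valid
    box geometry are redrawn up to 10 times, then dropped with a warning.
    """
    if not positives:
        raise ValueError("make_negatives requires a non-empty positive set")
    if sno_class not in FEATURE_NAMES:
        raise ValueError(f"unknown class {sno_class!r}")
    vectors = []
    for i, rec in enumerate(positives):
        for p in range(per_positive):
            feats = None
            for attempt in range(10):
                s = _child_seed(seed, i, p, attempt)
                shuffled = SequenceRecord(
                    id=f"{rec.id}_shuf{p}",
                    residues=dinucleotide_shuffle(rec.residues, s),
                )
                if sno_class == "HACA":
                    feats = relaxed_haca_features(
                        shuffled, pwms["H"], pwms["ACA"], config, engine, seed=s)
                else:
                    feats = relaxed_cd_features(
                        shuffled, pwms["C"], pwms["D"], config, engine, seed=s)
                if feats is not None:
                    break
            if feats is None:
                logger.warning("no box geometry in 10 shuffles of %s; dropped", rec.id)
                continue
            vectors.append(feats.as_vector())
    return np.array(vectors)


# ---------------------------------------------------------------------------
# similarity-aware split and the repeated training/test protocol
# ---------------------------------------------------------------------------


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def similarity_split(
    positives: Sequence[SequenceRecord],
    k: int = 6,
    threshold: float = 0.5,
    seed: int = 0,
) -> Tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Two-way split keeping similar sequences in the same partition.

    Single-linkage clusters on k-mer Jaccard similarity >= threshold are
    assigned alternately to the two partitions by descending cluster size,
    so near-duplicates never straddle the train/test boundary.
    """
    n = len(positives)
    if n < 2:
        raise ValueError("similarity_split needs at least 2 sequences")
    kmers = [_kmer_set(rec.residues, k) for rec in positives]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            union = len(kmers[i] | kmers[j])
            if union == 0:
                continue
            if len(kmers[i] & kmers[j]) / union >= threshold:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(clusters.values(), key=lambda c: (-len(c), c[0]))
    part1: list[int] = []
    part2: list[int] = []
    for idx, cluster in enumerate(ordered):
        (part1 if idx % 2 == 0 else part2).extend(cluster)
    return ([positives[i] for i in sorted(part1)],
            [positives[i] for i in sorted(part2)])


def repeated_protocol(
    dataset1: Sequence[SequenceRecord],
    dataset2: Sequence[SequenceRecord],
    sno_class: str,
    pwms: dict[str, PWM],
    config: PipelineConfig,
    engine,
    repeats: int = 10,
    seed: int = 0,
    exponents: Optional[Sequence[int]] = None,
    folds: Optional[int] = None,
) -> dict:
    """Train on one dataset, test on the other, both directions, repeatedly.

    Each repeat draws fresh dinucleotide-shuffled negatives for both sides,
    rescales on the training side, grid-searches (C, gamma), trains, and
    evaluates on the held-out side. Returns per-direction, per-metric means
    and standard deviations plus the last fitted model per direction.
    """
    if not dataset1 or not dataset2:
        raise ValueError("both datasets must be non-empty")
    if exponents is None:
        exponents = config.grid_exponents()
    if folds is None:
        folds = config.svm_folds
    pos_feats = {
        0: extract_positive_features(dataset1, sno_class, pwms, config, engine,
                                     seed=_child_seed(seed, 0)),
        1: extract_positive_features(dataset2, sno_class, pwms, config, engine,
                                     seed=_child_seed(seed, 1)),
    }
    directions = {"dat1->dat2": (0, 1), "dat2->dat1": (1, 0)}
    datasets = {0: dataset1, 1: dataset2}
    summary: dict = {}
    for dname, (tr, te) in directions.items():
        per_metric: dict[str, list[float]] = {}
        chosen = []
        model = None
        for r in range(repeats):
            rs = _child_seed(seed, tr, te, r)
            neg_tr = make_negatives(datasets[tr], sno_class, pwms, config, engine,
                                    seed=_child_seed(rs, 0))
            neg_te = make_negatives(datasets[te], sno_class, pwms, config, engine,
                                    seed=_child_seed(rs, 1))
            X_tr = np.vstack([pos_feats[tr], neg_tr])
            y_tr = np.concatenate([np.ones(len(pos_feats[tr]), int),
                                   np.zeros(len(neg_tr), int)])
            order = np.random.default_rng(rs).permutation(len(y_tr))
            X_tr, y_tr = X_tr[order], y_tr[order]
            params = scale_fit(X_tr)
            Xs_tr = scale_apply(params, X_tr)
            C, gamma, cv_acc = grid_search(Xs_tr, y_tr, exponents, folds, seed=rs)
            model = train(Xs_tr, y_tr, C, gamma, seed=rs, scaling=params,
                          sno_class=sno_class, pwms=pwms)
            X_te = np.vstack([pos_feats[te], neg_te])
            y_te = np.concatenate([np.ones(len(pos_feats[te]), int),
                                   np.zeros(len(neg_te), int)])
            labels, p_pos = predict(model, scale_apply(params, X_te))
            report = evaluate(y_te, labels, p_pos)
            for metric, value in report.as_dict().items():
                per_metric.setdefault(metric, []).append(value)
            chosen.append((C, gamma, cv_acc))
        summary[dname] = {
            "mean": {m: float(np.mean(v)) for m, v in per_metric.items()},
            "sd": {m: (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
                   for m, v in per_metric.items()},
            "grid": chosen,
            "model": model,
        }
    return summary


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------


def save_model(model: SvmModel, path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "sno_class": model.sno_class,
        "feature_names": model.feature_names,
        "scaling_min": model.scaling.min_.tolist(),
        "scaling_max": model.scaling.max_.tolist(),
        "C": model.C,
        "gamma": model.gamma,
        "seed": model.seed,
        "n_pos": model.n_pos,
        "n_neg": model.n_neg,
        "clf": model.clf,
        "pwms": model.pwms,
        "proba_flipped": model.proba_flipped,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> SvmModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format in {path}")
    expected = FEATURE_NAMES[payload["sno_class"]]
    if payload["feature_names"] != list(expected):
        raise ValueError(
            f"feature-order mismatch in {path}: model was trained with "
            f"{payload['feature_names']}, expected {list(expected)}"
        )
    return SvmModel(
        clf=payload["clf"],
        scaling=ScalingParams(min_=np.array(payload["scaling_min"]),
                              max_=np.array(payload["scaling_max"])),
        feature_names=payload["feature_names"],
        sno_class=payload["sno_class"],
        C=payload["C"],
        gamma=payload["gamma"],
        seed=payload["seed"],
        n_pos=payload["n_pos"],
        n_neg=payload["n_neg"],
        pwms=payload.get("pwms", {}),
        proba_flipped=payload.get("proba_flipped", False),
    )
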