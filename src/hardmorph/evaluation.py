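"""Random-forest benchmark of labeled easy/hard molecule sets.

Molecules are encoded as 512-bit radius-2 circular fingerprints and
classified by a 100-tree random forest.  The positive class is *easy to
synthesize*: true positives are easy structures predicted easy, true
negatives hard structures predicted hard.  Point metrics (accuracy,
sensitivity, specificity) are taken at the 0.5 probability threshold; the
ROC curve sweeps all thresholds and its trapezoidal area equals the
Mann–Whitney pair statistic (ties counted one half).

Because the easy class is sampled from a larger pool, headline numbers are
averaged over several independent easy-samples, each with its own trained
forest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .calibration import LEVELS, StopCondition, ThresholdTable
from .chem import fp_array, parse_smiles
from .datasets import LabeledSet, build_morph_sets

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts at a fixed decision threshold; positive class = easy."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """Point metrics, ROC/AUC and bookkeeping for one evaluated model."""

    acc: float
    sn: float
    sp: float
    auc: float
    roc: list[tuple[float, float]]
    confusion: ConfusionMatrix
    seed: int | None = None
    tag: str = ""
    params: dict = field(default_factory=dict)


def _features(smiles: list[str]) -> np.ndarray:
    return fp_array([parse_smiles(s) for s in smiles])


def train_classifier(
    train: LabeledSet, n_trees: int = 100, seed: int | None = None
) -> RandomForestClassifier:
    """Fit a random forest on the fingerprints of a labeled set.

    Labels are encoded 1 = easy (positive), 0 = hard.  Deterministic for a
    fixed seed and fixed data.
    """
    easy, hard = train.easy, train.hard
    if not easy or not hard:
        raise ValueError("training set must contain both classes")
    X = _features(easy + hard)
    y = np.array([1] * len(easy) + [0] * len(hard))
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(X, y)
    return clf


def predict_easy_proba(model: RandomForestClassifier, smiles: list[str]) -> np.ndarray:
    """P(easy) per molecule."""
    X = _features(smiles)
    pos = list(model.classes_).index(1)
    return model.predict_proba(X)[:, pos]


def confusion(
    model: RandomForestClassifier, test: LabeledSet, threshold: float = 0.5
) -> ConfusionMatrix:
    """Confusion counts on a labeled test set at a probability threshold."""
    easy, hard = test.easy, test.hard
    if not easy and not hard:
        raise ValueError("empty test set")
    tp = fn = tn = fp = 0
    if easy:
        pred = predict_easy_proba(model, easy) >= threshold
        tp = int(pred.sum())
        fn = len(easy) - tp
    if hard:
        pred = predict_easy_proba(model, hard) >= threshold
        fp = int(pred.sum())
        tn = len(hard) - fp
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN where a denominator is zero."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / cm.total
    sn = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else float("nan")
    sp = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else float("nan")
    return acc, sn, sp


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC swept over all score thresholds and its trapezoidal area.

    ``labels`` are 1 for positive (easy), 0 for negative.  The area equals
    the probability that a random positive scores above a random negative,
    with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            tp += int(sorted_labels[j] == 1)
            fp += int(sorted_labels[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return points, float(auc)


def evaluate(
    model: RandomForestClassifier,
    test: LabeledSet,
    seed: int | None = None,
    tag: str = "",
) -> EvalReport:
    """Full report: confusion at 0.5, point metrics and the ROC/AUC sweep."""
    cm = confusion(model, test)
    acc, sn, sp = metrics(cm)
    easy, hard = test.easy, test.hard
    scores = np.concatenate(
        [predict_easy_proba(model, easy), predict_easy_proba(model, hard)]
    )
    labels = np.array([1] * len(easy) + [0] * len(hard))
    roc, auc = roc_auc(scores, labels)
    params = {k: v for k, v in model.get_params().items() if k in ("n_estimators", "max_depth", "max_features")}
    return EvalReport(
        acc=acc, sn=sn, sp=sp, auc=auc, roc=roc, confusion=cm, seed=seed, tag=tag,
        params=params,
    )


@dataclass
class AveragedReport:
    """Arithmetic mean of point metrics and AUC over independent easy-samples."""

    acc: float
    sn: float
    sp: float
    auc: float
    samples: list[EvalReport]
    tag: str = ""


def repeat_eval(
    hard: list[str],
    easy_pool: list[str],
    test: LabeledSet,
    k: int = 5,
    seed: int = 0,
    n_trees: int = 100,
    tag: str = "",
) -> AveragedReport:
    """Average metrics over ``k`` independent easy-samples from the pool.

    Each sample draws ``len(hard)`` easy molecules without replacement,
    trains its own forest and is evaluated on the same test set; scalar
    metrics are averaged arithmetically.
    """
    if len(easy_pool) < len(hard):
        raise ValueError(
            f"easy pool ({len(easy_pool)}) smaller than hard set ({len(hard)})"
        )
    ss = np.random.SeedSequence(seed)
    reports = []
    for child in ss.spawn(k):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child_seed)
        idx = rng.choice(len(easy_pool), size=len(hard), replace=False)
        easy = [easy_pool[i] for i in sorted(idx)]
        train = LabeledSet.from_smiles(easy=easy, hard=hard, source=tag)
        model = train_classifier(train, n_trees=n_trees, seed=child_seed)
        reports.append(evaluate(model, test, seed=child_seed, tag=tag))
    return AveragedReport(
        acc=float(np.mean([r.acc for r in reports])),
        sn=float(np.mean([r.sn for r in reports])),
        sp=float(np.mean([r.sp for r in reports])),
        auc=float(np.mean([r.auc for r in reports])),
        samples=reports,
        tag=tag,
    )


def stop_condition_grid(
    starts,
    table: ThresholdTable,
    test: LabeledSet,
    seed: int = 0,
    max_steps: int = 30,
    n_trees: int = 100,
) -> pd.DataFrame:
    """Benchmark every stop condition: 3 threshold levels × k ∈ {1,2,3,4}.

    For each of the twelve configurations, a fresh morphing run builds a
    balanced training set (hard terminals vs their starting structures), a
    forest is trained and evaluated on ``test``.  The returned table has one
    row per configuration with the class sizes and metrics; the
    best-accuracy row is flagged in the ``best`` column.  Deterministic for
    fixed seed and inputs.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(LEVELS) * 4)
    ci = 0
    for level in LEVELS:
        for k in (1, 2, 3, 4):
            child_seed = int(children[ci].generate_state(1)[0] % (2**31))
            ci += 1
            rng = np.random.default_rng(child_seed)
            cond = StopCondition(level=level, k_indices=k)
            train, _ = build_morph_sets(
                starts, table, cond, rng, max_steps=max_steps
            )
            row = {
                "level": level,
                "k_indices": k,
                "n_easy": len(train.easy),
                "n_hard": len(train.hard),
                "acc": float("nan"),
                "sn": float("nan"),
                "sp": float("nan"),
                "auc": float("nan"),
            }
            if train.easy and train.hard:
                model = train_classifier(train, n_trees=n_trees, seed=child_seed)
                rep = evaluate(model, test, seed=child_seed, tag=f"{level}/k={k}")
                row.update(acc=rep.acc, sn=rep.sn, sp=rep.sp, auc=rep.auc)
            else:
                logger.warning("grid cell %s/k=%d produced an empty class", level, k)
            rows.append(row)
    df = pd.DataFrame(rows)
    df["best"] = False
    if df["acc"].notna().any():
        df.loc[df["acc"].idxmax(), "best"] = True
    return df
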