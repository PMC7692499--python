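"""Ensemble transcriptomic classification (ETC).

Many linear support-vector classifiers, one per dictionary entry, vote on
each sample.  The vote proportions of the two most popular classes, p1 and
p2, form the confidence score p1/p2; a sample is assigned to the most
popular class only when the score exceeds 3, and is "ambiguous" otherwise
(a score of exactly 3 is ambiguous).  Unanimity (p2 = 0) counts as infinite
confidence.

In-cohort calls are produced leak-free by fourfold cross-fitting: models are
trained on three folds and vote only on the held-out fold, so no sample is
ever classified by a model that saw it in training.  Samples the unsupervised
step left ambiguous are never trained on, and are voted on by models fitted
to the full labeled cohort.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .dbu import AMBIGUOUS
from .io_preprocess import ExpressionMatrix
from .signature import ModelDictionary, as_labels, make_svc

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleModel",
    "plurality_confidence",
    "crossfit_calls",
    "fit_final",
    "predict",
    "predict_external",
    "confidence_summary",
    "CONFIDENCE_CUTOFF",
]

CONFIDENCE_CUTOFF = 3.0


@dataclass
class _Linear:
    """A fitted one-vs-rest linear classifier on a gene subset."""

    genes: list[str]
    classes: list[str]
    coef: np.ndarray  # (n_classes, n_genes) or (1, n_genes) for 2 classes
    intercept: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        scores = x @ self.coef.T + self.intercept
        if len(self.classes) == 2:
            return np.where(scores.ravel() > 0, self.classes[1], self.classes[0])
        return np.asarray(self.classes)[scores.argmax(axis=1)]


def _fit_linear(expr: ExpressionMatrix, genes: list[str], y: pd.Series, seed: int) -> _Linear:
    x = expr.data.loc[genes, y.index].to_numpy().T
    clf = make_svc(seed).fit(x, y.to_numpy())
    return _Linear(
        genes=list(genes),
        classes=[str(c) for c in clf.classes_],
        coef=np.atleast_2d(clf.coef_).copy(),
        intercept=np.atleast_1d(clf.intercept_).copy(),
    )


@dataclass
class EnsembleModel:
    """The fitted ETC ensemble: one linear classifier per dictionary entry."""

    dictionary: ModelDictionary
    classifiers: list[_Linear]
    classes: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classifiers:
            raise ValueError("ensemble has no classifiers")
        for entry, clf in zip(self.dictionary.entries, self.classifiers):
            if list(entry) != clf.genes:
                raise ValueError("classifier gene subset does not match its dictionary entry")

    @property
    def signature_genes(self) -> set[str]:
        return self.dictionary.gene_union()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": self.classes,
            "seed": self.seed,
            "cv_accuracy": self.dictionary.cv_accuracy,
            "entries": [
                {
                    "genes": c.genes,
                    "classes": c.classes,
                    "coef": c.coef.tolist(),
                    "intercept": c.intercept.tolist(),
                }
                for c in self.classifiers
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleModel":
        d = json.loads(Path(path).read_text())
        classifiers = [
            _Linear(
                genes=e["genes"],
                classes=e["classes"],
                coef=np.asarray(e["coef"], dtype=float),
                intercept=np.asarray(e["intercept"], dtype=float),
            )
            for e in d["entries"]
        ]
        dictionary = ModelDictionary(
            entries=[c.genes for c in classifiers], cv_accuracy=d.get("cv_accuracy")
        )
        return cls(dictionary=dictionary, classifiers=classifiers, classes=d["classes"], seed=d["seed"])


def plurality_confidence(votes: "dict[str, int] | pd.Series") -> dict:
    """Confidence-scored plurality call from per-class vote counts.

    p1 and p2 are the vote proportions of the two most popular classes;
    confidence = p1/p2 (infinite when p2 = 0).  The call is the most
    popular class when confidence > 3, otherwise "ambiguous" — so an exact
    tie (confidence 1) and a 3:1 margin are both ambiguous.
    """
    counts = pd.Series(votes, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no votes")
    # deterministic order: count descending, class name ascending
    ordered = counts.sort_index().sort_values(ascending=False, kind="stable")
    p1 = float(ordered.iloc[0] / total)
    p2 = float(ordered.iloc[1] / total) if len(ordered) > 1 else 0.0
    confidence = np.inf if p2 == 0 else p1 / p2
    call = str(ordered.index[0]) if confidence > CONFIDENCE_CUTOFF else AMBIGUOUS
    return {
        "call": call,
        "p1": p1,
        "p2": p2,
        "confidence": confidence,
        "n_models_voting": int(total),
    }


def _calls_frame(vote_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample plurality calls from a samples x classes count matrix."""
    rows = [plurality_confidence(vote_counts.loc[s]) for s in vote_counts.index]
    out = pd.DataFrame(rows, index=vote_counts.index)
    out.index.name = "sample_id"
    return out[["call", "p1", "p2", "confidence", "n_models_voting"]]


def crossfit_calls(
    expr: ExpressionMatrix,
    labels,
    dictionary: ModelDictionary,
    n_folds: int = 4,
    seed: int = 0,
    return_folds: bool = False,
):
    """Leak-free in-cohort ETC calls via stratified cross-fitting.

    The labeled (non-ambiguous) samples are split into ``n_folds`` stratified
    folds; every dictionary entry is trained on the other folds and votes
    only on the held-out fold.  Unlabeled samples are voted on by entries
    fitted to all labeled samples.
    """
    lab = as_labels(labels)
    # canonical (sorted) order so folds do not depend on column order
    labeled = sorted(s for s in expr.sample_ids if s in lab.index)
    unlabeled = sorted(s for s in expr.sample_ids if s not in lab.index)
    y = lab.loc[labeled]
    class_counts = y.value_counts()
    if (class_counts < n_folds).any():
        raise ValueError(
            f"classes with fewer samples than folds: "
            f"{class_counts[class_counts < n_folds].to_dict()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    classes = sorted(y.unique())
    votes = pd.DataFrame(0, index=expr.sample_ids, columns=classes, dtype=int)
    fold_of = pd.Series(-1, index=labeled, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(labeled)), y.to_numpy())):
        train = [labeled[i] for i in train_idx]
        test = [labeled[i] for i in test_idx]
        fold_of.loc[test] = fold
        y_train = y.loc[train]
        for entry in dictionary.entries:
            clf = _fit_linear(expr, entry, y_train, seed)
            pred = clf.predict(expr.data.loc[entry, test].to_numpy().T)
            for c in classes:
                votes.loc[test, c] += (pred == c).astype(int)
    if unlabeled:
        final = fit_final(expr, labels, dictionary, seed=seed)
        for clf in final.classifiers:
            pred = clf.predict(expr.data.loc[clf.genes, unlabeled].to_numpy().T)
            for c in classes:
                votes.loc[unlabeled, c] += (pred == c).astype(int)
    calls = _calls_frame(votes)
    if return_folds:
        return calls, fold_of
    return calls


def fit_final(
    expr: ExpressionMatrix, labels, dictionary: ModelDictionary, seed: int = 0
) -> EnsembleModel:
    """Fit every dictionary entry's classifier on all labeled samples."""
    lab = as_labels(labels)
    labeled = [s for s in expr.sample_ids if s in lab.index]
    y = lab.loc[labeled]
    classifiers = [_fit_linear(expr, entry, y, seed) for entry in dictionary.entries]
    return EnsembleModel(
        dictionary=dictionary,
        classifiers=classifiers,
        classes=sorted(y.unique()),
        seed=seed,
    )


def predict(model: EnsembleModel, expr_new: ExpressionMatrix) -> pd.DataFrame:
    """Plurality-vote predictions for a cohort containing all model genes."""
    votes = pd.DataFrame(0, index=expr_new.sample_ids, columns=model.classes, dtype=int)
    for clf in model.classifiers:
        pred = clf.predict(expr_new.data.loc[clf.genes].to_numpy().T)
        for c in model.classes:
            votes.loc[:, c] += (pred == c).astype(int)
    return _calls_frame(votes)


def predict_external(
    model: EnsembleModel,
    expr_new: ExpressionMatrix,
    refit_expr: ExpressionMatrix | None = None,
    refit_labels=None,
) -> pd.DataFrame:
    """Classify an external cohort that may lack some signature genes.

    Entries whose genes are all present use their stored classifier.  An
    entry missing genes is refit on the training cohort restricted to its
    surviving genes (refitting preserves the entry's decision geometry on
    the available features, where zero-imputing standardized inputs would
    bias the linear scores); entries left with fewer than 2 genes abstain.
    The vote denominator is the number of entries actually voting.
    """
    if not expr_new.standardized:
        raise ValueError("external cohort must be standardized within itself")
    present = set(expr_new.gene_ids)
    sig = model.signature_genes
    frac = len(sig & present) / len(sig)
    if frac < 0.5:
        raise ValueError(
            f"only {frac:.0%} of signature genes present; platform too divergent"
        )
    needs_refit = [
        i for i, clf in enumerate(model.classifiers) if not set(clf.genes) <= present
    ]
    if needs_refit and (refit_expr is None or refit_labels is None):
        raise ValueError(
            f"{len(needs_refit)} entries are missing genes; refit_expr/refit_labels required"
        )
    y = None
    if needs_refit:
        lab = as_labels(refit_labels)
        labeled = [s for s in refit_expr.sample_ids if s in lab.index]
        y = lab.loc[labeled]
    votes = pd.DataFrame(0, index=expr_new.sample_ids, columns=model.classes, dtype=int)
    n_dropped = 0
    for i, clf in enumerate(model.classifiers):
        if i in set(needs_refit):
            surviving = [g for g in clf.genes if g in present]
            if len(surviving) < 2:
                n_dropped += 1
                continue
            clf = _fit_linear(refit_expr, surviving, y, model.seed)
        pred = clf.predict(expr_new.data.loc[clf.genes].to_numpy().T)
        for c in model.classes:
            votes.loc[:, c] += (pred == c).astype(int)
    if n_dropped:
        logger.info("predict_external: %d entries abstained (too few genes)", n_dropped)
    if int(votes.sum(axis=1).iloc[0]) == 0:
        raise ValueError("no entries could vote on the external cohort")
    return _calls_frame(votes)


def confidence_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Mean p1 (classification confidence) per predicted class."""
    return (
        calls.groupby("call")
        .agg(n=("p1", "size"), mean_confidence=("p1", "mean"))
        .rename_axis("call")
    )
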