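"""Gene-signature selection and the per-model gene dictionary.

The supervised classifier rests on a signature assembled from one-vs-rest
differential expression plus an optional curated gene list, with the
data-driven portion chosen by recursive feature elimination (RFE) under a
linear SVC.  Signature genes are partitioned into six groups by their
expression pattern across subtypes; each ensemble member then draws half of
every group at random and runs RFE on the union, yielding a dictionary of
gene subsets of varying size.  Dictionary entries must clear a threefold
cross-validation accuracy floor (default 95%).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

from .dbu import AMBIGUOUS, ConsensusCalls
from .io_preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "ModelDictionary",
    "one_vs_rest_de",
    "partition_gene_groups",
    "rfe_select",
    "build_signature",
    "build_model_dictionary",
    "cv_filter_models",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def as_labels(labels: "ConsensusCalls | pd.Series", drop_ambiguous: bool = True) -> pd.Series:
    """Normalize a labels argument to a per-sample Series of class strings."""
    s = labels.labels if isinstance(labels, ConsensusCalls) else labels
    s = s.astype(str)
    if drop_ambiguous:
        s = s[s != AMBIGUOUS]
    return s


def make_svc(seed: int = 0) -> LinearSVC:
    """The ensemble's base learner: one-vs-rest linear SVC, squared hinge, C=1."""
    return LinearSVC(C=1.0, loss="squared_hinge", max_iter=5000, random_state=seed)


def _design(expr: ExpressionMatrix, genes: list[str], samples: list[str]) -> np.ndarray:
    return expr.data.loc[genes, samples].to_numpy().T


@dataclass
class Signature:
    """A classification gene signature with expression-pattern groups.

    ``gene_ids`` is the disjoint union of ``curated_gene_ids`` (supplied by
    the analyst) and ``selected_gene_ids`` (chosen by RFE).  Every gene
    belongs to exactly one of ``n_groups`` expression-pattern groups,
    numbered from 1.
    """

    gene_ids: list[str]
    curated_gene_ids: list[str]
    selected_gene_ids: list[str]
    group_assignment: dict[str, int]

    def __post_init__(self) -> None:
        cur, sel = set(self.curated_gene_ids), set(self.selected_gene_ids)
        if cur & sel:
            raise ValueError(f"curated and selected genes overlap: {sorted(cur & sel)[:5]}")
        if cur | sel != set(self.gene_ids):
            raise ValueError("curated + selected genes do not equal the signature gene list")
        missing = [g for g in self.gene_ids if g not in self.group_assignment]
        if missing:
            raise ValueError(f"genes without a group: {missing[:5]}")

    @property
    def n_groups(self) -> int:
        return len(set(self.group_assignment.values()))

    def genes_in_group(self, group: int) -> list[str]:
        return [g for g in self.gene_ids if self.group_assignment[g] == group]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "curated_gene_ids": self.curated_gene_ids,
            "selected_gene_ids": self.selected_gene_ids,
            "group_assignment": self.group_assignment,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Signature":
        d = json.loads(Path(path).read_text())
        return cls(
            gene_ids=d["gene_ids"],
            curated_gene_ids=d["curated_gene_ids"],
            selected_gene_ids=d["selected_gene_ids"],
            group_assignment={k: int(v) for k, v in d["group_assignment"].items()},
        )


@dataclass
class ModelDictionary:
    """Gene subsets for the ensemble members, with optional CV accuracies."""

    entries: list[list[str]]
    cv_accuracy: list[float] | None = None

    def __post_init__(self) -> None:
        if self.cv_accuracy is not None and len(self.cv_accuracy) != len(self.entries):
            raise ValueError("cv_accuracy length != number of entries")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def entry_sizes(self) -> list[int]:
        return [len(e) for e in self.entries]

    def gene_union(self) -> set[str]:
        return set().union(*map(set, self.entries)) if self.entries else set()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"entries": self.entries, "cv_accuracy": self.cv_accuracy}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelDictionary":
        d = json.loads(Path(path).read_text())
        return cls(entries=d["entries"], cv_accuracy=d.get("cv_accuracy"))


def _welch_ovr(x_in: np.ndarray, x_out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t (group vs rest) per gene with degenerate-case rules.

    Zero pooled standard error with equal means gives t = 0, p = 1; with
    unequal means, t = +/-inf and p = 0.
    """
    n1, n2 = x_in.shape[1], x_out.shape[1]
    m1, m2 = x_in.mean(axis=1), x_out.mean(axis=1)
    v1, v2 = x_in.var(axis=1, ddof=1), x_out.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_se = se2 == 0
    t = np.where(zero_se, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    p = np.where(zero_se, np.where(diff == 0, 1.0, 0.0), p)
    return t, p


def one_vs_rest_de(
    expr: ExpressionMatrix, labels: "ConsensusCalls | pd.Series"
) -> pd.DataFrame:
    """Per-gene one-vs-rest differential expression for every group.

    Ambiguous samples are excluded.  Welch's t is used as the moderated
    two-sample statistic; p-values are Benjamini-Hochberg adjusted across
    genes within each contrast.  Groups with fewer than 3 samples are
    skipped with a warning.
    """
    lab = as_labels(labels)
    samples = [s for s in expr.sample_ids if s in lab.index]
    lab = lab.loc[samples]
    groups = sorted(lab.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for one-vs-rest DE")
    x = expr.data[samples].to_numpy()
    rows = []
    for g in groups:
        in_g = (lab == g).to_numpy()
        if in_g.sum() < 3 or (~in_g).sum() < 3:
            logger.warning("one_vs_rest_de: group %s has < 3 samples; contrast skipped", g)
            continue
        t, p = _welch_ovr(x[:, in_g], x[:, ~in_g])
        adj = bh_adjust(p)
        rows.append(
            pd.DataFrame(
                {"gene": expr.gene_ids, "group": g, "statistic": t, "p": p, "adj_p": adj}
            )
        )
    if not rows:
        raise ValueError("no group had enough samples for a contrast")
    return pd.concat(rows, ignore_index=True)


def partition_gene_groups(
    expr: ExpressionMatrix,
    labels: "ConsensusCalls | pd.Series",
    genes: list[str],
    n_groups: int = 6,
    seed: int = 0,
) -> dict[str, int]:
    """Assign each gene to one of ``n_groups`` expression-pattern groups.

    The feature of a gene is its per-subtype mean profile, z-scored across
    subtypes (so only the *pattern* of differences matters, not the overall
    level); genes are clustered by k-means with many restarts.  Group ids
    run from 1.
    """
    if len(genes) < n_groups:
        raise ValueError(f"cannot form {n_groups} groups from {len(genes)} genes")
    lab = as_labels(labels)
    samples = [s for s in expr.sample_ids if s in lab.index]
    lab = lab.loc[samples]
    sub = expr.data.loc[genes, samples]
    centroids = sub.T.groupby(lab).mean().T  # genes x subtypes
    prof = centroids.to_numpy()
    mean = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (prof - mean) / sd
    km = KMeans(n_clusters=n_groups, n_init=50, random_state=seed).fit(z)
    return {g: int(c) + 1 for g, c in zip(genes, km.labels_)}


def rfe_select(
    expr: ExpressionMatrix,
    labels: "ConsensusCalls | pd.Series",
    candidate_genes: list[str],
    step: int = 5,
    cv: int = 3,
    seed: int = 0,
    n_keep: int | None = None,
) -> list[str]:
    """Recursive feature elimination under a linear SVC.

    At each round the ``step`` genes with the smallest aggregate weight
    magnitude (sum of squared one-vs-rest weights) are removed.  With
    ``n_keep`` None, the cross-validated accuracy is tracked at every size
    and the smallest gene set attaining the maximum accuracy is returned
    (ties go to fewer genes).  With ``n_keep`` set, elimination simply runs
    down to exactly that size.
    """
    if not candidate_genes:
        raise ValueError("empty candidate gene list")
    lab = as_labels(labels)
    samples = [s for s in expr.sample_ids if s in lab.index]
    y = lab.loc[samples].to_numpy()
    current = list(candidate_genes)
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    evaluated: list[tuple[int, float, list[str]]] = []
    while True:
        x = _design(expr, current, samples)
        if n_keep is None:
            acc = float(cross_val_score(make_svc(seed), x, y, cv=skf).mean())
            evaluated.append((len(current), acc, list(current)))
        if n_keep is not None and len(current) <= n_keep:
            break
        if n_keep is None and len(current) <= step:
            break
        clf = make_svc(seed).fit(x, y)
        coef = np.atleast_2d(clf.coef_)
        rank = (coef**2).sum(axis=0)
        floor_size = n_keep if n_keep is not None else step
        n_drop = min(step, len(current) - floor_size)
        drop_idx = np.argsort(rank, kind="stable")[:n_drop]
        current = [g for i, g in enumerate(current) if i not in set(drop_idx.tolist())]
    if n_keep is not None:
        return current
    best_acc = max(acc for _, acc, _ in evaluated)
    best_size = min(size for size, acc, _ in evaluated if acc == best_acc)
    return next(genes for size, acc, genes in evaluated if acc == best_acc and size == best_size)


def build_signature(
    expr: ExpressionMatrix,
    labels: "ConsensusCalls | pd.Series",
    n_select: int = 142,
    curated_genes: list[str] | tuple[str, ...] = (),
    n_groups: int = 6,
    candidate_pool: int | None = None,
    step: int = 5,
    seed: int = 0,
) -> Signature:
    """Assemble the classification signature.

    Candidate genes are ranked by their best BH-adjusted one-vs-rest DE
    p-value; the top ``candidate_pool`` (default 3x the target count) go
    through RFE down to exactly ``n_select`` genes.  Curated genes join the
    signature afterwards, exempt from pruning.  All signature genes are then
    partitioned into expression-pattern groups.
    """
    curated = [g for g in curated_genes]
    missing = [g for g in curated if g not in expr.data.index]
    if missing:
        raise KeyError(f"curated genes absent from the matrix: {missing[:5]}")
    de = one_vs_rest_de(expr, labels)
    ranking = de.groupby("gene")["adj_p"].min().sort_values(kind="stable")
    pool_size = candidate_pool if candidate_pool is not None else min(3 * n_select, expr.n_genes)
    candidates = [g for g in ranking.index[:pool_size] if g not in set(curated)]
    if len(candidates) < n_select:
        raise ValueError(
            f"candidate pool ({len(candidates)}) smaller than n_select ({n_select})"
        )
    selected = rfe_select(expr, labels, candidates, step=step, seed=seed, n_keep=n_select)
    gene_ids = curated + [g for g in selected]
    groups = partition_gene_groups(expr, labels, gene_ids, n_groups=n_groups, seed=seed)
    return Signature(
        gene_ids=gene_ids,
        curated_gene_ids=curated,
        selected_gene_ids=list(selected),
        group_assignment=groups,
    )


def build_model_dictionary(
    expr: ExpressionMatrix,
    labels: "ConsensusCalls | pd.Series",
    signature: Signature,
    n_models: int = 1000,
    step: int = 5,
    cv: int = 3,
    seed: int = 0,
) -> ModelDictionary:
    """Draw the ensemble's gene subsets.

    For each model, half of the genes of every expression-pattern group
    (rounded down) are sampled at random; RFE on the pooled draw keeps the
    smallest subset with maximal cross-validated accuracy.  Reproducible
    from ``seed``.
    """
    groups = sorted(set(signature.group_assignment.values()))
    members = {g: signature.genes_in_group(g) for g in groups}
    empty = [g for g in groups if not members[g]]
    if empty:
        raise ValueError(f"empty signature groups: {empty}")
    ss = np.random.SeedSequence(seed)
    entries: list[list[str]] = []
    for child in ss.spawn(n_models):
        rng = np.random.default_rng(child)
        pool: list[str] = []
        for g in groups:
            half = len(members[g]) // 2
            if half:
                pool.extend(rng.choice(members[g], size=half, replace=False).tolist())
        model_seed = int(child.generate_state(1)[0] % (2**31))
        entries.append(rfe_select(expr, labels, pool, step=step, cv=cv, seed=model_seed))
    return ModelDictionary(entries=entries)


def cv_filter_models(
    dictionary: ModelDictionary,
    expr: ExpressionMatrix,
    labels: "ConsensusCalls | pd.Series",
    folds: int = 3,
    floor: float = 0.95,
    seed: int = 0,
) -> ModelDictionary:
    """Drop dictionary entries below the cross-validation accuracy floor.

    Each entry's mean accuracy over stratified k-fold CV of a linear SVC on
    its genes is computed; survivors carry their accuracy.
    """
    lab = as_labels(labels)
    samples = [s for s in expr.sample_ids if s in lab.index]
    y = lab.loc[samples].to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    kept: list[list[str]] = []
    accs: list[float] = []
    for entry in dictionary.entries:
        x = _design(expr, entry, samples)
        acc = float(cross_val_score(make_svc(seed), x, y, cv=skf).mean())
        if acc >= floor:
            kept.append(entry)
            accs.append(acc)
    if not kept:
        raise ValueError(
            "every dictionary entry fell below the accuracy floor; "
            "lower the floor or revisit the labels"
        )
    n_dropped = len(dictionary) - len(kept)
    if n_dropped:
        logger.info("cv_filter_models: dropped %d of %d entries", n_dropped, len(dictionary))
    return ModelDictionary(entries=kept, cv_accuracy=accs)
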