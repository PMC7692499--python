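"""Density-based UMAP (DBU) consensus clustering.

The algorithm repeats {subsample genes -> UMAP to 2-D -> DBSCAN} many times,
discards iterations whose cluster count disagrees with the consensus count,
aligns cluster labels across iterations by optimal assignment against a
reference iteration, and calls each sample by plurality voting: a sample is
assigned to a group only if at least ``ambiguity_threshold`` (default 70%) of
the retained iterations agree and the most common label is not the DBSCAN
noise label; otherwise it is "ambiguous".

Label 0 is reserved throughout for DBSCAN noise ("Group 0").
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import DBSCAN
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .io_preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DBUParams",
    "IterationLabeling",
    "ConsensusCalls",
    "DBURunInfo",
    "SubclusterResult",
    "run_dbu_iteration",
    "select_eps_knee",
    "filter_iterations",
    "choose_reference",
    "canonicalize_labels",
    "align_iteration_labels",
    "consensus_call",
    "run_dbu",
    "subcluster_group",
    "run_dbu_with_subclustering",
]

AMBIGUOUS = "ambiguous"


@dataclass
class DBUParams:
    """Parameters of the DBU consensus clustering run.

    Defaults suit a glioma cohort of roughly a thousand samples:
    1000 iterations of 1000 random genes, UMAP with 5 neighbors, minimum
    distance 0 and the manhattan metric, DBSCAN with ``min_points`` 100 and
    ``eps`` 1.55 (picked from the elbow of the k-nearest-neighbor distance
    plot).  Set ``eps="auto"`` to re-derive eps per iteration from the knee
    of the sorted k-th-neighbor distance curve, with k = ``min_points``.
    ``min_points`` should be on the order of the smallest expected group.
    """

    n_iterations: int = 1000
    genes_per_iteration: int = 1000
    n_neighbors: int = 5
    min_dist: float = 0.0
    metric: str = "manhattan"
    min_points: int = 100
    eps: float | str = 1.55
    expected_groups: int | str = "auto"
    ambiguity_threshold: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ambiguity_threshold <= 1):
            raise ValueError("ambiguity_threshold must be in (0, 1]")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")
        if isinstance(self.eps, str) and self.eps != "auto":
            raise ValueError("eps must be a positive number or 'auto'")
        if isinstance(self.eps, (int, float)) and self.eps <= 0:
            raise ValueError("eps must be positive")
        if isinstance(self.expected_groups, str) and self.expected_groups != "auto":
            raise ValueError("expected_groups must be an int >= 2 or 'auto'")


@dataclass
class IterationLabeling:
    """Cluster assignment of every sample in one DBU iteration (0 = noise)."""

    iteration_id: int
    sampled_gene_ids: list[str]
    labels: np.ndarray
    sample_ids: list[str]

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.tolist()) - {0})


@dataclass
class ConsensusCalls:
    """Per-sample consensus class, vote fraction and full vote matrix.

    ``calls`` has columns ``consensus_class`` (cluster id as string, or
    "ambiguous"), ``vote_fraction`` (largest non-noise vote share) and
    ``ambiguous``.  ``votes`` holds per-sample vote fractions over cluster
    labels; rows sum to at most 1, the remainder being noise votes (kept in
    column "0").
    """

    calls: pd.DataFrame
    votes: pd.DataFrame
    n_retained_iterations: int

    @property
    def labels(self) -> pd.Series:
        return self.calls["consensus_class"]

    @property
    def sample_ids(self) -> list[str]:
        return self.calls.index.tolist()

    def non_ambiguous(self) -> pd.Series:
        lab = self.labels
        return lab[lab != AMBIGUOUS]


@dataclass
class DBURunInfo:
    n_iterations: int
    n_removed: int
    expected_groups: int
    reference_iteration: int
    n_ambiguous: int
    eps_values: list[float] = field(default_factory=list)


def _umap_embed(x: np.ndarray, params: DBUParams, seed: int) -> np.ndarray:
    import umap  # deferred: numba compilation is slow at import time

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=params.n_neighbors,
        min_dist=params.min_dist,
        metric=params.metric,
        random_state=int(seed) % (2**31),
    )
    return reducer.fit_transform(x)


def select_eps_knee(embedding: np.ndarray, k: int) -> float:
    """DBSCAN eps from the knee of the sorted k-th-neighbor distance curve.

    Both axes are rescaled to [0, 1] and the curve lightly smoothed before
    the point of maximum discrete curvature is located, so the answer does
    not depend on the units of the embedding.
    """
    n = embedding.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k} distances, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, _ = nn.kneighbors(embedding)
    dk = np.sort(dist[:, -1])
    if dk[-1] - dk[0] < 1e-12:  # flat curve: any eps above the plateau works
        return float(dk[-1]) if dk[-1] > 0 else 1e-12
    w = max(5, n // 20)
    smooth = np.convolve(dk, np.ones(w) / w, mode="same")
    y = (smooth - smooth.min()) / (smooth.max() - smooth.min() + 1e-300)
    d1 = np.gradient(y) * n
    d2 = np.gradient(d1) * n
    curvature = d2 / (1.0 + d1**2) ** 1.5
    # ignore the convolution edge artefacts
    i = int(np.argmax(curvature[w:-w])) + w if n > 2 * w else int(np.argmax(curvature))
    return float(max(dk[i], 1e-12))


def run_dbu_iteration(
    expr: ExpressionMatrix, params: DBUParams, iteration_seed: int
) -> IterationLabeling:
    """One DBU iteration: gene subsample -> UMAP -> DBSCAN.

    DBSCAN runs on the 2-D embedding with Euclidean distance; the configured
    metric applies to UMAP's input space.  Noise becomes label 0, clusters
    are numbered from 1.
    """
    if not expr.standardized:
        raise ValueError("DBU expects a standardized expression matrix")
    if params.genes_per_iteration > expr.n_genes:
        raise ValueError(
            f"genes_per_iteration={params.genes_per_iteration} exceeds available genes ({expr.n_genes})"
        )
    rng = np.random.default_rng(iteration_seed)
    gene_idx = rng.choice(expr.n_genes, size=params.genes_per_iteration, replace=False)
    x = expr.values[gene_idx].T  # samples x genes
    embedding = _umap_embed(x, params, iteration_seed)
    eps = params.eps if not isinstance(params.eps, str) else select_eps_knee(embedding, params.min_points)
    raw = DBSCAN(eps=float(eps), min_samples=params.min_points).fit_predict(embedding)
    labels = raw + 1  # noise -1 -> 0, clusters 0.. -> 1..
    return IterationLabeling(
        iteration_id=int(iteration_seed),
        sampled_gene_ids=[expr.gene_ids[i] for i in gene_idx],
        labels=labels.astype(int),
        sample_ids=expr.sample_ids,
    )


def filter_iterations(
    iterations: list[IterationLabeling], expected_groups: int | str = "auto"
) -> tuple[list[IterationLabeling], int]:
    """Drop iterations whose cluster count disagrees with the expected count.

    ``expected_groups="auto"`` resolves to the modal cluster count across
    iterations (ties broken toward the larger count).
    """
    if not iterations:
        raise ValueError("no iterations to filter")
    counts = [it.n_clusters for it in iterations]
    if expected_groups == "auto":
        tally = Counter(counts)
        top = max(tally.values())
        expected = max(k for k, v in tally.items() if v == top)
    else:
        expected = int(expected_groups)
    retained = [it for it in iterations if it.n_clusters == expected]
    n_removed = len(iterations) - len(retained)
    if not retained:
        raise ValueError(f"all iterations removed (none with {expected} clusters)")
    if n_removed:
        logger.info("filter_iterations: removed %d of %d iterations", n_removed, len(iterations))
    return retained, expected


def choose_reference(iterations: list[IterationLabeling]) -> int:
    """Index of the iteration with maximal mean pairwise agreement (ARI)."""
    m = len(iterations)
    if m == 1:
        return 0
    agree = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            a = adjusted_rand_score(iterations[i].labels, iterations[j].labels)
            agree[i, j] = agree[j, i] = a
    return int(np.argmax(agree.sum(axis=1)))


def canonicalize_labels(it: IterationLabeling) -> IterationLabeling:
    """Renumber clusters by order of first appearance; noise stays 0."""
    mapping: dict[int, int] = {0: 0}
    nxt = 1
    for v in it.labels:
        if v != 0 and v not in mapping:
            mapping[v] = nxt
            nxt += 1
    new = np.array([mapping[v] for v in it.labels], dtype=int)
    return replace(it, labels=new)


def _best_permutation(labels: np.ndarray, reference: np.ndarray) -> dict[int, int]:
    """Optimal cluster relabeling (Hungarian on the overlap contingency).

    When several assignments tie on total overlap, the one producing the
    lexicographically smallest aligned label vector is chosen; the candidate
    set — and hence the result — is then invariant to how the iteration's
    clusters happened to be numbered.
    """
    a_ids = sorted(set(labels.tolist()) - {0})
    b_ids = sorted(set(reference.tolist()) - {0})
    overlap = np.zeros((len(a_ids), len(b_ids)))
    for i, a in enumerate(a_ids):
        in_a = labels == a
        for j, b in enumerate(b_ids):
            overlap[i, j] = np.sum(in_a & (reference == b))
    rows, cols = linear_sum_assignment(-overlap)
    best_score = overlap[rows, cols].sum()
    mapping = {a_ids[i]: b_ids[j] for i, j in zip(rows, cols)}
    k = len(a_ids)
    if k == len(b_ids) and k <= 8:
        from itertools import permutations

        tied = [
            perm
            for perm in permutations(range(k))
            if sum(overlap[i, perm[i]] for i in range(k)) == best_score
        ]
        if len(tied) > 1:
            def aligned_vec(perm):
                m = {a_ids[i]: b_ids[perm[i]] for i in range(k)}
                m[0] = 0
                return tuple(m[v] for v in labels)

            best = min(tied, key=aligned_vec)
            mapping = {a_ids[i]: b_ids[best[i]] for i in range(k)}
    return mapping


def align_iteration_labels(
    iterations: list[IterationLabeling], reference: IterationLabeling
) -> list[IterationLabeling]:
    """Permute each iteration's cluster labels to best match the reference.

    The permutation maximizes total sample overlap with the reference
    clusters (optimal assignment).  Noise (0) is never remapped.  Iterations
    whose cluster count differs from the reference's are excluded with a
    warning.
    """
    out = []
    ref_n = reference.n_clusters
    excluded = 0
    for it in iterations:
        if it.n_clusters != ref_n:
            excluded += 1
            continue
        mapping = _best_permutation(it.labels, reference.labels)
        mapping[0] = 0
        out.append(replace(it, labels=np.array([mapping[v] for v in it.labels], dtype=int)))
    if excluded:
        logger.warning("align_iteration_labels: excluded %d iterations with mismatched cluster counts", excluded)
    if not out:
        raise ValueError("no iterations left after alignment")
    return out


def consensus_call(aligned: list[IterationLabeling], threshold: float = 0.70) -> ConsensusCalls:
    """Plurality-vote consensus over aligned iterations.

    A sample gets its top non-noise cluster when (a) that cluster's vote
    fraction is at least ``threshold`` (exactly 70% passes: only *less than*
    the threshold is flagged) and (b) the most common label over all labels
    including noise is not 0; otherwise it is "ambiguous".  The vote
    denominator is the number of retained (aligned) iterations.
    """
    if not aligned:
        raise ValueError("empty iteration list")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    sample_ids = aligned[0].sample_ids
    n = len(sample_ids)
    labels_mat = np.stack([it.labels for it in aligned])  # iterations x samples
    max_label = int(labels_mat.max())
    counts = np.zeros((n, max_label + 1))
    for lab in range(max_label + 1):
        counts[:, lab] = (labels_mat == lab).sum(axis=0)
    fractions = counts / len(aligned)

    cluster_frac = fractions[:, 1:]
    top_cluster = cluster_frac.argmax(axis=1) + 1 if max_label >= 1 else np.zeros(n, dtype=int)
    top_frac = cluster_frac.max(axis=1) if max_label >= 1 else np.zeros(n)
    noise_wins = fractions.argmax(axis=1) == 0
    ambiguous = (top_frac < threshold) | noise_wins

    consensus = np.where(ambiguous, AMBIGUOUS, top_cluster.astype(str))
    calls = pd.DataFrame(
        {
            "consensus_class": consensus,
            "vote_fraction": top_frac,
            "ambiguous": ambiguous,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    votes = pd.DataFrame(
        fractions, index=calls.index, columns=[str(c) for c in range(max_label + 1)]
    )
    return ConsensusCalls(calls=calls, votes=votes, n_retained_iterations=len(aligned))


def _iteration_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_dbu(expr: ExpressionMatrix, params: DBUParams) -> tuple[ConsensusCalls, DBURunInfo]:
    """The full DBU pipeline: iterate, filter, align, vote."""
    seeds = _iteration_seeds(params.seed, params.n_iterations)
    iterations = [run_dbu_iteration(expr, params, s) for s in seeds]
    retained, expected = filter_iterations(iterations, params.expected_groups)
    ref = canonicalize_labels(retained[choose_reference(retained)])
    aligned = align_iteration_labels(retained, ref)
    calls = consensus_call(aligned, params.ambiguity_threshold)
    info = DBURunInfo(
        n_iterations=params.n_iterations,
        n_removed=params.n_iterations - len(retained),
        expected_groups=expected,
        reference_iteration=ref.iteration_id,
        n_ambiguous=int(calls.calls["ambiguous"].sum()),
    )
    return calls, info


@dataclass
class SubclusterResult:
    group: str
    split: bool
    calls: ConsensusCalls
    n_multi_iterations: int


def _subcluster_params(params: DBUParams, n_subset: int, n_total: int, n_genes: int) -> DBUParams:
    """Rescale the density parameters to the subset size.

    ``min_points`` shrinks proportionally (it was set from the size of the
    smallest expected group in the full cohort); the UMAP neighborhood is
    floored at ~10% of the subset so that local graphs on small subsets do
    not fragment a single cluster into clumps.
    """
    return replace(
        params,
        min_points=max(5, round(params.min_points * n_subset / n_total)),
        n_neighbors=max(params.n_neighbors, round(0.1 * n_subset)),
        genes_per_iteration=min(params.genes_per_iteration, n_genes),
    )


def subcluster_group(
    expr: ExpressionMatrix,
    calls: ConsensusCalls,
    group: str,
    params: DBUParams,
) -> SubclusterResult:
    """Probe a consensus group for further substructure by re-running DBU.

    DBSCAN/UMAP density parameters are rescaled to the subset.  Because most
    iterations on a group that genuinely contains two profiles still see one
    cluster, the split decision is not the modal cluster count: the
    iterations that *do* report more than one cluster are aligned and voted
    among themselves, and the split is accepted only when that consensus is
    coherent — at most half the subset ambiguous, and at least two subgroups
    each no smaller than the rescaled ``min_points``.  Otherwise the group
    is left intact (one subgroup, no split).

    Accepted subgroups are labeled ``<group>a``, ``<group>b``, ... in
    decreasing size order.
    """
    group = str(group)
    members = calls.labels.index[calls.labels == group].tolist()
    n_total = len(calls.labels)
    sub_params = _subcluster_params(params, len(members), n_total, expr.n_genes)
    if len(members) < 2 * sub_params.min_points:
        raise ValueError(
            f"group {group!r} has {len(members)} samples; need at least {2 * sub_params.min_points}"
        )
    sub_expr = expr.subset_samples(members)

    seeds = _iteration_seeds(params.seed + 1, params.n_iterations)
    iterations = [run_dbu_iteration(sub_expr, sub_params, s) for s in seeds]
    multi = [it for it in iterations if it.n_clusters >= 2]

    def no_split() -> SubclusterResult:
        unsplit = pd.DataFrame(
            {
                "consensus_class": group,
                "vote_fraction": 1.0,
                "ambiguous": False,
            },
            index=pd.Index(members, name="sample_id"),
        )
        votes = pd.DataFrame({group: 1.0}, index=unsplit.index)
        return SubclusterResult(
            group=group,
            split=False,
            calls=ConsensusCalls(unsplit, votes, len(iterations)),
            n_multi_iterations=len(multi),
        )

    if len(multi) < 2:
        return no_split()
    retained, _ = filter_iterations(multi, "auto")
    if retained[0].n_clusters < 2 or len(retained) < 2:
        return no_split()
    ref = canonicalize_labels(retained[choose_reference(retained)])
    aligned = align_iteration_labels(retained, ref)
    sub_calls = consensus_call(aligned, params.ambiguity_threshold)

    lab = sub_calls.labels
    sizes = lab[lab != AMBIGUOUS].value_counts()
    coherent = (
        (lab == AMBIGUOUS).mean() <= 0.5
        and len(sizes) >= 2
        and (sizes >= sub_params.min_points).sum() >= 2
    )
    if not coherent:
        logger.info("subcluster_group(%s): substructure votes not coherent; keeping group intact", group)
        return no_split()

    # rename subgroups by decreasing size: <group>a, <group>b, ...
    order = sizes.index.tolist()
    rename = {old: f"{group}{chr(ord('a') + i)}" for i, old in enumerate(order)}
    new_calls = sub_calls.calls.copy()
    new_calls["consensus_class"] = new_calls["consensus_class"].map(lambda v: rename.get(v, v))
    votes = sub_calls.votes.rename(columns={k: rename.get(k, k) for k in sub_calls.votes.columns})
    return SubclusterResult(
        group=group,
        split=True,
        calls=ConsensusCalls(new_calls, votes, sub_calls.n_retained_iterations),
        n_multi_iterations=len(multi),
    )


def run_dbu_with_subclustering(
    expr: ExpressionMatrix, params: DBUParams
) -> tuple[pd.Series, ConsensusCalls, dict[str, SubclusterResult]]:
    """Top-level DBU followed by a substructure probe of every group.

    Returns the final per-sample labels (subgroup labels where a split was
    accepted), the top-level consensus, and the per-group subcluster results.
    """
    calls, info = run_dbu(expr, params)
    labels = calls.labels.copy()
    results: dict[str, SubclusterResult] = {}
    for group in sorted(set(labels) - {AMBIGUOUS}):
        n_members = int((labels == group).sum())
        sub_params = _subcluster_params(params, n_members, len(labels), expr.n_genes)
        if n_members < 2 * sub_params.min_points:
            continue
        res = subcluster_group(expr, calls, group, params)
        results[group] = res
        if res.split:
            labels.loc[res.calls.labels.index] = res.calls.labels
    return labels, calls, results
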