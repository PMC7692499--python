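"""Downstream subtype characterization.

Mutation enrichment (one-vs-rest chi-squared with Benjamini-Hochberg
adjustment), survival stratification (Kaplan-Meier, log-rank, Cox hazard
ratios), tumor-purity comparison (one-way ANOVA), and concordance
cross-tabulation against other classification systems.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.optimize import linear_sum_assignment


from .dbu import AMBIGUOUS
from .signature import as_labels, bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "mutation_enrichment",
    "SurvivalSummary",
    "km_logrank",
    "purity_by_group",
    "ConcordanceResult",
    "concordance",
    "chi2_2x2",
]


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction.

    Returns (statistic, p).  A table with a zero margin carries no
    information about association: statistic 0, p 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    n = t.sum()
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if n == 0 or (rows == 0).any() or (cols == 0).any():
        return 0.0, 1.0
    a, b, c, d = t.ravel()
    stat = n * (a * d - b * c) ** 2 / (rows[0] * rows[1] * cols[0] * cols[1])
    return float(stat), float(stats.chi2.sf(stat, df=1))


def mutation_enrichment(
    mutations: pd.DataFrame,
    labels,
    include_ambiguous: bool = False,
) -> pd.DataFrame:
    """One-vs-rest mutation enrichment per gene and group.

    ``mutations`` is a binary gene x sample matrix (1 = mutated).  Genes
    with no mutation in any sample are removed before testing.  For every
    remaining gene and every group, a 2x2 chi-squared (mutated/wild-type x
    in-group/rest, no continuity correction) is computed; p-values are BH
    adjusted across all gene x group tests.  Rows flag small expected
    counts (< 5).
    """
    lab = as_labels(labels, drop_ambiguous=not include_ambiguous)
    shared = [s for s in mutations.columns if s in lab.index]
    if not shared:
        raise ValueError("no shared samples between mutations and labels")
    mut = mutations[shared]
    if not np.isin(mut.to_numpy(), [0, 1]).all():
        raise ValueError("mutation matrix must be binary 0/1")
    lab = lab.loc[shared]
    nonzero = mut.index[mut.sum(axis=1) > 0]
    n_removed = mut.shape[0] - len(nonzero)
    if n_removed:
        logger.info("mutation_enrichment: removed %d genes with no mutations", n_removed)
    mut = mut.loc[nonzero]
    groups = sorted(lab.unique())
    rows = []
    for group in groups:
        in_g = (lab == group).to_numpy()
        for gene in mut.index:
            m = mut.loc[gene].to_numpy().astype(bool)
            table = np.array(
                [
                    [np.sum(m & in_g), np.sum(~m & in_g)],
                    [np.sum(m & ~in_g), np.sum(~m & ~in_g)],
                ]
            )
            stat, p = chi2_2x2(table)
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "mut_in_group": int(table[0, 0]),
                    "wt_in_group": int(table[0, 1]),
                    "mut_rest": int(table[1, 0]),
                    "wt_rest": int(table[1, 1]),
                    "statistic": stat,
                    "p": p,
                    "small_expected": bool((expected < 5).any()),
                }
            )
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass
class SurvivalSummary:
    """Kaplan-Meier curves and tests for a set of groups.

    ``km_curves`` maps group -> DataFrame(time, survival, censored).
    ``hazard_ratios`` holds univariate Cox HRs versus the reference group
    with 95% CIs (NaN where a group had no events).  Median survival is NaN
    when the curve never reaches 0.5 ("not reached").
    """

    km_curves: dict[str, pd.DataFrame]
    medians: dict[str, float]
    logrank_statistic: float
    logrank_p: float
    hazard_ratios: pd.DataFrame
    reference: str


def km_logrank(
    clinical: pd.DataFrame,
    labels,
    reference: str | None = None,
    include_ambiguous: bool = False,
) -> SurvivalSummary:
    """Kaplan-Meier curves, log-rank test and Cox hazard ratios by group."""
    lab = as_labels(labels, drop_ambiguous=not include_ambiguous)
    shared = [s for s in clinical.index if s in lab.index]
    if not shared:
        raise ValueError("no shared samples between clinical table and labels")
    clin = clinical.loc[shared]
    lab = lab.loc[shared]
    groups = sorted(lab.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for survival comparison")
    if reference is None:
        reference = groups[0]
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")

    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    for g in groups:
        m = lab == g
        kmf = KaplanMeierFitter()
        kmf.fit(clin.loc[m.to_numpy(), "survival_time"], clin.loc[m.to_numpy(), "event"])
        sf = kmf.survival_function_
        censor_times = set(
            clin.loc[m.to_numpy()].query("event == 0")["survival_time"].tolist()
        )
        curves[g] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(),
                "survival": sf.iloc[:, 0].to_numpy(),
                "censored": [t in censor_times for t in sf.index],
            }
        )
        med = kmf.median_survival_time_
        medians[g] = float(med) if np.isfinite(med) else np.nan

    lr = multivariate_logrank_test(
        clin["survival_time"], lab.to_numpy(), clin["event"]
    )

    hr_rows = []
    for g in groups:
        if g == reference:
            continue
        m = lab.isin([g, reference]).to_numpy()
        sub = clin.loc[m]
        indicator = (lab.loc[m] == g).astype(int)
        if sub.loc[(indicator == 1).to_numpy(), "event"].sum() == 0:
            logger.warning("km_logrank: group %s has no events; HR not estimable", g)
            hr_rows.append({"group": g, "hr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan, "p": np.nan})
            continue
        df = pd.DataFrame(
            {
                "time": sub["survival_time"].to_numpy(),
                "event": sub["event"].to_numpy(),
                "x": indicator.to_numpy(),
            }
        )
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            hr_rows.append(
                {
                    "group": g,
                    "hr": float(np.exp(cph.params_["x"])),
                    "ci_lower": float(np.exp(cph.confidence_intervals_.iloc[0, 0])),
                    "ci_upper": float(np.exp(cph.confidence_intervals_.iloc[0, 1])),
                    "p": float(cph.summary.loc["x", "p"]),
                }
            )
        except Exception as err:  # non-convergence on degenerate strata
            logger.warning("km_logrank: Cox fit failed for group %s (%s)", g, err)
            hr_rows.append({"group": g, "hr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan, "p": np.nan})

    return SurvivalSummary(
        km_curves=curves,
        medians=medians,
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hazard_ratios=pd.DataFrame(hr_rows),
        reference=reference,
    )


def purity_by_group(purity: pd.Series, labels) -> tuple[pd.DataFrame, float, float]:
    """Median [IQR] purity per group plus a one-way ANOVA across groups.

    Ambiguous samples form their own group.  Groups of fewer than 2 samples
    are summarized but excluded from the ANOVA.  Returns (summary, F, p);
    F and p are NaN when fewer than 2 groups qualify.
    """
    lab = as_labels(labels, drop_ambiguous=False)
    shared = [s for s in purity.index if s in lab.index]
    if not shared:
        raise ValueError("no shared samples between purity and labels")
    pur, lab = purity.loc[shared].astype(float), lab.loc[shared]
    if ((pur < 0) | (pur > 1)).any():
        raise ValueError("purity values must lie in [0, 1]")
    rows = []
    anova_groups = []
    for g in sorted(lab.unique()):
        vals = pur[lab == g]
        rows.append(
            {
                "group": g,
                "n": len(vals),
                "median": float(vals.median()),
                "q1": float(vals.quantile(0.25)),
                "q3": float(vals.quantile(0.75)),
            }
        )
        if len(vals) >= 2:
            anova_groups.append(vals.to_numpy())
    if len(anova_groups) >= 2:
        f_stat, p = stats.f_oneway(*anova_groups)
        f_stat, p = float(f_stat), float(p)
    else:
        f_stat, p = np.nan, np.nan
    return pd.DataFrame(rows), f_stat, p


@dataclass
class ConcordanceResult:
    """Cross-tabulation of two classifications of the same samples."""

    table: pd.DataFrame  # contingency counts, labels_a rows x labels_b cols
    agreement: float  # matched-cell sum / total under the class matching
    matching: dict[str, str]  # label_a -> label_b used for agreement
    composition: list[str]  # human-readable per-class composition lines
    n: int


def concordance(
    calls_a,
    calls_b,
    ambiguous: str = "exclude",
    mapping: dict[str, str] | None = None,
) -> ConcordanceResult:
    """Agreement between two classifications under best class matching.

    Class labels of the two systems need not share a namespace: agreement
    is computed after matching classes one-to-one by optimal assignment on
    the contingency table, which makes the statistic invariant to label
    renaming and symmetric in its arguments.  A semantic ``mapping``
    (label_a -> label_b), when supplied, overrides the automatic matching.
    ``ambiguous`` is "exclude" (drop samples ambiguous in either system) or
    "category" (keep as an ordinary class).
    """
    if ambiguous not in ("exclude", "category"):
        raise ValueError("ambiguous must be 'exclude' or 'category'")
    a = as_labels(calls_a, drop_ambiguous=False)
    b = as_labels(calls_b, drop_ambiguous=False)
    shared = [s for s in a.index if s in b.index]
    if not shared:
        raise ValueError("the two classifications share no samples")
    a, b = a.loc[shared], b.loc[shared]
    if ambiguous == "exclude":
        keep = (a != AMBIGUOUS) & (b != AMBIGUOUS)
        a, b = a[keep], b[keep]
        if a.empty:
            raise ValueError("no non-ambiguous shared samples")
    table = pd.crosstab(a, b)
    if mapping is not None:
        match = dict(mapping)
        missing = [k for k in match if k not in table.index]
        if missing:
            raise ValueError(f"mapping keys not present in first classification: {missing}")
    else:
        counts = table.to_numpy()
        rows, cols = linear_sum_assignment(-counts)
        match = {str(table.index[i]): str(table.columns[j]) for i, j in zip(rows, cols)}
    matched = sum(
        int(table.loc[la, lb]) for la, lb in match.items() if lb in table.columns
    )
    total = int(table.to_numpy().sum())
    composition = []
    for la in table.index:
        row = table.loc[la]
        n_class = int(row.sum())
        for lb in table.columns:
            if row[lb] > 0:
                composition.append(f"{int(row[lb])} of {n_class} in class {la} map to {lb}")
    return ConcordanceResult(
        table=table,
        agreement=matched / total,
        matching=match,
        composition=composition,
        n=total,
    )
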