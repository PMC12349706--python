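"""Cytology statistics: chiasma estimation and focus-count comparisons.

Chiasma numbers per metaphase-I cell are estimated from bivalent shapes:
a ring bivalent (chiasmata on both arms) scores 2, a rod (one arm) scores 1,
a ring annotated as carrying an extra chiasma scores 3 and a univalent pair
scores 0.  The "3 crossovers" case is an annotation supplied in the input
table -- no cytological rule is invented for it.  On simulated cells the
ring=2/rod=1 estimator never exceeds the retained true crossover count,
so its bias can be measured directly.

Focus counts (RAD51, MLH1, MLH1-HEI10) are summarised per genotype and
treatment, with the histogram bins closed as printed:
{0}, [1,2], [3,10], [11,20], [21,50], [51, inf).

Group comparisons follow the study's statistical contract: unpaired t-test
for normal data, Mann-Whitney otherwise, Kruskal-Wallis + Dunn post hoc for
more than two groups, and a two-way ANOVA pass-through for factorial
designs.  Normality screening (D'Agostino-Pearson) is advisory output only;
the test actually applied is always explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .interference import TestResult

FOCI_BIN_LABELS = ("0", "1-2", "3-10", "11-20", "21-50", ">50")
_FOCI_BIN_EDGES = (0, 1, 3, 11, 21, 51)  # left-closed lower edges


@dataclass
class BivalentCell:
    """Observed bivalent configuration of one metaphase-I cell."""

    cell_id: str
    genotype: str
    ring: int = 0
    rod: int = 0
    ring3: int = 0  # rings annotated as carrying 3 chiasmata
    univalent_pairs: int = 0
    true_chiasmata: int | None = None  # retained by the simulator only

    def __post_init__(self):
        counts = (self.ring, self.rod, self.ring3, self.univalent_pairs)
        if any(c < 0 for c in counts):
            raise DataError(f"cell {self.cell_id}: negative shape count")
        if sum(counts) > 5:
            raise DataError(
                f"cell {self.cell_id}: {sum(counts)} bivalent-equivalents "
                "exceed the 5 Arabidopsis chromosomes"
            )

    @property
    def bivalents(self) -> int:
        return self.ring + self.ring3 + self.rod


@dataclass(frozen=True)
class ChiasmaScoring:
    """Chiasmata attributed per bivalent shape."""

    ring: int = 2
    rod: int = 1
    ring3: int = 3
    univalent_pair: int = 0


@dataclass
class FociRecord:
    """Focus count for one nucleus."""

    cell_id: str
    genotype: str
    count: int
    kind: str = "RAD51"
    treatment: str = "untreated"

    def __post_init__(self):
        if self.count < 0:
            raise DataError(f"cell {self.cell_id}: negative focus count")


# ---------------------------------------------------------------------------


def chiasma_count(cell: BivalentCell, scoring: ChiasmaScoring = ChiasmaScoring()) -> int:
    """Chiasma estimate for one cell: weighted sum over bivalent shapes."""
    return (
        cell.ring * scoring.ring
        + cell.rod * scoring.rod
        + cell.ring3 * scoring.ring3
        + cell.univalent_pairs * scoring.univalent_pair
    )


def mean_bivalents(cells: Sequence[BivalentCell]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genotype bivalent mean +/- SD and the cell distribution by count.

    Returns ``(summary, distribution)``: the summary has one row per
    genotype (mean, sd, n); the distribution gives the percentage of cells
    with 0..5 bivalents per genotype.
    """
    if not cells:
        raise DataError("no cells supplied")
    df = pd.DataFrame(
        {"genotype": c.genotype, "bivalents": c.bivalents} for c in cells
    )
    summary = (
        df.groupby("genotype")["bivalents"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="size")
        .reset_index()
    )
    dist = (
        df.groupby("genotype")["bivalents"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=range(6), fill_value=0.0)
        * 100.0
    )
    dist.columns = [f"pct_{k}_bivalents" for k in dist.columns]
    return summary, dist.reset_index()


def mean_chiasmata(
    cells: Sequence[BivalentCell], scoring: ChiasmaScoring = ChiasmaScoring()
) -> pd.DataFrame:
    """Per-genotype mean +/- SD of the per-cell chiasma estimate."""
    if not cells:
        raise DataError("no cells supplied")
    df = pd.DataFrame(
        {"genotype": c.genotype, "chiasmata": chiasma_count(c, scoring)}
        for c in cells
    )
    return (
        df.groupby("genotype")["chiasmata"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="size")
        .reset_index()
    )


def bin_foci(records: Sequence[FociRecord]) -> pd.DataFrame:
    """Percentage of cells per focus-count bin, by kind/genotype/treatment.

    Bins are closed as printed: {0}, [1,2], [3,10], [11,20], [21,50], >50.
    Percentages sum to 100 within each group.
    """
    if not records:
        raise DataError("no focus records supplied")
    df = pd.DataFrame(
        {
            "kind": r.kind,
            "genotype": r.genotype,
            "treatment": r.treatment,
            "count": r.count,
        }
        for r in records
    )
    edges = list(_FOCI_BIN_EDGES) + [np.inf]
    df["bin"] = pd.cut(
        df["count"], bins=edges, labels=FOCI_BIN_LABELS, right=False
    ).astype(str)
    out = (
        df.groupby(["kind", "genotype", "treatment"])["bin"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(FOCI_BIN_LABELS), fill_value=0.0)
        * 100.0
    )
    return out.reset_index()


# ---------------------------------------------------------------------------
# hypothesis tests


def _check_groups(*groups):
    for g in groups:
        if len(g) == 0:
            raise DataError("empty group supplied to a hypothesis test")


def mann_whitney(a, b, exact_limit: int = 400) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when ``len(a) * len(b) <= exact_limit`` and the data
    are tie-free; otherwise the tie-corrected, continuity-corrected normal
    approximation.  Identical constant groups are a degenerate case reported
    with p = 1 rather than an error.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    _check_groups(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(
            statistic=float(len(a) * len(b) / 2.0),
            p_value=1.0,
            method="Mann-Whitney (degenerate: all values identical)",
            degenerate=True,
        )
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (len(a) * len(b) <= exact_limit) and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="Mann-Whitney (exact)" if use_exact
        else "Mann-Whitney (normal approximation, tie/continuity corrected)",
        summaries={"n1": len(a), "n2": len(b)},
    )


def _dunn_pairwise(groups: dict, adjust: str) -> pd.DataFrame:
    """Dunn's post hoc z for each pair, with multiplicity adjustment."""
    from statsmodels.stats.multitest import multipletests

    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # tie correction to the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    sizes, mean_ranks, start = {}, {}, 0
    for k in names:
        size = len(groups[k])
        mean_ranks[k] = ranks[start:start + size].mean()
        sizes[k] = size
        start += size
    rows = []
    for g1, g2 in combinations(names, 2):
        var = (n_total * (n_total + 1) / 12.0 - tie_term) * (
            1.0 / sizes[g1] + 1.0 / sizes[g2]
        )
        # var = 0 when every pooled value is tied: no evidence either way
        z = (mean_ranks[g1] - mean_ranks[g2]) / np.sqrt(var) if var > 0 else 0.0
        rows.append({"group_1": g1, "group_2": g2, "z": z,
                     "p_raw": 2.0 * stats.norm.sf(abs(z))})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_raw"], method=adjust)[1]
    return df


def kruskal_dunn(groups: dict, adjust: str = "holm") -> tuple[TestResult, pd.DataFrame]:
    """Tie-corrected Kruskal-Wallis H plus Dunn's pairwise post hoc table.

    ``adjust`` names the statsmodels multiplicity-adjustment family
    (``holm`` default, ``bonferroni`` etc.); with two groups the procedure
    reduces to a rank-sum comparison.
    """
    if len(groups) < 2:
        raise DataError("at least two groups are required")
    _check_groups(*groups.values())
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        omnibus = TestResult(0.0, 1.0, "Kruskal-Wallis (degenerate)",
                             degenerate=True)
    else:
        h, p = stats.kruskal(*arrays)
        omnibus = TestResult(float(h), float(p), "Kruskal-Wallis",
                             summaries={k: len(v) for k, v in groups.items()})
    return omnibus, _dunn_pairwise(groups, adjust)


def ttest_unpaired(a, b, equal_var: bool = True) -> TestResult:
    """Two-sided unpaired t-test, pooled variance by default (Welch optional)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each group needs at least two observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, "t-test (degenerate: zero variance)",
                              degenerate=True)
        raise DataError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        statistic=float(t),
        p_value=float(p),
        method="unpaired t-test (pooled)" if equal_var else "Welch t-test",
        summaries={"mean1": float(a.mean()), "mean2": float(b.mean()),
                   "n1": len(a), "n2": len(b)},
    )


def normality_check(values, alpha: float = 0.05) -> TestResult:
    """Advisory D'Agostino-Pearson normality screen (never switches tests)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 8:
        return TestResult(np.nan, np.nan,
                          "D'Agostino-Pearson (too few observations)",
                          degenerate=True)
    k2, p = stats.normaltest(values)
    return TestResult(float(k2), float(p), "D'Agostino-Pearson",
                      summaries={"normal_at_alpha": bool(p > alpha)})


def anova_two_way(df: pd.DataFrame, response: str, factor_a: str,
                  factor_b: str) -> pd.DataFrame:
    """Two-way ANOVA with interaction (pass-through utility, statsmodels OLS)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols(
        f"{response} ~ C({factor_a}) * C({factor_b})", data=df
    ).fit()
    return sm.stats.anova_lm(model, typ=2)
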