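"""Tetrad-based estimators of map distance and crossover interference.

Genetic distance per interval follows the Perkins equation,

    X = 100 * (T/2 + 3*NPD) / n   [cM],

which corrects single-interval double crossovers to first order.  The
coefficient of coincidence over the adjacent interval pair is

    CoC = f12 / (f1 * f2),

where ``f1`` (``f2``) is the fraction of tetrads recombinant (tetratype or
NPD) in interval 1 (2) and ``f12`` the fraction recombinant in both;
interference is ``1 - CoC`` (0 = no interference, 1 = complete).  Each
tetrad counts once per interval regardless of ditype: an NPD is not
double-weighted.  An option to weight by crossover number instead is
exposed for sensitivity analysis.

Standard errors come from the multinomial delta method, with a seeded
tetrad-resampling bootstrap as the reference alternative.  Genotype
comparisons use two-sided Z-tests: pooled two-proportion for recombination
frequencies and a difference-of-interference Z with delta-method errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classify import TetradClassCounts, class_by_label
from .errors import DataError, DegenerateTestError, UndefinedCoCError


@dataclass
class DistanceEstimate:
    """Perkins map distance for one interval."""

    distance: float  # cM
    se: float  # cM
    n: int
    t_count: int
    npd_count: int
    interval_index: int = 0
    genotype: str = ""


@dataclass
class CoCEstimate:
    """Coefficient of coincidence and interference for an interval pair.

    ``no_doubles`` flags f12 = 0 with both marginals positive, in which case
    interference is exactly 1 and the delta-method SE degenerates to 0.
    """

    f1: float
    f2: float
    f12: float
    coc: float
    interference: float
    se_interference: float
    n: int
    genotype: str = ""
    no_doubles: bool = False
    se_method: str = "delta"


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    summaries: dict = field(default_factory=dict)
    degenerate: bool = False


# ---------------------------------------------------------------------------


def perkins_distance(
    class_counts: TetradClassCounts, interval_index: int
) -> DistanceEstimate:
    """Perkins map distance (cM) with a multinomial delta-method SE.

    Treating the per-interval (T, NPD, P) counts as multinomial, with
    ``t = T/n`` and ``q = NPD/n``::

        X = 100 (t/2 + 3 q)
        Var(X)/100^2 = [ t(1-t)/4 + 9 q(1-q) - 3 t q ] / n
    """
    n = class_counts.n
    if n == 0:
        raise DataError("cannot estimate a distance from zero tetrads")
    t_count, npd_count = class_counts.t_n_counts(interval_index)
    t, q = t_count / n, npd_count / n
    distance = 100.0 * (t / 2.0 + 3.0 * q)
    var = (t * (1 - t) / 4.0 + 9.0 * q * (1 - q) - 3.0 * t * q) / n
    return DistanceEstimate(
        distance=distance,
        se=100.0 * float(np.sqrt(max(var, 0.0))),
        n=n,
        t_count=t_count,
        npd_count=npd_count,
        interval_index=interval_index,
        genotype=class_counts.genotype,
    )


def recombinant_frequencies(
    class_counts: TetradClassCounts, weight_by_co: bool = False
) -> tuple[float, float, float]:
    """(f1, f2, f12): fractions of tetrads recombinant in I1, I2, and both.

    With ``weight_by_co`` the marginals weight NPDs twice (two crossovers)
    instead of counting tetrads; the default matches the tetrad-frequency
    reading of the CoC and is what all downstream estimates use.
    """
    n = class_counts.n
    if n == 0:
        return (0.0, 0.0, 0.0)
    n11, n10, n01, _ = class_counts.recombinant_table()
    if not weight_by_co:
        return ((n11 + n10) / n, (n11 + n01) / n, n11 / n)
    w1 = w2 = w12 = 0.0
    for label, v in class_counts.counts.items():
        d1, d2 = class_by_label(label).ditypes
        c1 = {"P": 0, "T": 1, "N": 2}[d1]
        c2 = {"P": 0, "T": 1, "N": 2}[d2]
        w1 += v * c1
        w2 += v * c2
        w12 += v * (1 if (c1 and c2) else 0)
    return (w1 / n, w2 / n, w12 / n)


def _coc_delta_se(n11: int, n10: int, n01: int, n00: int) -> float:
    """Delta-method SE of CoC (= SE of interference) from the 2x2 tetrad table."""
    n = n11 + n10 + n01 + n00
    p11, p10, p01 = n11 / n, n10 / n, n01 / n
    f1, f2 = p11 + p10, p11 + p01
    if p11 == 0:
        return 0.0
    g11 = (f1 * f2 - p11 * (f1 + f2)) / (f1 * f2) ** 2
    g10 = -p11 / (f1**2 * f2)
    g01 = -p11 / (f1 * f2**2)
    g = np.array([g11, g10, g01])
    p = np.array([p11, p10, p01])
    var = (np.sum(g**2 * p) - np.sum(g * p) ** 2) / n
    return float(np.sqrt(max(var, 0.0)))


def _coc_bootstrap_se(
    n11: int, n10: int, n01: int, n00: int, n_boot: int, seed: int
) -> float:
    """SE of interference by seeded multinomial resampling of tetrads."""
    n = n11 + n10 + n01 + n00
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, np.array([n11, n10, n01, n00]) / n, size=n_boot)
    b11, b10, b01 = draws[:, 0], draws[:, 1], draws[:, 2]
    f1, f2 = (b11 + b10) / n, (b11 + b01) / n
    ok = (f1 > 0) & (f2 > 0)
    coc = (b11[ok] / n) / (f1[ok] * f2[ok])
    return float(np.std(coc, ddof=1))


def coc_interference(
    class_counts: TetradClassCounts,
    se_method: str = "delta",
    n_boot: int = 2000,
    seed: int = 0,
) -> CoCEstimate:
    """CoC and interference = 1 - CoC for the interval pair.

    Raises :class:`UndefinedCoCError` when either marginal recombinant
    frequency is 0.  ``f12 = 0`` with positive marginals yields interference
    exactly 1 with the ``no_doubles`` flag set (it is an observation, not an
    error: short intervals routinely show no doubles).
    """
    n = class_counts.n
    if n == 0:
        raise DataError("cannot estimate CoC from zero tetrads")
    n11, n10, n01, n00 = class_counts.recombinant_table()
    f1, f2, f12 = recombinant_frequencies(class_counts)
    if f1 == 0 or f2 == 0:
        raise UndefinedCoCError(
            f"CoC undefined for {class_counts.genotype!r}: "
            f"f1={f1}, f2={f2} (n={n})",
            counts=(n11, n10, n01, n00),
        )
    coc = f12 / (f1 * f2)
    if se_method == "delta":
        se = _coc_delta_se(n11, n10, n01, n00)
    elif se_method == "bootstrap":
        se = _coc_bootstrap_se(n11, n10, n01, n00, n_boot, seed)
    else:
        raise DataError(f"unknown se_method {se_method!r}")
    return CoCEstimate(
        f1=f1,
        f2=f2,
        f12=f12,
        coc=coc,
        interference=1.0 - coc,
        se_interference=se,
        n=n,
        genotype=class_counts.genotype,
        no_doubles=(f12 == 0.0),
        se_method=se_method,
    )


# ---------------------------------------------------------------------------
# Z-tests


def ztest_proportions(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Two-proportion Z-test with pooled variance, two-sided.

    Used to compare per-interval recombinant tetrad frequencies between
    genotypes.  Sign convention: positive when group 1 has the higher
    proportion.
    """
    if n1 < 1 or n2 < 1:
        raise DataError("both groups need at least one observation")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise DataError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DegenerateTestError(
            f"pooled proportion is {pooled}; the Z statistic is undefined"
        )
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(
        statistic=float(z),
        p_value=float(p),
        method="two-proportion Z (pooled)",
        summaries={"p1": p1, "p2": p2, "n1": n1, "n2": n2},
    )


def ztest_interference(
    counts_g1: TetradClassCounts,
    counts_g2: TetradClassCounts,
    se_method: str = "delta",
    n_boot: int = 2000,
    seed: int = 0,
) -> TestResult:
    """Z-test on the difference of interference between two genotypes.

    ``z = (I1 - I2) / sqrt(se1^2 + se2^2)`` with delta-method (default) or
    bootstrap SEs; two-sided normal p.  Undefined CoC in either genotype
    propagates as :class:`UndefinedCoCError`.
    """
    e1 = coc_interference(counts_g1, se_method=se_method, n_boot=n_boot, seed=seed)
    e2 = coc_interference(counts_g2, se_method=se_method, n_boot=n_boot,
                          seed=seed + 1)
    se = np.sqrt(e1.se_interference**2 + e2.se_interference**2)
    if se == 0:
        if e1.interference == e2.interference:
            return TestResult(0.0, 1.0, "interference Z", degenerate=True)
        raise DegenerateTestError(
            "both interference SEs are zero but the estimates differ"
        )
    z = (e1.interference - e2.interference) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(
        statistic=float(z),
        p_value=float(p),
        method=f"interference Z ({se_method} SE)",
        summaries={
            "interference_1": e1.interference,
            "interference_2": e2.interference,
            "se_1": e1.se_interference,
            "se_2": e2.se_interference,
            "n1": e1.n,
            "n2": e2.n,
        },
    )


# ---------------------------------------------------------------------------
# per-plant and pooled summaries


@dataclass
class PlantSummary:
    """Per-plant estimates alongside the pooled-count estimate.

    Both are reported because per-plant dots with a mean bar and pooled
    counts answer slightly different questions; plants whose CoC is
    undefined (no recombinants in an interval) are excluded from the
    per-plant interference mean and listed in ``excluded``.
    """

    per_plant: "pandas.DataFrame"
    pooled_distance: tuple[DistanceEstimate, DistanceEstimate]
    pooled_coc: CoCEstimate
    mean_distance: tuple[float, float]
    mean_interference: float
    excluded: list[str]


def per_plant_and_pooled(plants: list[TetradClassCounts]) -> PlantSummary:
    import pandas as pd

    if not plants:
        raise DataError("at least one plant is required")
    rows = []
    excluded = []
    for pc in plants:
        d1 = perkins_distance(pc, 1)
        d2 = perkins_distance(pc, 2)
        row = {
            "plant": pc.plant,
            "genotype": pc.genotype,
            "n": pc.n,
            "distance_i1_cM": d1.distance,
            "distance_i2_cM": d2.distance,
        }
        try:
            est = coc_interference(pc)
            row.update(interference=est.interference, coc=est.coc,
                       no_doubles=est.no_doubles)
        except UndefinedCoCError:
            excluded.append(pc.plant or "<unnamed>")
            row.update(interference=np.nan, coc=np.nan, no_doubles=False)
        rows.append(row)
    df = pd.DataFrame(rows)
    pooled = plants[0]
    for pc in plants[1:]:
        pooled = pooled + pc
    return PlantSummary(
        per_plant=df,
        pooled_distance=(perkins_distance(pooled, 1), perkins_distance(pooled, 2)),
        pooled_coc=coc_interference(pooled),
        mean_distance=(
            float(df["distance_i1_cM"].mean()),
            float(df["distance_i2_cM"].mean()),
        ),
        mean_interference=float(df["interference"].mean(skipna=True)),
        excluded=excluded,
    )
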