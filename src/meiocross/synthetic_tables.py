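"""SYNTHETIC reconstructions of the study's raw-count tables.

The original per-tetrad and per-cell raw counts live in supplementary
spreadsheets that are not redistributed here.  This module builds
*synthetic stand-ins*: integer count tables constructed deterministically
to be consistent with the summary statistics printed in the article text
(per-genotype interference values, mean bivalent/chiasma numbers and focus
counts with their sample sizes).  They exercise the full ingestion and
estimation machinery and pin the published headline numbers as arithmetic
checks, but they are NOT the authors' data: within-group dispersion and
per-plant structure are invented, so only the group-level summaries are
meaningful.

All tables are deterministic (no randomness) so tests and reports are
byte-stable.
"""

from __future__ import annotations

import numpy as np

from .classify import TetradClassCounts
from .cyto import BivalentCell, FociRecord
from .errors import DataError

#: Interference (1 - CoC) per genotype and interval pair, as printed.
PUBLISHED_INTERFERENCE = {
    ("wild-type", "I1bc"): 0.53,
    ("srs2-1", "I1bc"): 0.65,
    ("srs2-3", "I1bc"): 0.63,
    ("wild-type", "I2fg"): 0.80,
    ("srs2-1", "I2fg"): 0.93,
}

#: Assumed interval-pair geometry for the reconstructions: (d1 cM, d2 cM,
#: total tetrads, NPD count in I1, NPD count in I2).  Genetic sizes are
#: plausible values for these FTL interval pairs (I2fg deliberately short);
#: n corresponds to ~10 plants at the reported 400-800 tetrads per plant.
SYNTHETIC_GEOMETRY = {
    "I1bc": (5.7, 10.3, 6000, 1, 3),
    "I2fg": (2.2, 5.4, 6000, 0, 0),
}


def _solve_class_counts(
    d1: float, d2: float, n: int, target_interference: float,
    npd1: int, npd2: int,
) -> dict[str, int]:
    """Integer class counts whose interference matches the target to <0.005.

    Single-interval tetratypes go to classes B/C, NPDs to D/E, and all
    double-recombinant tetrads to the two-strand (T,T) class F; marginal
    tetratype totals are then tuned by a few tetrads so the exact CoC
    arithmetic lands on the printed interference value.
    """
    t1_base = round((d1 * n / 100.0 - 3 * npd1) * 2)
    t2_base = round((d2 * n / 100.0 - 3 * npd2) * 2)

    best = None
    for da in range(-12, 13):
        for db in range(-12, 13):
            t1 = t1_base + da
            t2 = t2_base + db
            f1 = (t1 + npd1) / n
            f2 = (t2 + npd2) / n
            f_target = (1.0 - target_interference) * f1 * f2 * n
            for f_count in {int(np.floor(f_target)), int(np.ceil(f_target))}:
                if not 0 <= f_count <= min(t1, t2):
                    continue
                achieved = 1.0 - (f_count / n) / (f1 * f2)
                err = abs(achieved - target_interference)
                key = (err, abs(da) + abs(db))
                if best is None or key < best[0]:
                    best = (key, t1, t2, f_count)
    (err, _), t1, t2, f_count = best
    if err >= 0.005:
        raise DataError(
            f"could not reconstruct counts for interference {target_interference}"
        )
    counts = {
        "A": n - (t1 + t2 - f_count + npd1 + npd2),
        "B": t1 - f_count,
        "C": t2 - f_count,
        "D": npd1,
        "E": npd2,
        "F": f_count,
    }
    assert all(v >= 0 for v in counts.values())
    assert sum(counts.values()) == n
    return counts


def tetrad_class_tables() -> dict[tuple[str, str], TetradClassCounts]:
    """Synthetic FTL class-count tables, keyed by (genotype, interval pair).

    Pooled counts per genotype; applying the CoC/interference estimator to
    each table reproduces the printed interference values to 2 decimals.
    """
    out = {}
    for (genotype, interval), target in PUBLISHED_INTERFERENCE.items():
        d1, d2, n, npd1, npd2 = SYNTHETIC_GEOMETRY[interval]
        counts = _solve_class_counts(d1, d2, n, target, npd1, npd2)
        out[(genotype, interval)] = TetradClassCounts(
            genotype=genotype, counts=counts
        )
    return out


# ---------------------------------------------------------------------------
# cytology reconstructions


def _spread_cells(genotype: str, n: int, total: int, prefix: str) -> list[tuple]:
    """Deterministic per-cell integers with the exact required sum."""
    base, extra = divmod(total, n)
    return [(f"{prefix}{i}", base + (1 if i < extra else 0)) for i in range(n)]


#: (n cells, summed bivalents) per genotype -- means match the printed
#: 1.34 / 1.05 / 1.04 / 0.84 bivalents per cell after rounding.
_BIVALENT_TOTALS = {
    "zip4": (56, 75),
    "zip4 srs2-1": (42, 44),
    "msh5 srs2-1": (68, 71),
    "zip4 mus81": (77, 65),
}

#: ring-bivalent count distribution per genotype: {rings: cells}; rods fill
#: the remaining chromosomes, so chiasmata/cell = 5 + rings.  Means match
#: the printed 8.8 (wild type) and 9.2 (srs2) chiasmata per cell.
_CHIASMA_RING_DISTRIBUTIONS = {
    "wild-type": {5: 15, 4: 15, 3: 15, 2: 5},
    "srs2-1": {5: 25, 4: 15, 3: 5, 2: 5},
}

#: (n cells, summed foci) per (kind, genotype) -- means match the printed
#: 8.4/9.2 MLH1-HEI10 co-foci and 11.4/12.2/12.3 MLH1 foci.
_FOCI_TOTALS = {
    ("MLH1-HEI10", "wild-type"): (30, 252),
    ("MLH1-HEI10", "srs2-1"): (35, 322),
    ("MLH1", "wild-type"): (50, 570),
    ("MLH1", "srs2-1"): (55, 671),
    ("MLH1", "srs2-3"): (23, 283),
}


def bivalent_cells() -> list[BivalentCell]:
    """Synthetic metaphase-I cells for the zmm-background bivalent counts.

    Class II crossovers in these backgrounds are sparse, so every bivalent
    is represented as a rod; only the per-cell bivalent number is meaningful.
    """
    cells = []
    for genotype, (n, total) in _BIVALENT_TOTALS.items():
        for cell_id, k in _spread_cells(genotype, n, total, "c"):
            cells.append(
                BivalentCell(cell_id=cell_id, genotype=genotype, rod=k,
                             univalent_pairs=5 - k)
            )
    return cells


def chiasma_cells() -> list[BivalentCell]:
    """Synthetic wild-type-like metaphase-I cells for the chiasma estimate."""
    cells = []
    for genotype, dist in _CHIASMA_RING_DISTRIBUTIONS.items():
        i = 0
        for rings, n_cells in dist.items():
            for _ in range(n_cells):
                cells.append(
                    BivalentCell(cell_id=f"c{i}", genotype=genotype,
                                 ring=rings, rod=5 - rings)
                )
                i += 1
    return cells


def foci_records() -> list[FociRecord]:
    """Synthetic per-nucleus Class I focus counts (diakinesis)."""
    records = []
    for (kind, genotype), (n, total) in _FOCI_TOTALS.items():
        for cell_id, k in _spread_cells(genotype, n, total, "n"):
            records.append(
                FociRecord(cell_id=cell_id, genotype=genotype, count=k,
                           kind=kind)
            )
    return records
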