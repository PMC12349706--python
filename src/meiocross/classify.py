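"""Classification of three-marker fluorescent tetrads.

With three linked fluorophores in coupling, a tetrad restricted to either
marker pair is a **parental ditype** (P: two parental spore types twice
each), a **tetratype** (T: all four two-marker genotypes present) or a
**non-parental ditype** (N: two recombinant types twice each).  Jointly over
both intervals, the distinguishable spore-phenotype multisets form exactly
12 classes, labelled A-L.

The canonical table is produced by brute-force enumeration of every
chromatid assignment of 0-2 crossovers per interval under standard exchange
semantics (a crossover cuts the two original chromatids it joins and
rejoins them crosswise, so products follow their strand through each
exchange).  Letters are assigned in a documented order: the no-crossover
class first, then single-crossover classes, then classes whose minimal
configuration needs two crossovers, and so on; see :func:`enumerate_classes`.
The (T,T) ditype pair splits into four distinguishable phenotype subtypes,
one per strand configuration of a double crossover spanning the intervals:
two-strand, four-strand, and the two three-strand flavours (sharing a
fluorophore-carrying or a fluorophore-free chromatid).

Spore order within a tetrad is never meaningful: all logic operates on
multisets.  Tetrads violating 2:2 segregation (aberrant in real FTL
scoring) are flagged into an explicit overflow category, never guessed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Literal, Mapping, Sequence, Union

import numpy as np

from .errors import DataError
from .simulate import Tetrad, TetradSample

Ditype = Literal["P", "T", "N"]

#: Label used for tetrads whose phenotype multiset is not in the canonical
#: table (aberrant segregation); such tetrads are flagged, never dropped.
OVERFLOW_LABEL = "X"

_PAIR_P = (((0, 0), (0, 0), (1, 1), (1, 1)))
_PAIR_N = (((0, 1), (0, 1), (1, 0), (1, 0)))
_PAIR_T = (((0, 0), (0, 1), (1, 0), (1, 1)))


@dataclass(frozen=True)
class TetradClass:
    """One canonical tetrad phenotype class.

    ``multiset`` is the sorted tuple of 3-bit spore codes
    (``4*m1 + 2*m2 + m3``); ``min_crossovers`` is the smallest
    ``(I1, I2)`` crossover configuration that produces it.
    """

    label: str
    ditype_i1: Ditype
    ditype_i2: Ditype
    subtype: str
    multiset: tuple[int, int, int, int]
    min_crossovers: tuple[int, int]

    @property
    def ditypes(self) -> tuple[Ditype, Ditype]:
        return (self.ditype_i1, self.ditype_i2)


def _spore_codes(spores: Iterable[Sequence[int]]) -> tuple[int, ...]:
    return tuple(sorted(4 * s[0] + 2 * s[1] + s[2] for s in spores))


def _pair_ditype(pairs: Sequence[tuple[int, int]]) -> Ditype | None:
    key = tuple(sorted(pairs))
    if key == _PAIR_P:
        return "P"
    if key == _PAIR_N:
        return "N"
    if key == _PAIR_T:
        return "T"
    return None


def _enumerate_multisets() -> dict[tuple[int, ...], tuple[int, int]]:
    """All phenotype multisets reachable with 0-2 crossovers per interval.

    Returns each distinct multiset with the lexicographically smallest
    ``(k1, k2)`` crossover configuration (by total, then by k1) reaching it.
    Exchange semantics: a crossover cuts the two *original* chromatids it
    joins and rejoins them crosswise, so the meiotic product that enters a
    crossover on one of the joined chromatids continues on the partner
    (path-following); transpositions therefore compose at the value level,
    left to right.
    """
    pairings = [(a, b) for a in (0, 1) for b in (2, 3)]
    reached: dict[tuple[int, ...], tuple[int, int]] = {}
    for k1, k2 in sorted(
        itertools.product(range(3), range(3)), key=lambda kk: (sum(kk), kk[0])
    ):
        for as1 in itertools.product(pairings, repeat=k1):
            for as2 in itertools.product(pairings, repeat=k2):
                origins = [0, 1, 2, 3]
                snaps = [tuple(origins)]
                for a, b in as1:
                    origins = [b if o == a else a if o == b else o
                               for o in origins]
                snaps.append(tuple(origins))
                for a, b in as2:
                    origins = [b if o == a else a if o == b else o
                               for o in origins]
                snaps.append(tuple(origins))
                spores = [
                    tuple(int(snap[i] < 2) for snap in snaps) for i in range(4)
                ]
                key = _spore_codes(spores)
                reached.setdefault(key, (k1, k2))
    return reached


@lru_cache(maxsize=1)
def enumerate_classes() -> tuple[TetradClass, ...]:
    """The canonical table of the 12 tetrad classes, letters A-L.

    Ordering rule: ascending minimal total crossover number, then a fixed
    ditype-pair order, then ascending multiset key.  This yields::

        A=(P,P)  B=(T,P)  C=(P,T)              single/no crossover
        D=(N,P)  E=(P,N)                       double within one interval
        F,G,H,I=(T,T)                          double across the intervals
        J=(T,N)  K=(N,T)  L=(N,N)              three+ crossovers

    F/G/H/I are the two-strand, three-strand (shared dark chromatid),
    three-strand (shared fluorescent chromatid) and four-strand phenotypes
    of an across-interval double crossover; the two three-strand classes
    are each other's fluorophore complement.
    """
    reached = _enumerate_multisets()
    pair_rank = {
        ("P", "P"): 0, ("T", "P"): 1, ("P", "T"): 2, ("N", "P"): 3,
        ("P", "N"): 4, ("T", "T"): 5, ("T", "N"): 6, ("N", "T"): 7,
        ("N", "N"): 8,
    }

    def _key(item):
        key, kk = item
        spores = [((c >> 2) & 1, (c >> 1) & 1, c & 1) for c in key]
        d1 = _pair_ditype([(s[0], s[1]) for s in spores])
        d2 = _pair_ditype([(s[1], s[2]) for s in spores])
        return (sum(kk), pair_rank[(d1, d2)], key)

    ordered = sorted(reached.items(), key=_key)
    assert len(ordered) == 12, "canonical enumeration must yield 12 classes"
    letters = "ABCDEFGHIJKL"
    tt_names = iter(
        ["two-strand", "three-strand-dark", "three-strand-fluor", "four-strand"]
    )
    classes = []
    for letter, (key, kk) in zip(letters, ordered):
        spores = [((c >> 2) & 1, (c >> 1) & 1, c & 1) for c in key]
        d1 = _pair_ditype([(s[0], s[1]) for s in spores])
        d2 = _pair_ditype([(s[1], s[2]) for s in spores])
        subtype = next(tt_names) if (d1, d2) == ("T", "T") else "-"
        classes.append(TetradClass(letter, d1, d2, subtype, key, kk))
    return tuple(classes)


@lru_cache(maxsize=1)
def _class_lookup() -> dict[tuple[int, ...], TetradClass]:
    return {c.multiset: c for c in enumerate_classes()}


def class_by_label(label: str) -> TetradClass:
    for c in enumerate_classes():
        if c.label == label:
            return c
    raise DataError(f"unknown tetrad class label {label!r}")


def canonical_ditype_map() -> dict[str, tuple[Ditype, Ditype]]:
    """Letter -> (I1 ditype, I2 ditype) for the canonical table."""
    return {c.label: c.ditypes for c in enumerate_classes()}


# ---------------------------------------------------------------------------
# per-tetrad operations

TetradLike = Union[Tetrad, Sequence[Sequence[int]], np.ndarray]


def _as_spores(tetrad: TetradLike) -> list[tuple[int, int, int]]:
    spores = tetrad.spores if isinstance(tetrad, Tetrad) else tetrad
    out = [tuple(int(x) for x in s) for s in spores]
    if len(out) != 4 or any(len(s) != 3 for s in out):
        raise DataError("a tetrad must consist of 4 spores x 3 fluorophores")
    return out


def interval_ditype(tetrad: TetradLike, interval_index: int) -> Ditype:
    """Ditype (P/T/N) of a tetrad restricted to one interval's marker pair.

    ``interval_index`` is 1 (markers 1-2) or 2 (markers 2-3).  Raises
    :class:`DataError` for aberrant tetrads, mirroring FTL scoring practice
    of discarding them.
    """
    if interval_index not in (1, 2):
        raise DataError(f"interval_index must be 1 or 2, got {interval_index}")
    spores = _as_spores(tetrad)
    for m in (interval_index - 1, interval_index):
        if sum(s[m] for s in spores) != 2:
            raise DataError(
                f"tetrad {spores} violates 2:2 segregation at marker {m + 1}"
            )
    pairs = [(s[interval_index - 1], s[interval_index]) for s in spores]
    dt = _pair_ditype(pairs)
    if dt is None:
        raise DataError(f"unclassifiable genotype multiset for tetrad {spores}")
    return dt


def classify_tetrad(tetrad: TetradLike) -> TetradClass:
    """Canonical class of a tetrad's phenotype multiset.

    Multisets absent from the canonical table (aberrant segregation) are
    returned as an overflow class labelled :data:`OVERFLOW_LABEL`.
    """
    spores = _as_spores(tetrad)
    key = _spore_codes(spores)
    cls = _class_lookup().get(key)
    if cls is None:
        return TetradClass(OVERFLOW_LABEL, None, None, "overflow", key, (-1, -1))
    return cls


def classify_sample(sample: TetradSample | np.ndarray) -> np.ndarray:
    """Vectorised classification: array of class letters, one per tetrad."""
    spores = sample.spores if isinstance(sample, TetradSample) else np.asarray(sample)
    codes = spores[:, :, 0] * 4 + spores[:, :, 1] * 2 + spores[:, :, 2]
    codes = np.sort(codes, axis=1)
    packed = codes @ np.array([1, 8, 64, 512])
    table = np.full(8 * 512, -1, dtype=np.int8)
    classes = enumerate_classes()
    for i, c in enumerate(classes):
        m = c.multiset
        table[m[0] + 8 * m[1] + 64 * m[2] + 512 * m[3]] = i
    idx = table[packed]
    letters = np.array([c.label for c in classes] + [OVERFLOW_LABEL])
    return letters[idx]  # idx == -1 picks the trailing overflow label


# ---------------------------------------------------------------------------
# tabulation


@dataclass
class TetradClassCounts:
    """Counts of tetrads per canonical class for one genotype (or plant).

    ``n`` is the number of classified tetrads (flagged tetrads excluded but
    reported via ``flagged``); ``counts`` maps letters A-L to counts.
    """

    genotype: str
    counts: dict[str, int]
    plant: str | None = None
    flagged: int = 0

    def __post_init__(self):
        canonical = {c.label for c in enumerate_classes()}
        unknown = set(self.counts) - canonical
        if unknown:
            raise DataError(f"unknown class labels {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise DataError("class counts must be non-negative")
        self.counts = {c.label: int(self.counts.get(c.label, 0))
                       for c in enumerate_classes()}

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def t_n_counts(self, interval_index: int) -> tuple[int, int]:
        """(tetratype, NPD) counts for one interval, via the canonical table."""
        t = sum(
            v for k, v in self.counts.items()
            if class_by_label(k).ditypes[interval_index - 1] == "T"
        )
        npd = sum(
            v for k, v in self.counts.items()
            if class_by_label(k).ditypes[interval_index - 1] == "N"
        )
        return t, npd

    def recombinant_table(self) -> tuple[int, int, int, int]:
        """Tetrad counts (both, I1 only, I2 only, neither) recombinant (T or N)."""
        n11 = n10 = n01 = n00 = 0
        for k, v in self.counts.items():
            r1, r2 = (d != "P" for d in class_by_label(k).ditypes)
            if r1 and r2:
                n11 += v
            elif r1:
                n10 += v
            elif r2:
                n01 += v
            else:
                n00 += v
        return n11, n10, n01, n00

    @classmethod
    def from_totals(cls, genotype, counts, plant=None, flagged=0):
        return cls(genotype=genotype, counts=dict(counts), plant=plant,
                   flagged=flagged)

    def __add__(self, other: "TetradClassCounts") -> "TetradClassCounts":
        merged = {
            k: self.counts[k] + other.counts[k] for k in self.counts
        }
        return TetradClassCounts(
            genotype=self.genotype, counts=merged, plant=None,
            flagged=self.flagged + other.flagged,
        )


def tabulate(
    tetrads: TetradSample | Iterable[TetradLike],
    genotype: str = "unknown",
    plant: str | None = None,
) -> TetradClassCounts:
    """Count tetrads per class; aberrant tetrads are flagged, not dropped silently."""
    if isinstance(tetrads, (TetradSample, np.ndarray)):
        labels = classify_sample(tetrads)
    else:
        labels = np.array([classify_tetrad(t).label for t in tetrads]) \
            if tetrads else np.empty(0, dtype="<U1")
    uniq, cnt = np.unique(labels, return_counts=True) if labels.size else ((), ())
    counts = dict(zip(uniq, (int(c) for c in cnt)))
    flagged = counts.pop(OVERFLOW_LABEL, 0)
    return TetradClassCounts(genotype=genotype, counts=counts, plant=plant,
                             flagged=flagged)
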