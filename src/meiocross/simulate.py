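"""Forward simulator of two-pathway meiotic crossovers.

The model follows the standard two-pathway picture of plant meiosis:

* **Class I** crossovers (ZMM pathway, MLH1/HEI10-marked) interfere with one
  another.  They are placed by a *stationary gamma renewal process* on the
  genetic axis of the bivalent: inter-event distances are
  ``Gamma(shape=nu, mean=1/rate1)``; ``nu = 1`` is the Poisson (no
  interference) special case and larger ``nu`` produces more even spacing.
  Stationarity is obtained by drawing the first event from the equilibrium
  (length-biased residual) distribution, so interval position on the
  bivalent is irrelevant.
* **Class II** crossovers (MUS81-dependent) do not interfere: a homogeneous
  Poisson process, superposed independently on the Class I process.

Each crossover joins one chromatid of each homolog (no chromatid
interference: the four non-sister pairings are equiprobable and independent
across events).  With the default total rate of 2 crossovers per bivalent
per Morgan, the expected recombinant-spore fraction across a small interval
equals its map length, because a single crossover recombines 2 of the 4
chromatids.

Coordinates are Morgans internally; interfaces take centimorgans via
:class:`~meiocross.markers.IntervalPairMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ParameterError
from .markers import IntervalPairMap

Pathway = Literal["class1", "class2"]

#: Parental spore phenotypes: markers in coupling, so one parent carries all
#: three fluorophores and the other none.
_PARENTAL_SPORES = np.array(
    [[1, 1, 1], [1, 1, 1], [0, 0, 0], [0, 0, 0]], dtype=np.uint8
)


@dataclass(frozen=True)
class PathwayParams:
    """Parameters of the two-pathway crossover model.

    ``nu`` is the gamma shape of Class I inter-event distances
    (dimensionless; 1 = no interference).  ``frac_class2`` is the fraction of
    the expected crossover number contributed by the non-interfering Class II
    pathway.  ``total_rate`` is the expected number of crossovers per
    bivalent per Morgan; the default of 2 makes recombinant-spore fractions
    match map distance.

    Defaults emulate a wild-type-like Arabidopsis meiosis: strong Class I
    interference (``nu = 8``) and roughly 15% of crossovers from Class II.
    """

    nu: float = 8.0
    frac_class2: float = 0.15
    total_rate: float = 2.0

    def __post_init__(self):
        if not self.nu > 0:
            raise ParameterError(f"gamma shape nu must be > 0, got {self.nu}")
        if not 0.0 <= self.frac_class2 <= 1.0:
            raise ParameterError(
                f"frac_class2 must lie in [0, 1], got {self.frac_class2}"
            )
        if self.total_rate < 0:
            raise ParameterError(f"total_rate must be >= 0, got {self.total_rate}")

    @property
    def rate1(self) -> float:
        """Expected Class I crossovers per Morgan."""
        return (1.0 - self.frac_class2) * self.total_rate

    @property
    def rate2(self) -> float:
        """Expected Class II crossovers per Morgan."""
        return self.frac_class2 * self.total_rate


@dataclass
class CrossoverEvent:
    """One crossover on the bivalent.

    ``chromatids`` holds one chromatid index from each sister pair
    ({0,1} x {2,3}) once assigned; ``None`` before assignment.
    """

    position: float  # Morgans from the left end of the bivalent
    pathway: Pathway
    chromatids: tuple[int, int] | None = None


@dataclass
class Tetrad:
    """Four spores, each a presence/absence vector over the three fluorophores."""

    spores: tuple[tuple[int, int, int], ...]
    provenance: list[CrossoverEvent] | None = None

    def __post_init__(self):
        if len(self.spores) != 4 or any(len(s) != 3 for s in self.spores):
            raise ParameterError("a tetrad has 4 spores of 3 fluorophore states")

    def segregates_2to2(self) -> bool:
        """True when each fluorophore is present in exactly 2 of 4 spores."""
        return all(sum(s[m] for s in self.spores) == 2 for m in range(3))


@dataclass
class TetradSample:
    """A reproducible sample of simulated tetrads.

    ``spores`` is the dense ``(n, 4, 3)`` uint8 phenotype array;
    ``class1_counts``/``class2_counts`` retain the true number of crossovers
    per pathway on the bivalent of each meiosis (the in-silico analogue of an
    MLH1/HEI10 focus count for Class I).
    """

    spores: np.ndarray
    map: IntervalPairMap
    params: PathwayParams
    seed: int
    class1_counts: np.ndarray
    class2_counts: np.ndarray

    def __len__(self) -> int:
        return self.spores.shape[0]

    @property
    def tetrads(self) -> list[Tetrad]:
        """Materialise :class:`Tetrad` objects (use the array for bulk work)."""
        return [
            Tetrad(tuple(tuple(int(x) for x in spore) for spore in t))
            for t in self.spores
        ]


# ---------------------------------------------------------------------------
# crossover placement


def place_class1_crossovers(
    span_morgans: float, nu: float, rate1: float, rng: np.random.Generator
) -> np.ndarray:
    """Positions of interfering (Class I) crossovers on ``[0, span)``.

    Stationary gamma renewal process: the first inter-event distance is drawn
    from the equilibrium (length-biased residual) distribution of the
    ``Gamma(shape=nu, mean=1/rate1)`` inter-event law, subsequent gaps from
    the law itself.  The expected count over a span ``S`` is ``rate1 * S``.

    The equilibrium draw uses the length-biasing identity: a length-biased
    ``Gamma(nu, scale)`` interval is ``Gamma(nu + 1, scale)``, and the
    residual is a Uniform(0,1) fraction of it.
    """
    if not span_morgans > 0:
        raise ParameterError(f"span must be positive, got {span_morgans}")
    if not nu > 0:
        raise ParameterError(f"gamma shape nu must be > 0, got {nu}")
    if rate1 < 0:
        raise ParameterError(f"rate1 must be >= 0, got {rate1}")
    if rate1 == 0:
        return np.empty(0)
    scale = 1.0 / (nu * rate1)
    positions = []
    x = rng.uniform() * rng.gamma(nu + 1.0, scale)
    while x < span_morgans:
        positions.append(x)
        x += rng.gamma(nu, scale)
    return np.asarray(positions)


def place_class2_crossovers(
    span_morgans: float, rate2: float, rng: np.random.Generator
) -> np.ndarray:
    """Positions of non-interfering (Class II) crossovers: homogeneous Poisson."""
    if span_morgans < 0:
        raise ParameterError(f"span must be >= 0, got {span_morgans}")
    if rate2 < 0:
        raise ParameterError(f"rate2 must be >= 0, got {rate2}")
    if rate2 == 0 or span_morgans == 0:
        return np.empty(0)
    k = rng.poisson(rate2 * span_morgans)
    return np.sort(rng.uniform(0.0, span_morgans, size=k))


def assign_chromatids(
    events: Sequence[CrossoverEvent], rng: np.random.Generator
) -> list[CrossoverEvent]:
    """Assign chromatids to events: no chromatid interference.

    Each event independently receives one chromatid uniformly from each
    sister pair, so the four non-sister pairings are equiprobable.
    """
    out = []
    for ev in events:
        top = int(rng.integers(0, 2))
        bottom = int(rng.integers(2, 4))
        out.append(CrossoverEvent(ev.position, ev.pathway, (top, bottom)))
    return out


# ---------------------------------------------------------------------------
# tetrad formation


def _origins_at(
    events: Sequence[CrossoverEvent], position: float
) -> list[int]:
    """Parental-chromatid origin of each meiotic product at ``position``.

    A crossover cuts the two *original* chromatids it joins and rejoins
    them crosswise, so the product that starts at the left end of chromatid
    ``c`` follows ``c`` until a crossover involves the chromatid it is
    currently on, then continues on the partner.  Composing the strand
    transpositions left to right at the value level implements exactly this
    path-following.  Events exactly at ``position`` do not affect it
    (half-open interval convention).
    """
    origins = [0, 1, 2, 3]
    for ev in sorted(events, key=lambda e: e.position):
        if ev.position >= position:
            break
        a, b = ev.chromatids
        origins = [b if o == a else a if o == b else o for o in origins]
    return origins


def generate_tetrad(
    imap: IntervalPairMap, params: PathwayParams, rng: np.random.Generator
) -> Tetrad:
    """Simulate one meiosis on the marked bivalent and return its tetrad.

    A chromatid's phenotype at a marker is the parental origin of the strand
    at that position; markers are in coupling, so origin in the
    fluorophore-carrying homolog (chromatids 0,1) means presence.  2:2
    segregation holds by construction because origins form a permutation.
    """
    span = imap.span_morgans
    evs = [
        CrossoverEvent(float(x), "class1")
        for x in place_class1_crossovers(span, params.nu, params.rate1, rng)
    ] + [
        CrossoverEvent(float(x), "class2")
        for x in place_class2_crossovers(span, params.rate2, rng)
    ]
    evs = assign_chromatids(evs, rng)
    evs.sort(key=lambda e: e.position)
    spores = []
    per_marker = [_origins_at(evs, p) for p in imap.marker_positions_morgans]
    for strand in range(4):
        spores.append(tuple(int(o[strand] < 2) for o in per_marker))
    return Tetrad(tuple(spores), provenance=evs)


def simulate_sample(
    n: int, imap: IntervalPairMap, params: PathwayParams, seed: int
) -> TetradSample:
    """Simulate ``n`` independent tetrads, deterministically under ``seed``.

    This is a batched implementation of the same generative process as
    :func:`generate_tetrad` (vectorised crossover placement, then
    left-to-right strand-exchange bookkeeping per marker).
    """
    if n < 1:
        raise ParameterError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    span = imap.span_morgans
    markers = imap.marker_positions_morgans

    # --- Class I: stationary gamma renewal, one column of gaps at a time
    parts_t: list[np.ndarray] = []
    parts_x: list[np.ndarray] = []
    if params.rate1 > 0:
        scale = 1.0 / (params.nu * params.rate1)
        cur = rng.uniform(size=n) * rng.gamma(params.nu + 1.0, scale, size=n)
        idx = np.nonzero(cur < span)[0]
        while idx.size:
            parts_t.append(idx)
            parts_x.append(cur[idx].copy())
            cur[idx] += rng.gamma(params.nu, scale, size=idx.size)
            idx = idx[cur[idx] < span]
    c1_t = np.concatenate(parts_t) if parts_t else np.empty(0, dtype=np.int64)
    c1_x = np.concatenate(parts_x) if parts_x else np.empty(0)

    # --- Class II: homogeneous Poisson
    if params.rate2 > 0:
        k2 = rng.poisson(params.rate2 * span, size=n)
        c2_t = np.repeat(np.arange(n), k2)
        c2_x = rng.uniform(0.0, span, size=int(k2.sum()))
    else:
        k2 = np.zeros(n, dtype=np.int64)
        c2_t = np.empty(0, dtype=np.int64)
        c2_x = np.empty(0)

    ev_t = np.concatenate([c1_t, c2_t])
    ev_x = np.concatenate([c1_x, c2_x])
    m = ev_t.size
    class1_counts = np.bincount(c1_t, minlength=n).astype(np.int64)
    class2_counts = k2.astype(np.int64)

    spores = np.broadcast_to(_PARENTAL_SPORES, (n, 4, 3)).copy()
    if m:
        # chromatid assignment: one strand from each sister pair, uniform
        ev_a = rng.integers(0, 2, size=m)
        ev_b = rng.integers(2, 4, size=m)
        order = np.lexsort((ev_x, ev_t))
        ev_t, ev_x = ev_t[order], ev_x[order]
        ev_a, ev_b = ev_a[order], ev_b[order]
        counts = np.bincount(ev_t, minlength=n)
        offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
        rank = np.arange(m) - np.repeat(offsets, counts)
        kmax = int(counts.max())
        pos_p = np.full((n, kmax), np.inf)
        a_p = np.zeros((n, kmax), dtype=np.int64)
        b_p = np.zeros((n, kmax), dtype=np.int64)
        pos_p[ev_t, rank] = ev_x
        a_p[ev_t, rank] = ev_a
        b_p[ev_t, rank] = ev_b

        rows_all = np.arange(n)
        for j, mpos in enumerate(markers):
            # slots[r, c] = meiotic product currently carrying parental
            # chromatid c; swapping slots of the two parental chromatids a
            # crossover joins implements the cut-and-rejoin (path-following)
            # semantics at the value level.
            slots = np.tile(np.arange(4, dtype=np.int8), (n, 1))
            rows = rows_all
            for k in range(kmax):
                rows = rows[pos_p[rows, k] < mpos]
                if rows.size == 0:
                    break
                a = a_p[rows, k]
                b = b_p[rows, k]
                tmp = slots[rows, a].copy()
                slots[rows, a] = slots[rows, b]
                slots[rows, b] = tmp
            # fluorophore present on the products carrying chromatids 0, 1
            allele = np.zeros((n, 4), dtype=np.uint8)
            np.put_along_axis(allele, slots[:, :2].astype(np.int64), 1, axis=1)
            spores[:, :, j] = allele

    return TetradSample(
        spores=spores,
        map=imap,
        params=params,
        seed=seed,
        class1_counts=class1_counts,
        class2_counts=class2_counts,
    )


# ---------------------------------------------------------------------------
# cytology simulators


def simulate_metaphase_cells(
    n_cells: int,
    per_arm_expected_co: float | Sequence[float],
    rng: np.random.Generator,
    genotype: str = "simulated",
):
    """Simulate metaphase-I cells: 5 bivalents, Poisson crossovers per arm.

    A bivalent is observed as a *ring* when both arms carry at least one
    crossover, a *rod* when exactly one does, and resolves into a univalent
    pair when neither does.  The true total crossover count per cell is
    retained so the ring=2/rod=1 chiasma estimator can be assessed against
    truth.
    """
    from .cyto import BivalentCell  # local import to avoid a cycle

    rates = np.asarray(per_arm_expected_co, dtype=float)
    if rates.ndim == 0:
        rates = np.full((5, 2), float(rates))
    elif rates.shape != (5, 2):
        rates = rates.reshape(5, 2)
    if (rates < 0).any():
        raise ParameterError("per-arm expected crossover counts must be >= 0")
    cells = []
    for i in range(n_cells):
        arm_cos = rng.poisson(rates)
        has = arm_cos > 0
        ring = int((has.sum(axis=1) == 2).sum())
        rod = int((has.sum(axis=1) == 1).sum())
        univ = 5 - ring - rod
        cells.append(
            BivalentCell(
                cell_id=f"cell{i}",
                genotype=genotype,
                ring=ring,
                rod=rod,
                ring3=0,
                univalent_pairs=univ,
                true_chiasmata=int(arm_cos.sum()),
            )
        )
    return cells


_FOCI_FAMILIES = ("poisson", "negative_binomial", "zero_inflated_poisson")


def simulate_foci(n_cells: int, family: str, params: dict, seed: int) -> np.ndarray:
    """Simulate per-nucleus focus counts from a named count family.

    ``poisson`` takes ``mean``; ``negative_binomial`` takes ``mean`` and
    ``dispersion`` (gamma-Poisson, variance = mean + mean^2/dispersion);
    ``zero_inflated_poisson`` takes ``pi`` (zero-inflation mass) and ``lam``.
    """
    if family not in _FOCI_FAMILIES:
        raise ParameterError(
            f"unknown count family {family!r}; choose from {_FOCI_FAMILIES}"
        )
    rng = np.random.default_rng(seed)
    if n_cells == 0:
        return np.empty(0, dtype=np.int64)
    if n_cells < 0:
        raise ParameterError("n_cells must be >= 0")
    if family == "poisson":
        return rng.poisson(params["mean"], size=n_cells)
    if family == "negative_binomial":
        mean, k = params["mean"], params["dispersion"]
        p = k / (k + mean)
        return rng.negative_binomial(k, p, size=n_cells)
    pi, lam = params["pi"], params["lam"]
    zeros = rng.uniform(size=n_cells) < pi
    counts = rng.poisson(lam, size=n_cells)
    counts[zeros] = 0
    return counts
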