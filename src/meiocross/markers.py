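"""Marker layout for a three-marker fluorescent-tagged-line (FTL) interval pair.

Three linked pollen-expressed fluorophore transgenes define two adjacent
genetic intervals (I1 between markers 1 and 2, I2 between markers 2 and 3).
Genetic lengths are given in centimorgans at the interface; internally all
positions are carried in Morgans.  Intervals are half-open ``[left, right)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError


@dataclass(frozen=True)
class IntervalPairMap:
    """Three ordered markers and the genetic lengths between/around them.

    Parameters
    ----------
    marker_names :
        Labels of the three fluorophores, left to right along the chromosome.
    d1, d2 :
        Genetic lengths (cM) of interval I1 (markers 1-2) and I2 (markers 2-3).
    flank_left, flank_right :
        Genetic lengths (cM) of the bivalent outside the marker triplet.  The
        crossover placement process is stationary, so flanks do not change the
        statistics inside the intervals; they default to 0.
    """

    marker_names: tuple[str, str, str] = ("m1", "m2", "m3")
    d1: float = 10.0
    d2: float = 10.0
    flank_left: float = 0.0
    flank_right: float = 0.0

    def __post_init__(self):
        if len(self.marker_names) != 3:
            raise ParameterError("exactly three ordered markers are required")
        if not (self.d1 > 0 and self.d2 > 0):
            raise ParameterError("interval lengths d1, d2 must be positive (cM)")
        if self.flank_left < 0 or self.flank_right < 0:
            raise ParameterError("flank lengths must be non-negative (cM)")

    @property
    def span_morgans(self) -> float:
        """Total simulated bivalent length in Morgans."""
        return (self.flank_left + self.d1 + self.d2 + self.flank_right) / 100.0

    @property
    def marker_positions_morgans(self) -> tuple[float, float, float]:
        """Positions of the three markers along the bivalent, in Morgans."""
        left = self.flank_left / 100.0
        return (left, left + self.d1 / 100.0, left + (self.d1 + self.d2) / 100.0)
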