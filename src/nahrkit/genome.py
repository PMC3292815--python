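"""Genomic intervals and coordinate bookkeeping.

Intervals are stored 0-based half-open (the BED convention) and rendered
1-based inclusive as ``chrN:start-end``, the convention of genome browsers
and of the breakpoint coordinates this toolkit reports.

A zero-width interval (``start == end``) is legal: it marks a breakpoint
localized exactly between two bases, e.g. a crossover flanked by two
immediately adjacent diagnostic sites.  Its 1-based rendering has
``end = start - 1``; the parser accepts that form and round-trips it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: Chromosome sizes of the NCBI36/hg18 human assembly for the two
#: chromosomes involved in the recurrent t(4;18).  Shipped as constants so
#: derivative-chromosome arithmetic needs no genome download.
HG18_CHROM_LENGTHS = {
    "chr4": 191_273_063,
    "chr18": 76_117_153,
}

#: hg18 coordinates of the two sequenced t(4;18) breakpoint junctions
#: (carriers 18q-146C and 18q-82C), on each derivative chromosome's two
#: parental coordinate systems.
JUNCTION_BREAKPOINTS = {
    "18q-146C": {"chr4": "chr4:183974152-183974212",
                 "chr18": "chr18:69144350-69144410"},
    "18q-82C": {"chr4": "chr4:183974285-183974380",
                "chr18": "chr18:69144483-69144578"},
}

_INTERVAL_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A genomic interval, 0-based half-open internally."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end < start in {self.chrom}:{self.start}-{self.end} (0-based)")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        """Midpoint on the 1-based inclusive scale: (start_1 + end_1) / 2."""
        return ((self.start + 1) + self.end) / 2.0

    def render(self) -> str:
        """1-based inclusive ``chrom:start-end`` string."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def contains_boundary(self, pos: int) -> bool:
        """True if the inter-base boundary at 0-based offset ``pos`` lies
        inside (or on the edge of) this interval.  Boundary ``pos`` sits
        between bases ``pos - 1`` and ``pos``."""
        return self.start <= pos <= self.end

    @classmethod
    def parse(cls, text: str) -> "GenomeInterval":
        m = _INTERVAL_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse interval {text!r}; "
                             "expected chrom:start-end (1-based inclusive)")
        chrom, s1, e1 = m.group(1), int(m.group(2)), int(m.group(3))
        if s1 < 1:
            raise ValueError(f"1-based start must be >= 1 in {text!r}")
        if e1 < s1 - 1:
            raise ValueError(f"end < start in {text!r}")
        return cls(chrom, s1 - 1, e1)


def render_interval(iv: GenomeInterval) -> str:
    return iv.render()


def parse_interval(text: str) -> GenomeInterval:
    return GenomeInterval.parse(text)
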