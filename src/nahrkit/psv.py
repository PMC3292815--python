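"""Paralogous sequence variants (PSVs): the diagnostic-site ladder.

A PSV is a fixed difference between two paralogous copies - a base
substitution or an indel run - usable as a chromosome-specific marker when
reading a breakpoint junction.  Side "18" is sequence ``a`` of the
alignment and side "4" is sequence ``b``, following the t(4;18) use case,
but nothing here is specific to those chromosomes.

Substitution PSVs sitting within ``min_gap_distance`` alignment columns of
a gap run are flagged low-confidence: columns adjacent to gaps are
unstable across co-optimal alignments, so they are excluded from junction
resolution by default.  Columns involving ``N`` are likewise flagged.
An indel run is one marker, not one per column: a junction either carries
the inserted segment or it does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import PairwiseAlignment


@dataclass(frozen=True)
class PSV:
    """One diagnostic difference between the two paralogs.

    ``pos_18`` / ``pos_4`` are 0-based positions in each paralog; the
    inserted-side-absent position of an indel is ``None``, with
    ``anchor_18`` / ``anchor_4`` always giving a usable coordinate (for an
    absent side, the position before which the insertion sits).
    """

    column: int
    kind: str  # "substitution" | "indel"
    pos_18: int | None
    pos_4: int | None
    base_18: str
    base_4: str
    anchor_18: int = -1
    anchor_4: int = -1
    indel_length: int = 0
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if self.base_18 == self.base_4:
                raise ValueError("substitution PSV with equal alleles")
            if self.pos_18 is None or self.pos_4 is None:
                raise ValueError("substitution PSV must have both positions")
        elif self.kind == "indel":
            if (self.pos_18 is None) == (self.pos_4 is None):
                raise ValueError("indel PSV must have exactly one absent position")
            if self.indel_length <= 0:
                raise ValueError("indel PSV needs indel_length > 0")
        else:
            raise ValueError(f"unknown PSV kind {self.kind!r}")

    def span_18(self) -> tuple[int, int]:
        """Footprint on the 18 side, 0-based half-open (zero-width for the
        absent side of an indel)."""
        if self.kind == "substitution":
            return (self.pos_18, self.pos_18 + 1)
        if self.pos_18 is not None:
            return (self.pos_18, self.pos_18 + self.indel_length)
        return (self.anchor_18, self.anchor_18)

    def span_4(self) -> tuple[int, int]:
        if self.kind == "substitution":
            return (self.pos_4, self.pos_4 + 1)
        if self.pos_4 is not None:
            return (self.pos_4, self.pos_4 + self.indel_length)
        return (self.anchor_4, self.anchor_4)


@dataclass(frozen=True)
class PSVLadder:
    """Ordered ladder of PSVs between two paralogs."""

    psvs: tuple
    source: tuple
    filter_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = [p.column for p in self.psvs]
        if cols != sorted(cols) or len(set(cols)) != len(cols):
            raise ValueError("PSVs must be sorted by unique column")

    def __len__(self) -> int:
        return len(self.psvs)

    def __iter__(self):
        return iter(self.psvs)

    @property
    def informative(self) -> tuple:
        """Markers usable for junction resolution (not low-confidence)."""
        return tuple(p for p in self.psvs if not p.low_confidence)


def _runs(mask: np.ndarray):
    edges = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    return zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1))


def call_psvs(aln: PairwiseAlignment, min_gap_distance: int = 5) -> PSVLadder:
    """Derive the diagnostic-site ladder from a paralog alignment.

    Every mismatched column yields a substitution PSV; every maximal gap
    run on one side yields a single indel PSV.  See the module docstring
    for the low-confidence flag.
    """
    ia, ib = aln.idx_a, aln.idx_b
    aa = np.frombuffer(aln.aligned_a.encode("ascii"), dtype="S1")
    bb = np.frombuffer(aln.aligned_b.encode("ascii"), dtype="S1")
    gap_a = ia < 0
    gap_b = ib < 0
    gap_any = gap_a | gap_b

    # distance (in columns) from each column to the nearest gap column
    gap_cols = np.flatnonzero(gap_any)
    if gap_cols.size:
        pos = np.arange(aln.n_columns)
        right = np.searchsorted(gap_cols, pos)
        d_next = np.where(right < gap_cols.size,
                          gap_cols[np.clip(right, 0, gap_cols.size - 1)] - pos,
                          np.iinfo(np.int64).max)
        d_prev = np.where(right > 0,
                          pos - gap_cols[np.clip(right - 1, 0, None)],
                          np.iinfo(np.int64).max)
        gap_dist = np.minimum(d_next, d_prev)
    else:
        gap_dist = np.full(aln.n_columns, np.iinfo(np.int64).max)

    psvs = []
    both = ~gap_any
    mismatch = both & (aa != bb)
    for c in np.flatnonzero(mismatch):
        c = int(c)
        ca = aa[c].decode()
        cb = bb[c].decode()
        lowconf = bool(gap_dist[c] <= min_gap_distance) or "N" in (ca, cb)
        psvs.append(PSV(column=c, kind="substitution",
                        pos_18=int(ia[c]), pos_4=int(ib[c]),
                        base_18=ca, base_4=cb,
                        anchor_18=int(ia[c]), anchor_4=int(ib[c]),
                        low_confidence=lowconf))

    n_a = len(aln.seq_a)
    n_b = len(aln.seq_b)
    for st, en in _runs(gap_a):  # insertion carried by side 4
        st, en = int(st), int(en)
        anchor_18 = int(ia[:st][ia[:st] >= 0].max()) + 1 if (ia[:st] >= 0).any() else 0
        anchor_18 = min(anchor_18, n_a)
        psvs.append(PSV(column=st, kind="indel",
                        pos_18=None, pos_4=int(ib[st]),
                        base_18="", base_4=aln.seq_b[int(ib[st]):int(ib[st]) + en - st],
                        anchor_18=anchor_18, anchor_4=int(ib[st]),
                        indel_length=en - st))
    for st, en in _runs(gap_b):  # insertion carried by side 18
        st, en = int(st), int(en)
        anchor_4 = int(ib[:st][ib[:st] >= 0].max()) + 1 if (ib[:st] >= 0).any() else 0
        anchor_4 = min(anchor_4, n_b)
        psvs.append(PSV(column=st, kind="indel",
                        pos_18=int(ia[st]), pos_4=None,
                        base_18=aln.seq_a[int(ia[st]):int(ia[st]) + en - st], base_4="",
                        anchor_18=int(ia[st]), anchor_4=anchor_4,
                        indel_length=en - st))

    psvs.sort(key=lambda p: p.column)
    return PSVLadder(psvs=tuple(psvs), source=(aln.id_a, aln.id_b),
                     filter_params={"min_gap_distance": min_gap_distance})


def ladder_density(ladder: PSVLadder, region: tuple[int, int],
                   informative_only: bool = True) -> float:
    """Markers per kb of alignment columns over ``region`` (half-open).

    The expected crossover ambiguity-interval width is ~ 2 / density (in
    the same per-bp units), by size-biased sampling of marker gaps.
    """
    lo, hi = region
    if hi <= lo:
        raise ValueError("empty region")
    pool = ladder.informative if informative_only else ladder.psvs
    count = sum(1 for p in pool if lo <= p.column < hi)
    return 1000.0 * count / (hi - lo)
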