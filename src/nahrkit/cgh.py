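"""Single-changepoint segmentation of array-CGH log2-ratio probe tracks.

A deliberately transparent stand-in for commercial aberration callers:
each track is modelled as two constant-mean segments, the cut minimizing
the two-segment sum of squared errors, which is the maximum-likelihood
changepoint under Gaussian noise.  Each simulated arm of an unbalanced
translocation harbours exactly one event, so multi-segment calling (CBS,
HMMs) is out of scope.

Classification defaults sit midway between 0 and the diploid single-copy
expectations: a heterozygous loss gives log2(1/2) = -1.0, a single-copy
gain log2(3/2) = +0.585.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeInterval


@dataclass
class ProbeTrack:
    """Per-probe log2 ratios at strictly increasing 1-based positions."""

    chrom: str
    positions: np.ndarray
    log2: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.log2 = np.asarray(self.log2, dtype=np.float64)
        if self.positions.shape != self.log2.shape:
            raise ValueError("positions and log2 must have equal length")
        if len(self.positions) < 8:
            raise ValueError("need >= 8 probes")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("probe positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SegmentCall:
    """A single-changepoint call.

    ``breakpoint_interval`` spans the two probes straddling the cut
    (inclusive of both probe positions); it is None for neutral calls.
    ``delta_sse`` is the SSE improvement of the two-segment model over the
    one-segment fit.
    """

    chrom: str
    cut_index: int | None
    breakpoint_interval: GenomeInterval | None
    mean_left: float
    mean_right: float
    state: str  # loss | gain | neutral
    delta_sse: float


def _sse_split(y: np.ndarray, min_side: int):
    """Best two-segment SSE cut via prefix sums.  Returns (cut, sse_best,
    sse_flat); ``cut`` = number of probes in the left segment."""
    n = len(y)
    s = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))
    cuts = np.arange(min_side, n - min_side + 1)
    nl = cuts.astype(float)
    nr = n - nl
    sse_l = s2[cuts] - s[cuts] ** 2 / nl
    sse_r = (s2[n] - s2[cuts]) - (s[n] - s[cuts]) ** 2 / nr
    tot = sse_l + sse_r
    k = int(np.argmin(tot))
    sse_flat = float(s2[n] - s[n] ** 2 / n)
    return int(cuts[k]), float(tot[k]), sse_flat


def segment(track: ProbeTrack, min_delta: float = 0.4,
            loss_max: float = -0.5, gain_min: float = 0.3,
            min_side: int = 4) -> SegmentCall:
    """Call the best single changepoint of a probe track.

    The cut minimizing the two-segment SSE is chosen (earliest cut on
    ties); if the segment means differ by less than ``min_delta`` the
    track is called neutral with no breakpoint.  The altered side (larger
    absolute mean) is classified loss if its mean < ``loss_max``, gain if
    > ``gain_min``, else the call is neutral.
    """
    y = track.log2
    if len(y) < 2 * min_side:
        raise ValueError(f"need >= {min_side} probes on each side")
    cut, sse_best, sse_flat = _sse_split(y, min_side)
    mean_l = float(y[:cut].mean())
    mean_r = float(y[cut:].mean())
    delta_sse = sse_flat - sse_best

    state = "neutral"
    if abs(mean_l - mean_r) >= min_delta:
        altered = mean_l if abs(mean_l) >= abs(mean_r) else mean_r
        if altered < loss_max:
            state = "loss"
        elif altered > gain_min:
            state = "gain"
    if state == "neutral":
        return SegmentCall(chrom=track.chrom, cut_index=None,
                           breakpoint_interval=None, mean_left=mean_l,
                           mean_right=mean_r, state="neutral",
                           delta_sse=delta_sse)
    iv = GenomeInterval(track.chrom,
                        int(track.positions[cut - 1]) - 1,
                        int(track.positions[cut]))
    return SegmentCall(chrom=track.chrom, cut_index=cut,
                       breakpoint_interval=iv, mean_left=mean_l,
                       mean_right=mean_r, state=state, delta_sse=delta_sse)


def breakpoint_concordance(call_a: SegmentCall, call_b: SegmentCall,
                           tol: float | None = None) -> bool:
    """True iff two calls place their breakpoints within ``tol`` bp
    (midpoint to midpoint).  Default tol = twice the probe spacing implied
    by call_a's straddling-probe interval."""
    if call_a.chrom != call_b.chrom:
        raise ValueError("chromosome mismatch")
    if call_a.breakpoint_interval is None or call_b.breakpoint_interval is None:
        raise ValueError("both calls must have a breakpoint")
    if tol is None:
        tol = 2.0 * (call_a.breakpoint_interval.width - 1)
    return abs(call_a.breakpoint_interval.midpoint
               - call_b.breakpoint_interval.midpoint) <= tol
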