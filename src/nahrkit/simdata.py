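"""Synthetic data with the statistical structure of the t(4;18) loci.

Generates every input the pipeline consumes - paralogous repeat elements,
tandem-repeat allele pairs, NAHR junction clones, array-CGH probe tracks
and population genotype tables - together with machine-readable ground
truth, so parameter-recovery tests can compare inferred quantities to
known answers.

The model: one i.i.d.-uniform ACGT ancestor accumulates substitutions
independently on each descendant paralog at rate ``target_divergence / 2``
per site (so pairwise divergence ~ target; multiple-hit corrections are
negligible at the ~8% divergence of the HERV-H substrates and are
ignored).  Optional indels follow a per-site event rate with geometric
lengths.  Flanks are freshly sampled unrelated sequence, which guarantees
junction alignments anchor uniquely outside the repeat.

All randomness flows from one integer seed through named generator
streams; there is no global state, and equal seeds give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .align import DEFAULT_SCORING, PairwiseAlignment, global_align
from .cgh import ProbeTrack
from .genome import GenomeInterval
from .psv import PSVLadder, call_psvs

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# stream tags keeping the per-operation generators independent
_S_PARALOGS, _S_ALLELES, _S_JUNCTION, _S_TRACK, _S_GENOTYPES = range(5)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the simulator.

    Defaults mirror the t(4;18) substrates: a 5.7-kb repeat element pair at
    ~92% identity (divergence 0.08), a 61-bp tandem unit in 2 vs 4 copies
    (the 122-bp length polymorphism), 100-bp probe spacing, and diploid
    single-copy step means of -1.0 (loss) and +0.585 = log2(3/2) (gain).
    """

    ancestor_length: int = 5700
    target_divergence: float = 0.08
    indel_rate: float = 0.002
    indel_length_geometric_p: float = 0.5
    repeat_unit_length: int = 61
    copies_allele_A: int = 2
    copies_allele_B: int = 4
    flank_length: int = 2000
    probe_spacing: int = 100
    probe_noise_sd: float = 0.25
    loss_mean: float = -1.0
    gain_mean: float = 0.585
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ancestor_length", "repeat_unit_length", "copies_allele_A",
                     "copies_allele_B", "flank_length", "probe_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.target_divergence < 0.5):
            raise ValueError("target_divergence must be in [0, 0.5): higher "
                             "divergence breaks the paralogy assumption")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        if not (0.0 < self.indel_length_geometric_p <= 1.0):
            raise ValueError("indel_length_geometric_p must be in (0, 1]")
        if self.probe_noise_sd < 0:
            raise ValueError("probe_noise_sd must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset."""

    seed: int
    realized_divergence: float | None = None
    crossover_column: int | None = None
    crossover_pos_18: int | None = None  # junction keeps 18-bases [0, this)
    crossover_pos_4: int | None = None   # junction keeps 4-bases [this, end)
    interval_18: GenomeInterval | None = None
    interval_4: GenomeInterval | None = None
    repeat_copies: dict | None = None
    cgh_breakpoint_index: int | None = None  # last probe left of the step

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("interval_18", "interval_4"):
            iv = getattr(self, key)
            d[key] = iv.render() if iv is not None else None
        return d


@dataclass
class RepeatPair:
    """Two paralogous repeat elements with unrelated unique flanks."""

    paralog_18: str
    paralog_4: str
    flank_18: str
    flank_4: str
    truth: SimTruth
    chrom_18: str = "chr18"
    chrom_4: str = "chr4"
    #: exact substitution ledger (positions in ancestor coordinates where
    #: the paralogs differ); None when indels scrambled the coordinates
    substituted_sites: tuple | None = None

    @cached_property
    def alignment(self) -> PairwiseAlignment:
        return global_align(self.paralog_18, self.paralog_4, DEFAULT_SCORING,
                            id_a=self.chrom_18, id_b=self.chrom_4)

    @cached_property
    def ladder(self) -> PSVLadder:
        return call_psvs(self.alignment)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(codes: np.ndarray, rng: np.random.Generator, rate: float) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(len(codes)) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    out[mask] = (out[mask] + shift) % 4
    return out


def _apply_indels(seq: str, rng: np.random.Generator, rate: float,
                  geom_p: float) -> str:
    if rate <= 0:
        return seq
    n = len(seq)
    sites = np.flatnonzero(rng.random(n) < rate)
    if sites.size == 0:
        return seq
    lengths = rng.geometric(geom_p, size=sites.size)
    is_del = rng.random(sites.size) < 0.5
    ins_codes = [_random_codes(rng, int(l)) for l in lengths]
    out = seq
    for pos, length, deletion, ins in sorted(
            zip(sites.tolist(), lengths.tolist(), is_del.tolist(), ins_codes),
            reverse=True):
        if deletion:
            out = out[:pos] + out[pos + length:]
        else:
            out = out[:pos] + _codes_to_str(ins) + out[pos:]
    return out


def make_paralogs(config: SimConfig) -> RepeatPair:
    """Simulate a paralog pair descended from one ancestor.

    Substitutions are placed independently on each copy at rate
    ``target_divergence / 2``; indels (if any) follow afterwards, per
    copy.  Flanks are independent random sequence.  The substitution
    ledger is exact in ancestor coordinates when ``indel_rate == 0``.
    """
    rng = _rng(config.seed, _S_PARALOGS)
    anc = _random_codes(rng, config.ancestor_length)
    half = config.target_divergence / 2.0
    c18 = _mutate(anc, rng, half)
    c4 = _mutate(anc, rng, half)
    diff = c18 != c4
    realized = float(diff.mean())
    p18 = _apply_indels(_codes_to_str(c18), rng, config.indel_rate / 2.0,
                        config.indel_length_geometric_p)
    p4 = _apply_indels(_codes_to_str(c4), rng, config.indel_rate / 2.0,
                       config.indel_length_geometric_p)
    flank_18 = _codes_to_str(_random_codes(rng, config.flank_length))
    flank_4 = _codes_to_str(_random_codes(rng, config.flank_length))
    ledger = tuple(int(i) for i in np.flatnonzero(diff)) \
        if config.indel_rate == 0 else None
    truth = SimTruth(seed=config.seed, realized_divergence=realized)
    return RepeatPair(paralog_18=p18, paralog_4=p4, flank_18=flank_18,
                      flank_4=flank_4, truth=truth, substituted_sites=ledger)


def make_allele_pair(config: SimConfig, base: str,
                     locus: int | None = None) -> tuple[str, str]:
    """Build a tandem-repeat length-polymorphic allele pair.

    A single repeat unit of ``repeat_unit_length`` bp is sampled once and
    inserted as ``copies_allele_A`` exact tandem copies into allele A and
    ``copies_allele_B`` copies into allele B at the same locus (default:
    the midpoint of ``base``); the alleles are otherwise identical.  With
    the defaults (61-bp unit, 2 vs 4 copies) the alleles differ by a
    122-bp duplication.
    """
    base = base.upper()
    if locus is None:
        locus = len(base) // 2
    if not (0 <= locus <= len(base)):
        raise ValueError("locus outside base sequence")
    max_copies = max(config.copies_allele_A, config.copies_allele_B)
    if config.repeat_unit_length * max_copies > len(base):
        raise ValueError("repeat array longer than the base sequence")
    rng = _rng(config.seed, _S_ALLELES)
    unit = _codes_to_str(_random_codes(rng, config.repeat_unit_length))
    allele_a = base[:locus] + unit * config.copies_allele_A + base[locus:]
    allele_b = base[:locus] + unit * config.copies_allele_B + base[locus:]
    return allele_a, allele_b


def make_junction(pair: RepeatPair, crossover_column="random",
                  seed: int | None = None) -> tuple[str, SimTruth]:
    """Form a junction clone by a single crossover inside the repeat.

    ``crossover_column`` is an alignment column ``c`` of the paralog
    alignment: the junction keeps every 18-base aligned before ``c`` and
    every 4-base from ``c`` on, wrapped in the chr18 and chr4 flanks.
    ``"random"`` samples ``c`` uniformly between the first and last
    informative marker (the resolvable regime), avoiding columns inside
    indel-marker footprints.

    Truth records the crossover projections in both paralog coordinate
    systems and the ambiguity interval between the nearest flanking
    informative markers (the same open-interval convention the resolver
    reports); the intervals are None when no marker flanks the crossover
    on one side.
    """
    aln = pair.alignment
    ladder = pair.ladder
    markers = ladder.informative
    ncols = aln.n_columns

    if isinstance(crossover_column, str) and crossover_column == "random":
        if len(markers) < 2:
            raise ValueError("random crossover needs >= 2 informative markers")
        rng = _rng(pair.truth.seed if seed is None else seed, _S_JUNCTION)
        lo = markers[0].column + 1
        hi = markers[-1].column  # inclusive
        forbidden = set()
        for m in markers:
            if m.kind == "indel":
                forbidden.update(range(m.column + 1, m.column + m.indel_length))
        choices = [c for c in range(lo, hi + 1) if c not in forbidden]
        c = int(rng.choice(np.array(choices)))
    else:
        c = int(crossover_column)
        if not (0 <= c <= ncols):
            raise ValueError("crossover column outside the repeat alignment; "
                             "a crossover in the flank would not be NAHR "
                             "within the element")

    i18 = int((aln.idx_a[:c] >= 0).sum())
    j4 = int((aln.idx_b[:c] >= 0).sum())
    junction = pair.flank_18 + pair.paralog_18[:i18] + pair.paralog_4[j4:] \
        + pair.flank_4

    left = [m for m in markers if m.column < c]
    right = [m for m in markers if m.column >= c]
    iv18 = iv4 = None
    if left and right:
        lp, rp = left[-1], right[0]
        iv18 = GenomeInterval(pair.chrom_18, lp.span_18()[1], rp.span_18()[0])
        iv4 = GenomeInterval(pair.chrom_4, lp.span_4()[1], rp.span_4()[0])
    truth = dataclasses.replace(pair.truth, crossover_column=c,
                                crossover_pos_18=i18, crossover_pos_4=j4,
                                interval_18=iv18, interval_4=iv4)
    return junction, truth


def make_probe_track(chrom_length: int, breakpoint: int, kind: str,
                     config: SimConfig,
                     chrom: str = "chr18") -> tuple[ProbeTrack, SimTruth]:
    """Simulate an array-CGH probe track with one copy-number step.

    Probes sit every ``probe_spacing`` bp; probes past ``breakpoint`` take
    mean ``loss_mean`` or ``gain_mean`` (by ``kind``), the rest mean 0,
    with Gaussian noise of sd ``probe_noise_sd``.  Truth records the index
    of the last probe on the neutral side.
    """
    if kind not in ("loss", "gain"):
        raise ValueError(f"kind must be 'loss' or 'gain', got {kind!r}")
    if not (0 < breakpoint < chrom_length):
        raise ValueError("breakpoint must lie within the chromosome")
    positions = np.arange(config.probe_spacing, chrom_length + 1,
                          config.probe_spacing, dtype=np.int64)
    altered = positions > breakpoint
    n_left = int((~altered).sum())
    n_right = int(altered.sum())
    if n_left < 4 or n_right < 4:
        raise ValueError("need >= 4 probes on each side of the breakpoint")
    step = config.loss_mean if kind == "loss" else config.gain_mean
    means = np.where(altered, step, 0.0)
    rng = _rng(config.seed, _S_TRACK)
    log2 = means + rng.normal(0.0, config.probe_noise_sd, size=len(positions))
    track = ProbeTrack(chrom=chrom, positions=positions, log2=log2)
    truth = SimTruth(seed=config.seed, cgh_breakpoint_index=n_left - 1)
    return track, truth


def make_genotypes(pop_specs: list[tuple[str, int, float]],
                   seed: int = 0) -> pd.DataFrame:
    """Draw a biallelic genotype table: each individual draws two alleles
    independently Bernoulli(freq_A).  Columns: population, individual,
    allele1, allele2."""
    rng = _rng(seed, _S_GENOTYPES)
    rows = []
    for name, n, freq_a in pop_specs:
        if not (0.0 <= freq_a <= 1.0):
            raise ValueError(f"freq_A out of [0, 1] for population {name}")
        draws = rng.random((n, 2)) < freq_a
        for i in range(n):
            rows.append((name, f"{name}_{i + 1:04d}",
                         "A" if draws[i, 0] else "B",
                         "A" if draws[i, 1] else "B"))
    return pd.DataFrame(rows, columns=["population", "individual",
                                       "allele1", "allele2"])
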