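"""Tandem-repeat allele structure, in-silico PCR typing, and population
allele-frequency summaries.

The 4q repeat element carries a 61-bp tandem unit in two copies (allele A)
or four copies (allele B); the extra two units are a 122-bp length
polymorphism typed by a short PCR spanning the array (326-bp vs 446-bp
products).  This module finds such arrays with a transparent
period-detection scan, measures allele length differences from the global
alignment, predicts PCR product sizes, classifies alleles by band size,
and summarizes population allele counts with a chi-square homogeneity
test (Monte-Carlo p-value for sparse tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .align import DEFAULT_SCORING, ScoringScheme, global_align, percent_identity
from .genome import GenomeInterval
from .junction import revcomp

ALLELE_LABELS = ("A", "B")

#: Product sizes of the allele-typing PCR: 326 bp for the 2-copy (A)
#: allele, 446 bp for the 4-copy (B) allele.
EXPECTED_BAND_SIZES = {326: "A", 446: "B"}


def percent(x: float, decimals: int = 1) -> float:
    """Percentage rendering with half-up rounding (so 37/198 -> 18.7)."""
    q = Decimal("1." + "0" * decimals) if decimals else Decimal("1")
    return float(Decimal(str(100.0 * x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# tandem repeats

@dataclass(frozen=True)
class TandemRepeat:
    """A tandem array: where it sits, its period, and how many copies."""

    region: GenomeInterval
    unit_length: int
    copy_number: float
    consensus_unit: str
    percent_match: float

    def __post_init__(self) -> None:
        if self.copy_number < 2:
            raise ValueError("tandem repeat needs >= 2 copies")


def _candidate_windows(m: np.ndarray, min_identity: float, min_run: int = 4):
    """Greedily merge runs of True in the period-match mask while the
    merged span keeps match fraction >= min_identity.

    Runs shorter than ``min_run`` are not used as window boundaries:
    unrelated sequence matches a shifted copy of itself at ~25% per base,
    so short spurious runs would otherwise drag array edges into the
    flanks."""
    edges = np.diff(np.concatenate(([0], m.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    windows = []
    cur = None
    for st, en in zip(starts, ends):
        st, en = int(st), int(en)
        if en - st < min_run:
            continue
        if cur is None:
            cur = [st, en, en - st]
        else:
            merged_span = en - cur[0]
            merged_matches = cur[2] + (en - st)
            if merged_matches / merged_span >= min_identity:
                cur[1], cur[2] = en, merged_matches
            else:
                windows.append(tuple(cur))
                cur = [st, en, en - st]
    if cur is not None:
        windows.append(tuple(cur))
    return windows


def find_tandem_repeats(seq: str, min_unit: int = 10, max_unit: int = 100,
                        min_copies: float = 2.0, min_identity: float = 0.8,
                        seq_id: str = "query") -> list[TandemRepeat]:
    """Find tandem arrays by an exhaustive period scan.

    For each candidate period p the sequence is compared to itself shifted
    by p; maximal stretches with >= ``min_identity`` agreement and
    >= ``min_copies`` copies are reported, overlapping reports collapsed
    to the highest-scoring period (ties to the shortest, i.e. the
    primitive unit).  A deliberately transparent alternative to
    heuristic repeat finders; no alignment within copies, so highly
    diverged arrays are out of scope.
    """
    seq = seq.upper()
    if len(seq) <= 2 * min_unit:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    candidates = []
    for p in range(min_unit, min(max_unit, len(seq) // 2) + 1):
        m = arr[p:] == arr[:-p]
        for w0, w1, matches in _candidate_windows(m, min_identity):
            region_len = (w1 - w0) + p
            copies = region_len / p
            if copies + 1e-9 < min_copies:
                continue
            frac = matches / (w1 - w0)
            if frac < min_identity:
                continue
            candidates.append((matches, p, w0, w0 + region_len, frac))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    out: list[TandemRepeat] = []
    taken: list[tuple[int, int]] = []
    for matches, p, start, end, frac in candidates:
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        n_full = (end - start) // p
        frames = np.stack([arr[start + k * p: start + (k + 1) * p]
                           for k in range(n_full)])
        consensus = []
        for col in range(p):
            vals, counts = np.unique(frames[:, col], return_counts=True)
            consensus.append(vals[np.argmax(counts)].decode())
        out.append(TandemRepeat(
            region=GenomeInterval(seq_id, start, end),
            unit_length=p,
            copy_number=round((end - start) / p, 3),
            consensus_unit="".join(consensus),
            percent_match=100.0 * frac,
        ))
    out.sort(key=lambda r: r.region.start)
    return out


def duplication_length(allele_a: str, allele_b: str,
                       scoring: ScoringScheme = DEFAULT_SCORING,
                       min_identity: float = 90.0) -> int:
    """Net indel length between two alleles from their global alignment.

    Positive when ``allele_b`` is longer.  Gap lengths are summed signed
    by direction, so a clean 2-extra-copies array of a 61-bp unit gives
    exactly +122.  Raises if the alleles are too diverged outside indels
    (substitution-only identity below ``min_identity``%).
    """
    aln = global_align(allele_a, allele_b, scoring, id_a="alleleA", id_b="alleleB")
    if percent_identity(aln, "substitution_only") < min_identity:
        raise ValueError("alleles too diverged to be the same locus")
    gaps_in_a = int((aln.idx_a < 0).sum())
    gaps_in_b = int((aln.idx_b < 0).sum())
    return gaps_in_a - gaps_in_b


# ---------------------------------------------------------------------------
# in-silico PCR

@dataclass(frozen=True)
class PcrProduct:
    """A predicted amplicon; coordinates are 1-based inclusive of both
    primers, so length = rev_end - fwd_start + 1."""

    template_id: str
    fwd_start: int
    rev_end: int
    length: int
    allele_label: str = "unknown"

    def __post_init__(self) -> None:
        if self.length != self.rev_end - self.fwd_start + 1:
            raise ValueError("inconsistent product coordinates")


def _match_starts(template: str, probe: str, max_mismatch: int) -> np.ndarray:
    t = np.frombuffer(template.encode("ascii"), dtype="S1")
    p = np.frombuffer(probe.encode("ascii"), dtype="S1")
    if len(t) < len(p):
        return np.array([], dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(t, len(p))
    mism = (windows != p).sum(axis=1)
    return np.flatnonzero(mism <= max_mismatch).astype(np.int64)


def insilico_pcr(template: str, fwd: str, rev: str, max_mismatch: int = 0,
                 max_product: int = 5000,
                 template_id: str = "template") -> list[PcrProduct]:
    """Predict PCR products: the forward primer on the plus strand paired
    with the reverse primer's reverse-complement downstream, each within
    ``max_mismatch``.  Every compatible pair up to ``max_product`` bp is
    reported; absence of either site yields an empty list."""
    template, fwd, rev = template.upper(), fwd.upper(), rev.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be >= 15 bp")
    f_starts = _match_starts(template, fwd, max_mismatch)
    r_starts = _match_starts(template, revcomp(rev), max_mismatch)
    products = []
    for f in f_starts:
        for r in r_starts:
            if r < f + len(fwd):
                continue  # reverse site must be downstream of the forward primer
            rev_end0 = int(r) + len(rev) - 1
            length = rev_end0 - int(f) + 1
            if length <= max_product:
                products.append(PcrProduct(template_id=template_id,
                                           fwd_start=int(f) + 1,
                                           rev_end=rev_end0 + 1,
                                           length=length))
    products.sort(key=lambda p: (p.fwd_start, p.rev_end))
    return products


def classify_allele(products: list[PcrProduct],
                    expected: dict[int, str] | None = None,
                    tol: int = 5) -> str:
    """Call an allele (or heterozygous pair) from observed band sizes.

    ``expected`` maps product size to label (default: the 326/446-bp
    A/B assay).  Returns a single label, a '/'-joined heterozygote, or
    'unknown' when no band matches within ``tol`` bp."""
    if expected is None:
        expected = EXPECTED_BAND_SIZES
    sizes = sorted(expected)
    for i, s1 in enumerate(sizes):
        for s2 in sizes[i + 1:]:
            if abs(s2 - s1) <= 2 * tol:
                raise ValueError("expected sizes not separable at this tolerance")
    labels = []
    for prod in products:
        hits = [lab for size, lab in expected.items()
                if abs(prod.length - size) <= tol]
        if len(hits) > 1:
            raise ValueError(f"band {prod.length} matches several expected sizes")
        if hits and hits[0] not in labels:
            labels.append(hits[0])
    if not labels:
        return "unknown"
    return "/".join(sorted(labels))


# ---------------------------------------------------------------------------
# allele frequencies

@dataclass
class AlleleFreqSummary:
    """Per-population and pooled allele counts/frequencies plus a
    chi-square homogeneity test across populations."""

    per_population: pd.DataFrame
    pooled_counts: dict
    pooled_freqs: dict
    n_alleles: int
    chi_square: float | None = None
    df: int | None = None
    p_value: float | None = None
    method: str | None = None
    note: str = ""

    def pooled_percent(self, label: str, decimals: int = 1) -> float:
        return percent(self.pooled_freqs[label], decimals)


def _validate_genotypes(table: pd.DataFrame,
                        labels: tuple = ALLELE_LABELS) -> pd.DataFrame:
    required = {"population", "individual", "allele1", "allele2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"genotype table missing columns {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("empty genotype table")
    if table["individual"].duplicated().any():
        dup = table.loc[table["individual"].duplicated(), "individual"].iloc[0]
        raise ValueError(f"duplicate individual id: {dup}")
    seen = set(table["allele1"]) | set(table["allele2"])
    if not seen <= set(labels):
        raise ValueError(f"alleles {sorted(seen - set(labels))} outside "
                         f"label set {labels}")
    return table


def _chi2_stat(counts: np.ndarray) -> float:
    """Homogeneity chi-square of a populations x alleles count table."""
    row = counts.sum(axis=1, keepdims=True).astype(float)
    col = counts.sum(axis=0, keepdims=True).astype(float)
    total = counts.sum()
    expected = row @ col / total
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def _monte_carlo_p(counts: np.ndarray, n_permutations: int,
                   seed: int) -> float:
    """Permutation p-value for allele-count homogeneity.

    Permuting allele labels across populations with fixed margins is a
    multivariate-hypergeometric draw of the per-population allele counts,
    sampled directly instead of shuffling."""
    rng = np.random.default_rng([97, seed])
    k, n_lab = counts.shape
    pop_sizes = counts.sum(axis=1)
    colors = counts.sum(axis=0)
    obs = _chi2_stat(counts)
    total = counts.sum()
    exp = pop_sizes[:, None].astype(float) * colors[None, :] / total

    remaining = np.tile(colors, (n_permutations, 1)).astype(np.int64)
    stats_perm = np.zeros(n_permutations)
    for i in range(k):
        n_i = int(pop_sizes[i])
        draw = np.zeros((n_permutations, n_lab), dtype=np.int64)
        left = n_i * np.ones(n_permutations, dtype=np.int64)
        rem_total = remaining.sum(axis=1)
        for j in range(n_lab - 1):
            good = remaining[:, j]
            bad = rem_total - good
            take = rng.hypergeometric(good, bad, left)
            draw[:, j] = take
            left -= take
            rem_total -= good
        draw[:, -1] = left
        remaining -= draw
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(exp[i] > 0, (draw - exp[i]) ** 2 / exp[i], 0.0)
        stats_perm += t.sum(axis=1)
    ge = int((stats_perm >= obs - 1e-12).sum())
    return (1 + ge) / (1 + n_permutations)


def allele_frequencies(table: pd.DataFrame, n_permutations: int = 10_000,
                       seed: int = 0,
                       labels: tuple = ALLELE_LABELS) -> AlleleFreqSummary:
    """Summarize allele counts per population and pooled, and test
    homogeneity of frequencies across populations.

    The test is the chi-square on the populations x alleles count table
    (df = populations - 1 for two alleles); when any expected count is
    below 5 the asymptotic distribution is unreliable at these panel
    sizes, so a seeded Monte-Carlo permutation p-value is used instead.
    A single population skips the test with a notice.
    """
    table = _validate_genotypes(table, labels)
    melted = pd.concat([
        table[["population", "allele1"]].rename(columns={"allele1": "allele"}),
        table[["population", "allele2"]].rename(columns={"allele2": "allele"}),
    ])
    pops = list(dict.fromkeys(table["population"]))
    counts = np.array([[int(((melted["population"] == pop)
                             & (melted["allele"] == lab)).sum())
                        for lab in labels] for pop in pops], dtype=np.int64)
    pop_totals = counts.sum(axis=1)
    rows = []
    for i, pop in enumerate(pops):
        row = {"population": pop, "n_individuals": int(pop_totals[i] // 2),
               "n_alleles": int(pop_totals[i])}
        for j, lab in enumerate(labels):
            row[f"count_{lab}"] = int(counts[i, j])
            row[f"freq_{lab}"] = counts[i, j] / pop_totals[i]
        rows.append(row)
    per_pop = pd.DataFrame(rows)
    pooled = counts.sum(axis=0)
    n_alleles = int(pooled.sum())
    pooled_counts = {lab: int(pooled[j]) for j, lab in enumerate(labels)}
    pooled_freqs = {lab: pooled[j] / n_alleles for j, lab in enumerate(labels)}
    summary = AlleleFreqSummary(per_population=per_pop,
                                pooled_counts=pooled_counts,
                                pooled_freqs=pooled_freqs,
                                n_alleles=n_alleles)
    if len(pops) < 2:
        summary.note = "single population: homogeneity test skipped"
        return summary
    if (pooled == 0).any():
        summary.chi_square, summary.df = 0.0, len(pops) - 1
        summary.p_value, summary.method = 1.0, "degenerate"
        summary.note = "an allele is absent from the pooled sample"
        return summary
    expected = pop_totals[:, None] * pooled[None, :] / n_alleles
    summary.df = len(pops) - 1
    summary.chi_square = _chi2_stat(counts)
    if (expected < 5).any():
        summary.p_value = _monte_carlo_p(counts, n_permutations, seed)
        summary.method = "monte_carlo"
    else:
        chi2, p, dof, _ = stats.chi2_contingency(counts, correction=False)
        summary.chi_square, summary.p_value = float(chi2), float(p)
        summary.df = int(dof)
        summary.method = "asymptotic"
    return summary
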