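"""Readers/writers for the plain-text formats the pipeline speaks, plus
the pipeline configuration.

Everything written here is re-readable by this module: FASTA for
sequences, TSV for probe tracks (chrom, pos, log2) and genotype tables
(population, individual, allele1, allele2), JSON for truth sidecars and
reports, BED for intervals.  BED output is 0-based half-open per the BED
standard; human-readable reports use 1-based inclusive strings; both
carry an explicit convention tag.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import ScoringScheme, _ALPHABET_SET
from .genome import GenomeInterval
from .simdata import SimConfig


class FastaRecord(NamedTuple):
    id: str
    seq: str


def read_fasta(path) -> list[FastaRecord]:
    """Read FASTA records, order-preserving and uppercased.

    Duplicate ids and characters outside ACGTN raise, naming the record.
    """
    records: list[FastaRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        bad = set(seq) - _ALPHABET_SET
        if bad:
            raise ValueError(f"record {rec.id!r} has illegal characters "
                             f"{sorted(bad)}")
        seen.add(rec.id)
        records.append(FastaRecord(rec.id, seq))
    return records


def write_fasta(path, records, width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_probe_track(path):
    from .cgh import ProbeTrack
    df = pd.read_csv(path, sep="\t")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("probe track must cover a single chromosome")
    return ProbeTrack(chrom=str(chroms[0]),
                      positions=df["pos"].to_numpy(),
                      log2=df["log2"].to_numpy())


def write_probe_track(path, track) -> None:
    pd.DataFrame({"chrom": track.chrom, "pos": track.positions,
                  "log2": track.log2}).to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_genotypes(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_example_genotypes(panel: str) -> pd.DataFrame:
    """Bundled synthetic genotype tables reproducing the published panel
    totals: ``coriell`` (99 individuals, 37/161 A/B alleles) and ``hgdp``
    (62 individuals in 10 populations, 26/98 A/B alleles).  The tables are
    synthetic stand-ins for the unpublished per-individual genotype
    listings; only the totals (and, for hgdp, homogeneity across
    populations) are faithful."""
    names = {"coriell": "coriell_panel_synthetic.tsv",
             "hgdp": "hgdp_panel_synthetic.tsv"}
    if panel not in names:
        raise ValueError(f"unknown panel {panel!r}; choose from {sorted(names)}")
    ref = resources.files("nahrkit.data") / names[panel]
    with resources.as_file(ref) as p:
        return read_genotypes(p)


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_bed(path, intervals, names=None) -> None:
    """BED (0-based half-open) with a convention comment line."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open (BED)\n")
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bed(path) -> list[GenomeInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        out.append(GenomeInterval(chrom, int(start), int(end)))
    return out


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """Every stage parameter in one (YAML-serializable) place.

    Unknown keys in the on-disk form are rejected rather than ignored, so
    typos fail loudly.
    """

    seed: int = 0
    out_dir: str = "nahrkit_out"
    coordinate_convention: str = "1-based-inclusive"
    sim: SimConfig = field(default_factory=SimConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    min_gap_distance: int = 5
    identity_window: int = 500
    identity_step: int = 250
    cgh_min_delta: float = 0.4
    cgh_loss_max: float = -0.5
    cgh_gain_min: float = 0.3
    track_chrom_length: int = 20_000
    track_breakpoint: int = 12_340
    genotype_pops: list = field(default_factory=lambda: [
        ["CEPH", 99, 0.19], ["HGDP", 62, 0.21]])
    genotype_permutations: int = 10_000

    def __post_init__(self) -> None:
        # one seed drives everything; stage configs inherit it
        if self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in data and isinstance(data["sim"], dict):
            sim_known = {f.name for f in fields(SimConfig)}
            bad = set(data["sim"]) - sim_known
            if bad:
                raise ValueError(f"unknown sim config keys: {sorted(bad)}")
            data["sim"] = SimConfig(**data["sim"])
        if "scoring" in data and isinstance(data["scoring"], dict):
            sc_known = {f.name for f in fields(ScoringScheme)}
            bad = set(data["scoring"]) - sc_known
            if bad:
                raise ValueError(f"unknown scoring config keys: {sorted(bad)}")
            data["scoring"] = ScoringScheme(**data["scoring"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
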