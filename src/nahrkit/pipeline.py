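"""The pipeline driver: simulate -> align -> PSVs -> resolve -> segment
-> genotype, with one JSON report aggregating every stage plus
truth-vs-inferred comparisons.

Reports contain no timestamps, so the same config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import yaml

from . import __version__
from .align import percent_identity, windowed_identity
from .cgh import segment
from .genome import GenomeInterval
from .io import (PipelineConfig, write_bed, write_fasta, write_genotypes,
                 write_json, write_probe_track)
from .junction import resolve_junction
from .psv import call_psvs, ladder_density
from .repeatgt import allele_frequencies
from .simdata import (make_genotypes, make_junction, make_paralogs,
                      make_probe_track)

log = logging.getLogger("nahrkit")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage.  Outputs written by
    earlier stages are retained."""


def _config_hash(config: PipelineConfig) -> str:
    canon = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on simulated data and write the aggregate report.

    Returns the report dict; files land under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    log.info("nahrkit %s seed=%d config=%s", __version__, config.seed, chash)
    report: dict = {"version": __version__, "seed": config.seed,
                    "config_sha256": chash,
                    "coordinate_convention": config.coordinate_convention,
                    "stages": {}}
    stage = "simulate"
    try:
        pair = make_paralogs(config.sim)
        write_fasta(out / "paralogs.fasta",
                    [(pair.chrom_18, pair.paralog_18),
                     (pair.chrom_4, pair.paralog_4),
                     ("flank_18", pair.flank_18),
                     ("flank_4", pair.flank_4)])
        report["stages"]["simulate"] = {
            "files": ["paralogs.fasta"],
            "truth": pair.truth.to_dict(),
        }

        stage = "align"
        aln = pair.alignment
        windows = windowed_identity(aln, config.identity_window,
                                    config.identity_step)
        report["stages"]["align"] = {
            "score": aln.score,
            "identity_overall": percent_identity(aln, "overall"),
            "identity_substitution_only":
                percent_identity(aln, "substitution_only"),
            "n_windows": len(windows),
            "min_window_identity": min(w.identity for w in windows),
            "max_window_identity": max(w.identity for w in windows),
        }

        stage = "psv"
        ladder = call_psvs(aln, config.min_gap_distance)
        density = ladder_density(ladder, (0, aln.n_columns))
        report["stages"]["psv"] = {
            "n_psvs": len(ladder),
            "n_informative": len(ladder.informative),
            "density_per_kb": density,
        }

        stage = "resolve"
        if len(ladder.informative) >= 2:
            junction, truth = make_junction(pair, "random")
            write_fasta(out / "junction.fasta", [("sim_junction", junction)])
            write_json(out / "junction_truth.json", truth.to_dict())
            call = resolve_junction(junction, ladder, pair, config.scoring)
            entry = {"status": call.status,
                     "discordance": call.discordance,
                     "conversion_flag": call.conversion_flag,
                     "orientation_ok": call.orientation_ok,
                     "note": call.note}
            if call.interval_18 is not None:
                entry["interval_18"] = call.interval_18.render()
                entry["interval_4"] = call.interval_4.render()
                entry["truth_interval_18"] = truth.interval_18.render()
                entry["interval_contains_truth"] = bool(
                    call.interval_18.contains_boundary(truth.crossover_pos_18)
                    and call.interval_4.contains_boundary(truth.crossover_pos_4))
                write_bed(out / "junction_intervals.bed",
                          [call.interval_18, call.interval_4],
                          ["ambiguity_18", "ambiguity_4"])
        else:
            entry = {"status": "unresolvable",
                     "note": "unresolvable - no informative markers"}
        report["stages"]["resolve"] = entry

        stage = "segment"
        seg_report = {}
        for kind in ("loss", "gain"):
            track, ttruth = make_probe_track(config.track_chrom_length,
                                             config.track_breakpoint, kind,
                                             config.sim)
            write_probe_track(out / f"track_{kind}.tsv", track)
            call = segment(track, config.cgh_min_delta, config.cgh_loss_max,
                           config.cgh_gain_min)
            seg_report[kind] = {
                "state": call.state,
                "mean_left": call.mean_left,
                "mean_right": call.mean_right,
                "delta_sse": call.delta_sse,
                "breakpoint_interval":
                    call.breakpoint_interval.render()
                    if call.breakpoint_interval else None,
                "cut_index": call.cut_index,
                "truth_breakpoint_index": ttruth.cgh_breakpoint_index,
                "probe_offset_from_truth":
                    None if call.cut_index is None
                    else call.cut_index - 1 - ttruth.cgh_breakpoint_index,
            }
        report["stages"]["segment"] = seg_report

        stage = "genotype"
        table = make_genotypes([tuple(p) for p in config.genotype_pops],
                               seed=config.seed)
        write_genotypes(out / "genotypes.tsv", table)
        summary = allele_frequencies(table, config.genotype_permutations,
                                     seed=config.seed)
        report["stages"]["genotype"] = {
            "pooled_counts": summary.pooled_counts,
            "pooled_percent": {lab: summary.pooled_percent(lab)
                               for lab in summary.pooled_counts},
            "n_alleles": summary.n_alleles,
            "chi_square": summary.chi_square,
            "df": summary.df,
            "p_value": summary.p_value,
            "method": summary.method,
            "note": summary.note,
        }
    except Exception as exc:  # noqa: BLE001 - re-raise with the stage named
        write_json(out / "report.json", report)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    write_json(out / "report.json", report)
    return report
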