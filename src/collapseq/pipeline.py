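"""End-to-end pipeline: simulate -> normalize -> peaks -> score -> report.

A single YAML/TOML-style config (a plain mapping) drives the run.  One
global seed is expanded into per-stage substreams so stages can be
re-run in isolation reproducibly; the run writes per-stage TSV/BED/
bedGraph artifacts plus a machine-readable manifest (package version,
seed, parameters, output hashes).  A stage failure aborts the run with
the failing stage named and leaves a FAILED marker next to any partial
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .end_structure import classify_end_structure, peak_asymmetry
from .peaks import call_peaks, peak_intensity, qualify_peaks
from .resection import resection_length_sliding, resection_length_unique, summarize_resection
from .rfd import classify_nick, write_rfd_tsv
from .synthetic import (
    CollisionSimParams,
    DeletionSpec,
    ResectionModel,
    background_rate_for_fraction,
    random_amplicon_reference,
    simulate_amplicon_reads,
    simulate_collision_track,
    simulate_rfd_field,
    simulate_spikein,
    write_fasta,
)
from .tracks_io import (
    GenomeSpec,
    NickSite,
    SpikeInConfig,
    StrandedTrack,
    compute_rpm,
    spikein_normalize,
    write_nicks_bed,
    write_peaks_bed,
    write_track_bedgraph,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _require(config: Mapping[str, Any], key: str, context: str = "config") -> Any:
    if key not in config:
        raise ConfigError(f"{context} is missing required key {key!r}")
    return config[key]


def parse_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Validate a config mapping and build typed objects from it."""
    seed = _require(config, "seed")
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer (stochastic stages require one)")
    gspec = _require(config, "genome")
    genome = GenomeSpec(
        main=dict(_require(gspec, "main", "genome")), spikein=dict(gspec.get("spikein", {}))
    )
    nicks_cfg = config.get("nicks")
    if nicks_cfg is None:
        nicks_cfg = [_require(config, "nick")]
    nicks = []
    for i, nc in enumerate(nicks_cfg):
        nick = NickSite(
            chrom=_require(nc, "chrom", f"nick[{i}]"),
            position=int(_require(nc, "position", f"nick[{i}]")),
            target_strand=_require(nc, "target_strand", f"nick[{i}]"),
            label=str(nc.get("label", f"nick_{i}")),
        )
        nick.validate_against(genome)
        nicks.append(nick)
    sim = dict(_require(config, "simulation"))
    sim.pop("seed", None)  # the global seed is authoritative
    res_cfg = sim.pop("resection", {})
    background_fraction = sim.pop("background_fraction", None)
    try:
        params = CollisionSimParams(
            resection=ResectionModel(**res_cfg), seed=seed, **sim
        )
    except TypeError as exc:
        raise ConfigError(f"bad simulation section: {exc}") from None
    spike_cfg = config.get("spikein")
    spike = None
    if spike_cfg is not None:
        spike = {
            "config": SpikeInConfig(
                chrom=_require(spike_cfg, "chrom", "spikein"),
                start=int(_require(spike_cfg, "start", "spikein")),
                end=int(_require(spike_cfg, "end", "spikein")),
                fraction=float(spike_cfg.get("fraction", 0.20)),
            ),
            "depth": int(spike_cfg.get("depth", 10000)),
        }
    return {
        "seed": seed,
        "genome": genome,
        "nicks": nicks,
        "params": params,
        "background_fraction": background_fraction,
        "spike": spike,
        "rfd": dict(config.get("rfd", {})),
        "peaks": dict(config.get("peaks", {})),
        "asymmetry": dict(config.get("asymmetry", {})),
        "resection": dict(config.get("resection_analysis", {})),
        "amplicon": dict(config.get("amplicon", {})),
        "raw": dict(config),
    }


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_tracks(cfg: dict[str, Any]) -> StrandedTrack:
    """Simulate the combined break-end track for all configured nicks."""
    genome: GenomeSpec = cfg["genome"]
    params: CollisionSimParams = cfg["params"]
    streams = _substreams(cfg["seed"], len(cfg["nicks"]) + 1)
    track = StrandedTrack.zeros(genome)
    total = 0.0
    for nick, rng in zip(cfg["nicks"], streams[:-1]):
        p = params
        if cfg["background_fraction"] is not None:
            rate = background_rate_for_fraction(nick, params, genome, cfg["background_fraction"])
            p = CollisionSimParams(
                fork_directionality=params.fork_directionality,
                cut_efficiency=params.cut_efficiency,
                converging_prob=params.converging_prob,
                converging_distance=params.converging_distance,
                resection=params.resection,
                background_rate=rate,
                n_events=params.n_events,
                seed=params.seed,
            )
        sub = simulate_collision_track(nick, p, genome, rng=rng)
        for c in track.plus:
            track.plus[c] += sub.plus[c]
            track.minus[c] += sub.minus[c]
        total += sub.total_mapped_reads
    track.total_mapped_reads = total
    if cfg["spike"] is not None:
        track = simulate_spikein(track, cfg["spike"]["config"], cfg["spike"]["depth"], streams[-1])
    return track


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run the full pipeline and write the report bundle into ``outdir``.

    Returns the manifest (also written as ``manifest.json``).
    """
    cfg = parse_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage = "simulate"
    try:
        raw = simulate_tracks(cfg)
        write_nicks_bed(cfg["nicks"], outdir / "nicks.bed")
        write_track_bedgraph(raw, outdir / "raw_plus.bedGraph", outdir / "raw_minus.bedGraph")

        stage = "normalize"
        norm = compute_rpm(raw)
        logger.info(
            "normalize: total_mapped_reads=%s spikein_reads=%s",
            raw.total_mapped_reads,
            raw.spikein_reads,
        )
        if cfg["spike"] is not None and norm.spikein_reads > 0:
            norm = spikein_normalize(norm, cfg["spike"]["config"])
        write_track_bedgraph(norm, outdir / "norm_plus.bedGraph", outdir / "norm_minus.bedGraph")

        stage = "rfd"
        rfd_profile = None
        if cfg["rfd"]:
            rfd_cfg = cfg["rfd"]
            chrom = rfd_cfg.get("chrom", cfg["nicks"][0].chrom)
            rfd_profile = simulate_rfd_field(
                _require(rfd_cfg, "origins", "rfd"),
                cfg["genome"].length(chrom),
                int(rfd_cfg.get("bin_size", 1000)),
                smoothing_width=int(rfd_cfg.get("smoothing_width", 0)),
                depth=int(rfd_cfg.get("depth", 100)),
                chrom=chrom,
            )
            write_rfd_tsv(rfd_profile, outdir / "rfd.tsv")

        stage = "peaks"
        pk_cfg = cfg["peaks"]
        peaks = call_peaks(
            norm,
            min_signal=float(pk_cfg.get("min_signal", 3.0)),
            merge_gap=int(pk_cfg.get("merge_gap", 500)),
            background_rate=float(pk_cfg.get("background_rate", 0.1)),
        )
        max_p = float(pk_cfg.get("max_pvalue", 0.001))
        peaks = [p for p in peaks if p.qvalue < max_p]
        qualified, qreport = qualify_peaks(
            peaks, cfg["nicks"], min_separation=int(pk_cfg.get("min_separation", 8000))
        )
        write_peaks_bed(qualified, outdir / "peaks.bed")

        stage = "score"
        window = int(cfg["asymmetry"].get("window", 3000))
        res_cfg = cfg["resection"]
        method = res_cfg.get("method", "sliding")
        rows = []
        for nick in cfg["nicks"]:
            asym = peak_asymmetry(norm, nick, window=window)
            cls = classify_end_structure(asym) if math.isfinite(asym) else "undefined"
            rfd_value = rfd_profile.value_at(nick.position) if rfd_profile is not None else math.nan
            orientation = classify_nick(nick, rfd_value) if rfd_profile is not None else "unclassified"
            estimates = {}
            for side in ("left", "right"):
                if method == "unique":
                    est = resection_length_unique(
                        norm,
                        nick,
                        side,
                        flank_bg_range=tuple(res_cfg.get("flank_bg_range", (20000, 30000))),
                        k_sigma=float(res_cfg.get("k_sigma", 3.0)),
                        max_gap=int(res_cfg.get("max_gap", 200)),
                    )
                else:
                    est = resection_length_sliding(
                        norm,
                        nick,
                        side,
                        bg_range=tuple(res_cfg.get("bg_range", (7000, 9000))),
                        search_limit=int(res_cfg.get("search_limit", 50000)),
                    )
                estimates[side] = est
            rows.append(
                {
                    "label": nick.label,
                    "chrom": nick.chrom,
                    "position": nick.position,
                    "target_strand": nick.target_strand,
                    "asymmetry": asym,
                    "end_structure": cls,
                    "rfd": rfd_value,
                    "orientation": orientation,
                    "intensity_30kb": peak_intensity(norm, nick),
                    "resection_left": estimates["left"].length,
                    "resection_left_at_limit": estimates["left"].at_limit,
                    "resection_right": estimates["right"].length,
                    "resection_right_at_limit": estimates["right"].at_limit,
                }
            )
        report = pd.DataFrame(rows)
        report.to_csv(outdir / "report.tsv", sep="\t", index=False)

        stage = "amplicon"
        if cfg["amplicon"]:
            amp = cfg["amplicon"]
            ref = amp.get("reference") or random_amplicon_reference(
                int(amp.get("ref_length", 240)), cfg["seed"]
            )
            model = DeletionSpec(
                p_del=float(amp.get("p_del", 0.6)),
                max_len=int(amp.get("max_len", 30)),
                mh_bias=bool(amp.get("mh_bias", False)),
            )
            reads = simulate_amplicon_reads(
                ref,
                int(amp.get("nick_offset", len(ref) // 2)),
                model,
                int(amp.get("n_reads", 500)),
                cfg["seed"] + 1,
            )
            write_fasta([("amplicon_ref", ref)], outdir / "amplicon_ref.fasta")
            write_fasta(reads, outdir / "amplicon_reads.fasta")
    except (ConfigError, PipelineError):
        failed_marker.write_text(stage)
        raise
    except Exception as exc:
        failed_marker.write_text(stage)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage_files = sorted(p for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "package": "collapseq",
        "version": __version__,
        "numpy": np.__version__,
        "seed": cfg["seed"],
        "parameters": cfg["raw"],
        "qualification": {
            "n_input": qreport.n_input,
            "n_kept": qreport.n_kept,
            "n_no_site": qreport.n_no_site,
            "n_multi_site": qreport.n_multi_site,
            "n_too_close": qreport.n_too_close,
        },
        "outputs": {p.name: _sha256(p) for p in stage_files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# ---------------------------------------------------------------------------
# Canned scenarios

SCENARIOS = ("leading_seDSB", "lagging_deDSB", "rad51_like_hyperresection", "brca1_like")


def scenario_config(scenario: str, seed: int = 20240) -> dict[str, Any]:
    """Deterministic study-condition configs for the canned scenarios.

    * ``leading_seDSB`` / ``lagging_deDSB`` — fork directionality 0.85 at
      a Watson- / Crick-strand nick, 1,000 cells, uniform resection up to
      5 kb, background reads at 5% of signal: the canonical one-ended and
      two-ended break patterns.
    * ``rad51_like_hyperresection`` — unresolved single-ended breaks:
      pure leading collapse, uniform resection up to 45 kb, converging
      forks supplying second ends at 47 kb.  Hyper-resected tracts extend
      past the default 7-9 kb background window, so the scenario sets a
      distal background range (55-60 kb) for the sliding estimator.
    * ``brca1_like`` — hyper-resection plus amplicon reads whose nick-
      spanning deletions are biased toward microhomology-bearing
      junctions.
    """
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}; choices: {', '.join(SCENARIOS)}")
    base: dict[str, Any] = {
        "seed": seed,
        "genome": {"main": {"chr1": 200_000}, "spikein": {"spikeM": 20_000}},
        "nick": {"chrom": "chr1", "position": 100_000, "target_strand": "+", "label": scenario},
        "simulation": {
            "fork_directionality": 0.85,
            "n_events": 1000,
            "background_fraction": 0.05,
            "resection": {"family": "uniform", "l_max": 5000.0},
        },
        "spikein": {"chrom": "spikeM", "start": 8000, "end": 12000, "fraction": 0.2, "depth": 10000},
        "rfd": {"origins": [20_000], "bin_size": 1000, "depth": 200},
        "peaks": {"min_signal": 3.0, "merge_gap": 500, "max_pvalue": 0.001},
        "asymmetry": {"window": 3000},
        "resection_analysis": {"method": "sliding"},
    }
    if scenario == "lagging_deDSB":
        base["nick"]["target_strand"] = "-"
    if scenario in ("rad51_like_hyperresection", "brca1_like"):
        base["genome"]["main"] = {"chr1": 500_000}
        base["nick"]["position"] = 250_000
        base["rfd"]["origins"] = [50_000]
        base["simulation"].update(
            {
                "fork_directionality": 1.0,
                "n_events": 4000,
                "background_fraction": 0.005,
                "converging_prob": 0.5,
                "converging_distance": 47_000,
                "resection": {"family": "uniform", "l_max": 45_000.0},
            }
        )
        base["resection_analysis"] = {
            "method": "sliding",
            "bg_range": (55_000, 60_000),
            "search_limit": 50_000,
        }
    if scenario == "brca1_like":
        base["amplicon"] = {
            "ref_length": 240,
            "nick_offset": 120,
            "p_del": 0.7,
            "max_len": 30,
            "mh_bias": True,
            "n_reads": 400,
        }
    return base


def make_fixtures(scenario: str, outdir: str | Path, seed: int = 20240) -> dict[str, Any]:
    """Materialize one scenario as a small deterministic dataset on disk."""
    return run_pipeline(scenario_config(scenario, seed=seed), outdir)
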