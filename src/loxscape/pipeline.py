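"""End-to-end orchestration: simulate -> call -> classify -> landscape ->
integrate, with one flat config and one seed.

Each stage writes its text artifacts into a stage-named subdirectory of the
output directory plus a machine-readable ``summary.json``; a final
``report.json`` aggregates event-class percentages, hotspot/coldspot calls,
correlations and model fits. A stage failure halts the run with the failing
stage named; partial outputs are retained.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import caller as _caller
from . import chromatin as _chromatin
from . import landscape as _landscape
from . import simulate as _simulate
from .classify import class_summary as _class_summary
from .classify import classify_all as _classify_all
from .genome import GenomeDefinition, load_genome, write_region_bed
from .tracks import ContactModel, SignalTrack

log = logging.getLogger("loxscape")

STAGES = ("simulate", "call", "classify", "landscape", "integrate")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Flat pipeline configuration; echoed verbatim into the output dir."""

    fasta: str
    sites: str
    chromosomes: str
    outdir: str
    seed: int = 0
    # simulation
    n_cells: int = 500
    lambda_events: float = 2.0
    reads_per_junction: float = 10.0
    error_rate: float = 0.0
    background_reads: int = 1000
    read_len: int = 150
    mode: str = "junction_pool"
    alpha: float = 1.0
    beta: float = 1.0
    open_fraction: float = 0.2
    bin_size: int = 1000
    gamma: float = 1.0
    kappa: float = 0.01
    boost_cen: float = 4.0
    boost_tel: float = 4.0
    # caller
    min_flank: int = 20
    max_mismatch: int = 0
    # integration
    halfwidth: int = 400
    pseudocount: float = 1e-6

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def validate(self) -> None:
        for key in ("fasta", "sites", "chromosomes"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise PipelineError(f"config: missing input file {key}={p}")


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")


class Pipeline:
    """Stage runner bound to one config; stages read the artifacts of the
    previous ones from the output directory, so each subcommand is
    idempotent given identical inputs and seed."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(self.out / "config.yaml")
        self.genome: GenomeDefinition = load_genome(
            config.fasta, config.sites, config.chromosomes
        )

    def _stage_dir(self, stage: str) -> Path:
        d = self.out / stage
        d.mkdir(exist_ok=True)
        return d

    # -- stages ----------------------------------------------------------

    def simulate(self) -> dict:
        cfg = self.config
        d = self._stage_dir("simulate")
        profile, track = _simulate.synth_accessibility(
            self.genome, seed=cfg.seed, open_fraction=cfg.open_fraction
        )
        contacts = _simulate.synth_contacts(
            self.genome,
            bin_size=cfg.bin_size,
            gamma=cfg.gamma,
            kappa=cfg.kappa,
            boost_cen=cfg.boost_cen,
            boost_tel=cfg.boost_tel,
        )
        model = _simulate.EventWeightModel(alpha=cfg.alpha, beta=cfg.beta)
        weights = _simulate.compute_pair_weights(self.genome, model, profile, contacts)
        sim_cfg = _simulate.SimConfig(
            n_cells=cfg.n_cells,
            lambda_events=cfg.lambda_events,
            read_len=cfg.read_len,
            reads_per_junction=cfg.reads_per_junction,
            error_rate=cfg.error_rate,
            seed=cfg.seed,
            mode=cfg.mode,
            background_reads=cfg.background_reads,
            min_flank=cfg.min_flank,
        )
        event_log, _ = _simulate.simulate_pool(self.genome, weights, sim_cfg)
        reads = _simulate.emit_reads(
            event_log, self.genome, sim_cfg, fastq_path=d / "reads.fastq"
        )
        profile.to_tsv(d / "accessibility.tsv")
        track.to_bedgraph(d / "accessibility.bedgraph")
        contacts.write(d / "contacts.matrix.txt", d / "contacts.bins.tsv")
        event_log.to_tsv(d / "true_events.tsv")
        write_region_bed(self.genome, d / "regions.bed")
        summary = {
            "n_events": len(event_log.records),
            "n_reads": len(reads),
            "n_junction_reads": sum(
                c for r in event_log.records for c in r.read_counts
            ),
        }
        _write_json(summary, d / "summary.json")
        return summary

    def call(self) -> dict:
        cfg = self.config
        d = self._stage_dir("call")
        fastq = self.out / "simulate" / "reads.fastq"
        if not fastq.exists():
            raise PipelineError("call: no reads.fastq; run simulate first")
        result = _caller.process_reads(
            _caller.read_fastq(fastq),
            self.genome,
            min_flank=cfg.min_flank,
            max_mismatch=cfg.max_mismatch,
        )
        _caller.write_events_tsv(result.events, d / "events.tsv")
        result.dispositions.to_csv(d / "read_dispositions.tsv", sep="\t", index=False)
        summary = result.summary()
        _write_json(summary, d / "summary.json")
        return summary

    def _load_events(self):
        import pandas as pd

        path = self.out / "call" / "events.tsv"
        if not path.exists():
            raise PipelineError("classify: no events.tsv; run call first")
        from .events import RearrangementEvent, parse_signature

        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        return [
            RearrangementEvent(
                signature=parse_signature(r.signature),
                read_count=int(r.read_count),
                read_seq=str(r.read_seq),
            )
            for r in df.itertuples(index=False)
        ]

    def classify(self) -> dict:
        d = self._stage_dir("classify")
        events = self._load_events()
        classified = _classify_all(events, self.genome)
        _caller.write_events_tsv([c.event for c in classified], d / "classified_events.tsv")
        summary = _class_summary(classified)
        _write_json(summary, d / "summary.json")
        return summary

    def landscape(self) -> dict:
        d = self._stage_dir("landscape")
        events = self._load_events()
        classified = _classify_all(events, self.genome)
        freq = _landscape.site_frequencies(classified, self.genome)
        binned = _landscape.decile_bins(freq)
        _landscape.write_landscape_tsv(binned, d / "landscape.tsv")
        _landscape.write_spot_bed(binned, self.genome, d / "spots.bed")
        summary: dict = {
            "n_sites": int(len(binned)),
            "n_hotspots": int((binned.label == _landscape.HOTSPOT).sum()),
            "n_coldspots": int((binned.label == _landscape.COLDSPOT).sum()),
        }
        try:
            r, p = _landscape.per_chromosome_correlation(classified, self.genome)
            summary["per_chromosome_r"] = r
            summary["per_chromosome_p"] = p
        except _landscape.LandscapeError as exc:
            summary["per_chromosome_r"] = None
            summary["per_chromosome_note"] = str(exc)
        _write_json(summary, d / "summary.json")
        return summary

    def integrate(self) -> dict:
        cfg = self.config
        d = self._stage_dir("integrate")
        sim = self.out / "simulate"
        for required in ("accessibility.bedgraph", "contacts.matrix.txt"):
            if not (sim / required).exists():
                raise PipelineError(f"integrate: missing {required}; run simulate first")
        track = SignalTrack.from_bedgraph(sim / "accessibility.bedgraph", self.genome)
        contacts = ContactModel.read(
            sim / "contacts.matrix.txt", sim / "contacts.bins.tsv", cfg.bin_size
        )
        profile = _simulate.AccessibilityProfile.from_tsv(sim / "accessibility.tsv")
        events = self._load_events()
        classified = _classify_all(events, self.genome)

        signals = _chromatin.site_signals(track, self.genome, halfwidth=cfg.halfwidth)
        signals.to_csv(d / "site_signals.tsv", sep="\t", index=False)
        pair_table = _chromatin.build_pair_table(
            classified, self.genome, profile, contacts
        )
        pair_table.to_csv(d / "pair_table.tsv", sep="\t", index=False)
        fit = _chromatin.joint_model_fit(pair_table, pseudocount=cfg.pseudocount)
        enrich = _chromatin.region_enrichment(pair_table, self.genome, contacts)
        panels = _chromatin.compensation_pairs(pair_table)
        for name, panel in panels.items():
            panel.to_csv(d / f"compensation_{name}.tsv", sep="\t", index=False)

        binned = _landscape.decile_bins(
            _landscape.site_frequencies(classified, self.genome)
        )
        merged = binned.merge(signals[["site_id", "signal"]], on="site_id")
        hot = merged.loc[merged.label == _landscape.HOTSPOT, "signal"]
        cold = merged.loc[merged.label == _landscape.COLDSPOT, "signal"]
        if len(hot) >= 2 and len(cold) >= 2:
            spot_cmp = _chromatin.group_compare(hot, cold, paired=False)
        else:
            spot_cmp = {"skipped": True, "reason": "fewer than 2 spots per group"}
        summary = {
            "joint_model": fit,
            "region_enrichment": enrich,
            "hotspot_vs_coldspot_signal": spot_cmp,
            "n_pairs": int(len(pair_table)),
        }
        try:
            r, p = _chromatin.heatmap_concordance(pair_table, self.genome, contacts)
            summary["heatmap_concordance_r"] = r
            summary["heatmap_concordance_p"] = p
        except _chromatin.IntegrationError as exc:
            summary["heatmap_concordance_note"] = str(exc)
        _write_json(summary, d / "summary.json")
        return summary

    def run(self, stages=STAGES) -> dict:
        report = {}
        for stage in stages:
            t0 = time.monotonic()
            try:
                report[stage] = getattr(self, stage)()
            except PipelineError:
                raise
            except Exception as exc:  # halt with the failing stage named
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
            log.info("stage %s finished in %.1fs", stage, time.monotonic() - t0)
        _write_json(report, self.out / "report.json")
        return report


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Run the requested stages in dependency order; see :class:`Pipeline`."""
    return Pipeline(config).run(stages)


def make_fixture(profile: str, seed: int, outdir: str | Path) -> dict[str, Path]:
    from .fixtures import make_fixture as _mk

    return _mk(profile, seed, outdir)
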