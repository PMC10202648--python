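#!/usr/bin/env python
"""Simulate a SCRaMbLE pool on the mini genome and call junctions.

Runs the full pipeline (simulate -> call -> classify -> landscape ->
integrate) under the accessibility x contact weight law (alpha = beta = 1)
at ~10^5 reads, writing all stage artifacts under results/mini_run/ and
printing the event-class breakdown by event and read number.
"""

import json
import shutil
from pathlib import Path

from loxscape.fixtures import make_fixture
from loxscape.pipeline import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent
SEED = 1


def main() -> None:
    # stage artifacts (FASTQ, contact matrix, ...) are tens of MB: scratch
    paths = make_fixture("mini", seed=SEED, outdir=ROOT / "scratch" / "fixtures")
    config = RunConfig.from_yaml(paths["config"])
    config.outdir = str(ROOT / "scratch" / "mini_run")
    config.n_cells = 1200
    config.lambda_events = 9.0
    config.reads_per_junction = 7.0
    config.background_reads = 2000
    report = run_pipeline(config)

    # keep the small summary artifacts under results/
    out = ROOT / "results" / "mini_run"
    out.mkdir(parents=True, exist_ok=True)
    shutil.copy(Path(config.outdir) / "report.json", out / "report.json")
    shutil.copy(
        Path(config.outdir) / "landscape" / "landscape.tsv", out / "landscape.tsv"
    )

    call = report["call"]
    print(f"reads: {call['total']}  novel: {call['novel']}  "
          f"reference: {call['reference']}  no-motif: {call['no_motif']}")
    classes = report["classify"]
    for label in ("deletion", "inversion", "complex", "inter"):
        c = classes[label]
        print(f"{label:10s} {c['events']:6d} events ({c['pct_events']:5.2f}%)  "
              f"{c['reads']:6d} reads ({c['pct_reads']:5.2f}%)")
    print(json.dumps(report["landscape"], indent=2))


if __name__ == "__main__":
    main()
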