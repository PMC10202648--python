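"""Per-site rearrangement-frequency landscapes and correlation statistics.

The landscape counts rearrangement *reads* per analyzable loxPsym site:
every junction touches two sites and each endpoint site is credited the
junction's full read count, so total site mass is exactly twice the total
read count. Sites are then ranked into 10% steps; the top decile are
hotspots, the bottom decile coldspots (round-half-up of 0.10*N each side,
so 877 analyzable sites give 88 of each). Ties break by site_id ascending
for determinism.

No multiple-testing correction is applied anywhere; raw two-sided P values
are reported.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .events import ClassifiedEvent
from .genome import GenomeDefinition

HOTSPOT = "hotspot"
COLDSPOT = "coldspot"
NONE = "none"


class LandscapeError(ValueError):
    pass


def site_frequencies(
    classified: list[ClassifiedEvent],
    genome: GenomeDefinition,
    by_reads: bool = True,
) -> pd.DataFrame:
    """Landscape table (site_id, chrom, pos, read_count) over analyzable
    sites. ``by_reads=False`` counts events instead of reads."""
    sites = genome.analyzable_sites()
    ok = {s.site_id for s in sites}
    counts = {s.site_id: 0 for s in sites}
    for c in classified:
        (i, _), (j, _) = c.event.signature
        for sid in (i, j):
            if sid not in ok:
                raise LandscapeError(
                    f"event touches non-analyzable or unknown site {sid}"
                )
        mass = c.event.read_count if by_reads else 1
        counts[i] += mass
        counts[j] += mass
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "read_count": [counts[s.site_id] for s in sites],
        }
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def decile_bins(landscape: pd.DataFrame) -> pd.DataFrame:
    """Attach decile bins (1 = highest frequency) and hotspot/coldspot
    labels to a landscape table."""
    n = len(landscape)
    if n < 10:
        raise LandscapeError("need at least 10 sites for decile binning")
    out = landscape.reset_index(drop=True).copy()
    order = np.lexsort((out.site_id.to_numpy(), -out.read_count.to_numpy()))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    out["decile"] = 1 + (rank * 10) // n
    k = _round_half_up(0.10 * n)
    label = np.full(n, NONE, dtype=object)
    label[rank < k] = HOTSPOT
    label[rank >= n - k] = COLDSPOT
    out["label"] = label
    return out


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided P value from the
    t-transform on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise LandscapeError("pearson needs two equal-length vectors, n >= 3")
    xd, yd = x - x.mean(), y - y.mean()
    sx = math.sqrt(float(xd @ xd))
    sy = math.sqrt(float(yd @ yd))
    if sx == 0.0 or sy == 0.0:
        raise LandscapeError("pearson undefined: zero variance")
    r = float(xd @ yd) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * _stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def per_chromosome_correlation(
    classified: list[ClassifiedEvent],
    genome: GenomeDefinition,
    by_reads: bool = False,
) -> tuple[float, float]:
    """Correlation of loxPsym sites per chromosome against the number of
    rearrangements involving that chromosome (inter events credit both)."""
    chroms = list(genome.chromosomes)
    if len(chroms) < 3:
        raise LandscapeError("need at least 3 chromosomes")
    n_sites = {c: 0 for c in chroms}
    for s in genome.analyzable_sites():
        n_sites[s.chrom] += 1
    n_events = {c: 0 for c in chroms}
    for c in classified:
        (i, _), (j, _) = c.event.signature
        mass = c.event.read_count if by_reads else 1
        touched = {genome.site(i).chrom, genome.site(j).chrom}
        for chrom in touched:
            n_events[chrom] += mass
    return pearson(
        [n_sites[c] for c in chroms], [n_events[c] for c in chroms]
    )


def replicate_correlation(
    landscape_a: pd.DataFrame, landscape_b: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation of two landscapes over a shared site registry."""
    if not landscape_a.site_id.equals(landscape_b.site_id):
        raise LandscapeError("landscapes cover different site registries")
    return pearson(landscape_a.read_count, landscape_b.read_count)


def write_landscape_tsv(landscape: pd.DataFrame, path: str | Path) -> None:
    landscape.to_csv(path, sep="\t", index=False)


def write_spot_bed(
    landscape: pd.DataFrame, genome: GenomeDefinition, path: str | Path
) -> None:
    """Hotspot/coldspot motif intervals as BED (0-based half-open)."""
    m = genome.motif_len
    with open(path, "w") as fh:
        for row in landscape.itertuples(index=False):
            if row.label == NONE:
                continue
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + m}\t{row.label}\t{row.read_count}\n")
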