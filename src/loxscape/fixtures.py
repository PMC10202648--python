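"""Synthetic genome bundles for simulation and testing.

Sequences are pseudo-random nucleotides with a synthetic 34-bp palindromic
motif spliced at declared positions — no real Sc2.0 sequence is shipped.
Three profiles:

* ``toy``       — 2 linear chromosomes, 10 sites; smallest useful genome.
* ``ring``      — 1 circular + 1 linear chromosome; exercises wraparound
  coordinate arithmetic and ring end-adjacency.
* ``paperlike`` — 6 chromosomes including 1 ring, with 894 loxPsym sites of
  which 17 are flagged telomeric (877 analyzable), site counts proportioned
  to chromosome lengths; reproduces the design accounting of a strain
  carrying 5.5 synthetic yeast chromosomes.
* ``mini``      — 6 linear chromosomes, ~200 sites in 600 kb; the working
  scale for stochastic recovery studies (large event pools stay fast while
  per-chromosome site counts still vary).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .genome import (
    CIRCULAR,
    LINEAR,
    ChromosomeSpec,
    GenomeDefinition,
    LoxPsymSite,
    revcomp,
    write_genome,
)

#: synthetic 34-bp palindrome standing in for the (unpublished) loxPsym motif
_HALF = "ACTGGACGTTCAGGCTA"
SYNTHETIC_LOXPSYM = _HALF + revcomp(_HALF)

PROFILES = ("toy", "ring", "paperlike", "mini")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def build_genome(
    chrom_specs: list[ChromosomeSpec],
    site_positions: dict[str, list[tuple[int, bool]]],
    seed: int,
    motif: str = SYNTHETIC_LOXPSYM,
) -> GenomeDefinition:
    """Random sequences with the motif spliced at the declared positions.

    ``site_positions`` maps chromosome name to (pos, telomeric) tuples;
    site_ids are assigned in genome order.
    """
    rng = np.random.default_rng(seed)
    m = len(motif)
    sequences: dict[str, str] = {}
    sites: list[LoxPsymSite] = []
    sid = 0
    for spec in chrom_specs:
        seq = list(_random_seq(rng, spec.length))
        for pos, _tel in sorted(site_positions.get(spec.name, [])):
            seq[pos : pos + m] = motif
        sequences[spec.name] = "".join(seq)
        for pos, tel in sorted(site_positions.get(spec.name, [])):
            sites.append(LoxPsymSite(site_id=sid, chrom=spec.name, pos=pos, telomeric=tel))
            sid += 1
    return GenomeDefinition(
        chromosomes={s.name: s for s in chrom_specs},
        sequences=sequences,
        sites=sites,
        loxpsym_motif=motif,
    )


def _spread(rng: np.random.Generator, lo: int, hi: int, n: int, min_gap: int = 300) -> list[int]:
    """n jittered positions spread over [lo, hi), pairwise gap >= min_gap."""
    base = np.linspace(lo, hi, n, endpoint=False)
    gap = (hi - lo) / max(n, 1)
    jitter = rng.uniform(-0.3, 0.3, size=n) * max(gap - min_gap, 0)
    pos = np.clip(base + jitter, lo, hi - min_gap).astype(int)
    pos.sort()
    for k in range(1, n):  # enforce the gap exactly
        pos[k] = max(pos[k], pos[k - 1] + min_gap)
    return pos.tolist()


def toy_genome(seed: int = 0) -> GenomeDefinition:
    rng = np.random.default_rng(seed)
    specs = [
        ChromosomeSpec("chrA", 60_000, LINEAR, centromere_pos=30_000, telomere_len=500),
        ChromosomeSpec("chrB", 40_000, LINEAR, centromere_pos=20_000, telomere_len=500),
    ]
    positions = {
        "chrA": [(p, False) for p in _spread(rng, 8_000, 52_000, 6, min_gap=2_000)],
        "chrB": [(p, False) for p in _spread(rng, 8_000, 32_000, 4, min_gap=2_000)],
    }
    return build_genome(specs, positions, seed=seed + 1)


def ring_genome(seed: int = 0) -> GenomeDefinition:
    """One ring whose sites flank the sequence origin (former telomeres now
    adjacent) plus one linear control chromosome."""
    rng = np.random.default_rng(seed)
    specs = [
        ChromosomeSpec("ringC", 50_000, CIRCULAR, centromere_pos=25_000),
        ChromosomeSpec("linD", 40_000, LINEAR, centromere_pos=20_000, telomere_len=500),
    ]
    ring_pos = [1_000, 9_000, 17_000, 33_000, 41_000, 48_500]
    positions = {
        "ringC": [(p, False) for p in ring_pos],
        "linD": [(p, False) for p in _spread(rng, 6_000, 34_000, 4, min_gap=2_000)],
    }
    return build_genome(specs, positions, seed=seed + 1)


# paperlike chromosome plan: (name, length, topology, telomeric sites per end)
_PAPERLIKE_PLAN = [
    ("synII", 770_000, LINEAR, 264, 2),
    ("synIII", 272_000, LINEAR, 93, 2),  # 3 telomeric total: 2 left + 1 right
    ("synV", 536_000, LINEAR, 183, 2),
    ("synVI", 242_000, CIRCULAR, 83, 0),
    ("synIXR", 84_000, LINEAR, 29, 1),
    ("synX", 707_000, LINEAR, 242, 2),
]


def paperlike_genome(seed: int = 0) -> GenomeDefinition:
    """894 loxPsym sites over 6 chromosomes (1 ring), 17 telomeric-flagged.

    Site counts are proportioned to chromosome lengths; telomeric sites sit
    inside the 5-kb telomere tracts of the linear chromosomes (the ring has
    none), giving 877 analyzable sites.
    """
    rng = np.random.default_rng(seed)
    tel_len = 5_000
    specs = []
    positions: dict[str, list[tuple[int, bool]]] = {}
    for name, length, topo, n_sites, tel_per_end in _PAPERLIKE_PLAN:
        spec = ChromosomeSpec(
            name,
            length,
            topo,
            centromere_pos=length // 2,
            telomere_len=0 if topo == CIRCULAR else tel_len,
        )
        specs.append(spec)
        tel_positions = []
        if topo == LINEAR:
            left = _spread(rng, 500, tel_len - 500, tel_per_end, min_gap=600)
            n_right = tel_per_end if name != "synIII" else 1
            right = _spread(
                rng, length - tel_len + 500, length - 500, n_right, min_gap=600
            )
            tel_positions = [(p, True) for p in left + right]
        interior_n = n_sites - len(tel_positions)
        lo = tel_len + 2_000 if topo == LINEAR else 1_000
        hi = length - lo
        interior = [(p, False) for p in _spread(rng, lo, hi, interior_n)]
        positions[name] = sorted(tel_positions + interior)
    genome = build_genome(specs, positions, seed=seed + 1)
    assert len(genome.sites) == 894 and len(genome.analyzable_sites()) == 877
    return genome


_MINI_SIZES = [120_000, 90_000, 150_000, 60_000, 100_000, 80_000]


def mini_genome(seed: int = 0) -> GenomeDefinition:
    """6 linear chromosomes, one site per ~3 kb (about 200 sites total)."""
    rng = np.random.default_rng(seed)
    specs, positions = [], {}
    for i, length in enumerate(_MINI_SIZES):
        name = f"chr{i + 1}"
        specs.append(
            ChromosomeSpec(name, length, LINEAR, centromere_pos=length // 2,
                           telomere_len=500)
        )
        n = length // 3_000
        positions[name] = [
            (p, False) for p in _spread(rng, 2_000, length - 2_000, n, min_gap=1_000)
        ]
    return build_genome(specs, positions, seed=seed + 1)


def six_site_genome(seed: int = 0) -> GenomeDefinition:
    """One 40-kb chromosome with 6 sites: the smallest genome on which pair
    sampling statistics are worth testing (15 distinct pairs)."""
    specs = [ChromosomeSpec("chrS", 40_000, LINEAR, centromere_pos=20_500,
                            telomere_len=200)]
    positions = {"chrS": [(p, False) for p in
                          (4_000, 10_000, 16_000, 24_000, 30_000, 36_000)]}
    return build_genome(specs, positions, seed=seed)


def make_genome(profile: str, seed: int = 0) -> GenomeDefinition:
    if profile == "toy":
        return toy_genome(seed)
    if profile == "ring":
        return ring_genome(seed)
    if profile == "paperlike":
        return paperlike_genome(seed)
    if profile == "mini":
        return mini_genome(seed)
    raise ValueError(f"unknown fixture profile {profile!r}; choose from {PROFILES}")


def make_fixture(profile: str, seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write a genome bundle (FASTA + chromosome table + site table) and a
    ready-to-run pipeline config; returns the paths."""
    from .pipeline import RunConfig

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = make_genome(profile, seed)
    paths = {
        "fasta": outdir / f"{profile}.fa",
        "sites": outdir / f"{profile}.sites.tsv",
        "chromosomes": outdir / f"{profile}.chroms.tsv",
        "config": outdir / f"{profile}.config.yaml",
    }
    write_genome(genome, paths["fasta"], paths["sites"], paths["chromosomes"])
    config = RunConfig(
        fasta=str(paths["fasta"]),
        sites=str(paths["sites"]),
        chromosomes=str(paths["chromosomes"]),
        outdir=str(outdir / f"{profile}_run"),
        seed=seed,
    )
    config.to_yaml(paths["config"])
    return paths
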