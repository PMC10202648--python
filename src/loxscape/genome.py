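"""Genome model: chromosomes, loxPsym sites and topology-aware coordinates.

All coordinates are 0-based, half-open. A loxPsym site is anchored at the
start of its 34-bp palindromic motif; distances between sites are measured
motif-start to motif-start. Circular chromosomes wrap; linear chromosomes
truncate at their ends.

Region classes follow the conventions used for budding-yeast contact maps:
pericentromeric (CEN) means within 5 kb of the centromere midpoint (a
centromere-centered 10 kb window), peritelomeric (TEL) means within 5 kb of
a telomere tract on a linear chromosome. CEN takes precedence where the two
windows would overlap; a circular chromosome has no telomeres and never
returns TEL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

LINEAR = "linear"
CIRCULAR = "circular"

CEN = "CEN"
TEL = "TEL"
OTHER = "OTHER"

#: half-width of the pericentromeric window (10 kb centered on the centromere)
CEN_HALFWIDTH = 5_000
#: maximum distance from a telomere tract that still counts as peritelomeric
TEL_MARGIN = 5_000

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeError(ValueError):
    """Raised when a genome definition violates its invariants."""


@dataclass(frozen=True)
class ChromosomeSpec:
    """Static description of one chromosome."""

    name: str
    length: int
    topology: str = LINEAR
    centromere_pos: int = 0
    telomere_len: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GenomeError(f"{self.name}: length must be positive")
        if self.topology not in (LINEAR, CIRCULAR):
            raise GenomeError(f"{self.name}: unknown topology {self.topology!r}")
        if not 0 <= self.centromere_pos < self.length:
            raise GenomeError(f"{self.name}: centromere_pos out of range")
        if self.telomere_len < 0:
            raise GenomeError(f"{self.name}: negative telomere_len")
        if self.topology == CIRCULAR and self.telomere_len != 0:
            raise GenomeError(f"{self.name}: circular chromosome cannot have telomeres")

    @property
    def circular(self) -> bool:
        return self.topology == CIRCULAR


@dataclass(frozen=True)
class LoxPsymSite:
    """A loxPsym motif occurrence, anchored at the motif start."""

    site_id: int
    chrom: str
    pos: int
    telomeric: bool = False


@dataclass
class GenomeDefinition:
    """Chromosome sequences plus the loxPsym site registry.

    Validates on construction: motif windows must equal the motif exactly,
    the motif must be palindromic, sites must be ordered and unique.
    """

    chromosomes: dict[str, ChromosomeSpec]
    sequences: dict[str, str]
    sites: list[LoxPsymSite]
    loxpsym_motif: str
    _by_id: dict[int, LoxPsymSite] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        motif = self.loxpsym_motif.upper()
        if revcomp(motif) != motif:
            raise GenomeError("loxPsym motif must be its own reverse complement")
        object.__setattr__(self, "loxpsym_motif", motif)
        for name, spec in self.chromosomes.items():
            if name not in self.sequences:
                raise GenomeError(f"missing sequence for chromosome {name}")
            if len(self.sequences[name]) != spec.length:
                raise GenomeError(
                    f"{name}: sequence length {len(self.sequences[name])} "
                    f"!= declared length {spec.length}"
                )
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}
        seen_ids: set[int] = set()
        last_pos: dict[str, int] = {}
        m = len(motif)
        for site in self.sites:
            if site.site_id in seen_ids:
                raise GenomeError(f"duplicate site_id {site.site_id}")
            seen_ids.add(site.site_id)
            if site.chrom not in self.chromosomes:
                raise GenomeError(f"site {site.site_id}: unknown chromosome {site.chrom}")
            spec = self.chromosomes[site.chrom]
            if not 0 <= site.pos <= spec.length - m:
                raise GenomeError(
                    f"site {site.site_id}: motif interval outside {site.chrom}"
                )
            if site.chrom in last_pos and site.pos <= last_pos[site.chrom]:
                raise GenomeError(
                    f"site {site.site_id}: sites on {site.chrom} not strictly ordered"
                )
            last_pos[site.chrom] = site.pos
            window = self.sequences[site.chrom][site.pos : site.pos + m]
            if window != motif:
                raise GenomeError(
                    f"site {site.site_id}: sequence window at {site.chrom}:{site.pos} "
                    f"does not match the loxPsym motif"
                )
        self._by_id = {s.site_id: s for s in self.sites}

    # -- lookups ---------------------------------------------------------

    @property
    def motif_len(self) -> int:
        return len(self.loxpsym_motif)

    def site(self, site_id: int) -> LoxPsymSite:
        try:
            return self._by_id[site_id]
        except KeyError:
            raise GenomeError(f"unknown site_id {site_id}") from None

    def sites_on(self, chrom: str) -> list[LoxPsymSite]:
        return [s for s in self.sites if s.chrom == chrom]

    def analyzable_sites(self) -> list[LoxPsymSite]:
        """Sites usable for rearrangement-read identification.

        Telomeric loxPsym sites sit in repeated telomere sequence whose
        flanks cannot be mapped uniquely, so they are excluded from every
        landscape computation.
        """
        return [s for s in self.sites if not s.telomeric]

    # -- coordinate arithmetic ------------------------------------------

    def genomic_distance(self, chrom: str, a: int, b: int) -> int:
        spec = self.chromosomes[chrom]
        for x in (a, b):
            if not 0 <= x < spec.length:
                raise GenomeError(f"{chrom}: coordinate {x} out of range")
        d = abs(a - b)
        if spec.circular:
            d = min(d, spec.length - d)
        return d

    def region_class(self, chrom: str, pos: int) -> str:
        spec = self.chromosomes[chrom]
        if not 0 <= pos < spec.length:
            raise GenomeError(f"{chrom}: coordinate {pos} out of range")
        if self.genomic_distance(chrom, pos, spec.centromere_pos) <= CEN_HALFWIDTH:
            return CEN
        if not spec.circular:
            # telomere tracts occupy [0, tel) and [len-tel, len)
            t = spec.telomere_len + TEL_MARGIN
            if pos < t or pos >= spec.length - t:
                return TEL
        return OTHER

    def site_flanks(self, site: LoxPsymSite, flank_len: int) -> tuple[str, str]:
        """Reference sequence immediately 5' and 3' of the motif.

        Circular chromosomes wrap through the origin; linear chromosomes
        return a truncated flank near an end.
        """
        if flank_len < 1:
            raise GenomeError("flank_len must be >= 1")
        seq = self.sequences[site.chrom]
        n = len(seq)
        m = self.motif_len
        if self.chromosomes[site.chrom].circular:
            left = "".join(seq[(site.pos - flank_len + k) % n] for k in range(flank_len))
            right = "".join(seq[(site.pos + m + k) % n] for k in range(flank_len))
        else:
            left = seq[max(0, site.pos - flank_len) : site.pos]
            right = seq[site.pos + m : site.pos + m + flank_len]
        return left, right


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

MOTIF_DIRECTIVE = "#loxpsym_motif="


def load_genome(
    fasta_path: str | Path,
    sites_table_path: str | Path,
    chrom_table_path: str | Path,
) -> GenomeDefinition:
    """Load and validate a genome definition from its three text files.

    ``fasta_path``: one record per chromosome. ``chrom_table_path``: TSV with
    columns name, length, topology, centromere_pos, telomere_len.
    ``sites_table_path``: TSV with columns chrom, pos, site_id, telomeric,
    preceded by a ``#loxpsym_motif=<seq>`` directive line.

    Any invariant violation is rejected with a :class:`GenomeError` naming
    the offending record; nothing is repaired silently.
    """
    chromosomes: dict[str, ChromosomeSpec] = {}
    with open(chrom_table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            spec = ChromosomeSpec(
                name=row["name"],
                length=int(row["length"]),
                topology=row["topology"],
                centromere_pos=int(row["centromere_pos"]),
                telomere_len=int(row["telomere_len"]),
            )
            chromosomes[spec.name] = spec

    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sequences[rec.id] = str(rec.seq).upper()
    for name in chromosomes:
        if name not in sequences:
            raise GenomeError(f"FASTA is missing chromosome {name}")

    motif = None
    sites: list[LoxPsymSite] = []
    with open(sites_table_path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(MOTIF_DIRECTIVE):
                motif = line[len(MOTIF_DIRECTIVE) :].strip().upper()
                continue
            if line.startswith("#") or not line.strip():
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            sites.append(
                LoxPsymSite(
                    site_id=int(row["site_id"]),
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    telomeric=row["telomeric"] in ("1", "True", "true"),
                )
            )
    if motif is None:
        raise GenomeError(f"{sites_table_path}: missing {MOTIF_DIRECTIVE} directive")

    return GenomeDefinition(
        chromosomes=chromosomes, sequences=sequences, sites=sites, loxpsym_motif=motif
    )


def write_genome(
    genome: GenomeDefinition,
    fasta_path: str | Path,
    sites_table_path: str | Path,
    chrom_table_path: str | Path,
) -> None:
    """Write the three genome-definition files read by :func:`load_genome`."""
    with open(fasta_path, "w") as fh:
        for name in genome.chromosomes:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(chrom_table_path, "w") as fh:
        fh.write("name\tlength\ttopology\tcentromere_pos\ttelomere_len\n")
        for spec in genome.chromosomes.values():
            fh.write(
                f"{spec.name}\t{spec.length}\t{spec.topology}\t"
                f"{spec.centromere_pos}\t{spec.telomere_len}\n"
            )
    with open(sites_table_path, "w") as fh:
        fh.write(f"{MOTIF_DIRECTIVE}{genome.loxpsym_motif}\n")
        fh.write("chrom\tpos\tsite_id\ttelomeric\n")
        for s in genome.sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.site_id}\t{int(s.telomeric)}\n")


def write_region_bed(genome: GenomeDefinition, path: str | Path) -> None:
    """BED of pericentromeric and peritelomeric windows (0-based half-open)."""
    with open(path, "w") as fh:
        for spec in genome.chromosomes.values():
            c0 = max(0, spec.centromere_pos - CEN_HALFWIDTH)
            c1 = min(spec.length, spec.centromere_pos + CEN_HALFWIDTH + 1)
            fh.write(f"{spec.name}\t{c0}\t{c1}\tCEN\n")
            if not spec.circular:
                t = spec.telomere_len + TEL_MARGIN
                fh.write(f"{spec.name}\t0\t{min(t, spec.length)}\tTEL\n")
                fh.write(f"{spec.name}\t{max(0, spec.length - t)}\t{spec.length}\tTEL\n")


def fetch_wrapped(genome: GenomeDefinition, chrom: str, start: int, length: int) -> str:
    """Sequence of ``length`` bases from ``start``, wrapping on circular
    chromosomes and truncating at the ends of linear ones. ``start`` may be
    negative on circular chromosomes."""
    seq = genome.sequences[chrom]
    n = len(seq)
    if genome.chromosomes[chrom].circular:
        start %= n
        if start + length <= n:
            return seq[start : start + length]
        out = seq[start:]
        while len(out) < length:
            out += seq[: length - len(out)]
        return out
    return seq[max(0, start) : max(0, start + length)]
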