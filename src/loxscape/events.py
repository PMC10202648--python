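"""Junction signatures and rearrangement events.

A loxPsym junction is fully described by the unordered pair of reference
*sides* flanking the recombined motif. Each side is ``(site_id, 'L'|'R')``:
``L`` is the reference sequence immediately 5' of that site's motif, ``R``
immediately 3'. Because the motif is palindromic, a junction read and its
reverse complement describe the same side pair, so the unordered pair is the
canonical, strand-free signature:

* reference junction at site s      -> {(s,L), (s,R)}
* deletion between i<j (intra)      -> {(i,L), (j,R)}
* excision circle / duplication     -> {(j,L), (i,R)}  (downstream L joined
  to upstream R in reference orientation)
* inversion between i,j             -> {(i,L), (j,L)} and {(i,R), (j,R)}
* reciprocal translocation          -> one L/R side from each chromosome
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import GenomeDefinition, revcomp

LEFT = "L"
RIGHT = "R"

Side = tuple[int, str]  # (site_id, LEFT | RIGHT)
Signature = tuple[Side, Side]  # sorted lexicographically


def signature(a: Side, b: Side) -> Signature:
    """Canonical (sorted) unordered side pair."""
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def is_reference(sig: Signature) -> bool:
    (i, si), (j, sj) = sig
    return i == j and {si, sj} == {LEFT, RIGHT}


def format_signature(sig: Signature) -> str:
    return ";".join(f"{sid}{side}" for sid, side in sig)


def parse_signature(text: str) -> Signature:
    parts = text.split(";")
    sides = tuple((int(p[:-1]), p[-1]) for p in parts)
    return signature(*sides)


def side_sequence_toward_motif(
    genome: GenomeDefinition, side: Side, length: int
) -> str:
    """Sequence presented by a side when it forms the 5' part of a junction
    read (ends at the motif boundary)."""
    site = genome.site(side[0])
    left, right = genome.site_flanks(site, length)
    return left if side[1] == LEFT else revcomp(right)


def side_sequence_from_motif(genome: GenomeDefinition, side: Side, length: int) -> str:
    """Sequence presented by a side when it forms the 3' part of a junction
    read (starts at the motif boundary)."""
    site = genome.site(side[0])
    left, right = genome.site_flanks(site, length)
    return right if side[1] == RIGHT else revcomp(left)


def junction_read(
    genome: GenomeDefinition,
    left_side: Side,
    right_side: Side,
    left_len: int,
    right_len: int,
) -> str:
    """Reconstruct the junction-spanning sequence ``flank + motif + flank``.

    Reading the two sides in the opposite order yields the reverse
    complement — the same molecule.
    """
    return (
        side_sequence_toward_motif(genome, left_side, left_len)
        + genome.loxpsym_motif
        + side_sequence_from_motif(genome, right_side, right_len)
    )


# rearrangement event classes (Fig-style grouping: intra splits into
# deletion / inversion / complex; everything between chromosomes is inter)
DELETION = "deletion"
INVERSION = "inversion"
COMPLEX = "complex"
INTER = "inter"
CLASSES = (DELETION, INVERSION, COMPLEX, INTER)


@dataclass
class RearrangementEvent:
    """A deduplicated novel junction: one unique read sequence.

    Distinct read sequences supporting the same junction remain separate
    events but share ``signature``, so tallies by event count and by read
    count are both available.
    """

    signature: Signature
    read_count: int
    read_seq: str = ""
    event_class: str | None = None

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        self.signature = signature(*self.signature)


@dataclass
class ClassifiedEvent:
    event: RearrangementEvent
    event_class: str
    intra: bool

    def __post_init__(self) -> None:
        if self.event_class not in CLASSES:
            raise ValueError(f"unknown class {self.event_class}")
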