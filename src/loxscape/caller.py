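"""Junction caller: motif scan, exact flank mapping, junction resolution.

Every read is assigned exactly one disposition:

* ``no_motif``      — no loxPsym motif within the mismatch budget
* ``reference``     — both flanks are the two reference flanks of one site
* ``novel``         — flanks abut two different site sides (a rearrangement)
* ``unresolvable``  — a flank is too short, ambiguous, unmapped, or does
  not end exactly at a motif boundary

Because the motif is palindromic, a read and its reverse complement
describe the same junction; reads are canonicalized to the
lexicographically smaller of the two before anything else, so counting is
strand-consistent and identical molecules collapse in deduplication.

Flank mapping is exact-match (anchored on the first ``min_flank``-mer, then
verified over the full flank); there is no gapped alignment. A substitution
inside a flank therefore yields ``unresolvable``, never a wrong signature.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from .events import (
    LEFT,
    RIGHT,
    RearrangementEvent,
    Side,
    Signature,
    format_signature,
    is_reference,
    signature,
)
from .genome import GenomeDefinition, fetch_wrapped, revcomp

AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"

NO_MOTIF = "no_motif"
REFERENCE = "reference"
NOVEL = "novel"
UNRESOLVABLE = "unresolvable"
DISPOSITIONS = (NO_MOTIF, REFERENCE, NOVEL, UNRESOLVABLE)


def scan_motif(read_seq: str, motif: str, max_mismatch: int = 0) -> int | None:
    """Leftmost offset where the motif occurs with Hamming distance <=
    ``max_mismatch``; None if absent or the read is shorter than the motif.

    The motif is palindromic, so scanning one strand suffices.
    """
    m = len(motif)
    if len(read_seq) < m:
        return None
    exact = read_seq.find(motif)
    if max_mismatch <= 0:
        return exact if exact >= 0 else None
    arr = np.frombuffer(read_seq.encode(), dtype=np.uint8)
    pat = np.frombuffer(motif.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    mism = (windows != pat).sum(axis=1)
    if exact >= 0:
        mism = mism[: exact + 1]  # an exact hit cannot be beaten, only preempted
    hits = np.flatnonzero(mism <= max_mismatch)
    return int(hits[0]) if hits.size else None


@dataclass(frozen=True)
class Locus:
    """An exact flank placement: the flank equals the forward-strand
    reference over [pos, pos+len) (strand +1) or its reverse complement
    (strand -1)."""

    chrom: str
    pos: int
    strand: int


class FlankIndex:
    """Exact-match index over both strands of all chromosomes.

    Anchored on ``k = min_flank``-mers of the forward sequence (circular
    chromosomes are indexed through the origin); a query collects the
    candidate placements of its first k-mer — on the forward strand
    directly, on the reverse strand via the query's reverse complement —
    and verifies the full flank at each.
    """

    def __init__(self, genome: GenomeDefinition, min_flank: int = 20):
        self.genome = genome
        self.k = min_flank
        self._kmers: dict[str, list[tuple[str, int]]] = defaultdict(list)
        k = self.k
        for name, spec in genome.chromosomes.items():
            seq = genome.sequences[name]
            indexed = seq + seq[: k - 1] if spec.circular else seq
            n = len(seq)
            for i in range(len(indexed) - k + 1):
                self._kmers[indexed[i : i + k]].append((name, i % n))

    def _occurrences(self, flank: str) -> list[tuple[str, int]]:
        out = []
        for chrom, pos in self._kmers.get(flank[: self.k], ()):
            if fetch_wrapped(self.genome, chrom, pos, len(flank)) == flank:
                out.append((chrom, pos))
        return out

    def map_flank(self, flank_seq: str) -> Locus | str:
        """Unique exact occurrence -> Locus; several -> ``ambiguous``; none
        (or flank shorter than min_flank) -> ``unmapped``."""
        if len(flank_seq) < self.k:
            return UNMAPPED
        fwd = self._occurrences(flank_seq)
        rev = self._occurrences(revcomp(flank_seq))
        total = len(fwd) + len(rev)
        if total == 0:
            return UNMAPPED
        if total > 1:
            return AMBIGUOUS
        if fwd:
            chrom, pos = fwd[0]
            return Locus(chrom, pos, +1)
        chrom, pos = rev[0]
        return Locus(chrom, pos, -1)


@dataclass
class JunctionObservation:
    """One motif-bearing read with both flanks mapped."""

    read_id: str
    read_seq: str  # canonical orientation
    motif_offset: int
    left_locus: Locus | str
    right_locus: Locus | str
    left_len: int
    right_len: int


def _resolve_side(
    genome: GenomeDefinition, locus: Locus, flank_len: int, which: str
) -> Side | None:
    """Side of a registered site that a mapped flank abuts (tolerance 0),
    or None if the flank does not end exactly at a motif boundary."""
    m = genome.motif_len
    spec = genome.chromosomes[locus.chrom]
    sites = {s.pos: s for s in genome.sites_on(locus.chrom)}

    def site_at(pos: int):
        if spec.circular:
            pos %= spec.length
        return sites.get(pos)

    if which == "left":
        if locus.strand > 0:  # flank ends at pos+len; motif must start there
            s = site_at(locus.pos + flank_len)
            return (s.site_id, LEFT) if s else None
        s = site_at(locus.pos - m)  # reverse: motif precedes the interval
        return (s.site_id, RIGHT) if s else None
    # right flank
    if locus.strand > 0:  # motif must end where the flank starts
        s = site_at(locus.pos - m)
        return (s.site_id, RIGHT) if s else None
    s = site_at(locus.pos + flank_len)
    return (s.site_id, LEFT) if s else None


def call_junction(
    obs: JunctionObservation, genome: GenomeDefinition
) -> tuple[str, Signature | None]:
    """Classify one observation as reference / novel / unresolvable.

    Novel means both flanks map uniquely and abut registered motif
    boundaries, and the two sides are not the two reference flanks of a
    single site.
    """
    if not isinstance(obs.left_locus, Locus) or not isinstance(obs.right_locus, Locus):
        return UNRESOLVABLE, None
    left = _resolve_side(genome, obs.left_locus, obs.left_len, "left")
    right = _resolve_side(genome, obs.right_locus, obs.right_len, "right")
    if left is None or right is None:
        return UNRESOLVABLE, None
    sig = signature(left, right)
    if is_reference(sig):
        return REFERENCE, sig
    return NOVEL, sig


@dataclass
class CallResult:
    """Per-read dispositions plus deduplicated novel events."""

    dispositions: pd.DataFrame  # read_id, disposition, signature
    events: list[RearrangementEvent]
    n_reads: int

    def summary(self) -> dict[str, int]:
        counts = Counter(self.dispositions.disposition)
        out = {d: int(counts.get(d, 0)) for d in DISPOSITIONS}
        out["total"] = self.n_reads
        out["events"] = len(self.events)
        return out

    def signature_read_counts(self) -> dict[Signature, int]:
        out: dict[Signature, int] = {}
        for ev in self.events:
            out[ev.signature] = out.get(ev.signature, 0) + ev.read_count
        return out


def dedupe(observations: Iterable[tuple[str, Signature]]) -> list[RearrangementEvent]:
    """Collapse identical (canonical) read sequences into single events.

    Identical reads are one rearrangement event with ``read_count`` equal
    to their multiplicity; distinct reads over the same junction remain
    separate events sharing a signature, so tallies by event number and by
    read number are both reproducible.
    """
    groups: dict[str, tuple[Signature, int]] = {}
    for seq, sig in observations:
        if seq in groups:
            prev_sig, n = groups[seq]
            groups[seq] = (prev_sig, n + 1)
        else:
            groups[seq] = (sig, 1)
    return [
        RearrangementEvent(signature=sig, read_count=n, read_seq=seq)
        for seq, (sig, n) in sorted(groups.items())
    ]


def process_reads(
    reads: Iterable[tuple[str, str]],
    genome: GenomeDefinition,
    index: FlankIndex | None = None,
    min_flank: int = 20,
    max_mismatch: int = 0,
) -> CallResult:
    """Run the full caller over (read_id, sequence) pairs.

    Output is invariant to input read order up to row ordering of the
    per-read table; events are sorted by canonical read sequence.
    """
    if index is None:
        index = FlankIndex(genome, min_flank)
    motif = genome.loxpsym_motif
    m = len(motif)
    rows = []
    novel_obs: list[tuple[str, Signature]] = []
    n_reads = 0
    for read_id, raw in reads:
        n_reads += 1
        seq = min(raw.upper(), revcomp(raw.upper()))
        off = scan_motif(seq, motif, max_mismatch)
        if off is None:
            rows.append((read_id, NO_MOTIF, ""))
            continue
        left, right = seq[:off], seq[off + m :]
        obs = JunctionObservation(
            read_id=read_id,
            read_seq=seq,
            motif_offset=off,
            left_locus=index.map_flank(left) if len(left) >= min_flank else UNMAPPED,
            right_locus=index.map_flank(right) if len(right) >= min_flank else UNMAPPED,
            left_len=len(left),
            right_len=len(right),
        )
        disp, sig = call_junction(obs, genome)
        rows.append((read_id, disp, format_signature(sig) if sig else ""))
        if disp == NOVEL:
            novel_obs.append((seq, sig))
    dispositions = pd.DataFrame(rows, columns=["read_id", "disposition", "signature"])
    return CallResult(
        dispositions=dispositions, events=dedupe(novel_obs), n_reads=n_reads
    )


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """(read_id, sequence) pairs from a FASTQ file (gzip allowed)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq)


def write_events_tsv(events: list[RearrangementEvent], path: str | Path) -> None:
    rows = [
        {
            "signature": format_signature(ev.signature),
            "class": ev.event_class or "",
            "read_count": ev.read_count,
            "read_seq": ev.read_seq,
        }
        for ev in events
    ]
    pd.DataFrame(
        rows, columns=["signature", "class", "read_count", "read_seq"]
    ).to_csv(path, sep="\t", index=False)
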