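"""Rearrangement classes from junction signatures, plus a surgery oracle.

Classification is purely positional, from the two (site, side) endpoints:

* different chromosomes                      -> ``inter``
* same chromosome, L/L or R/R join           -> ``inversion``
* same chromosome, L of i joined to R of j:
    - i before j (reference order)           -> ``deletion``
    - j before i                             -> ``complex`` (the junction is
      consistent with a duplication or an excision circle; a single
      junction read cannot distinguish the two, so they share one bucket)

On circular chromosomes "before" uses the modular order anchored at the
sequence origin, and an L/R join takes the label of the shorter arc: the
arc running forward from the L-endpoint to the R-endpoint is the deleted
one, so the junction is a deletion when that arc is the shorter of the two.

:func:`enumerate_cre_products` provides the independent check: it builds
every single-event Cre product by direct sequence surgery on the reference,
rediscovers each product's novel junction by motif scanning and flank
lookup on the product sequence, and labels it by the product that created
it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .events import (
    COMPLEX,
    DELETION,
    INTER,
    INVERSION,
    LEFT,
    RIGHT,
    ClassifiedEvent,
    RearrangementEvent,
    Signature,
    is_reference,
    signature,
)
from .genome import GenomeDefinition, GenomeError, revcomp


class ClassificationError(ValueError):
    """Endpoint does not correspond to a registered loxPsym site."""


def classify_signature(sig: Signature, genome: GenomeDefinition) -> tuple[str, bool]:
    """(class label, intra flag) for a novel junction signature."""
    (i, si), (j, sj) = sig
    try:
        site_i, site_j = genome.site(i), genome.site(j)
    except GenomeError as exc:
        raise ClassificationError(str(exc)) from exc
    if is_reference(sig):
        raise ClassificationError("reference junction is not classifiable")
    if site_i.chrom != site_j.chrom:
        return INTER, False
    if si == sj:
        return INVERSION, True
    # exactly one L and one R endpoint on one chromosome
    (u, v) = (site_i, site_j) if si == LEFT else (site_j, site_i)
    spec = genome.chromosomes[u.chrom]
    if not spec.circular:
        return (DELETION, True) if u.pos < v.pos else (COMPLEX, True)
    # ring: the junction deletes the forward arc u -> v; shorter arc wins
    fwd = (v.pos - u.pos) % spec.length
    return (DELETION, True) if fwd <= spec.length - fwd else (COMPLEX, True)


def classify(
    event: RearrangementEvent, genome: GenomeDefinition
) -> ClassifiedEvent:
    label, intra = classify_signature(event.signature, genome)
    event.event_class = label
    return ClassifiedEvent(event=event, event_class=label, intra=intra)


def classify_all(
    events: list[RearrangementEvent], genome: GenomeDefinition
) -> list[ClassifiedEvent]:
    return [classify(ev, genome) for ev in events]


def class_summary(classified: list[ClassifiedEvent]) -> dict:
    """Counts and percentages per class, by event number and read number."""
    out: dict = {}
    total_ev = len(classified)
    total_reads = sum(c.event.read_count for c in classified)
    for label in (DELETION, INVERSION, COMPLEX, INTER):
        evs = [c for c in classified if c.event_class == label]
        n_ev = len(evs)
        n_rd = sum(c.event.read_count for c in evs)
        out[label] = {
            "events": n_ev,
            "reads": n_rd,
            "pct_events": 100.0 * n_ev / total_ev if total_ev else 0.0,
            "pct_reads": 100.0 * n_rd / total_reads if total_reads else 0.0,
        }
    out["total"] = {"events": total_ev, "reads": total_reads}
    return out


# ---------------------------------------------------------------------------
# brute-force Cre product oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CreProduct:
    """One single-event Cre product: its label and the novel junction(s) it
    creates."""

    label: str
    product: str  # deletion_chromosome | excision_circle | inversion | translocation_a/b
    signatures: tuple[Signature, ...]


def _novel_junctions_in(
    seq: str, circular: bool, genome: GenomeDefinition, flank_probe: int = 30
) -> list[Signature]:
    """Find every loxPsym junction in a product sequence by scanning for
    exact motif occurrences and matching the probe flanks against each
    registered site's reference flanks (both orientations)."""
    motif = genome.loxpsym_motif
    m = len(motif)
    sides_toward = {}  # sequence ending at a motif boundary -> side
    sides_from = {}
    for s in genome.sites:
        lf, rf = genome.site_flanks(s, flank_probe)
        sides_toward[lf] = (s.site_id, LEFT)
        sides_toward[revcomp(rf)] = (s.site_id, RIGHT)
        sides_from[rf] = (s.site_id, RIGHT)
        sides_from[revcomp(lf)] = (s.site_id, LEFT)
    scan = seq + seq[: m + flank_probe] if circular else seq
    out = []
    start = 0
    while True:
        off = scan.find(motif, start)
        if off < 0 or off >= len(seq):
            break
        start = off + 1
        if circular:
            left = "".join(seq[(off - flank_probe + k) % len(seq)] for k in range(flank_probe))
            right = "".join(seq[(off + m + k) % len(seq)] for k in range(flank_probe))
        else:
            left = seq[max(0, off - flank_probe) : off]
            right = seq[off + m : off + m + flank_probe]
        a = sides_toward.get(left)
        b = sides_from.get(right)
        if a is None or b is None:
            continue
        sig = signature(a, b)
        if not is_reference(sig):
            out.append(sig)
    return out


def enumerate_cre_products(
    genome: GenomeDefinition, site_i: int, site_j: int
) -> list[CreProduct]:
    """All single-event Cre products for a site pair, by sequence surgery.

    Intra pair on a linear chromosome: the deletion chromosome, the excised
    circle (labelled ``complex`` — its junction is the
    duplication/circularization-consistent join) and the inversion product
    (two junctions): four distinct novel signatures in total. Intra on a
    ring: two excision circles (labels follow the deleted-arc convention:
    shorter deleted arc -> ``deletion``) and the inversion product. Inter
    pair: the two chromosomes of the direct reciprocal translocation, one
    novel junction each.
    """
    a, b = genome.site(site_i), genome.site(site_j)
    if a.site_id == b.site_id:
        raise ClassificationError("need two distinct sites")
    motif = genome.loxpsym_motif
    m = len(motif)
    products: list[CreProduct] = []

    if a.chrom == b.chrom:
        spec = genome.chromosomes[a.chrom]
        seq = genome.sequences[a.chrom]
        u, v = (a, b) if a.pos < b.pos else (b, a)
        if not spec.circular:
            pre, mid, post = seq[: u.pos], seq[u.pos + m : v.pos], seq[v.pos + m :]
            del_chrom = pre + motif + post
            circle = motif + mid
            inv = pre + motif + revcomp(mid) + motif + post
            products.append(
                CreProduct(
                    DELETION,
                    "deletion_chromosome",
                    tuple(_novel_junctions_in(del_chrom, False, genome)),
                )
            )
            products.append(
                CreProduct(
                    COMPLEX,
                    "excision_circle",
                    tuple(_novel_junctions_in(circle, True, genome)),
                )
            )
            products.append(
                CreProduct(
                    INVERSION,
                    "inversion",
                    tuple(_novel_junctions_in(inv, False, genome)),
                )
            )
        else:
            L = len(seq)
            arc_uv = seq[u.pos + m : v.pos]  # forward arc u -> v
            arc_vu = seq[v.pos + m :] + seq[: u.pos]  # forward arc v -> u
            circle_uv = motif + arc_uv  # deletes arc v -> u
            circle_vu = motif + arc_vu  # deletes arc u -> v
            for circ, deleted_len in ((circle_uv, L - m - len(arc_uv)),
                                      (circle_vu, L - m - len(arc_vu))):
                label = DELETION if deleted_len <= L - deleted_len else COMPLEX
                products.append(
                    CreProduct(
                        label,
                        "excision_circle",
                        tuple(_novel_junctions_in(circ, True, genome)),
                    )
                )
            inv = (
                seq[: u.pos] + motif + revcomp(arc_uv) + motif + seq[v.pos + m :]
            )
            products.append(
                CreProduct(
                    INVERSION,
                    "inversion",
                    tuple(_novel_junctions_in(inv, True, genome)),
                )
            )
    else:
        seq_a, seq_b = genome.sequences[a.chrom], genome.sequences[b.chrom]
        chrom_1 = seq_a[: a.pos] + motif + seq_b[b.pos + m :]
        chrom_2 = seq_b[: b.pos] + motif + seq_a[a.pos + m :]
        for name, prod in (("translocation_a", chrom_1), ("translocation_b", chrom_2)):
            products.append(
                CreProduct(
                    INTER, name, tuple(_novel_junctions_in(prod, False, genome))
                )
            )
    return products
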