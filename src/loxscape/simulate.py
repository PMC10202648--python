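"""Cre/loxPsym recombination simulator.

Generates everything the analysis consumes, synthetically: per-site
accessibility weights with a matching per-base track, a binned contact
matrix with intra-chromosomal distance decay plus centromere/telomere
cluster enrichment, recombination events whose pair choice is biased by
accessibility and spatial contact, and junction-spanning 150-bp reads.

The pair-selection law is the minimal positive, symmetric, separable form

    w_ij = (a_i * a_j)**alpha * C(bin_i, bin_j)**beta

with ``a`` the latent per-site accessibility and ``C`` the contact
probability; ``alpha = beta = 0`` recovers uniform pair choice.

Two modes:

* ``junction_pool`` (default): every event is recorded against the fixed
  reference — the right regime for testing the junction caller and the
  landscape statistics, independent of population dynamics.
* ``genome_sequential``: events are applied in order to an evolving
  segmented genome per cell; cells ending with an acentric or dicentric
  chromosome are discarded as dead (one-centromere viability rule).
  Excised circles are assumed lost before sequencing.

All randomness flows from one ``numpy`` generator seeded by
``SimConfig.seed``, in documented draw order, so every output is
reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genome import GenomeDefinition, LoxPsymSite, revcomp
from .tracks import ContactModel, SignalTrack, make_bins
from .events import (
    LEFT,
    RIGHT,
    Side,
    Signature,
    format_signature,
    junction_read,
    parse_signature,
    signature,
)

DELETION = "deletion"
INVERSION = "inversion"
TRANSLOCATION = "translocation"


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# accessibility
# ---------------------------------------------------------------------------


@dataclass
class AccessibilityProfile:
    """Latent per-site accessibility weights (positive, arbitrary units)."""

    a: dict[int, float]

    def __post_init__(self) -> None:
        for sid, v in self.a.items():
            if not np.isfinite(v) or v <= 0:
                raise SimulationError(f"site {sid}: accessibility must be positive")

    def __getitem__(self, site_id: int) -> float:
        return self.a[site_id]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"site_id": list(self.a), "accessibility": list(self.a.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AccessibilityProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df.site_id.astype(int), df.accessibility)))


def synth_accessibility(
    genome: GenomeDefinition,
    seed: int,
    open_fraction: float = 0.2,
    sigma: float = 0.75,
    open_boost: float = 8.0,
    peak_scale: float = 200.0,
    peak_sd: float = 120.0,
    halfwidth: int = 400,
    background: float = 0.05,
    flat: bool = False,
) -> tuple[AccessibilityProfile, SignalTrack]:
    """Draw per-site weights and lay a matching ATAC-like per-base track.

    Weights are log-normal; a randomly designated "open" fraction of sites
    is boosted by ``open_boost``. The track is low uniform background noise
    plus one Gaussian peak per site (sd ``peak_sd`` bp, clipped to the
    site-centered ±``halfwidth`` window) whose integral is proportional to
    the site's weight. ``flat=True`` gives the degenerate equal-weight case.
    """
    if not 0 < open_fraction < 1:
        raise SimulationError("open_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    sites = genome.sites
    n = len(sites)
    if flat:
        a = np.ones(n)
    else:
        a = rng.lognormal(mean=0.0, sigma=sigma, size=n)
        n_open = max(1, round(open_fraction * n))
        open_idx = rng.choice(n, size=n_open, replace=False)
        a[open_idx] *= open_boost
    profile = AccessibilityProfile({s.site_id: float(v) for s, v in zip(sites, a)})

    values = {
        name: rng.uniform(0.0, background, size=spec.length)
        for name, spec in genome.chromosomes.items()
    }
    half = genome.motif_len // 2
    for s, amp in zip(sites, a):
        arr = values[s.chrom]
        m = arr.size
        center = s.pos + half
        offs = np.arange(-halfwidth, halfwidth)
        peak = peak_scale * float(amp) * norm.pdf(offs, scale=peak_sd)
        if genome.chromosomes[s.chrom].circular:
            arr[(center + offs) % m] += peak
        else:
            ok = (center + offs >= 0) & (center + offs < m)
            arr[center + offs[ok]] += peak[ok]
    return profile, SignalTrack(values)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def synth_contacts(
    genome: GenomeDefinition,
    bin_size: int = 1000,
    gamma: float = 1.0,
    kappa: float = 0.01,
    boost_cen: float = 4.0,
    boost_tel: float = 4.0,
) -> ContactModel:
    """Contact matrix with power-law intra-chromosomal distance decay.

    Intra-chromosomal entries are ``(1 + d)**-gamma`` with ``d`` the
    topology-aware bin distance (circular chromosomes wrap, making the two
    former ends adjacent). Inter-chromosomal entries start at the baseline
    ``kappa``. Entries whose two bins are both pericentromeric are
    multiplied by ``boost_cen`` (spindle-pole clustering); both
    peritelomeric, by ``boost_tel`` (nuclear-envelope clustering).
    """
    bins = make_bins(genome, bin_size)
    n = len(bins)
    C = np.full((n, n), kappa)
    offsets: dict[str, tuple[int, int]] = {}
    for chrom, grp in bins.groupby("chrom", sort=False):
        offsets[chrom] = (int(grp.index.min()), int(grp.index.max()) + 1)
    for chrom, (lo, hi) in offsets.items():
        k = hi - lo
        idx = np.arange(k)
        d = np.abs(idx[:, None] - idx[None, :])
        if genome.chromosomes[chrom].circular:
            d = np.minimum(d, k - d)
        C[lo:hi, lo:hi] = (1.0 + d) ** (-gamma)
    mid = ((bins.start + bins.end) // 2).to_numpy()
    rc = np.array(
        [genome.region_class(c, int(p)) for c, p in zip(bins.chrom, mid)]
    )
    cen = rc == "CEN"
    tel = rc == "TEL"
    C[np.ix_(cen, cen)] *= boost_cen
    C[np.ix_(tel, tel)] *= boost_tel
    return ContactModel(bin_size=bin_size, bins=bins, C=C)


# ---------------------------------------------------------------------------
# pair weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventWeightModel:
    """Exponents of the separable accessibility x contact weight law."""

    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise SimulationError("weight exponents must be finite")


def pair_weight(
    model: EventWeightModel,
    site_i: LoxPsymSite,
    site_j: LoxPsymSite,
    accessibility: AccessibilityProfile,
    contacts: ContactModel,
) -> float:
    """w_ij = (a_i a_j)^alpha * C(bin_i, bin_j)^beta; symmetric in i, j."""
    if site_i.site_id == site_j.site_id:
        raise SimulationError("pair weight requires two distinct sites")
    w = (accessibility[site_i.site_id] * accessibility[site_j.site_id]) ** model.alpha
    c = contacts.contact(site_i.chrom, site_i.pos, site_j.chrom, site_j.pos)
    if model.beta != 0.0:
        w *= c**model.beta
    return float(w)


@dataclass
class PairWeights:
    """Symmetric weight matrix over the analyzable sites, zero diagonal."""

    sites: list[LoxPsymSite]
    W: np.ndarray
    index: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        np.fill_diagonal(self.W, 0.0)
        if (self.W < 0).any() or not np.allclose(self.W, self.W.T):
            raise SimulationError("weight matrix must be symmetric nonnegative")
        self.index = {s.site_id: i for i, s in enumerate(self.sites)}

    def marginal(self) -> pd.Series:
        """Total weight per site (sum over partners) — the truth landscape."""
        return pd.Series(self.W.sum(axis=1), index=[s.site_id for s in self.sites])


def compute_pair_weights(
    genome: GenomeDefinition,
    model: EventWeightModel,
    accessibility: AccessibilityProfile,
    contacts: ContactModel,
) -> PairWeights:
    sites = genome.analyzable_sites()
    a = np.array([accessibility[s.site_id] for s in sites])
    bins = np.array([contacts.bin_index(s.chrom, s.pos) for s in sites])
    W = (np.outer(a, a)) ** model.alpha
    if model.beta != 0.0:
        W = W * contacts.C[np.ix_(bins, bins)] ** model.beta
    np.fill_diagonal(W, 0.0)
    return PairWeights(sites=sites, W=W)


# ---------------------------------------------------------------------------
# event log
# ---------------------------------------------------------------------------


@dataclass
class EventRecord:
    cell: int
    site_i: int
    site_j: int
    outcome: str  # deletion | inversion | translocation
    viable: bool
    junctions: list[Signature]
    read_counts: list[int] = field(default_factory=list)


@dataclass
class TrueEventLog:
    """Simulator ground truth: sampled pairs, outcomes, emitted junctions."""

    records: list[EventRecord]

    def viable_records(self) -> list[EventRecord]:
        return [r for r in self.records if r.viable]

    def pair_counts(self) -> pd.Series:
        key = [
            tuple(sorted((r.site_i, r.site_j))) for r in self.records
        ]
        return pd.Series(key).value_counts()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "cell": r.cell,
                    "site_i": r.site_i,
                    "site_j": r.site_j,
                    "outcome": r.outcome,
                    "viable": int(r.viable),
                    "junctions": ",".join(format_signature(s) for s in r.junctions),
                    "read_counts": ",".join(str(c) for c in r.read_counts),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "cell", "site_i", "site_j", "outcome", "viable",
                "junctions", "read_counts",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TrueEventLog":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        records = []
        for row in df.itertuples(index=False):
            juncs = (
                [parse_signature(s) for s in str(row.junctions).split(",")]
                if str(row.junctions)
                else []
            )
            counts = (
                [int(c) for c in str(row.read_counts).split(",")]
                if str(row.read_counts)
                else []
            )
            records.append(
                EventRecord(
                    cell=int(row.cell),
                    site_i=int(row.site_i),
                    site_j=int(row.site_j),
                    outcome=str(row.outcome),
                    viable=bool(row.viable),
                    junctions=juncs,
                    read_counts=counts,
                )
            )
        return cls(records)

    def emitted_signature_counts(self) -> dict[Signature, int]:
        out: dict[Signature, int] = {}
        for r in self.records:
            for sig, c in zip(r.junctions, r.read_counts):
                out[sig] = out.get(sig, 0) + c
        return out


@dataclass
class SimConfig:
    n_cells: int = 100
    lambda_events: float = 1.0
    read_len: int = 150
    reads_per_junction: float = 10.0
    error_rate: float = 0.0
    seed: int = 0
    mode: str = "junction_pool"
    background_reads: int = 0
    min_flank: int = 20

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.lambda_events < 0 or self.reads_per_junction < 0:
            raise SimulationError("counts must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise SimulationError("error_rate must be in [0, 1)")
        if self.mode not in ("junction_pool", "genome_sequential"):
            raise SimulationError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------------
# segmented genomes (genome_sequential mode)
# ---------------------------------------------------------------------------


@dataclass
class Seg:
    """A reference interval between motif boundaries, possibly inverted.

    ``left``/``right`` are the loxPsym sides the segment presents at its two
    ends in its current orientation (None at a linear chromosome end). For
    circular source chromosomes ``end < start`` encodes wrap through the
    origin.
    """

    chrom: str
    start: int
    end: int
    strand: int
    left: Side | None
    right: Side | None
    has_cen: bool

    def flipped(self) -> "Seg":
        return Seg(self.chrom, self.start, self.end, -self.strand,
                   self.right, self.left, self.has_cen)


@dataclass
class Motif:
    site_id: int


@dataclass
class SegChrom:
    """Alternating segment/motif list. Linear chromosomes start and end with
    a segment; circular ones start with a motif (element 0) so motifs sit at
    even indices."""

    name: str
    circular: bool
    elements: list

    def motif_positions(self) -> list[int]:
        return [i for i, e in enumerate(self.elements) if isinstance(e, Motif)]

    def centromere_count(self) -> int:
        return sum(1 for e in self.elements if isinstance(e, Seg) and e.has_cen)

    def junctions(self) -> list[Signature]:
        out = []
        n = len(self.elements)
        for i in self.motif_positions():
            left_seg = self.elements[(i - 1) % n] if self.circular else (
                self.elements[i - 1]
            )
            right_seg = self.elements[(i + 1) % n] if self.circular else (
                self.elements[i + 1]
            )
            if left_seg.right is None or right_seg.left is None:
                continue
            out.append(signature(left_seg.right, right_seg.left))
        return out


def segment_genome(genome: GenomeDefinition) -> list[SegChrom]:
    """Initial segmentation of the reference into motif-delimited segments."""
    m = genome.motif_len
    out = []
    for name, spec in genome.chromosomes.items():
        sites = genome.sites_on(name)
        cen = spec.centromere_pos

        def mkseg(start, end, left, right, wraps=False):
            if wraps:
                has_cen = cen >= start or cen < end
            else:
                has_cen = start <= cen < end
            return Seg(name, start, end, 1, left, right, has_cen)

        if spec.circular:
            if not sites:
                out.append(SegChrom(name, True, [mkseg(0, spec.length, None, None)]))
                continue
            elements: list = []
            k = len(sites)
            for i, s in enumerate(sites):
                nxt = sites[(i + 1) % k]
                elements.append(Motif(s.site_id))
                wraps = (i + 1) == k
                elements.append(
                    mkseg(
                        s.pos + m,
                        nxt.pos,
                        (s.site_id, RIGHT),
                        (nxt.site_id, LEFT),
                        wraps=wraps,
                    )
                )
            out.append(SegChrom(name, True, elements))
        else:
            elements = []
            prev_bound = 0
            prev_side: Side | None = None
            for s in sites:
                elements.append(mkseg(prev_bound, s.pos, prev_side, (s.site_id, LEFT)))
                elements.append(Motif(s.site_id))
                prev_bound = s.pos + m
                prev_side = (s.site_id, RIGHT)
            elements.append(mkseg(prev_bound, spec.length, prev_side, None))
            out.append(SegChrom(name, False, elements))
    return out


def viability_check(cell: list[SegChrom]) -> bool:
    """Viable iff every chromosome carries exactly one centromere."""
    return all(c.centromere_count() == 1 for c in cell)


def realize_genome(cell: list[SegChrom], genome: GenomeDefinition) -> dict[str, str]:
    """Reconstruct nucleotide sequences of a segmented (rearranged) genome."""
    out = {}
    for chrom in cell:
        parts = []
        for e in chrom.elements:
            if isinstance(e, Motif):
                parts.append(genome.loxpsym_motif)
            else:
                src = genome.sequences[e.chrom]
                if e.end >= e.start:
                    seq = src[e.start : e.end]
                else:  # wrap on circular source
                    seq = src[e.start :] + src[: e.end]
                parts.append(seq if e.strand > 0 else revcomp(seq))
        out[chrom.name] = "".join(parts)
    return out


def _junction_at(chrom: SegChrom, idx: int) -> Signature | None:
    """Junction signature at the motif element ``idx``, or None at a
    chromosome end."""
    n = len(chrom.elements)
    if chrom.circular:
        left_seg = chrom.elements[(idx - 1) % n]
        right_seg = chrom.elements[(idx + 1) % n]
    else:
        if idx - 1 < 0 or idx + 1 >= n:
            return None
        left_seg = chrom.elements[idx - 1]
        right_seg = chrom.elements[idx + 1]
    if not (isinstance(left_seg, Seg) and isinstance(right_seg, Seg)):
        return None
    if left_seg.right is None or right_seg.left is None:
        return None
    return signature(left_seg.right, right_seg.left)


def _flip_run(elements: list) -> list:
    """Reverse a run of elements, flipping each segment's orientation."""
    return [e.flipped() if isinstance(e, Seg) else e for e in reversed(elements)]


def _apply_intra(chrom: SegChrom, ip: int, iq: int, outcome: str) -> list[Signature]:
    """Apply a deletion or inversion between motif elements at list indices
    ``ip`` and ``iq``; returns the novel junction signatures created in the
    retained molecule(s). On a ring, deletion keeps the excision circle that
    retains the centromere (the acentric circle is lost)."""
    els = chrom.elements
    if chrom.circular:
        # rotate so ip's motif is element 0 of a motif-first circular view
        els = els[ip:] + els[:ip]
        iq = (iq - ip) % len(chrom.elements)
        ip = 0
    if outcome == DELETION:
        if chrom.circular:
            circle_a = els[:iq]   # motif ip + arc ip->iq
            circle_b = els[iq:]   # motif iq + arc iq->ip
            keep = circle_a if any(
                isinstance(e, Seg) and e.has_cen for e in circle_a
            ) else circle_b
            chrom.elements = keep
            out = _junction_at(chrom, 0)
        else:
            chrom.elements = els[: ip + 1] + els[iq + 1 :]
            out = _junction_at(chrom, ip)
        return [out] if out is not None else []
    # inversion: reverse and flip everything strictly between the two motifs
    mid = _flip_run(els[ip + 1 : iq])
    chrom.elements = els[: ip + 1] + mid + els[iq:]
    sigs = [_junction_at(chrom, ip), _junction_at(chrom, ip + len(mid) + 1)]
    return [s for s in sigs if s is not None]


def _apply_inter(
    cell: list[SegChrom], ca: int, ip: int, cb: int, iq: int, form: int
) -> list[Signature]:
    """Recombine motif ``ip`` of chromosome ``ca`` with motif ``iq`` of
    chromosome ``cb`` (distinct chromosomes). Linear x linear gives a
    reciprocal translocation (``form`` 0 = direct joins, 1 = inverted
    joins); a ring integrates into its partner; two rings fuse. Mutates
    ``cell`` in place and returns the novel junctions."""
    A, B = cell[ca], cell[cb]
    if not A.circular and not B.circular:
        if form == 0:
            new_a = A.elements[: ip + 1] + B.elements[iq + 1 :]
            new_b = B.elements[: iq + 1] + A.elements[ip + 1 :]
            A.elements, B.elements = new_a, new_b
            sigs = [_junction_at(A, ip), _junction_at(B, iq)]
        else:
            a_tail_flipped = _flip_run(A.elements[ip + 1 :])
            new_a = A.elements[: ip + 1] + _flip_run(B.elements[:iq])
            new_b = a_tail_flipped + B.elements[iq:]
            A.elements, B.elements = new_a, new_b
            sigs = [_junction_at(A, ip), _junction_at(B, len(a_tail_flipped))]
        return [s for s in sigs if s is not None]
    if A.circular and B.circular:
        # fusion of two rings into one
        a_rot = A.elements[ip:] + A.elements[:ip]
        b_rot = B.elements[iq:] + B.elements[:iq]
        body = b_rot[1:] if form == 0 else _flip_run(b_rot[1:])
        fused = SegChrom(
            name=f"{A.name}+{B.name}",
            circular=True,
            elements=a_rot + [Motif(b_rot[0].site_id)] + body,
        )
        cell[ca] = fused
        del cell[cb]
        sigs = [_junction_at(fused, 0), _junction_at(fused, len(a_rot))]
        return [s for s in sigs if s is not None]
    # ring integrates into a linear chromosome
    if A.circular:
        A, B = B, A
        ip, iq = iq, ip
        ca, cb = cb, ca
    ring_rot = B.elements[iq:] + B.elements[:iq]
    body = ring_rot[1:] if form == 0 else _flip_run(ring_rot[1:])
    new_a = (
        A.elements[: ip + 1]
        + body
        + [Motif(ring_rot[0].site_id)]
        + A.elements[ip + 1 :]
    )
    A.elements = new_a
    del cell[cb]
    sigs = [_junction_at(A, ip), _junction_at(A, ip + len(body) + 1)]
    return [s for s in sigs if s is not None]


def apply_event(
    cell: list[SegChrom],
    site_i: int,
    site_j: int,
    outcome: str,
    form: int = 0,
) -> list[Signature]:
    """Apply one recombination event between the (unique) current instances
    of two site ids in a segmented genome; returns the novel junctions."""
    locs = []
    for ci, chrom in enumerate(cell):
        for ei, e in enumerate(chrom.elements):
            if isinstance(e, Motif) and e.site_id in (site_i, site_j):
                locs.append((ci, ei, e.site_id))
    found = {sid for _, _, sid in locs}
    if found != {site_i, site_j}:
        raise SimulationError(f"sites {site_i},{site_j} not both present exactly once")
    (ca, ia, _), (cb, ib, _) = locs[:2]
    if ca == cb:
        if outcome == TRANSLOCATION:
            raise SimulationError("translocation requires two chromosomes")
        ip, iq = sorted((ia, ib))
        return _apply_intra(cell[ca], ip, iq, outcome)
    if outcome != TRANSLOCATION:
        raise SimulationError(f"{outcome} requires one chromosome")
    return _apply_inter(cell, ca, ia, cb, ib, form)


# ---------------------------------------------------------------------------
# event sampling
# ---------------------------------------------------------------------------


def _pool_junctions(
    genome: GenomeDefinition,
    si: LoxPsymSite,
    sj: LoxPsymSite,
    outcome: str,
    form: int,
) -> list[Signature]:
    """Junction signatures recorded against the fixed reference for one
    event (junction_pool mode). Deletions contribute only the chromosomal
    junction — the excision circle is assumed lost; inversions contribute
    both breakpoint junctions; translocations both reciprocal joins."""
    i, j = si.site_id, sj.site_id
    if si.chrom == sj.chrom:
        if outcome == INVERSION:
            return [signature((i, LEFT), (j, LEFT)), signature((i, RIGHT), (j, RIGHT))]
        spec = genome.chromosomes[si.chrom]
        if not spec.circular:
            u, v = (si, sj) if si.pos < sj.pos else (sj, si)
            return [signature((u.site_id, LEFT), (v.site_id, RIGHT))]
        # ring: keep the excision circle that retains the centromere;
        # junction {(u,L),(v,R)} corresponds to deleting the forward arc u->v
        L = spec.length
        cen_in_fwd_arc = (spec.centromere_pos - si.pos) % L < (sj.pos - si.pos) % L
        if cen_in_fwd_arc:
            return [signature((j, LEFT), (i, RIGHT))]
        return [signature((i, LEFT), (j, RIGHT))]
    if form == 0:
        return [signature((i, LEFT), (j, RIGHT)), signature((j, LEFT), (i, RIGHT))]
    return [signature((i, LEFT), (j, LEFT)), signature((i, RIGHT), (j, RIGHT))]


def simulate_pool(
    genome: GenomeDefinition,
    weights: PairWeights,
    config: SimConfig,
) -> tuple[TrueEventLog, list[list[SegChrom]]]:
    """Sample Cre events over the analyzable sites, pair choice ~ w_ij.

    Per cell, ``k ~ Poisson(lambda_events)`` events; intra-chromosomal
    outcomes split uniformly between deletion and inversion, inter pairs
    recombine as reciprocal exchanges (orientation form sampled uniformly).
    Returns the ground-truth log and, in genome_sequential mode, the
    surviving rearranged genomes (empty list in junction_pool mode).
    """
    if weights.W.sum() <= 0:
        raise SimulationError("no positive pair weights")
    rng = np.random.default_rng(config.seed)
    n = len(weights.sites)
    iu, ju = np.triu_indices(n, k=1)
    p = weights.W[iu, ju]
    p = p / p.sum()
    records: list[EventRecord] = []
    survivors: list[list[SegChrom]] = []

    analyzable_ids = {s.site_id for s in weights.sites}
    for cell_id in range(config.n_cells):
        k = rng.poisson(config.lambda_events)
        if config.mode == "junction_pool":
            if k == 0:
                continue
            picks = rng.choice(p.size, size=k, p=p)
            for flat in picks:
                si, sj = weights.sites[iu[flat]], weights.sites[ju[flat]]
                if si.chrom == sj.chrom:
                    outcome = DELETION if rng.integers(2) == 0 else INVERSION
                else:
                    outcome = TRANSLOCATION
                form = int(rng.integers(2))
                juncs = _pool_junctions(genome, si, sj, outcome, form)
                records.append(
                    EventRecord(cell_id, si.site_id, sj.site_id, outcome, True, juncs)
                )
        else:  # genome_sequential
            cell = segment_genome(genome)
            cell_records: list[EventRecord] = []
            for _ in range(k):
                locs = [
                    (ci, ei, e.site_id)
                    for ci, chrom in enumerate(cell)
                    for ei, e in enumerate(chrom.elements)
                    if isinstance(e, Motif) and e.site_id in analyzable_ids
                ]
                if len(locs) < 2:
                    break
                idx = [weights.index[sid] for _, _, sid in locs]
                Winst = weights.W[np.ix_(idx, idx)]
                ii, jj = np.triu_indices(len(locs), k=1)
                pw = Winst[ii, jj]
                tot = pw.sum()
                if tot <= 0:
                    break
                flat = rng.choice(pw.size, p=pw / tot)
                (ca, ia, sid_a) = locs[ii[flat]]
                (cb, ib, sid_b) = locs[jj[flat]]
                if ca == cb:
                    outcome = DELETION if rng.integers(2) == 0 else INVERSION
                    ip, iq = sorted((ia, ib))
                    juncs = _apply_intra(cell[ca], ip, iq, outcome)
                else:
                    outcome = TRANSLOCATION
                    form = int(rng.integers(2))
                    juncs = _apply_inter(cell, ca, ia, cb, ib, form)
                cell_records.append(
                    EventRecord(cell_id, sid_a, sid_b, outcome, True, juncs)
                )
            viable = viability_check(cell)
            for r in cell_records:
                r.viable = viable
            records.extend(cell_records)
            if viable:
                survivors.append(cell)
    return TrueEventLog(records), survivors


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _add_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(seq), size=n_err, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def emit_reads(
    log: TrueEventLog,
    genome: GenomeDefinition,
    config: SimConfig,
    fastq_path: str | Path | None = None,
) -> list[tuple[str, str]]:
    """Emit junction-spanning reads plus background reads, as (id, seq).

    Each viable logged junction receives ~Poisson(reads_per_junction)
    reads; the motif start offset within each read is uniform over the
    range keeping both flanks >= min_flank, so every junction read carries
    mappable flanks. Per-base substitution errors at ``error_rate``;
    background reads are drawn uniformly from the reference (both strands)
    and interleaved. Deterministic for a fixed config (generator seeded
    with ``seed + 1``; see the simulator docs for draw order).

    Emitted per-junction read counts are recorded back into the log.
    """
    from .genome import fetch_wrapped

    m = genome.motif_len
    if config.read_len <= m + 2 * config.min_flank - 1:
        raise SimulationError("read_len too short for motif plus two flanks")
    rng = np.random.default_rng(config.seed + 1)
    lo = config.min_flank
    hi = config.read_len - m - config.min_flank
    reads: list[tuple[str, str]] = []
    serial = 0
    for rec in log.records:
        rec.read_counts = []
        if not rec.viable:
            rec.read_counts = [0] * len(rec.junctions)
            continue
        for sig in rec.junctions:
            n_reads = rng.poisson(config.reads_per_junction)
            rec.read_counts.append(int(n_reads))
            for _ in range(n_reads):
                s1, s2 = sig
                if rng.integers(2) == 1:
                    s1, s2 = s2, s1
                off = int(rng.integers(lo, hi + 1))
                seq = junction_read(genome, s1, s2, off, config.read_len - m - off)
                seq = _add_errors(seq, config.error_rate, rng)
                reads.append((f"J{serial}|{format_signature(sig)}", seq))
                serial += 1
    chrom_names = list(genome.chromosomes)
    lengths = np.array([genome.chromosomes[c].length for c in chrom_names], float)
    pchrom = lengths / lengths.sum()
    for b in range(config.background_reads):
        ci = rng.choice(len(chrom_names), p=pchrom)
        chrom = chrom_names[ci]
        spec = genome.chromosomes[chrom]
        if spec.circular:
            start = int(rng.integers(0, spec.length))
        else:
            start = int(rng.integers(0, max(1, spec.length - config.read_len + 1)))
        seq = fetch_wrapped(genome, chrom, start, config.read_len)
        if rng.integers(2) == 1:
            seq = revcomp(seq)
        seq = _add_errors(seq, config.error_rate, rng)
        reads.append((f"BG{b}|{chrom}:{start}", seq))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    return reads


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
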