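"""Accessibility and contact-probability analysis at loxPsym sites.

Quantifies an accessibility track in site-centered ±400 bp windows
(normalized so the mean over all analyzable sites is exactly 1), extracts
log2 contact probabilities at 1-kb bins, runs the weighted-mean group
comparisons (paired t-test where a pairing exists, Welch's unequal-variance
test otherwise — the mode is always recorded), and fits the combinatorial
accessibility x contact model on the pair table:

    log2(f_ij + 1) = b0 + b_a * log2(a_i * a_j) + b_c * log2(C_ij + eps)

Pseudocounts: eps = 1e-6 for contacts, +1 for read counts before log2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .events import ClassifiedEvent
from .genome import CEN, OTHER, TEL, GenomeDefinition
from .simulate import AccessibilityProfile
from .tracks import ContactModel, SignalTrack

CONTACT_PSEUDOCOUNT = 1e-6


class IntegrationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# per-site signal
# ---------------------------------------------------------------------------


def site_signals(
    track: SignalTrack,
    genome: GenomeDefinition,
    halfwidth: int = 400,
) -> pd.DataFrame:
    """Normalized window-mean signal for every analyzable site.

    The window is centered on the motif midpoint, truncated at linear
    chromosome ends and wrapped on rings; each site's window mean is
    divided by the average of that quantity over all analyzable sites, so
    the normalized values average exactly 1.
    """
    sites = genome.analyzable_sites()
    half_motif = genome.motif_len // 2
    raw = np.array(
        [
            track.window_mean(genome, s.chrom, s.pos + half_motif, halfwidth)
            for s in sites
        ]
    )
    mean = raw.mean()
    if mean == 0:
        raise IntegrationError("track is identically zero over all sites")
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "raw_signal": raw,
            "signal": raw / mean,
        }
    )


def site_signal(
    track: SignalTrack,
    genome: GenomeDefinition,
    site_id: int,
    halfwidth: int = 400,
) -> float:
    """Normalized signal of one site (see :func:`site_signals`)."""
    df = site_signals(track, genome, halfwidth)
    return float(df.loc[df.site_id == site_id, "signal"].iloc[0])


def contact_at(
    contacts: ContactModel,
    locus_a: tuple[str, int],
    locus_b: tuple[str, int],
    pseudocount: float = CONTACT_PSEUDOCOUNT,
) -> float:
    """log2(contact + pseudocount) between two loci; symmetric."""
    c = contacts.contact(locus_a[0], locus_a[1], locus_b[0], locus_b[1])
    return math.log2(c + pseudocount)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    t: float
    p: float
    mode: str  # "paired" or "welch"


def group_compare(
    values_a,
    values_b,
    weights_a=None,
    weights_b=None,
    paired: bool | None = None,
) -> GroupComparison:
    """Weighted means plus a two-sided t-test.

    A paired two-sample t-test is used when a pairing is defined
    (equal-length aligned vectors and ``paired`` is not False); otherwise
    Welch's unequal-variance test. Weights affect only the reported means
    (equal weights by default); the tests are unweighted.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise IntegrationError("need at least 2 values per group")
    wa = np.ones_like(a) if weights_a is None else np.asarray(weights_a, float)
    wb = np.ones_like(b) if weights_b is None else np.asarray(weights_b, float)
    mean_a = float((a * wa).sum() / wa.sum())
    mean_b = float((b * wb).sum() / wb.sum())
    if paired is None:
        paired = a.size == b.size
    if paired:
        if a.size != b.size:
            raise IntegrationError("paired mode requires equal lengths")
        d = a - b
        if np.allclose(d, 0):
            return GroupComparison(mean_a, mean_b, 0.0, 1.0, "paired")
        t, p = _stats.ttest_rel(a, b)
        return GroupComparison(mean_a, mean_b, float(t), float(p), "paired")
    t, p = _stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(mean_a, mean_b, float(t), float(p), "welch")


# ---------------------------------------------------------------------------
# pair table
# ---------------------------------------------------------------------------


def build_pair_table(
    classified: list[ClassifiedEvent],
    genome: GenomeDefinition,
    accessibility: AccessibilityProfile,
    contacts: ContactModel,
) -> pd.DataFrame:
    """Aggregate events into a symmetric-canonical (site_i < site_j) table
    with rearrangement read counts, accessibility products and contacts."""
    counts: dict[tuple[int, int], int] = {}
    for c in classified:
        (i, _), (j, _) = c.event.signature
        key = (min(i, j), max(i, j))
        counts[key] = counts.get(key, 0) + c.event.read_count
    rows = []
    for (i, j), f in sorted(counts.items()):
        si, sj = genome.site(i), genome.site(j)
        rows.append(
            {
                "site_i": i,
                "site_j": j,
                "read_count": f,
                "access_product": accessibility[i] * accessibility[j],
                "contact": contacts.contact(si.chrom, si.pos, sj.chrom, sj.pos),
                "intra": si.chrom == sj.chrom,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["site_i", "site_j", "read_count", "access_product", "contact", "intra"],
    )


def joint_model_fit(
    pair_table: pd.DataFrame,
    pseudocount: float = CONTACT_PSEUDOCOUNT,
) -> dict:
    """Least-squares fit of the combinatorial accessibility x contact model.

    Returns the intercept, both slopes and R²; flags collinear or constant
    predictors instead of silently returning garbage.
    """
    if len(pair_table) < 3:
        raise IntegrationError("need at least 3 pairs to fit")
    y = np.log2(pair_table.read_count.to_numpy(float) + 1.0)
    xa = np.log2(pair_table.access_product.to_numpy(float))
    xc = np.log2(pair_table.contact.to_numpy(float) + pseudocount)
    flags = []
    for name, v in (("access", xa), ("contact", xc)):
        if np.allclose(v, v[0]):
            flags.append(f"constant predictor: {name}")
    X = np.column_stack([np.ones_like(xa), xa, xc])
    if np.linalg.matrix_rank(X) < 3:
        flags.append("collinear predictors")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return {
        "beta0": float(coef[0]),
        "beta_access": float(coef[1]),
        "beta_contact": float(coef[2]),
        "r_squared": r2,
        "n_pairs": int(len(pair_table)),
        "flags": flags,
    }


# ---------------------------------------------------------------------------
# region enrichment (CEN / TEL vs others)
# ---------------------------------------------------------------------------


def region_enrichment(
    pair_table: pd.DataFrame,
    genome: GenomeDefinition,
    contacts: ContactModel,
) -> dict:
    """Inter-chromosomal contact and rearrangement frequency of CEN and TEL
    bins against all other bins.

    Pairs are aggregated to 1-kb bins (each inter pair credits both
    endpoint bins); bins are partitioned by region class and compared with
    Welch's test (the groups have different sizes, so no pairing exists).
    The contact comparison covers all bins; the rearrangement-frequency
    comparison covers only bins containing at least one analyzable loxPsym
    site — bins without a site cannot recombine, so including them would
    only add structural zeros to both groups. Empty region classes are
    flagged and skipped, not errors.
    """
    nbins = contacts.C.shape[0]
    mid = ((contacts.bins.start + contacts.bins.end) // 2).to_numpy()
    rclass = np.array(
        [
            genome.region_class(c, int(p))
            for c, p in zip(contacts.bins.chrom, mid)
        ]
    )
    chrom_of = contacts.bins.chrom.to_numpy()
    inter_mask = chrom_of[:, None] != chrom_of[None, :]
    with np.errstate(divide="ignore"):
        inter_contact = np.where(inter_mask, contacts.C, np.nan)
    mean_inter_contact = np.nanmean(inter_contact, axis=1)

    freq = np.zeros(nbins)
    has_site = np.zeros(nbins, dtype=bool)
    for s in genome.analyzable_sites():
        has_site[contacts.bin_index(s.chrom, s.pos)] = True
    inter_pairs = pair_table[~pair_table.intra]
    for row in inter_pairs.itertuples(index=False):
        si = genome.site(row.site_i)
        sj = genome.site(row.site_j)
        freq[contacts.bin_index(si.chrom, si.pos)] += row.read_count
        freq[contacts.bin_index(sj.chrom, sj.pos)] += row.read_count

    out: dict = {}
    others = rclass == OTHER
    for label in (CEN, TEL):
        sel = rclass == label
        if sel.sum() < 2 or others.sum() < 2:
            out[label] = {"skipped": True, "reason": f"fewer than 2 {label} bins"}
            continue
        cmp_contact = group_compare(
            mean_inter_contact[sel], mean_inter_contact[others], paired=False
        )
        sel_f, others_f = sel & has_site, others & has_site
        if sel_f.sum() < 2 or others_f.sum() < 2:
            out[label] = {
                "skipped": True,
                "reason": f"fewer than 2 site-bearing {label} bins",
            }
            continue
        cmp_freq = group_compare(freq[sel_f], freq[others_f], paired=False)
        out[label] = {
            "skipped": False,
            "n_bins": int(sel.sum()),
            "n_site_bins": int(sel_f.sum()),
            "contact": cmp_contact,
            "frequency": cmp_freq,
        }
    return out


# ---------------------------------------------------------------------------
# compensation pairs
# ---------------------------------------------------------------------------


def compensation_pairs(
    pair_table: pd.DataFrame,
    tol_access: float = 0.5,
    tol_contact: float = 0.5,
    tol_freq: float = 0.5,
    pseudocount: float = CONTACT_PSEUDOCOUNT,
    max_rows: int = 200,
    max_input: int = 500,
) -> dict[str, pd.DataFrame]:
    """Matched pair-of-pairs panels (tolerances in log2 units).

    * ``matched_access``: similar accessibility product, different contact —
      frequency follows contact.
    * ``matched_contact``: similar contact, different accessibility —
      frequency follows accessibility.
    * ``counter_effect``: one pair open-but-distant, the other
      closed-but-proximal, with similar frequencies.

    The search is quadratic in table rows, so tables larger than
    ``max_input`` are restricted to their best-supported pairs (highest
    read count; deterministic) — the panels illustrate matched examples,
    they are not an exhaustive census. An empty panel is an empty table,
    not an error.
    """
    t = pair_table.reset_index(drop=True)
    if len(t) > max_input:
        t = (
            t.sort_values(["read_count", "site_i", "site_j"],
                          ascending=[False, True, True])
            .head(max_input)
            .reset_index(drop=True)
        )
    la = np.log2(t.access_product.to_numpy(float))
    lc = np.log2(t.contact.to_numpy(float) + pseudocount)
    lf = np.log2(t.read_count.to_numpy(float) + 1.0)
    n = len(t)
    matched_access, matched_contact, counter = [], [], []
    for p in range(n):
        for q in range(p + 1, n):
            da, dc, df = la[p] - la[q], lc[p] - lc[q], lf[p] - lf[q]
            row = {
                "pair_1": (int(t.site_i[p]), int(t.site_j[p])),
                "pair_2": (int(t.site_i[q]), int(t.site_j[q])),
                "d_log2_access": da,
                "d_log2_contact": dc,
                "d_log2_freq": df,
            }
            if abs(da) <= tol_access and abs(dc) > tol_contact:
                matched_access.append(row)
            if abs(dc) <= tol_contact and abs(da) > tol_access:
                matched_contact.append(row)
            if (
                abs(df) <= tol_freq
                and abs(da) > tol_access
                and abs(dc) > tol_contact
                and np.sign(da) == -np.sign(dc)
            ):
                counter.append(row)
    cols = ["pair_1", "pair_2", "d_log2_access", "d_log2_contact", "d_log2_freq"]
    return {
        "matched_access": pd.DataFrame(matched_access[:max_rows], columns=cols),
        "matched_contact": pd.DataFrame(matched_contact[:max_rows], columns=cols),
        "counter_effect": pd.DataFrame(counter[:max_rows], columns=cols),
    }


def heatmap_concordance(
    pair_table: pd.DataFrame,
    genome: GenomeDefinition,
    contacts: ContactModel,
) -> tuple[float, float]:
    """Pearson correlation between the binned rearrangement-frequency
    heatmap (log2(f+1)) and the log2 contact map over the populated upper
    triangle — the simulated analogue of comparing the two heatmaps."""
    from .landscape import pearson

    f: dict[tuple[int, int], float] = {}
    for row in pair_table.itertuples(index=False):
        si, sj = genome.site(row.site_i), genome.site(row.site_j)
        bi = contacts.bin_index(si.chrom, si.pos)
        bj = contacts.bin_index(sj.chrom, sj.pos)
        key = (min(bi, bj), max(bi, bj))
        f[key] = f.get(key, 0.0) + row.read_count
    if len(f) < 3:
        raise IntegrationError("too few populated bin pairs")
    keys = sorted(f)
    x = [math.log2(contacts.C[k] + CONTACT_PSEUDOCOUNT) for k in keys]
    y = [math.log2(f[k] + 1.0) for k in keys]
    return pearson(x, y)
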