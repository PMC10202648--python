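"""Canonical simulation studies: the experiments the package was built for.

Each function sets up one seeded study at a stated problem size, runs the
full machinery (simulate -> call -> classify -> landscape/integrate) and
returns the headline numbers. The studies double as the reproducibility
entry points: the analysis scripts and the acceptance machinery call these
rather than re-wiring the stages by hand.

Problem sizes are desk scale by design: a few hundred sites and 10^4-10^5
reads or events per study, enough for the statistics tested while keeping
any single study under a minute.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .caller import NOVEL, process_reads
from .chromatin import build_pair_table, group_compare, joint_model_fit, site_signals
from .classify import classify_all, classify_signature, enumerate_cre_products
from .events import RearrangementEvent
from .fixtures import make_genome
from .genome import ChromosomeSpec, GenomeDefinition, LINEAR
from .landscape import (
    COLDSPOT,
    HOTSPOT,
    decile_bins,
    per_chromosome_correlation,
    replicate_correlation,
    site_frequencies,
)
from .simulate import (
    AccessibilityProfile,
    EventWeightModel,
    SimConfig,
    compute_pair_weights,
    emit_reads,
    simulate_pool,
    synth_accessibility,
    synth_contacts,
)


def paperlike_accounting(seed: int = 0) -> dict:
    """Site accounting of the paperlike fixture: 894 sites, 17 telomeric,
    877 analyzable; decile labelling of the analyzable landscape gives 88
    hotspots and 88 coldspots (round-half-up of 10%)."""
    genome = make_genome("paperlike", seed)
    landscape = decile_bins(site_frequencies([], genome))
    return {
        "total_sites": len(genome.sites),
        "telomeric_sites": sum(s.telomeric for s in genome.sites),
        "analyzable_sites": len(genome.analyzable_sites()),
        "hotspots": int((landscape.label == HOTSPOT).sum()),
        "coldspots": int((landscape.label == COLDSPOT).sum()),
    }


def oracle_agreement(seed: int = 0) -> dict:
    """Exhaustive classifier-vs-surgery check over all 45 site pairs of the
    10-site toy fixture: every junction of every Cre product must classify
    as the label of the product that created it."""
    genome = make_genome("toy", seed)
    ids = [s.site_id for s in genome.sites]
    n_junctions = n_agree = 0
    for i, j in itertools.combinations(ids, 2):
        for prod in enumerate_cre_products(genome, i, j):
            for sig in prod.signatures:
                n_junctions += 1
                label, _ = classify_signature(sig, genome)
                n_agree += label == prod.label
    return {
        "n_pairs": len(ids) * (len(ids) - 1) // 2,
        "n_junctions": n_junctions,
        "agreement_pct": 100.0 * n_agree / n_junctions,
    }


def _uniform_weights(genome: GenomeDefinition, **contact_kw):
    profile = AccessibilityProfile({s.site_id: 1.0 for s in genome.sites})
    cm = synth_contacts(genome, **contact_kw)
    return compute_pair_weights(genome, EventWeightModel(0, 0), profile, cm)


def caller_round_trip(seed: int = 0) -> dict:
    """Junction-caller recovery on ~10^4 junction reads (mini genome).

    Error-free emission must be recovered read for read with the correct
    signatures. Under 0.5% per-base substitution with a 1-mismatch motif
    budget, flank mapping stays exact-match, so a read with a flank error
    becomes unresolvable rather than miscalled; recovery is therefore
    measured per junction (a junction is recovered when at least one of
    its reads is called with the correct signature). Background-only
    emission must yield zero novel calls.
    """
    genome = make_genome("mini", seed)
    w = _uniform_weights(genome)
    cfg = SimConfig(
        n_cells=150, lambda_events=5, reads_per_junction=10,
        background_reads=0, seed=seed + 1,
    )
    log, _ = simulate_pool(genome, w, cfg)
    reads = emit_reads(log, genome, cfg)
    res = process_reads(reads, genome)
    emitted = log.emitted_signature_counts()
    called = res.signature_read_counts()
    n_emitted = sum(emitted.values())
    n_correct = sum(min(called.get(s, 0), c) for s, c in emitted.items())
    out = {
        "n_junction_reads": n_emitted,
        "read_recovery_pct": 100.0 * n_correct / n_emitted,
        "wrong_signature_reads": sum(
            c for s, c in called.items() if s not in emitted
        ),
    }

    noisy = SimConfig(
        n_cells=150, lambda_events=5, reads_per_junction=10,
        background_reads=0, error_rate=0.005, seed=seed + 1,
    )
    log2, _ = simulate_pool(genome, w, noisy)
    reads2 = emit_reads(log2, genome, noisy)
    res2 = process_reads(reads2, genome, max_mismatch=1)
    emitted2 = log2.emitted_signature_counts()
    called2 = res2.signature_read_counts()
    covered = [s for s, c in emitted2.items() if c > 0]
    recovered = sum(1 for s in covered if called2.get(s, 0) > 0)
    out["noisy_n_junctions"] = len(covered)
    out["noisy_junction_recovery_pct"] = 100.0 * recovered / len(covered)

    bg = SimConfig(
        n_cells=1, lambda_events=0, reads_per_junction=0,
        background_reads=5000, error_rate=0.005, seed=seed + 2,
    )
    log3, _ = simulate_pool(genome, w, SimConfig(n_cells=1, lambda_events=1,
                                                 seed=seed + 2))
    log3.records = []  # background-only emission
    reads3 = emit_reads(log3, genome, bg)
    res3 = process_reads(reads3, genome, max_mismatch=1)
    out["background_reads"] = len(reads3)
    out["background_false_novel"] = int(
        (res3.dispositions.disposition == NOVEL).sum()
    )
    return out


def landscape_recovery(seed: int = 0) -> dict:
    """Full-pipeline landscape recovery under alpha=1, beta=1 (~10^5 reads,
    mini genome): per-site read counts against the true marginal weights
    (Spearman), hotspot overlap with the truth top decile (Jaccard), and
    the hotspot-vs-coldspot normalized accessibility contrast."""
    genome = make_genome("mini", seed)
    profile, track = synth_accessibility(genome, seed=seed + 10)
    cm = synth_contacts(genome)
    w = compute_pair_weights(genome, EventWeightModel(1, 1), profile, cm)
    cfg = SimConfig(
        n_cells=1200, lambda_events=9, reads_per_junction=7,
        background_reads=2000, seed=seed + 11,
    )
    log, _ = simulate_pool(genome, w, cfg)
    reads = emit_reads(log, genome, cfg)
    res = process_reads(reads, genome)
    classified = classify_all(res.events, genome)
    landscape = decile_bins(site_frequencies(classified, genome))

    truth = w.marginal()
    rho = _stats.spearmanr(
        landscape.read_count.to_numpy(),
        truth.loc[landscape.site_id].to_numpy(),
    ).statistic
    hot = set(landscape.loc[landscape.label == HOTSPOT, "site_id"])
    top = set(truth.sort_values(ascending=False).index[: len(hot)])
    jaccard = len(hot & top) / len(hot | top)

    signals = site_signals(track, genome)
    merged = landscape.merge(signals[["site_id", "signal"]], on="site_id")
    cmp = group_compare(
        merged.loc[merged.label == HOTSPOT, "signal"],
        merged.loc[merged.label == COLDSPOT, "signal"],
        paired=False,
    )
    r_chrom, p_chrom = per_chromosome_correlation(classified, genome)
    return {
        "n_reads": len(reads),
        "truth_spearman": float(rho),
        "hotspot_jaccard": float(jaccard),
        "hotspot_signal_mean": cmp.mean_a,
        "coldspot_signal_mean": cmp.mean_b,
        "hotspot_coldspot_p": cmp.p,
        "per_chromosome_r": r_chrom,
        "per_chromosome_p": p_chrom,
        "landscape": landscape,
        "classified": classified,
        "genome": genome,
        "profile": profile,
        "contacts": cm,
    }


def replicate_reproducibility(seed: int = 0) -> dict:
    """Two independent event pools under the same weights: the per-site
    landscapes must correlate strongly; unrelated weights must not."""
    genome = make_genome("mini", seed)
    profile, _ = synth_accessibility(genome, seed=seed + 20)
    cm = synth_contacts(genome)
    w = compute_pair_weights(genome, EventWeightModel(1, 1), profile, cm)
    tables = []
    for k in (21, 22):
        log, _ = simulate_pool(
            genome, w, SimConfig(n_cells=1000, lambda_events=100, seed=seed + k)
        )
        events = [
            RearrangementEvent(sig, 1)
            for rec in log.records
            for sig in rec.junctions
        ]
        tables.append(site_frequencies(classify_all(events, genome), genome))
    r, p = replicate_correlation(*tables)
    return {"replicate_r": r, "replicate_p": p}


def model_recovery(seed: int = 0) -> dict:
    """Joint accessibility x contact model: exact recovery on a noise-free
    constructed table, a near-zero contact coefficient when none was
    generated, and positive coefficients on a simulated alpha=1, beta=1
    pool."""
    rng = np.random.default_rng(seed)

    def constructed(n, beta_a, beta_c, noise=0.0):
        access = 2.0 ** rng.uniform(-3, 3, n)
        contact = 2.0 ** rng.uniform(-10, -1, n)
        log_f = 14.0 + beta_a * np.log2(access) + beta_c * np.log2(contact + 1e-6)
        if noise:
            log_f = log_f + rng.normal(0, noise, n)
        return pd.DataFrame(
            {
                "site_i": np.arange(n),
                "site_j": np.arange(n) + 10_000,
                "read_count": 2.0**log_f - 1.0,
                "access_product": access,
                "contact": contact,
                "intra": True,
            }
        )

    exact = joint_model_fit(constructed(40, 1.0, 1.0))
    null = joint_model_fit(constructed(500, 1.0, 0.0, noise=0.05))

    genome = make_genome("mini", seed)
    profile, _ = synth_accessibility(genome, seed=seed + 30)
    cm = synth_contacts(genome)
    w = compute_pair_weights(genome, EventWeightModel(1, 1), profile, cm)
    log, _ = simulate_pool(
        genome, w, SimConfig(n_cells=500, lambda_events=100, seed=seed + 31)
    )
    events = [
        RearrangementEvent(sig, 1) for rec in log.records for sig in rec.junctions
    ]
    table = build_pair_table(classify_all(events, genome), genome, profile, cm)
    sim = joint_model_fit(table)
    return {
        "exact_beta_access": exact["beta_access"],
        "exact_beta_contact": exact["beta_contact"],
        "exact_beta_access_err": abs(exact["beta_access"] - 1.0),
        "exact_beta_contact_err": abs(exact["beta_contact"] - 1.0),
        "null_beta_contact": null["beta_contact"],
        "sim_beta_access": sim["beta_access"],
        "sim_beta_contact": sim["beta_contact"],
        "sim_r_squared": sim["r_squared"],
        "sim_n_pairs": sim["n_pairs"],
    }


def ring_end_adjacency(seed: int = 0, n_events: int = 10_000) -> dict:
    """Ring versus matched linear control: recombination between the two
    sites flanking the ring's origin (the former chromosome ends) against
    the same pair on an otherwise identical linear chromosome.

    Accessibility is flat and the CEN/TEL boosts are off, so the only
    difference between the two arms of the comparison is topology through
    the contact model's distance decay. One-sided binomial test of the
    ring's end-joining event count at the linear control's rate.
    """
    ring = make_genome("ring", seed)
    lin_specs = dict(ring.chromosomes)
    rc = lin_specs["ringC"]
    lin_specs["ringC"] = ChromosomeSpec(
        "ringC", rc.length, LINEAR, centromere_pos=rc.centromere_pos, telomere_len=0
    )
    linear = GenomeDefinition(
        lin_specs, dict(ring.sequences), list(ring.sites), ring.loxpsym_motif
    )
    ring_sites = ring.sites_on("ringC")
    end_pair = {ring_sites[0].site_id, ring_sites[-1].site_id}

    counts = {}
    for name, genome in (("ring", ring), ("linear", linear)):
        profile = AccessibilityProfile({s.site_id: 1.0 for s in genome.sites})
        cm = synth_contacts(genome, boost_cen=1.0, boost_tel=1.0)
        w = compute_pair_weights(genome, EventWeightModel(0, 1), profile, cm)
        cells = max(1, n_events // 100)
        log, _ = simulate_pool(
            genome, w, SimConfig(n_cells=cells, lambda_events=100, seed=seed + 41)
        )
        k = sum(1 for r in log.records if {r.site_i, r.site_j} == end_pair)
        counts[name] = (k, len(log.records))
    k_ring, n_ring = counts["ring"]
    k_lin, n_lin = counts["linear"]
    p0 = max(k_lin, 1) / n_lin  # conservative floor if the control saw none
    test = _stats.binomtest(k_ring, n_ring, p0, alternative="greater")
    return {
        "ring_end_events": k_ring,
        "ring_total_events": n_ring,
        "linear_end_events": k_lin,
        "linear_total_events": n_lin,
        "enrichment_ratio": (k_ring / n_ring) / p0,
        "p_value": float(test.pvalue),
    }
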