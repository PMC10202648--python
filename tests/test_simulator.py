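"""Simulator: accessibility/contact synthesis, weighted sampling, genome
surgery with viability, and read emission."""

import numpy as np
import pytest
from scipy import stats

from loxscape.genome import ChromosomeSpec, GenomeDefinition
from loxscape.simulate import (
    DELETION,
    INVERSION,
    TRANSLOCATION,
    AccessibilityProfile,
    EventWeightModel,
    SimConfig,
    SimulationError,
    apply_event,
    compute_pair_weights,
    emit_reads,
    pair_weight,
    realize_genome,
    segment_genome,
    simulate_pool,
    synth_accessibility,
    synth_contacts,
    viability_check,
)


class TestSynthAccessibility:
    def test_same_seed_identical_output(self, toy):
        p1, t1 = synth_accessibility(toy, seed=7)
        p2, t2 = synth_accessibility(toy, seed=7)
        assert p1.a == p2.a
        for chrom in t1.values:
            assert np.array_equal(t1.values[chrom], t2.values[chrom])

    def test_track_window_means_rank_match_weights(self, mini):
        profile, track = synth_accessibility(mini, seed=3)
        sites = mini.sites
        means = [
            track.window_mean(mini, s.chrom, s.pos + 17, 400) for s in sites
        ]
        a = [profile[s.site_id] for s in sites]
        rho = stats.spearmanr(means, a).statistic
        assert rho >= 0.95

    def test_flat_option_gives_uniform_track(self, toy):
        profile, track = synth_accessibility(toy, seed=1, flat=True)
        assert set(profile.a.values()) == {1.0}
        means = np.array(
            [track.window_mean(toy, s.chrom, s.pos + 17, 400) for s in toy.sites]
        )
        assert means.std() / means.mean() < 0.05

    def test_positive_weights_enforced(self):
        with pytest.raises(SimulationError):
            AccessibilityProfile({1: 0.0})


class TestSynthContacts:
    def test_distance_decay_ratio(self, mini):
        cm = synth_contacts(mini, gamma=1.0)
        # mid-arm bins of chr3 (150 bins), away from CEN/TEL boosts
        lo = cm.bin_index("chr3", 10_000)
        assert cm.C[lo, lo + 1] / cm.C[lo, lo + 100] == pytest.approx(101 / 2)

    def test_circular_wraparound_symmetry(self, ring):
        cm = synth_contacts(ring)
        b0 = cm.bin_index("ringC", 0)
        n = cm.n_bins("ringC")
        assert cm.C[b0, b0 + n - 1] == cm.C[b0, b0 + 1]

    def test_cen_cen_boost_ratio(self, toy):
        boost = 4.0
        cm = synth_contacts(toy, boost_cen=boost, boost_tel=1.0)
        cen_a = cm.bin_index("chrA", toy.chromosomes["chrA"].centromere_pos)
        cen_b = cm.bin_index("chrB", toy.chromosomes["chrB"].centromere_pos)
        mid_a = cm.bin_index("chrA", 10_000)
        mid_b = cm.bin_index("chrB", 10_000)
        assert cm.C[cen_a, cen_b] / cm.C[mid_a, mid_b] == pytest.approx(boost)

    def test_matrix_symmetric_positive_diagonal(self, ring):
        cm = synth_contacts(ring)
        assert np.array_equal(cm.C, cm.C.T)
        assert (np.diag(cm.C) > 0).all()


class TestPairWeight:
    def test_uniform_limit(self, toy):
        profile, _ = synth_accessibility(toy, seed=0)
        cm = synth_contacts(toy)
        model = EventWeightModel(0.0, 0.0)
        for i, j in [(0, 1), (2, 8), (5, 9)]:
            assert pair_weight(model, toy.sites[i], toy.sites[j], profile, cm) == 1.0

    def test_homogeneity_in_accessibility(self, toy):
        _, _ = synth_accessibility(toy, seed=0)
        cm = synth_contacts(toy)
        base = {s.site_id: 1.0 for s in toy.sites}
        p1 = AccessibilityProfile(dict(base))
        doubled = dict(base)
        doubled[toy.sites[0].site_id] = 2.0
        p2 = AccessibilityProfile(doubled)
        model = EventWeightModel(alpha=1.0, beta=0.0)
        w1 = pair_weight(model, toy.sites[0], toy.sites[3], p1, cm)
        w2 = pair_weight(model, toy.sites[0], toy.sites[3], p2, cm)
        assert w2 == pytest.approx(2 * w1)

    def test_matches_brute_force_on_grid(self, toy):
        profile, _ = synth_accessibility(toy, seed=5)
        cm = synth_contacts(toy)
        model = EventWeightModel(alpha=1.3, beta=0.7)
        pw = compute_pair_weights(toy, model, profile, cm)
        for i in range(4):
            for j in range(i + 1, 4):
                si, sj = toy.sites[i], toy.sites[j]
                expect = (
                    profile[si.site_id] * profile[sj.site_id]
                ) ** 1.3 * cm.contact(si.chrom, si.pos, sj.chrom, sj.pos) ** 0.7
                assert pair_weight(model, si, sj, profile, cm) == pytest.approx(expect)
                assert pw.W[i, j] == pytest.approx(expect)


def _uniform_weights(genome):
    profile = AccessibilityProfile({s.site_id: 1.0 for s in genome.sites})
    cm = synth_contacts(genome)
    return compute_pair_weights(genome, EventWeightModel(0, 0), profile, cm)


class TestSimulatePool:
    def test_lambda_zero_empty_log(self, toy):
        log, genomes = simulate_pool(
            toy, _uniform_weights(toy), SimConfig(n_cells=20, lambda_events=0, seed=1)
        )
        assert log.records == [] and genomes == []

    def test_fixed_seed_reproducible(self, toy):
        w = _uniform_weights(toy)
        cfg = SimConfig(n_cells=30, lambda_events=2, seed=9)
        log1, _ = simulate_pool(toy, w, cfg)
        log2, _ = simulate_pool(toy, w, cfg)
        assert log1.to_frame().equals(log2.to_frame())

    def test_no_positive_weights_error(self, toy):
        w = _uniform_weights(toy)
        w.W[:] = 0.0
        with pytest.raises(SimulationError, match="weight"):
            simulate_pool(toy, w, SimConfig(n_cells=5, lambda_events=1, seed=0))

    def test_pair_frequencies_converge_to_weights(self, six_site):
        """Chi-square goodness of fit of sampled pairs against w/sum(w)."""
        profile, _ = synth_accessibility(six_site, seed=2)
        cm = synth_contacts(six_site)
        w = compute_pair_weights(six_site, EventWeightModel(1.0, 1.0), profile, cm)
        cfg = SimConfig(n_cells=1000, lambda_events=100, seed=11)
        log, _ = simulate_pool(six_site, w, cfg)
        counts = log.pair_counts()
        iu, ju = np.triu_indices(6, k=1)
        expected_p = w.W[iu, ju] / w.W[iu, ju].sum()
        observed = np.array(
            [
                counts.get((w.sites[a].site_id, w.sites[b].site_id), 0)
                for a, b in zip(iu, ju)
            ]
        )
        chi = stats.chisquare(observed, expected_p * observed.sum())
        assert chi.pvalue > 0.01

    def test_event_counts_monotone_in_accessibility(self, mini):
        profile, _ = synth_accessibility(mini, seed=4)
        cm = synth_contacts(mini)
        w = compute_pair_weights(mini, EventWeightModel(1.0, 0.0), profile, cm)
        cfg = SimConfig(n_cells=1000, lambda_events=100, seed=12)
        log, _ = simulate_pool(mini, w, cfg)
        per_site = {s.site_id: 0 for s in w.sites}
        for r in log.records:
            per_site[r.site_i] += 1
            per_site[r.site_j] += 1
        a = [profile[sid] for sid in per_site]
        rho = stats.spearmanr(list(per_site.values()), a).statistic
        assert rho >= 0.9

    def test_contact_exponent_concentrates_events_near_diagonal(self, toy):
        profile = AccessibilityProfile({s.site_id: 1.0 for s in toy.sites})
        cm = synth_contacts(toy)
        medians = []
        for beta in (0.0, 1.0, 2.0):
            w = compute_pair_weights(toy, EventWeightModel(0.0, beta), profile, cm)
            log, _ = simulate_pool(
                toy, w, SimConfig(n_cells=200, lambda_events=100, seed=13)
            )
            dists = [
                abs(toy.site(r.site_i).pos - toy.site(r.site_j).pos)
                for r in log.records
                if toy.site(r.site_i).chrom == toy.site(r.site_j).chrom
            ]
            medians.append(np.median(dists))
        assert medians[0] > medians[1] > medians[2]


class TestGenomeSequential:
    def test_survivors_always_have_one_centromere_each(self, toy):
        w = _uniform_weights(toy)
        cfg = SimConfig(n_cells=60, lambda_events=3, seed=21, mode="genome_sequential")
        log, survivors = simulate_pool(toy, w, cfg)
        assert survivors, "some cells should survive"
        for cell in survivors:
            assert viability_check(cell)
            assert all(c.centromere_count() == 1 for c in cell)

    def test_inviable_cells_logged_not_returned(self, toy):
        w = _uniform_weights(toy)
        cfg = SimConfig(n_cells=120, lambda_events=4, seed=22, mode="genome_sequential")
        log, survivors = simulate_pool(toy, w, cfg)
        dead_cells = {r.cell for r in log.records if not r.viable}
        assert dead_cells, "deletions over the centromere should kill some cells"
        alive_cells = {r.cell for r in log.records if r.viable}
        assert len(survivors) <= cfg.n_cells - len(dead_cells) + len(alive_cells)

    def test_deletion_shortens_by_inter_site_interval(self, toy):
        cell = segment_genome(toy)
        s0, s1 = toy.sites_on("chrA")[0], toy.sites_on("chrA")[1]
        juncs = apply_event(cell, s0.site_id, s1.site_id, DELETION)
        seqs = realize_genome(cell, toy)
        assert len(seqs["chrA"]) == toy.chromosomes["chrA"].length - (s1.pos - s0.pos)
        assert juncs == [((s0.site_id, "L"), (s1.site_id, "R"))]

    def test_deletion_spanning_centromere_is_inviable(self, toy):
        cell = segment_genome(toy)
        cen = toy.chromosomes["chrA"].centromere_pos
        before = [s for s in toy.sites_on("chrA") if s.pos < cen][-1]
        after = [s for s in toy.sites_on("chrA") if s.pos > cen][0]
        apply_event(cell, before.site_id, after.site_id, DELETION)
        assert not viability_check(cell)

    def test_arm_swap_translocation_preserves_viability(self, toy):
        cell = segment_genome(toy)
        a = [s for s in toy.sites_on("chrA") if s.pos > 30_000][0]
        b = [s for s in toy.sites_on("chrB") if s.pos > 20_000][0]
        apply_event(cell, a.site_id, b.site_id, TRANSLOCATION, form=0)
        assert viability_check(cell)
        seqs = realize_genome(cell, toy)
        total_ref = sum(c.length for c in toy.chromosomes.values())
        assert sum(len(s) for s in seqs.values()) == total_ref

    def test_inversion_preserves_length_and_reverses_interior(self, toy):
        cell = segment_genome(toy)
        sA = toy.sites_on("chrA")
        apply_event(cell, sA[1].site_id, sA[3].site_id, INVERSION)
        seqs = realize_genome(cell, toy)
        ref = toy.sequences["chrA"]
        assert len(seqs["chrA"]) == len(ref)
        assert seqs["chrA"] != ref
        # outside the inverted interval the sequence is untouched
        assert seqs["chrA"][: sA[1].pos + 34] == ref[: sA[1].pos + 34]
        assert seqs["chrA"][sA[3].pos :] == ref[sA[3].pos :]


class TestEmitReads:
    def test_zero_coverage_background_only(self, toy):
        w = _uniform_weights(toy)
        cfg = SimConfig(
            n_cells=10, lambda_events=2, reads_per_junction=0,
            background_reads=50, seed=5,
        )
        log, _ = simulate_pool(toy, w, cfg)
        reads = emit_reads(log, toy, cfg)
        assert len(reads) == 50
        assert all(rid.startswith("BG") for rid, _ in reads)

    def test_fixed_seed_byte_identical_fastq(self, toy, tmp_path):
        w = _uniform_weights(toy)
        cfg = SimConfig(n_cells=10, lambda_events=2, background_reads=20, seed=6)
        log, _ = simulate_pool(toy, w, cfg)
        emit_reads(log, toy, cfg, fastq_path=tmp_path / "a.fastq")
        log2, _ = simulate_pool(toy, w, cfg)
        emit_reads(log2, toy, cfg, fastq_path=tmp_path / "b.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_junction_reads_contain_motif_with_min_flanks(self, toy):
        w = _uniform_weights(toy)
        cfg = SimConfig(n_cells=20, lambda_events=2, seed=7, error_rate=0.0)
        log, _ = simulate_pool(toy, w, cfg)
        reads = emit_reads(log, toy, cfg)
        assert reads
        for rid, seq in reads:
            off = seq.find(toy.loxpsym_motif)
            assert off >= cfg.min_flank
            assert len(seq) - off - 34 >= cfg.min_flank

    def test_read_len_too_short_rejected(self, toy):
        w = _uniform_weights(toy)
        cfg = SimConfig(n_cells=1, lambda_events=1, seed=1, read_len=70)
        log, _ = simulate_pool(toy, w, cfg)
        with pytest.raises(SimulationError, match="read_len"):
            emit_reads(log, toy, cfg)
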