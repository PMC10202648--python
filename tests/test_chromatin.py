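"""Chromatin integration: window signals, contacts, t-tests, model fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from loxscape.chromatin import (
    IntegrationError,
    build_pair_table,
    compensation_pairs,
    contact_at,
    group_compare,
    heatmap_concordance,
    joint_model_fit,
    region_enrichment,
    site_signal,
    site_signals,
)
from loxscape.classify import classify_all
from loxscape.events import RearrangementEvent, signature
from loxscape.simulate import (
    AccessibilityProfile,
    EventWeightModel,
    SimConfig,
    compute_pair_weights,
    simulate_pool,
    synth_accessibility,
    synth_contacts,
)
from loxscape.tracks import ContactModel, SignalTrack, make_bins


class TestSiteSignal:
    def test_uniform_track_normalizes_to_one(self, toy):
        track = SignalTrack(
            {n: np.full(c.length, 3.5) for n, c in toy.chromosomes.items()}
        )
        table = site_signals(track, toy)
        assert np.allclose(table.signal, 1.0)

    def test_single_site_carries_all_signal(self, toy):
        values = {n: np.zeros(c.length) for n, c in toy.chromosomes.items()}
        s0 = toy.sites[0]
        values[s0.chrom][s0.pos - 400 : s0.pos + 400] = 1.0
        table = site_signals(SignalTrack(values), toy)
        n = len(toy.analyzable_sites())
        assert table.signal.iloc[0] == pytest.approx(n, rel=0.05)
        assert (table.signal.iloc[1:] < 0.1).all()
        assert table.signal.mean() == pytest.approx(1.0)

    def test_window_truncated_at_linear_end(self):
        from loxscape.fixtures import build_genome
        from loxscape.genome import ChromosomeSpec

        g = build_genome(
            [ChromosomeSpec("c", 2_000, "linear", centromere_pos=1_000)],
            {"c": [(100, False), (1_000, False)]},
            seed=0,
        )
        values = {"c": np.ones(2_000)}
        values["c"][:600] = 2.0  # boosts only the truncated first window
        table = site_signals(SignalTrack(values), g)
        # first window is [0, 517): mean 2.0 over 483 bases + 1.0 over 34+...
        raw0 = values["c"][0:517].mean()
        raw1 = values["c"][617 : 1_417].mean()
        assert table.raw_signal.iloc[0] == pytest.approx(raw0)
        assert table.raw_signal.iloc[1] == pytest.approx(raw1)

    def test_single_site_lookup_matches_table(self, toy):
        _, track = __import__("loxscape").simulate.synth_accessibility(toy, seed=5)
        table = site_signals(track, toy)
        sid = int(table.site_id.iloc[3])
        assert site_signal(track, toy, sid) == pytest.approx(
            table.signal.iloc[3]
        )


class TestContactAt:
    @pytest.fixture()
    def cm(self, toy):
        return synth_contacts(toy)

    def test_symmetry(self, toy, cm):
        a, b = ("chrA", 5_000), ("chrB", 12_345)
        assert contact_at(cm, a, b) == contact_at(cm, b, a)

    def test_same_bin_uses_diagonal(self, toy, cm):
        v = contact_at(cm, ("chrA", 5_100), ("chrA", 5_900))
        assert v == pytest.approx(np.log2(1.0 + 1e-6))

    def test_zero_entry_hits_pseudocount_floor(self, toy):
        bins = make_bins(toy, 1000)
        C = np.eye(len(bins)) * 0.5
        cm = ContactModel(bin_size=1000, bins=bins, C=C)
        assert contact_at(cm, ("chrA", 0), ("chrB", 0)) == pytest.approx(
            np.log2(1e-6)
        )

    def test_locus_outside_range_rejected(self, toy, cm):
        with pytest.raises(KeyError):
            contact_at(cm, ("chrA", 70_000), ("chrB", 0))


class TestGroupCompare:
    def test_identical_paired_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = group_compare(a, list(a))
        assert res.t == 0.0 and res.p == 1.0 and res.mode == "paired"

    def test_equal_weights_give_arithmetic_mean(self):
        res = group_compare([1.0, 3.0], [2.0, 6.0], paired=False)
        assert res.mean_a == pytest.approx(2.0)
        assert res.mean_b == pytest.approx(4.0)
        assert res.mode == "welch"

    def test_weighted_means(self):
        res = group_compare([1.0, 3.0], [2.0, 6.0], weights_a=[3.0, 1.0],
                            weights_b=[1.0, 1.0], paired=False)
        assert res.mean_a == pytest.approx(1.5)

    def test_welch_matches_closed_form(self):
        a = np.array([1.0, 2.0, 4.0, 8.0])
        b = np.array([3.0, 3.5, 5.0, 9.0, 11.0])
        res = group_compare(a, b, paired=False)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_exp = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p_exp = 2 * stats.t.sf(abs(t_exp), df)
        assert res.t == pytest.approx(t_exp, abs=1e-12)
        assert res.p == pytest.approx(p_exp, abs=1e-12)

    def test_paired_matches_closed_form(self):
        a = np.array([1.0, 2.0, 4.0, 8.0])
        b = np.array([1.5, 1.8, 5.2, 7.1])
        res = group_compare(a, b)
        d = a - b
        t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        p_exp = 2 * stats.t.sf(abs(t_exp), d.size - 1)
        assert res.t == pytest.approx(t_exp, abs=1e-12)
        assert res.p == pytest.approx(p_exp, abs=1e-12)

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(IntegrationError):
            group_compare([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)


def _constructed_pair_table(n=40, beta_a=1.0, beta_c=1.0, seed=0, beta0=14.0):
    """Noise-free table generated exactly from the joint model (the
    intercept keeps every frequency positive, so log2(f+1) is exact)."""
    rng = np.random.default_rng(seed)
    access = 2.0 ** rng.uniform(-3, 3, n)
    contact = 2.0 ** rng.uniform(-10, -1, n)
    log_f = beta0 + beta_a * np.log2(access) + beta_c * np.log2(contact + 1e-6)
    f = 2.0**log_f - 1.0
    return pd.DataFrame(
        {
            "site_i": np.arange(n),
            "site_j": np.arange(n) + 1000,
            "read_count": f,
            "access_product": access,
            "contact": contact,
            "intra": True,
        }
    )


class TestJointModelFit:
    def test_noise_free_recovery_to_1e6(self):
        fit = joint_model_fit(_constructed_pair_table(beta_a=1.0, beta_c=1.0))
        assert fit["beta_access"] == pytest.approx(1.0, abs=1e-6)
        assert fit["beta_contact"] == pytest.approx(1.0, abs=1e-6)
        assert fit["beta0"] == pytest.approx(14.0, abs=1e-6)
        assert fit["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_null_contact_coefficient_stays_small(self):
        rng = np.random.default_rng(3)
        t = _constructed_pair_table(n=500, beta_a=1.0, beta_c=0.0, seed=3)
        t["read_count"] = t.read_count * 2.0 ** rng.normal(0, 0.05, len(t))
        fit = joint_model_fit(t)
        assert abs(fit["beta_contact"]) < 0.05

    def test_constant_predictor_flagged(self):
        t = _constructed_pair_table()
        t["contact"] = 0.25
        fit = joint_model_fit(t)
        assert any("contact" in f for f in fit["flags"])


@pytest.fixture(scope="module")
def sim_pair_table(mini):
    """Pool simulated under alpha=1, beta=1 on the mini genome."""
    profile, track = synth_accessibility(mini, seed=9)
    cm = synth_contacts(mini)
    w = compute_pair_weights(mini, EventWeightModel(1, 1), profile, cm)
    log, _ = simulate_pool(
        mini, w, SimConfig(n_cells=500, lambda_events=100, seed=41)
    )
    events = [
        RearrangementEvent(sig, 1) for rec in log.records for sig in rec.junctions
    ]
    classified = classify_all(events, mini)
    table = build_pair_table(classified, mini, profile, cm)
    return mini, profile, cm, table


class TestOnSimulatedPool:
    def test_joint_fit_recovers_positive_coefficients(self, sim_pair_table):
        _, _, _, table = sim_pair_table
        fit = joint_model_fit(table)
        assert fit["beta_access"] > 0
        assert fit["beta_contact"] > 0

    def test_heatmap_concordance_positive(self, sim_pair_table):
        mini, _, cm, table = sim_pair_table
        r, p = heatmap_concordance(table, mini, cm)
        assert r > 0 and p < 0.05

    def test_compensation_monotone_in_contact(self, sim_pair_table):
        """Within accessibility-matched pairs, frequency follows contact."""
        _, _, _, table = sim_pair_table
        panels = compensation_pairs(table, tol_access=0.25, tol_contact=0.5)
        matched = panels["matched_access"]
        assert len(matched) > 10
        agree = np.sign(matched.d_log2_contact) == np.sign(matched.d_log2_freq)
        res = stats.binomtest(int(agree.sum()), len(matched), 0.5,
                              alternative="greater")
        assert res.pvalue < 0.05


class TestRegionEnrichment:
    def test_cen_boost_detected(self, mini):
        profile = AccessibilityProfile({s.site_id: 1.0 for s in mini.sites})
        cm = synth_contacts(mini, boost_cen=6.0, boost_tel=1.0)
        w = compute_pair_weights(mini, EventWeightModel(0, 1), profile, cm)
        log, _ = simulate_pool(
            mini, w, SimConfig(n_cells=1000, lambda_events=100, seed=43)
        )
        events = [
            RearrangementEvent(sig, 1) for rec in log.records for sig in rec.junctions
        ]
        table = build_pair_table(classify_all(events, mini), mini, profile, cm)
        res = region_enrichment(table, mini, cm)
        assert not res["CEN"]["skipped"]
        cen = res["CEN"]
        assert cen["contact"].mean_a > cen["contact"].mean_b
        assert cen["frequency"].mean_a > cen["frequency"].mean_b
        assert cen["frequency"].p < 0.05
        assert cen["frequency"].mode == "welch"

    def test_no_boost_no_signal(self, mini):
        profile = AccessibilityProfile({s.site_id: 1.0 for s in mini.sites})
        cm = synth_contacts(mini, boost_cen=1.0, boost_tel=1.0)
        w = compute_pair_weights(mini, EventWeightModel(0, 1), profile, cm)
        log, _ = simulate_pool(
            mini, w, SimConfig(n_cells=400, lambda_events=100, seed=44)
        )
        events = [
            RearrangementEvent(sig, 1) for rec in log.records for sig in rec.junctions
        ]
        table = build_pair_table(classify_all(events, mini), mini, profile, cm)
        res = region_enrichment(table, mini, cm)
        # stochastic null: no strong enrichment expected at a fixed seed
        assert res["CEN"]["frequency"].p > 0.05

    def test_degenerate_region_skipped(self, toy):
        # a genome where no bin is pericentromeric cannot be compared
        from loxscape.fixtures import build_genome
        from loxscape.genome import ChromosomeSpec

        g = build_genome(
            [
                ChromosomeSpec("x", 30_000, "linear", centromere_pos=15_000),
                ChromosomeSpec("y", 30_000, "linear", centromere_pos=15_000),
            ],
            {"x": [(12_000, False), (20_000, False)], "y": [(12_000, False)]},
            seed=1,
        )
        cm = synth_contacts(g)
        profile = AccessibilityProfile({s.site_id: 1.0 for s in g.sites})
        table = build_pair_table([], g, profile, cm)
        res = region_enrichment(table, g, cm)
        assert set(res) == {"CEN", "TEL"}


class TestCompensationPairs:
    def _table(self):
        # four pairs realizing the three schematic patterns exactly:
        # p0/p1 matched accessibility, different contact;
        # p0/p2 matched contact, different accessibility;
        # p2/p3 counter-effect: open-but-distant vs closed-but-proximal
        return pd.DataFrame(
            {
                "site_i": [0, 1, 2, 3],
                "site_j": [10, 11, 12, 13],
                "read_count": [63.0, 3.0, 15.0, 15.0],
                "access_product": [4.0, 4.0, 1.0, 64.0],
                "contact": [2.0**-4, 2.0**-8, 2.0**-4, 2.0**-10],
                "intra": True,
            }
        )

    def test_each_panel_detects_its_pattern(self):
        panels = compensation_pairs(self._table(), tol_access=0.1,
                                    tol_contact=0.1, tol_freq=0.1)
        assert panels["matched_access"].pair_1.tolist() == [(0, 10)]
        assert panels["matched_access"].pair_2.tolist() == [(1, 11)]
        assert panels["matched_contact"].pair_1.tolist() == [(0, 10)]
        assert panels["matched_contact"].pair_2.tolist() == [(2, 12)]
        assert panels["counter_effect"].pair_1.tolist() == [(2, 12)]
        assert panels["counter_effect"].pair_2.tolist() == [(3, 13)]

    def test_zero_tolerance_empty_report_on_generic_data(self):
        # generic (continuous random) values never tie exactly
        panels = compensation_pairs(
            _constructed_pair_table(n=30, seed=11),
            tol_access=1e-12, tol_contact=1e-12, tol_freq=1e-12,
        )
        assert all(len(p) == 0 for p in panels.values())
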