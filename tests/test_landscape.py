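"""Landscape statistics: read attribution, decile labels, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from loxscape.classify import classify_all
from loxscape.events import RearrangementEvent, signature
from loxscape.landscape import (
    COLDSPOT,
    HOTSPOT,
    NONE,
    LandscapeError,
    decile_bins,
    pearson,
    per_chromosome_correlation,
    replicate_correlation,
    site_frequencies,
)


def _event(i, j, count=1):
    return RearrangementEvent(signature((i, "L"), (j, "R")), count)


class TestSiteFrequencies:
    def test_both_endpoints_credited_full_read_count(self, toy):
        cl = classify_all([_event(0, 3, count=5)], toy)
        table = site_frequencies(cl, toy)
        assert table.set_index("site_id").read_count.loc[0] == 5
        assert table.set_index("site_id").read_count.loc[3] == 5
        assert table.read_count.sum() == 10

    def test_empty_event_set_all_zero(self, toy):
        table = site_frequencies([], toy)
        assert (table.read_count == 0).all()
        assert len(table) == len(toy.analyzable_sites())

    def test_mass_conservation_on_simulated_pool(self, toy, pool_events):
        cl = classify_all(pool_events, toy)
        table = site_frequencies(cl, toy)
        assert table.read_count.sum() == 2 * sum(e.read_count for e in pool_events)

    def test_additive_over_concatenation(self, toy):
        a = classify_all([_event(0, 3, 2)], toy)
        b = classify_all([_event(3, 7, 4)], toy)
        both = classify_all([_event(0, 3, 2), _event(3, 7, 4)], toy)
        t = site_frequencies(a, toy).read_count + site_frequencies(b, toy).read_count
        assert (site_frequencies(both, toy).read_count == t).all()

    def test_event_touching_unknown_site_rejected(self, toy):
        ev = RearrangementEvent(signature((0, "L"), (999, "R")), 1)
        ev.event_class = "deletion"
        from loxscape.events import ClassifiedEvent

        with pytest.raises(LandscapeError):
            site_frequencies(
                [ClassifiedEvent(ev, "deletion", True)], toy
            )


@pytest.fixture(scope="module")
def pool_events(toy):
    from loxscape.simulate import (
        AccessibilityProfile,
        EventWeightModel,
        SimConfig,
        compute_pair_weights,
        simulate_pool,
        synth_contacts,
    )

    profile = AccessibilityProfile({s.site_id: 1.0 for s in toy.sites})
    w = compute_pair_weights(toy, EventWeightModel(0, 0), profile, synth_contacts(toy))
    log, _ = simulate_pool(
        toy, w, SimConfig(n_cells=100, lambda_events=3, seed=31)
    )
    return [
        RearrangementEvent(sig, 1)
        for rec in log.records
        for sig in rec.junctions
    ]


def _landscape_frame(counts):
    n = len(counts)
    return pd.DataFrame(
        {
            "site_id": np.arange(n),
            "chrom": "c",
            "pos": np.arange(n) * 100,
            "read_count": counts,
        }
    )


class TestDecileBins:
    def test_877_sites_give_88_hotspots_and_88_coldspots(self):
        rng = np.random.default_rng(0)
        binned = decile_bins(_landscape_frame(rng.integers(0, 10_000, 877)))
        assert (binned.label == HOTSPOT).sum() == 88
        assert (binned.label == COLDSPOT).sum() == 88

    def test_ten_sites_give_one_each(self):
        binned = decile_bins(_landscape_frame(np.arange(10)))
        assert (binned.label == HOTSPOT).sum() == 1
        assert (binned.label == COLDSPOT).sum() == 1
        assert binned.loc[binned.read_count.idxmax(), "label"] == HOTSPOT

    def test_deciles_partition_and_order(self):
        counts = np.arange(200)[::-1]
        binned = decile_bins(_landscape_frame(counts))
        assert sorted(binned.decile.unique()) == list(range(1, 11))
        assert (binned.groupby("decile").size() == 20).all()
        assert not set(binned[binned.label == HOTSPOT].index) & set(
            binned[binned.label == COLDSPOT].index
        )

    def test_all_equal_counts_tie_break_by_site_id(self):
        binned = decile_bins(_landscape_frame(np.full(50, 7)))
        assert list(binned[binned.label == HOTSPOT].site_id) == list(range(5))
        assert list(binned[binned.label == COLDSPOT].site_id) == list(range(45, 50))

    def test_fewer_than_ten_sites_rejected(self):
        with pytest.raises(LandscapeError):
            decile_bins(_landscape_frame(np.arange(9)))


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        x = np.arange(8.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_vectors_match_closed_form(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([0.5, 1.1, 1.9, 4.2, 5.0])
        r, p = pearson(x, y)
        # closed form: r = cov / (sx sy); p via the t transform, n-2 df
        xd, yd = x - x.mean(), y - y.mean()
        r_exp = (xd @ yd) / np.sqrt((xd @ xd) * (yd @ yd))
        t = r_exp * np.sqrt(3 / (1 - r_exp**2))
        p_exp = 2 * stats.t.sf(abs(t), df=3)
        assert r == pytest.approx(r_exp, abs=1e-12)
        assert p == pytest.approx(p_exp, abs=1e-12)

    def test_agrees_with_scipy_on_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            r, p = pearson(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(LandscapeError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPerChromosomeCorrelation:
    def test_uniform_weights_track_site_counts(self, mini):
        from loxscape.simulate import (
            AccessibilityProfile,
            EventWeightModel,
            SimConfig,
            compute_pair_weights,
            simulate_pool,
            synth_contacts,
        )

        profile = AccessibilityProfile({s.site_id: 1.0 for s in mini.sites})
        w = compute_pair_weights(
            mini, EventWeightModel(0, 0), profile, synth_contacts(mini)
        )
        log, _ = simulate_pool(
            mini, w, SimConfig(n_cells=1000, lambda_events=100, seed=33)
        )
        events = [
            RearrangementEvent(rec.junctions[0], 1) for rec in log.records
        ]
        r, p = per_chromosome_correlation(classify_all(events, mini), mini)
        assert r >= 0.9
        assert p < 0.05

    def test_fewer_than_three_chromosomes_rejected(self, toy):
        with pytest.raises(LandscapeError, match="3 chromosomes"):
            per_chromosome_correlation([], toy)

    def test_zero_variance_flagged(self, mini):
        with pytest.raises(LandscapeError, match="variance"):
            per_chromosome_correlation([], mini)  # all-zero event counts


class TestReplicateCorrelation:
    def test_identical_landscapes_r_one(self, toy):
        cl = classify_all([_event(0, 3, 5), _event(2, 7, 2)], toy)
        table = site_frequencies(cl, toy)
        r, _ = replicate_correlation(table, table.copy())
        assert r == pytest.approx(1.0)

    def test_independent_runs_same_weights_reproduce(self, mini):
        from loxscape.simulate import (
            EventWeightModel,
            SimConfig,
            compute_pair_weights,
            simulate_pool,
            synth_accessibility,
            synth_contacts,
        )

        profile, _ = synth_accessibility(mini, seed=8)
        cm = synth_contacts(mini)
        w = compute_pair_weights(mini, EventWeightModel(1, 1), profile, cm)
        tables = []
        for seed in (101, 202):
            log, _ = simulate_pool(
                mini, w, SimConfig(n_cells=1000, lambda_events=100, seed=seed)
            )
            events = [
                RearrangementEvent(sig, 1)
                for rec in log.records
                for sig in rec.junctions
            ]
            tables.append(site_frequencies(classify_all(events, mini), mini))
        r, p = replicate_correlation(*tables)
        assert r >= 0.9
        assert p < 1e-6

    def test_unrelated_landscapes_near_zero(self):
        rng = np.random.default_rng(7)
        a = _landscape_frame(rng.integers(0, 100, 200))
        b = _landscape_frame(rng.integers(0, 100, 200))
        r, _ = replicate_correlation(a, b)
        assert abs(r) < 0.2

    def test_registry_mismatch_rejected(self):
        a = _landscape_frame(np.arange(20))
        b = _landscape_frame(np.arange(21))
        with pytest.raises(LandscapeError):
            replicate_correlation(a, b)
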