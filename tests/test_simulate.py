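"""Scenario generator: determinism, balance, and sweep signatures.

The Monte-Carlo checks verify the two population-genetic signatures the
classifier is meant to learn: a local loss of polymorphism around the
swept site and a site-frequency spectrum pushed toward rare and
near-fixed derived variants.
"""

import numpy as np
import pytest
from scipy import stats

from dafnet import simulate
from dafnet.representation import compute_daf
from dafnet.simulate import (
    DatasetSpec,
    ScenarioConfig,
    load_scenario,
    make_dataset,
    make_toy_fixture,
    replicate_seed,
    simulate_replicate,
)


class TestScenarioConfigs:
    def test_all_six_scenarios_load(self):
        for sid in simulate.SCENARIO_IDS:
            cfg = load_scenario(sid)
            assert cfg.id == sid
            assert cfg.present_size == 50_000
            assert cfg.selection_coefficient == 0.02

    @pytest.mark.parametrize(
        "sid,field,value",
        [
            ("D1", "severity", 0.5),
            ("D2", "severity", 0.005),
            ("D1", "onset", 0.1),
            ("D2", "onset", 0.01),
            ("D3", "join_time", 0.003),
            ("D4", "join_time", 3),
            ("D5", "hotspot_intensity", 2),
            ("D6", "hotspot_intensity", 20),
            ("D5", "theta", 2000),
            ("D6", "rho", 2000),
            ("D1", "sweep_start", 0.016),
            ("D3", "sweep_start", 0.005),
        ],
    )
    def test_scenario_parameters(self, sid, field, value):
        assert getattr(load_scenario(sid), field) == value

    def test_confounder_fields_are_validated(self):
        with pytest.raises(ValueError, match="severity"):
            ScenarioConfig(id="X", confounder="bottleneck")

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            load_scenario("D9")


class TestSimulateReplicate:
    def test_seeded_determinism(self):
        cfg = load_scenario("D1")
        a = simulate_replicate(cfg, "neutral", 42, sample_size=16, min_snps=32)
        b = simulate_replicate(cfg, "neutral", 42, sample_size=16, min_snps=32)
        np.testing.assert_array_equal(a.alleles, b.alleles)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_polarized_output_and_metadata(self):
        cfg = load_scenario("D3")
        m = simulate_replicate(cfg, "sweep", 7, sample_size=16, min_snps=32)
        assert m.label == "sweep" and m.scenario_id == "D3"
        assert m.n_samples == 16
        assert set(np.unique(m.alleles)) <= {0, 1}
        assert np.all(np.diff(m.positions) >= 0)
        counts = m.alleles.sum(axis=0)
        assert np.all((counts > 0) & (counts < 16))  # segregating, derived = 1

    def test_sweep_shifts_sfs_to_extremes(self):
        """Sweep windows put more DAF mass at the frequency extremes."""
        cfg = load_scenario("D1")
        frac = {"neutral": [], "sweep": []}
        for cls in frac:
            for k in range(200):
                m = simulate_replicate(cfg, cls, 5000 + k, sample_size=32, min_snps=64)
                from dafnet.representation import extract_center_window

                daf = compute_daf(extract_center_window(m, 64))
                frac[cls].append(float(np.mean((daf < 0.1) | (daf > 0.9))))
            assert len(frac[cls]) == 200
        res = stats.mannwhitneyu(frac["sweep"], frac["neutral"], alternative="greater")
        assert res.pvalue < 0.01

    def test_sweep_reduces_local_polymorphism(self):
        """Fewer SNPs fall near the swept centre than in neutral data."""
        cfg = load_scenario("D1")
        central = {"neutral": [], "sweep": []}
        for cls in central:
            for k in range(200):
                m = simulate_replicate(cfg, cls, 6000 + k, sample_size=32, min_snps=64)
                central[cls].append(
                    float(np.mean(np.abs(m.positions - 0.5) < 0.1))
                )
        res = stats.mannwhitneyu(
            central["sweep"], central["neutral"], alternative="less"
        )
        assert res.pvalue < 0.01

    def test_severe_bottleneck_reduces_segregating_sites(self):
        """D2 neutral replicates carry fewer SNPs than a constant-size
        population at equal theta (Monte-Carlo, 500 each)."""
        d2 = load_scenario("D2")
        const = load_scenario("CONST")
        assert d2.theta == const.theta
        n_d2, n_const = [], []
        for k in range(500):
            n_d2.append(
                simulate_replicate(d2, "neutral", 7000 + k, sample_size=16, min_snps=1).n_snps
            )
            n_const.append(
                simulate_replicate(const, "neutral", 8000 + k, sample_size=16, min_snps=1).n_snps
            )
        assert np.mean(n_d2) < np.mean(n_const)
        assert stats.mannwhitneyu(n_d2, n_const, alternative="less").pvalue < 0.01


@pytest.fixture(scope="module")
def small():
    return make_dataset(
        load_scenario("D1"),
        DatasetSpec(n_train=20, n_val=10, n_test=10, sample_size=16,
                    window_width=32, seed=5),
    )


class TestMakeDataset:
    def test_split_sizes_and_exact_balance(self, small):
        for name, n in (("train", 20), ("val", 10), ("test", 10)):
            split = small.splits[name]
            assert len(split) == n
            assert int(split.labels.sum()) == n // 2

    def test_windows_cut_to_width(self, small):
        assert all(m.n_snps == 32 for m in small.train.matrices)
        assert all(m.n_samples == 16 for m in small.train.matrices)

    def test_same_seed_reproduces_dataset(self, small):
        again = make_dataset(
            load_scenario("D1"),
            DatasetSpec(n_train=20, n_val=10, n_test=10, sample_size=16,
                        window_width=32, seed=5),
        )
        for a, b in zip(small.test.matrices, again.test.matrices):
            np.testing.assert_array_equal(a.alleles, b.alleles)

    def test_replicate_reproducible_in_isolation(self, small):
        k = 3  # a neutral train window
        m = simulate_replicate(
            load_scenario("D1"), "neutral", replicate_seed(5, "train", k),
            sample_size=16, min_snps=32,
        )
        from dafnet.representation import extract_center_window

        np.testing.assert_array_equal(
            extract_center_window(m, 32).alleles, small.train.matrices[k].alleles
        )

    def test_odd_split_sizes_rejected(self):
        with pytest.raises(ValueError):
            DatasetSpec(n_train=11)

    def test_features_shape(self, small):
        x, y = small.val.features()
        assert x.shape == (10, 2, 32) and y.shape == (10,)


class TestToyFixtures:
    def test_all_derived(self):
        assert compute_daf(make_toy_fixture("all_derived")) == pytest.approx([1.0] * 4)

    def test_checkerboard(self):
        assert compute_daf(make_toy_fixture("checkerboard")) == pytest.approx([0.5] * 4)

    def test_with_missing_uses_reduced_denominator(self):
        m = make_toy_fixture("with_missing")
        assert compute_daf(m) == pytest.approx([2 / 3, 2 / 3, 1 / 2])

    def test_sweep_like_is_more_extreme_than_neutral_like(self):
        sweep = compute_daf(make_toy_fixture("sweep_like"))
        neutral = compute_daf(make_toy_fixture("neutral_like"))
        extreme = lambda d: np.mean((d < 0.2) | (d > 0.8))
        assert extreme(sweep) > extreme(neutral)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_toy_fixture("nope")
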