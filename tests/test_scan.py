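"""Sliding-window scanning: geometry, reuse equivalence, localization."""

import numpy as np
import pytest

from dafnet import scan as scan_mod
from dafnet.representation import SNPMatrix
from dafnet.scan import ScanRecord, read_scan_tsv, scan, sliding_windows, write_scan_tsv
from dafnet.simulate import load_scenario, simulate_replicate
from dafnet.training import evaluate


def random_chromosome(rng, n=8, snps=40, chrom=None):
    a = rng.integers(0, 2, size=(n, snps), dtype=np.int8)
    a[0] = 1  # keep loci called
    pos = np.sort(rng.uniform(size=snps)) if chrom is None else np.sort(
        rng.integers(1, 10**6, size=snps)
    ).astype(float)
    return SNPMatrix(alleles=a, positions=pos, chrom=chrom)


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "snps,width,step,starts",
        [
            (10, 4, 2, [0, 2, 4, 6]),
            (10, 5, 5, [0, 5]),  # step = W tiles without overlap
            (10, 10, 1, [0]),
            (9, 4, 4, [0, 4]),  # trailing partial window dropped
        ],
    )
    def test_offsets(self, rng, snps, width, step, starts):
        m = random_chromosome(rng, snps=snps)
        got = [s for s, _ in sliding_windows(m, width, step)]
        assert got == starts

    def test_windows_carry_correct_slices(self, rng):
        m = random_chromosome(rng, snps=12)
        for s, win in sliding_windows(m, 5, 3):
            np.testing.assert_array_equal(win.alleles, m.alleles[:, s : s + 5])

    def test_too_wide_window_yields_empty_stream(self, rng):
        m = random_chromosome(rng, snps=5)
        assert list(sliding_windows(m, 10, 1)) == []

    def test_coverage_when_step_not_larger_than_width(self, rng):
        m = random_chromosome(rng, snps=30)
        width, step = 8, 5
        covered = np.zeros(30, dtype=bool)
        last_end = 0
        for s, _ in sliding_windows(m, width, step):
            covered[s : s + width] = True
            last_end = s + width
        assert covered[:last_end].all()


#: constant-size scan scenario with enough recombination that the sweep
#: footprint occupies only part of the region, so localization is testable
SCAN_SCENARIO = load_scenario("CONST").replace(theta=2000, rho=2000, sweep_start=0.005)


@pytest.fixture(scope="module")
def toy_checkpoint():
    """A small 1-D model trained on constant-size simulations."""
    from dafnet import models, simulate, training

    spec = simulate.DatasetSpec(
        n_train=300, n_val=100, n_test=2, sample_size=32, window_width=32, seed=77
    )
    data = simulate.make_dataset(SCAN_SCENARIO, spec)
    model = models.build_1d_model(
        models.ModelSpec(3, 32, 2, 1, input_width=32), seed=0
    )
    ckpt, _ = training.train(
        model,
        training.ArraySet.from_windows(data.train),
        training.ArraySet.from_windows(data.val),
        training.TrainConfig(epochs=30, seed=0),
    )
    return ckpt


class TestScan:
    def test_records_are_ordered_and_bounded(self, toy_checkpoint, rng):
        m = random_chromosome(rng, n=16, snps=100)
        records = scan(toy_checkpoint, m, width=32, step=8)
        assert [r.snp_start for r in records] == sorted(r.snp_start for r in records)
        assert all(0.0 <= r.p_sweep <= 1.0 for r in records)
        assert all(r.snp_end - r.snp_start == 32 for r in records)

    def test_reuse_and_naive_paths_bit_identical(self, toy_checkpoint, rng):
        for _ in range(5):
            m = random_chromosome(rng, n=16, snps=90)
            fast = scan(toy_checkpoint, m, width=32, step=7, reuse=True)
            slow = scan(toy_checkpoint, m, width=32, step=7, reuse=False)
            assert [r.p_sweep for r in fast] == [r.p_sweep for r in slow]
            assert [r.snp_start for r in fast] == [r.snp_start for r in slow]

    def test_translation_invariance_of_probabilities(self, toy_checkpoint, rng):
        m = random_chromosome(rng, n=16, snps=80)
        shifted = SNPMatrix(
            alleles=m.alleles, positions=m.positions + 123.0, chrom=m.chrom
        )
        a = scan(toy_checkpoint, m, width=32, step=8)
        b = scan(toy_checkpoint, shifted, width=32, step=8)
        assert [r.p_sweep for r in a] == pytest.approx(
            [r.p_sweep for r in b], abs=1e-12
        )

    def test_width_mismatch_rejected(self, toy_checkpoint, rng):
        with pytest.raises(ValueError, match="window"):
            scan(toy_checkpoint, random_chromosome(rng, snps=100), width=64)

    def test_sweep_localization(self, toy_checkpoint):
        """The top-probability window centres on the swept site in most
        replicates (sweeps sit at the region centre)."""
        hits = 0
        n_reps = 50
        for k in range(n_reps):
            m = simulate_replicate(
                SCAN_SCENARIO, "sweep", 40_000 + k, sample_size=32, min_snps=64
            )
            records = scan(toy_checkpoint, m, width=32, step=16)
            best = max(records, key=lambda r: r.p_sweep)
            centre = (best.snp_start + best.snp_end) / 2
            if abs(centre - m.n_snps / 2) <= m.n_snps * 0.125:
                hits += 1
        assert hits > n_reps / 2

    def test_neutral_scan_mean_probability_below_half(self, toy_checkpoint):
        means = []
        for k in range(20):
            m = simulate_replicate(
                SCAN_SCENARIO, "neutral", 50_000 + k, sample_size=32, min_snps=64
            )
            records = scan(toy_checkpoint, m, width=32, step=32)
            means.append(np.mean([r.p_sweep for r in records]))
        assert np.mean(means) < 0.5


class TestScanTsv:
    def make_records(self):
        return [
            ScanRecord(0, 0, 4, 0.25, chrom="chr2", bp_start=100, bp_end=400),
            ScanRecord(1, 2, 6, 0.75, chrom="chr2", bp_start=300, bp_end=700),
            ScanRecord(2, 4, 8, 0.5),
            ScanRecord(3, 6, 10, 1 / 3),
        ]

    def test_row_count_and_round_trip(self, tmp_path):
        path = str(tmp_path / "scan.tsv")
        records = self.make_records()
        write_scan_tsv(records, path)
        lines = open(path).read().splitlines()
        assert len(lines) == 5 and lines[0].startswith("chrom\t")
        back = read_scan_tsv(path)
        for a, b in zip(records, back):
            assert (a.snp_start, a.snp_end, a.chrom, a.bp_start) == (
                b.snp_start, b.snp_end, b.chrom, b.bp_start,
            )
            assert b.p_sweep == pytest.approx(a.p_sweep, abs=1e-6)

    def test_empty_records_write_header_only(self, tmp_path):
        path = str(tmp_path / "scan.tsv")
        write_scan_tsv([], path)
        assert open(path).read().splitlines() == [
            "chrom\tbp_start\tbp_end\tsnp_start\tsnp_end\tp_sweep"
        ]
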