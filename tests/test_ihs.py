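import numpy as np
import pandas as pd
import pytest

from glycoscan.core_io import GlycoscanError
from glycoscan.ihs import (
    EhhCurve,
    IhsParams,
    ehh,
    ihh,
    ihs_scan,
    ihs_unstandardized,
    standardize_ihs,
)
from glycoscan.synthetic import SimulationConfig, simulate_panel

from _oracles import ehh_pairwise
from conftest import make_panel, single_group_scheme


def curve(points, **kw):
    pos = np.array([p for p, _ in points], dtype=float)
    val = np.array([v for _, v in points], dtype=float)
    return EhhCurve("s0", "derived", "right", pos, val, **kw)


class TestEhh:
    def test_unity_at_core(self):
        H = np.array([[1, 0], [1, 1], [1, 0], [1, 1]], dtype=np.int8)
        c = ehh(make_panel(H), 0, "derived", "right", cutoff=0.0)
        assert c.ehh[0] == 1.0
        assert c.positions[0] == 1000

    def test_hand_counted_example(self):
        """4 carriers extending right as (0,1),(0,1),(1,1),(1,0):
        EHH = 2/6 after one SNP, 1/6 after two."""
        H = np.array(
            [[1, 0, 1], [1, 0, 1], [1, 1, 1], [1, 1, 0], [0, 0, 0], [0, 0, 0]],
            dtype=np.int8,
        )
        c = ehh(make_panel(H), 0, "derived", "right", cutoff=0.0)
        np.testing.assert_allclose(c.ehh, [1.0, 2 / 6, 1 / 6])

    def test_identical_carriers_stay_at_one(self):
        H = np.tile(np.array([[1, 0, 1, 1, 0]], dtype=np.int8), (6, 1))
        c = ehh(make_panel(H), 2, "derived", "right", cutoff=0.05)
        np.testing.assert_array_equal(c.ehh, 1.0)
        assert c.truncated_at_end

    def test_truncates_at_cutoff_inclusive(self):
        H = np.array(
            [[1, 0, 0], [1, 1, 0], [1, 0, 1], [1, 1, 1]], dtype=np.int8
        )
        # after one SNP groups are {2,2} -> EHH 2/6; after two all distinct -> 0
        c = ehh(make_panel(H), 0, "derived", "right", cutoff=0.4)
        np.testing.assert_allclose(c.ehh, [1.0, 2 / 6])
        assert not c.truncated_at_end

    def test_too_few_carriers_errors(self):
        H = np.array([[1, 0], [0, 0], [0, 1], [0, 0]], dtype=np.int8)
        with pytest.raises(GlycoscanError, match="too rare"):
            ehh(make_panel(H), 0, "derived", "right")

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            H = (np.random.default_rng(seed).random((12, 15)) < 0.5).astype(np.int8)
            H[:, 7] = np.array([1] * 6 + [0] * 6)
            for allele in ("ancestral", "derived"):
                for direction in ("left", "right"):
                    c = ehh(make_panel(H), 7, allele, direction, cutoff=0.0)
                    assert (np.diff(c.ehh) <= 1e-12).all()

    def test_agrees_with_pairwise_homozygosity_oracle(self):
        """Grouped-haplotype EHH equals the probability two random distinct
        carriers are identical over the span (O(n^2 m) oracle)."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            H = (rng.random((30, 20)) < rng.uniform(0.2, 0.8)).astype(np.int8)
            core = 10
            H[:, core] = np.array([1] * 15 + [0] * 15)
            panel = make_panel(H)
            for allele, code in (("derived", 1), ("ancestral", 0)):
                carriers = np.flatnonzero(H[:, core] == code)
                for direction, step in (("right", 1), ("left", -1)):
                    c = ehh(panel, core, allele, direction, cutoff=0.0)
                    for k, e in enumerate(c.ehh[1:], start=1):
                        j = core + step * k
                        assert e == pytest.approx(
                            ehh_pairwise(H, carriers, core, j), abs=1e-12
                        )


class TestIhh:
    def test_trapezoid_example(self):
        left = curve([(0, 1.0)])
        right = curve([(0, 1.0), (1000, 0.5), (2000, 0.05)])
        assert ihh(left, right) == pytest.approx(750 + 275)

    def test_constant_ehh_over_10kb(self):
        left = curve([(0, 1.0)])
        right = curve([(0, 1.0), (5000, 1.0), (10_000, 1.0)])
        assert ihh(left, right) == pytest.approx(10_000)

    def test_halving_distances_halves_integral(self):
        right = curve([(0, 1.0), (1000, 0.6), (3000, 0.1)])
        half = curve([(0, 1.0), (500, 0.6), (1500, 0.1)])
        flat = curve([(0, 1.0)])
        assert ihh(flat, half) == pytest.approx(ihh(flat, right) / 2)

    def test_mismatched_cores_error(self):
        a = curve([(0, 1.0)])
        b = EhhCurve("other", "derived", "left", np.array([0.0]), np.array([1.0]))
        with pytest.raises(GlycoscanError, match="share"):
            ihh(b, a)


class TestUnstandardized:
    def test_equal_integrals_zero(self):
        assert ihs_unstandardized(1000.0, 1000.0) == 0.0

    def test_log_two(self):
        assert ihs_unstandardized(2000.0, 1000.0) == pytest.approx(np.log(2))

    def test_antisymmetric(self):
        assert ihs_unstandardized(1500.0, 700.0) == pytest.approx(
            -ihs_unstandardized(700.0, 1500.0)
        )

    def test_zero_integral_missing(self):
        assert np.isnan(ihs_unstandardized(0.0, 1000.0))


class TestStandardize:
    def _frame(self, freqs, values):
        return pd.DataFrame({"derived_freq": freqs, "unstandardized": values})

    def test_within_bin_moments(self):
        rng = np.random.default_rng(1)
        df = self._frame(rng.uniform(0.05, 0.95, 500), rng.normal(0, 1, 500))
        out = standardize_ihs(df, n_bins=20, min_bin_count=10)
        for b, sub in out.groupby("bin_id"):
            z = sub["standardized"]
            assert abs(z.mean()) < 1e-12
            assert abs(z.std(ddof=1) - 1) < 1e-12

    def test_value_at_bin_mean_maps_to_zero(self):
        df = self._frame([0.11, 0.12, 0.13], [1.0, 2.0, 3.0])
        out = standardize_ihs(df, n_bins=5, min_bin_count=1)
        assert out["standardized"].iloc[1] == pytest.approx(0.0)

    def test_two_bin_hand_oracle(self):
        """Hand-computed bin means/sds (spreadsheet style) to 1e-12."""
        freqs = [0.10, 0.12, 0.14, 0.60, 0.62, 0.64]
        vals = [1.0, 2.0, 4.0, -1.0, 0.0, 3.0]
        out = standardize_ihs(self._frame(freqs, vals), n_bins=2, min_bin_count=1)
        m1, s1 = np.mean([1, 2, 4]), np.std([1, 2, 4], ddof=1)
        m2, s2 = np.mean([-1, 0, 3]), np.std([-1, 0, 3], ddof=1)
        expected = [(v - m1) / s1 for v in [1, 2, 4]] + [(v - m2) / s2 for v in [-1, 0, 3]]
        np.testing.assert_allclose(out["standardized"], expected, atol=1e-12)
        np.testing.assert_allclose(out["abs_standardized"], np.abs(expected), atol=1e-12)

    def test_small_bins_merge_into_neighbor(self):
        freqs = [0.05] * 2 + [0.50] * 20
        vals = list(np.arange(22, dtype=float))
        out = standardize_ihs(self._frame(freqs, vals), n_bins=20, min_bin_count=10)
        assert out["bin_id"].nunique() == 1

    def test_degenerate_bin_errors(self):
        df = self._frame([0.5] * 5, [2.0] * 5)
        with pytest.raises(GlycoscanError, match="degenerate"):
            standardize_ihs(df, n_bins=20, min_bin_count=1)


class TestIhsScan:
    def test_deterministic(self, null_panel, neutral_ihs_track):
        again = ihs_scan(null_panel, single_group_scheme(null_panel), "G1")
        pd.testing.assert_frame_equal(again.table, neutral_ihs_track.table)

    def test_flagged_frequencies_not_scored(self, neutral_ihs_track):
        t = neutral_ihs_track.table
        extreme = (t["derived_freq_group"] < 0.05) | (t["derived_freq_group"] > 0.95)
        assert t.loc[extreme, "value"].isna().all()

    def test_global_allele_flip_preserves_absolute_values(self):
        cfg = SimulationConfig(
            seed=21, n_groups=1, samples_per_group=25, n_snps=300,
            chromosome_length_bp=3_000_000, gene_count=4, background_region_count=5,
        )
        panel = simulate_panel(cfg)
        flipped = make_panel(1 - panel.haplotypes, panel.snps["position_bp"].to_numpy())
        a = ihs_scan(panel, single_group_scheme(panel), "G1").table
        b = ihs_scan(flipped, single_group_scheme(flipped), "G1").table
        ok = a["value"].notna() & b["value"].notna()
        assert ok.sum() > 200
        np.testing.assert_allclose(a.loc[ok, "value"], b.loc[ok, "value"], atol=1e-9)
        np.testing.assert_allclose(
            a.loc[ok, "ihs"], -b.loc[ok, "ihs"], atol=1e-9
        )

    def test_missing_genotypes_rejected(self):
        H = np.zeros((4, 3), dtype=np.int8)
        H[0, 0] = -1
        H[1] = 1
        panel = make_panel(H)
        with pytest.raises(GlycoscanError, match="complete haplotypes"):
            ihs_scan(panel, single_group_scheme(panel), "G1")
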