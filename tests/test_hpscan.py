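from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolsweep.hpscan import (
    PooledHpScan,
    SiteCounts,
    hp,
    permute_thresholds,
    permute_window_pvalues,
    scan,
    significant_windows,
    site_counts,
    site_counts_frame,
    window_grid,
)
from poolsweep.io import GenomeLayout

from .conftest import make_call


def sites_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "n_maj", "n_min"])


def brute_force_scan(sites, layout, window=40_000, step=20_000, min_snps=10):
    """Independent per-window recomputation by direct summation."""
    rows = []
    for chrom in layout.chroms:
        for start, end in window_grid(layout[chrom], window, step):
            sub = sites[
                (sites["chrom"] == chrom)
                & (sites["pos"] - 1 >= start)
                & (sites["pos"] - 1 < end)
            ]
            n = len(sub)
            if n > min_snps:
                s_maj = sub["n_maj"].sum()
                s_min = sub["n_min"].sum()
                value = 2.0 * s_maj * s_min / (s_maj + s_min) ** 2
            else:
                value = np.nan
            rows.append((chrom, start, end, n, value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "hp"])


class TestSiteCounts:
    @pytest.mark.parametrize(
        "depth,alt,expected",
        [(10, 3, (7, 3)), (10, 5, (5, 5)), (8, 8, (8, 0))],
    )
    def test_orientation(self, depth, alt, expected):
        call = make_call(1, depth=depth, alt_fwd=alt // 2, alt_rev=alt - alt // 2)
        sc = site_counts(call)
        assert (sc.n_maj, sc.n_min) == expected

    def test_zero_depth_error(self):
        with pytest.raises(ValueError):
            site_counts(make_call(1, depth=0, alt_fwd=0, alt_rev=0))

    def test_invariants(self):
        with pytest.raises(ValueError):
            SiteCounts("chr1", 1, 2, 3)  # n_maj < n_min
        with pytest.raises(ValueError):
            SiteCounts("chr1", 1, 0, 0)  # zero reads


class TestHpFormula:
    def test_single_balanced_site_is_half(self):
        assert hp([SiteCounts("c", 1, 5, 5)]) == 0.5

    def test_all_fixed_is_zero(self):
        assert hp([SiteCounts("c", 1, 9, 0), SiteCounts("c", 2, 7, 0)]) == 0.0

    def test_printed_example(self):
        got = hp([SiteCounts("c", 1, 8, 2), SiteCounts("c", 2, 6, 4)])
        assert got == pytest.approx(0.42)

    def test_array_form_agrees(self):
        assert hp(np.array([8, 6]), np.array([2, 4])) == pytest.approx(0.42)

    def test_empty_window_undefined(self):
        with pytest.raises(ValueError):
            hp([])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=1, max_size=20))
    def test_bounds_and_symmetry(self, pairs):
        pairs = [(max(a, b), min(a, b)) for a, b in pairs if a + b > 0]
        if not pairs:
            return
        counts = [SiteCounts("c", i + 1, a, b) for i, (a, b) in enumerate(pairs)]
        value = hp(counts)
        assert 0.0 <= value <= 0.5
        # swapping labels at every site leaves Hp unchanged (formula symmetry)
        swapped = hp(
            np.array([b for _, b in pairs]), np.array([a for a, _ in pairs])
        )
        assert value == pytest.approx(swapped)
        s_maj = sum(a for a, _ in pairs)
        s_min = sum(b for _, b in pairs)
        assert (value == 0.5) == (s_maj == s_min)


class TestWindowGrid:
    def test_hundred_kb_has_four_windows(self):
        assert window_grid(100_000) == [
            (0, 40_000), (20_000, 60_000), (40_000, 80_000), (60_000, 100_000)
        ]

    def test_partial_terminal_window_included_when_long_enough(self):
        assert window_grid(110_000)[-1] == (80_000, 110_000)

    def test_short_remainder_dropped(self):
        # 95 kb: last full window [40k, 80k), remainder [60k, 95k) is 35 kb
        assert window_grid(95_000)[-1] == (60_000, 95_000)
        # 90 kb: remainder from 60k is 30 kb >= 20 kb -> kept
        assert window_grid(90_000)[-1] == (60_000, 90_000)

    def test_chromosome_shorter_than_window(self):
        assert window_grid(30_000) == [(0, 30_000)]
        assert window_grid(10_000) == []

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            window_grid(0)


class TestScan:
    def layout(self):
        return GenomeLayout(lengths={"chr1": 100_000})

    def test_window_with_ten_sites_excluded(self):
        rows = [("chr1", 1000 + i * 100, 6, 4) for i in range(10)]
        df = scan(sites_df(rows), self.layout())
        first = df.iloc[0]
        assert first["n_snps"] == 10
        assert np.isnan(first["hp"])

    def test_eleven_fixed_sites_analysed_hp_zero(self):
        rows = [("chr1", 1000 + i * 100, 8, 0) for i in range(11)]
        df = scan(sites_df(rows), self.layout())
        first = df.iloc[0]
        assert first["n_snps"] == 11
        assert first["hp"] == 0.0

    def test_site_beyond_chromosome_is_hard_error(self):
        rows = [("chr1", 200_000, 6, 4)]
        with pytest.raises(ValueError, match="beyond chromosome"):
            scan(sites_df(rows), self.layout())

    def test_matches_brute_force_on_random_sites(self):
        rng = np.random.default_rng(5)
        layout = GenomeLayout(lengths={"chr1": 300_000, "chr2": 150_000})
        rows = []
        for chrom, length in layout.lengths.items():
            for p in np.sort(rng.choice(length, size=400, replace=False)):
                d = int(rng.integers(1, 30))
                a = int(rng.integers(0, d + 1))
                rows.append((chrom, int(p) + 1, max(a, d - a), min(a, d - a)))
        sites = sites_df(rows)
        got = scan(sites, layout)
        want = brute_force_scan(sites, layout)
        pd.testing.assert_frame_equal(got, want, check_dtype=False)


class TestPermutation:
    def uniform_sites(self, n=300, length=100_000, seed=0, pair=(6, 4)):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        return sites_df([("chr1", int(p), pair[0], pair[1]) for p in pos])

    def test_requires_seed(self):
        layout = GenomeLayout(lengths={"chr1": 100_000})
        with pytest.raises(ValueError, match="seed"):
            permute_thresholds(self.uniform_sites(), layout, n_perm=10)

    def test_shuffle_invariant_input_yields_no_significance(self):
        """Identical (6,4) counts everywhere: every shuffle reproduces the
        observed windows, so the threshold equals the observed Hp and no
        window is strictly below it."""
        layout = GenomeLayout(lengths={"chr1": 100_000})
        sites = self.uniform_sites()
        thresholds = permute_thresholds(
            sites, layout, n_perm=50, alphas=(0.05,), seed=9
        )
        windows = scan(sites, layout)
        observed = windows["hp"].dropna().unique()
        assert len(set(np.round(observed, 12))) == 1
        (thr,) = thresholds
        assert thr.threshold == pytest.approx(observed[0])
        flagged = significant_windows(windows, thresholds, 0.05)
        assert not flagged["significant"].any()

    def test_two_permutation_replay_oracle(self):
        """n_perm=2 on a small chromosome: replay the same seeded shuffles by
        hand and recompute window minima by brute force."""
        layout = GenomeLayout(lengths={"chr1": 100_000})
        rng0 = np.random.default_rng(1)
        pos = np.sort(rng0.choice(100_000, size=60, replace=False)) + 1
        maj = rng0.integers(5, 20, size=60)
        mnr = rng0.integers(0, 5, size=60)
        mnr = np.minimum(maj, mnr)
        sites = sites_df(list(zip(["chr1"] * 60, pos, maj, mnr)))

        seed = 77
        thresholds = permute_thresholds(
            sites, layout, n_perm=2, alphas=(0.5,), seed=seed, min_snps=5
        )
        # independent replay: same generator sequence, brute-force windows
        rng = np.random.default_rng(seed)
        idx = rng.permuted(np.tile(np.arange(60), (2, 1)), axis=1)
        minima = []
        for row in idx:
            shuffled = sites_df(
                list(zip(["chr1"] * 60, pos, maj[row], mnr[row]))
            )
            win = brute_force_scan(shuffled, layout, min_snps=5)
            minima.append(win["hp"].min())
        expected = sorted(minima)[0]  # ceil(0.5 * 2) = 1st order statistic
        (thr,) = thresholds
        assert thr.threshold == pytest.approx(expected)

    def test_permutation_preserves_count_multiset(self):
        sites = self.uniform_sites(n=40)
        pos0 = sites["pos"].to_numpy() - 1
        maj = sites["n_maj"].to_numpy()
        mnr = sites["n_min"].to_numpy()
        rng = np.random.default_rng(4)
        idx = rng.permuted(np.tile(np.arange(40), (5, 1)), axis=1)
        for row in idx:
            assert sorted(zip(maj[row], mnr[row])) == sorted(zip(maj, mnr))

    def test_thresholds_monotone_in_alpha(self):
        rng = np.random.default_rng(12)
        pos = np.sort(rng.choice(200_000, size=900, replace=False)) + 1
        maj = rng.integers(4, 16, size=900)
        mnr = rng.integers(0, 5, size=900)
        mnr = np.minimum(maj, mnr)
        sites = sites_df(list(zip(["chr1"] * 900, pos, maj, mnr)))
        layout = GenomeLayout(lengths={"chr1": 200_000})
        thresholds = permute_thresholds(
            sites, layout, n_perm=200, alphas=(0.001, 0.01, 0.05), seed=2
        )
        values = [t.threshold for t in sorted(thresholds, key=lambda t: t.alpha)]
        assert values == sorted(values)
        assert all(0.0 <= v <= 0.5 for v in values)

    def test_no_analysable_window_yields_no_thresholds(self):
        layout = GenomeLayout(lengths={"chr1": 100_000})
        sites = self.uniform_sites(n=5)  # every window has <= 5 sites
        out = permute_thresholds(sites, layout, n_perm=10, alphas=(0.05,), seed=1)
        assert out == []

    def test_per_window_pvalues_mode(self):
        layout = GenomeLayout(lengths={"chr1": 100_000})
        sites = self.uniform_sites(n=300, seed=3)
        df = permute_window_pvalues(sites, layout, n_perm=20, seed=6)
        analysable = df["hp"].notna()
        assert df.loc[analysable, "p_empirical"].between(0, 1).all()
        # identical counts at every site: every shuffle reproduces the
        # observed Hp, so every empirical P is exactly 1
        assert (df.loc[analysable, "p_empirical"] == 1.0).all()


class TestSignificantWindows:
    def windows(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [0, 20_000, 0],
                "end": [40_000, 60_000, 40_000],
                "n_snps": [20, 20, 20],
                "hp": [0.10, 0.30, 0.05],
            }
        )

    def test_boundary_equal_not_significant(self):
        flagged = significant_windows(self.windows(), {"chr1": 0.10, "chr2": 0.2}, 0.05)
        assert flagged["significant"].tolist() == [False, False, True]

    def test_missing_threshold_marks_untested(self):
        flagged = significant_windows(self.windows(), {"chr1": 0.2}, 0.05)
        chr2 = flagged[flagged["chrom"] == "chr2"].iloc[0]
        assert not chr2["tested"] and not chr2["significant"]

    def test_empty_threshold_table_all_untested(self):
        flagged = significant_windows(self.windows(), {}, 0.05)
        assert not flagged["tested"].any()


class TestModelApi:
    def test_from_calls_and_fit(self):
        layout = GenomeLayout(lengths={"chr1": 100_000})
        rng = np.random.default_rng(8)
        calls = [
            make_call(int(p) + 1, depth=12, alt_fwd=3, alt_rev=3)
            for p in np.sort(rng.choice(100_000, size=400, replace=False))
        ]
        model = PooledHpScan.from_calls(calls, layout)
        assert model.line_id == "L1"
        fit = model.fit(n_perm=30, alphas=(0.05,), seed=5)
        assert set(fit.windows.columns) >= {"chrom", "start", "end", "n_snps", "hp"}
        assert "significant @" in fit.summary()
        with pytest.raises(ValueError, match="not fitted"):
            fit.significant(0.01)

    def test_site_counts_frame_from_calls(self):
        frame = site_counts_frame([make_call(5, depth=10, alt_fwd=2, alt_rev=1)])
        assert frame.iloc[0].tolist() == ["chr1", 5, 7, 3]
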