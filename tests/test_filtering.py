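from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolsweep.filtering import (
    FilterConfig,
    apply_filters,
    apply_filters_frame,
    filter_coverage,
    filter_snpq,
    filter_spacing,
    filter_strand_support,
    mask_dense_regions,
)

from .conftest import make_call


def twenty_call_fixture():
    """Hand-designed 20-call set exercising every failure mode.

    With line stats mean 10 +/- 2 (upper bound 16) and default thresholds:

    - pos 100: SNPQ 39            -> fails quality
    - pos 200: depth 4            -> fails coverage (floor)
    - pos 300: depth 17           -> fails coverage (17 > 10 + 3*2)
    - pos 400: alt (2, 0)         -> fails strand (one-sided)
    - pos 500: alt (1, 0)         -> fails strand (single read)
    - pos 600, 601: adjacent      -> both fail spacing
    - pos 700, 702: good          -> retained (gap 2)
    - pos 1000..1020 step 2 (11)  -> all fail density (11 SNPs in 21 bases)
    """
    calls = [
        make_call(100, snpq=39.0),
        make_call(200, depth=4),
        make_call(300, depth=17, alt_fwd=8, alt_rev=8),
        make_call(400, alt_fwd=2, alt_rev=0),
        make_call(500, depth=10, alt_fwd=1, alt_rev=0),
        make_call(600),
        make_call(601),
        make_call(700),
        make_call(702),
    ]
    calls += [make_call(1000 + 2 * i) for i in range(11)]
    expected_survivors = [700, 702]
    expected_report = {
        "input": 20,
        "fail_snpq": 1,
        "fail_coverage": 2,
        "fail_strand": 2,
        "fail_spacing": 2,
        "fail_density": 11,
        "retained": 2,
    }
    return calls, expected_survivors, expected_report


class TestStages:
    def test_snpq_boundary_inclusive(self):
        kept = filter_snpq([make_call(1, snpq=40.0), make_call(2, snpq=39.0)],
                           FilterConfig())
        assert [c.pos for c in kept] == [1]

    def test_snpq_empty_input(self):
        assert filter_snpq([], FilterConfig()) == []

    def test_coverage_bounds(self, line_stats):
        cfg = FilterConfig()
        keep5 = filter_coverage([make_call(1, depth=5)], line_stats, cfg)
        assert len(keep5) == 1  # floor is inclusive
        gone17 = filter_coverage(
            [make_call(1, depth=17, alt_fwd=8, alt_rev=8)], line_stats, cfg
        )
        assert gone17 == []  # 17 > 10 + 3*2
        gone4 = filter_coverage([make_call(1, depth=4)], line_stats, cfg)
        assert gone4 == []

    @pytest.mark.parametrize(
        "alt_fwd,alt_rev,kept",
        [(1, 1, True), (2, 0, False), (0, 0, False), (3, 1, True)],
    )
    def test_strand_rule(self, alt_fwd, alt_rev, kept):
        out = filter_strand_support(
            [make_call(1, alt_fwd=alt_fwd, alt_rev=alt_rev)], FilterConfig()
        )
        assert bool(out) is kept

    def test_spacing_removes_both(self):
        out = filter_spacing([make_call(100), make_call(101)], FilterConfig())
        assert out == []

    def test_spacing_keeps_distance_two(self):
        out = filter_spacing([make_call(100), make_call(102)], FilterConfig())
        assert len(out) == 2

    def test_spacing_triple(self):
        out = filter_spacing(
            [make_call(100), make_call(101), make_call(103)], FilterConfig()
        )
        assert [c.pos for c in out] == [103]

    def test_spacing_requires_sorted(self):
        with pytest.raises(ValueError, match="sorted"):
            filter_spacing([make_call(200), make_call(100)], FilterConfig())

    def test_spacing_chromosome_boundary_not_a_pair(self):
        calls = [make_call(100, chrom="chr1"), make_call(100, chrom="chr2")]
        assert len(filter_spacing(calls, FilterConfig())) == 2

    def test_density_eleven_in_fifty_removed(self):
        calls = [make_call(1000 + 4 * i) for i in range(11)]  # span 41 bases
        assert mask_dense_regions(calls, FilterConfig()) == []

    def test_density_ten_in_fifty_retained(self):
        calls = [make_call(1000 + 5 * i) for i in range(10)]
        assert len(mask_dense_regions(calls, FilterConfig())) == 10

    def test_density_spread_eleven_retained(self):
        # 11 calls over 60 bases, no 50-base span holds more than 10
        calls = [make_call(1000 + 6 * i) for i in range(11)]
        assert len(mask_dense_regions(calls, FilterConfig())) == 11

    def test_density_matches_exhaustive_span_check(self):
        rng = np.random.default_rng(11)
        pos = np.sort(rng.choice(2000, size=120, replace=False)) + 1
        calls = [make_call(int(p)) for p in pos]
        cfg = FilterConfig()
        got = {c.pos for c in mask_dense_regions(calls, cfg)}
        # brute force: every 50-base window over the position range
        bad = set()
        for x in range(1, 2002):
            inside = [p for p in pos if x <= p <= x + cfg.dense_window - 1]
            if len(inside) > cfg.dense_max_snps:
                bad.update(inside)
        assert got == {int(p) for p in pos if int(p) not in bad}


class TestCascade:
    def test_hand_fixture_survivors_and_report(self, line_stats):
        calls, survivors, expected = twenty_call_fixture()
        kept, report = apply_filters(calls, line_stats)
        assert [c.pos for c in kept] == survivors
        assert report.as_dict() == expected

    def test_report_conservation(self, line_stats):
        calls, _, _ = twenty_call_fixture()
        _, rep = apply_filters(calls, line_stats)
        fails = (rep.fail_snpq + rep.fail_coverage + rep.fail_strand
                 + rep.fail_spacing + rep.fail_density)
        assert rep.retained == rep.input - fails

    def test_identity_config_returns_input(self, line_stats):
        calls, _, _ = twenty_call_fixture()
        kept, rep = apply_filters(calls, line_stats, FilterConfig.identity())
        assert kept == calls
        assert rep.retained == rep.input == len(calls)

    def test_empty_input(self, line_stats):
        kept, rep = apply_filters([], line_stats)
        assert kept == []
        assert all(v == 0 for v in rep.as_dict().values())

    def test_spacing_and_density_idempotent(self, line_stats):
        calls, _, _ = twenty_call_fixture()
        cfg = FilterConfig()
        once = filter_spacing(calls, cfg)
        assert filter_spacing(once, cfg) == once
        once_d = mask_dense_regions(calls, cfg)
        assert mask_dense_regions(once_d, cfg) == once_d

    def test_full_cascade_idempotent(self, line_stats):
        calls, _, _ = twenty_call_fixture()
        kept, _ = apply_filters(calls, line_stats)
        again, _ = apply_filters(kept, line_stats)
        assert again == kept

    def test_order_sensitivity_documented(self, line_stats):
        """Spacing sees only quality-surviving calls: a low-quality neighbour
        does not drag down a good call; running spacing first would."""
        calls = [make_call(600), make_call(601, snpq=39.0)]
        kept, _ = apply_filters(calls, line_stats)
        assert [c.pos for c in kept] == [600]
        spacing_first = filter_spacing(calls, FilterConfig())
        assert spacing_first == []

    def test_pointwise_stages_commute(self, line_stats):
        calls, _, _ = twenty_call_fixture()
        cfg = FilterConfig()
        a = filter_strand_support(
            filter_coverage(filter_snpq(calls, cfg), line_stats, cfg), cfg
        )
        b = filter_snpq(
            filter_coverage(filter_strand_support(calls, cfg), line_stats, cfg), cfg
        )
        assert a == b


@st.composite
def random_calls(draw):
    n = draw(st.integers(0, 60))
    positions = sorted(draw(st.sets(st.integers(1, 500), min_size=n, max_size=n)))
    calls = []
    for p in positions:
        depth = draw(st.integers(1, 30))
        alt = draw(st.integers(0, depth))
        fwd = draw(st.integers(0, alt))
        calls.append(
            make_call(
                p,
                snpq=float(draw(st.integers(0, 100))),
                depth=depth,
                alt_fwd=fwd,
                alt_rev=alt - fwd,
            )
        )
    return calls


class TestProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(random_calls(), st.integers(0, 100))
    def test_raising_snpq_never_retains_more(self, calls, thr):
        from poolsweep.io import LineStats

        stats = LineStats("L1", "broiler", 12, 10.0, 2.0)
        lo, _ = apply_filters(calls, stats, FilterConfig(min_snpq=float(thr)))
        hi, _ = apply_filters(calls, stats, FilterConfig(min_snpq=float(thr + 10)))
        assert len(hi) <= len(lo)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(random_calls())
    def test_frame_api_agrees_with_record_api(self, calls):
        from poolsweep.io import LineStats

        stats = LineStats("L1", "broiler", 12, 10.0, 2.0)
        kept, rep = apply_filters(calls, stats)
        frame = pd.DataFrame(
            {
                "chrom": [c.chrom for c in calls],
                "pos": [c.pos for c in calls],
                "snpq": [c.snpq for c in calls],
                "depth": [c.depth for c in calls],
                "alt_fwd": [c.alt_fwd for c in calls],
                "alt_rev": [c.alt_rev for c in calls],
            }
        )
        fkept, frep = apply_filters_frame(frame, stats)
        assert frep.as_dict() == rep.as_dict()
        assert fkept["pos"].tolist() == [c.pos for c in kept]
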