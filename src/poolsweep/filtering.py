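"""Post-calling filtration cascade for one line's pooled SNP calls.

Stages, applied in fixed order:

1. SNPQ: variant quality >= ``min_snpq`` (inclusive).
2. Coverage: depth >= ``min_depth`` and depth <= mean line coverage +
   ``max_depth_sd`` standard deviations.  The lower tail of the +/- SD band
   is subsumed by the explicit floor.
3. Strand support: at least ``min_alt_reads`` alternative-allele reads and,
   when ``require_both_strands``, at least one on each strand.
4. Spacing: adjacent retained calls on a chromosome must be >= ``min_gap``
   bases apart; both members of a violating pair are removed (conservative).
5. Density: every possible ``dense_window``-base span (sliding by one base,
   not tiled bins) holding more than ``dense_max_snps`` calls is masked
   entirely.

Filters are per line: a SNP removed in one line may survive in another.
Each stage is a vectorized mask over position/quality/depth arrays; the
:class:`SnpCall`-sequence API and the DataFrame API share those masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import LineStats, SnpCall

FRAME_COLUMNS = ["chrom", "pos", "snpq", "depth", "alt_fwd", "alt_rev"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtration cascade (defaults: SNPQ >= 40,
    depth in [5, mean + 3 SD], >= 2 alt reads split across strands,
    inter-marker gap > 1 base, mask spans with > 10 SNPs / 50 bases)."""

    min_snpq: float = 40.0
    min_depth: int = 5
    max_depth_sd: float = 3.0
    min_alt_reads: int = 2
    require_both_strands: bool = True
    min_gap: int = 2
    dense_window: int = 50
    dense_max_snps: int = 10

    def __post_init__(self) -> None:
        for name in (
            "min_snpq",
            "min_depth",
            "max_depth_sd",
            "min_alt_reads",
            "min_gap",
            "dense_window",
            "dense_max_snps",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def identity(cls) -> "FilterConfig":
        """A configuration under which every call passes every stage."""
        return cls(
            min_snpq=0.0,
            min_depth=0,
            max_depth_sd=float("inf"),
            min_alt_reads=0,
            require_both_strands=False,
            min_gap=0,
            dense_window=0,
            dense_max_snps=0,
        )


@dataclass
class FilterReport:
    """Per-stage attrition counts for one line.

    ``retained == input - (fail_snpq + fail_coverage + fail_strand +
    fail_spacing + fail_density)`` because stages run sequentially.
    """

    input: int = 0
    fail_snpq: int = 0
    fail_coverage: int = 0
    fail_strand: int = 0
    fail_spacing: int = 0
    fail_density: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


# --- vectorized stage masks ------------------------------------------------


def snpq_mask(snpq: np.ndarray, config: FilterConfig) -> np.ndarray:
    return snpq >= config.min_snpq


def coverage_mask(
    depth: np.ndarray, stats: LineStats, config: FilterConfig
) -> np.ndarray:
    if stats.sd_cov is None:
        raise ValueError(f"line {stats.line_id}: sd_cov missing")
    upper = stats.mean_cov + config.max_depth_sd * stats.sd_cov
    return (depth >= config.min_depth) & (depth <= upper)


def strand_mask(
    alt_fwd: np.ndarray, alt_rev: np.ndarray, config: FilterConfig
) -> np.ndarray:
    keep = (alt_fwd + alt_rev) >= config.min_alt_reads
    if config.require_both_strands:
        keep = keep & (alt_fwd >= 1) & (alt_rev >= 1)
    return keep


def _check_sorted(chrom: np.ndarray, pos: np.ndarray) -> None:
    if len(pos) < 2:
        return
    same = chrom[1:] == chrom[:-1]
    backwards = same & (np.diff(pos) < 0)
    if backwards.any():
        i = int(np.nonzero(backwards)[0][0]) + 1
        raise ValueError(
            f"calls not sorted by (chrom, pos): {chrom[i - 1]}:{pos[i - 1]} "
            f"before {chrom[i]}:{pos[i]}"
        )
    n_runs = 1 + int((~same).sum())
    if n_runs != len(set(chrom.tolist())):
        raise ValueError("calls not sorted: chromosome blocks are interleaved")


def _chrom_slices(chrom: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of each chromosome run in a sorted array."""
    if len(chrom) == 0:
        return []
    breaks = np.nonzero(chrom[1:] != chrom[:-1])[0] + 1
    bounds = [0, *breaks.tolist(), len(chrom)]
    return list(zip(bounds, bounds[1:]))


def spacing_mask(
    chrom: np.ndarray, pos: np.ndarray, config: FilterConfig
) -> np.ndarray:
    """Keep mask: False for BOTH members of any same-chromosome pair closer
    than ``min_gap`` bases.  Input must be sorted by (chrom, pos)."""
    _check_sorted(chrom, pos)
    keep = np.ones(len(pos), dtype=bool)
    if config.min_gap <= 0:
        return keep
    for lo, hi in _chrom_slices(chrom):
        p = pos[lo:hi]
        close = np.diff(p) < config.min_gap
        bad = np.zeros(hi - lo, dtype=bool)
        bad[:-1] |= close
        bad[1:] |= close
        keep[lo:hi] = ~bad
    return keep


def density_mask(
    chrom: np.ndarray, pos: np.ndarray, config: FilterConfig
) -> np.ndarray:
    """Keep mask: False for every call inside any ``dense_window``-base span
    holding more than ``dense_max_snps`` calls.

    Because calls are position-sorted, any offending span contains a run of
    ``dense_max_snps + 1`` consecutive calls; the union of all spans
    containing such a run covers bases [pos[last] - w + 1, pos[first] + w - 1]
    and every call in that base range is removed.
    """
    _check_sorted(chrom, pos)
    w, k = config.dense_window, config.dense_max_snps
    keep = np.ones(len(pos), dtype=bool)
    if w <= 0 or k <= 0:
        return keep
    for lo, hi in _chrom_slices(chrom):
        p = pos[lo:hi].astype(np.int64)
        if len(p) <= k:
            continue
        trigger = np.nonzero(p[k:] - p[:-k] <= w - 1)[0]
        if trigger.size == 0:
            continue
        span_lo = p[trigger + k] - w + 1  # non-decreasing in trigger order
        span_hi = p[trigger] + w - 1
        # merge overlapping/adjacent masked base ranges
        merged_lo = [span_lo[0]]
        merged_hi = [span_hi[0]]
        for a, b in zip(span_lo[1:], span_hi[1:]):
            if a <= merged_hi[-1] + 1:
                merged_hi[-1] = max(merged_hi[-1], b)
            else:
                merged_lo.append(a)
                merged_hi.append(b)
        mlo = np.array(merged_lo)
        mhi = np.array(merged_hi)
        idx = np.searchsorted(mlo, p, side="right") - 1
        inside = (idx >= 0) & (p <= mhi[np.clip(idx, 0, len(mhi) - 1)])
        keep[lo:hi] = ~inside
    return keep


# --- SnpCall-sequence API --------------------------------------------------


def _arrays(calls: Sequence[SnpCall]):
    chrom = np.array([c.chrom for c in calls], dtype=object)
    pos = np.array([c.pos for c in calls], dtype=np.int64)
    return chrom, pos


def filter_snpq(calls: Sequence[SnpCall], config: FilterConfig) -> list[SnpCall]:
    """Keep calls with variant quality >= ``min_snpq`` (boundary retained)."""
    mask = snpq_mask(np.array([c.snpq for c in calls]), config) if calls else []
    return [c for c, m in zip(calls, mask) if m]


def filter_coverage(
    calls: Sequence[SnpCall], stats: LineStats, config: FilterConfig
) -> list[SnpCall]:
    """Keep calls with depth >= ``min_depth`` and <= mean + k*SD of the line."""
    mask = coverage_mask(np.array([c.depth for c in calls]), stats, config) if calls else []
    return [c for c, m in zip(calls, mask) if m]


def filter_strand_support(
    calls: Sequence[SnpCall], config: FilterConfig
) -> list[SnpCall]:
    """Keep calls whose alternative allele has >= ``min_alt_reads`` supporting
    reads and, when required, at least one on each strand."""
    if not calls:
        return []
    mask = strand_mask(
        np.array([c.alt_fwd for c in calls]),
        np.array([c.alt_rev for c in calls]),
        config,
    )
    return [c for c, m in zip(calls, mask) if m]


def filter_spacing(calls: Sequence[SnpCall], config: FilterConfig) -> list[SnpCall]:
    """Remove BOTH members of every pair of same-chromosome calls closer than
    ``min_gap`` bases.  Input must be sorted by (chrom, pos)."""
    if not calls:
        return []
    mask = spacing_mask(*_arrays(calls), config)
    return [c for c, m in zip(calls, mask) if m]


def mask_dense_regions(
    calls: Sequence[SnpCall], config: FilterConfig
) -> list[SnpCall]:
    """Remove every call inside any ``dense_window``-base span that holds more
    than ``dense_max_snps`` calls."""
    if not calls:
        return []
    mask = density_mask(*_arrays(calls), config)
    return [c for c, m in zip(calls, mask) if m]


def apply_filters(
    calls: Sequence[SnpCall], stats: LineStats, config: FilterConfig | None = None
) -> tuple[list[SnpCall], FilterReport]:
    """Run the full cascade (SNPQ -> coverage -> strand -> spacing -> density)
    and report per-stage attrition."""
    if config is None:
        config = FilterConfig()
    report = FilterReport(input=len(calls))
    stage = filter_snpq(calls, config)
    report.fail_snpq = len(calls) - len(stage)

    after_cov = filter_coverage(stage, stats, config)
    report.fail_coverage = len(stage) - len(after_cov)

    after_strand = filter_strand_support(after_cov, config)
    report.fail_strand = len(after_cov) - len(after_strand)

    after_gap = filter_spacing(after_strand, config)
    report.fail_spacing = len(after_strand) - len(after_gap)

    after_dense = mask_dense_regions(after_gap, config)
    report.fail_density = len(after_gap) - len(after_dense)

    report.retained = len(after_dense)
    return after_dense, report


# --- DataFrame API (same masks, columnar data) -----------------------------


def apply_filters_frame(
    calls: pd.DataFrame, stats: LineStats, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Cascade over a calls frame with columns ``chrom, pos, snpq, depth,
    alt_fwd, alt_rev``, sorted by (chrom, pos).  Same stage masks and order
    as :func:`apply_filters`."""
    if config is None:
        config = FilterConfig()
    missing = [c for c in FRAME_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"calls frame lacks columns {missing}")
    report = FilterReport(input=len(calls))
    df = calls

    m = snpq_mask(df["snpq"].to_numpy(), config)
    report.fail_snpq = int((~m).sum())
    df = df[m]

    m = coverage_mask(df["depth"].to_numpy(), stats, config)
    report.fail_coverage = int((~m).sum())
    df = df[m]

    m = strand_mask(df["alt_fwd"].to_numpy(), df["alt_rev"].to_numpy(), config)
    report.fail_strand = int((~m).sum())
    df = df[m]

    chrom = df["chrom"].to_numpy(dtype=object)
    pos = df["pos"].to_numpy(dtype=np.int64)
    m = spacing_mask(chrom, pos, config)
    report.fail_spacing = int((~m).sum())
    df = df[m]

    chrom = df["chrom"].to_numpy(dtype=object)
    pos = df["pos"].to_numpy(dtype=np.int64)
    m = density_mask(chrom, pos, config)
    report.fail_density = int((~m).sum())
    df = df[m]

    report.retained = len(df)
    return df.reset_index(drop=True), report
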