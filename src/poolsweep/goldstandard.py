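"""False-discovery evaluation of NGS calls against a gold-standard truth set.

A call matches a truth SNP on (chrom, pos) only; allele agreement is not
required.  True negatives are counted per base over the covered intervals, so
specificity depends on the total covered length.  The "FP proportion" is the
fraction of retained NGS calls (inside covered intervals) that are false,
i.e. FP / (TP + FP).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .filtering import FilterConfig, filter_strand_support
from .io import SnpCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GoldStandard:
    """Truth SNP positions and the intervals over which truth is known.

    ``covered`` intervals are 0-based half-open and must be non-overlapping;
    every truth SNP (1-based position) must lie inside a covered interval.
    """

    truth_snps: frozenset[tuple[str, int]]
    covered: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.covered:
            if start >= end:
                raise ValueError(f"empty covered interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError("covered intervals overlap")
        for chrom, pos in self.truth_snps:
            if not self.contains(chrom, pos):
                raise ValueError(f"truth SNP {chrom}:{pos} outside covered intervals")

    @property
    def covered_bases(self) -> int:
        return sum(end - start for _, start, end in self.covered)

    def contains(self, chrom: str, pos: int) -> bool:
        """Is the 1-based position inside a covered interval?"""
        p0 = pos - 1
        return any(
            c == chrom and start <= p0 < end for c, start, end in self.covered
        )


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts and derived rates for one call set.

    Rates that are undefined (zero denominator) are ``None``.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float | None:
        """TPR = TP / (TP + FN); the fraction of truth SNPs recovered."""
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        """TN / (TN + FP), with TN counted per covered base."""
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def fpr(self) -> float | None:
        s = self.specificity
        return None if s is None else 1.0 - s

    @property
    def fnr(self) -> float | None:
        s = self.sensitivity
        return None if s is None else 1.0 - s

    @property
    def fp_proportion(self) -> float | None:
        """FP / (retained NGS calls inside covered intervals)."""
        d = self.tp + self.fp
        return self.fp / d if d else None

    def fp_proportion_pct(self, truncate: bool = True) -> int | float | None:
        """FP proportion as a percentage; truncated to an integer by default
        (presentation option matching how such error rates are printed)."""
        p = self.fp_proportion
        if p is None:
            return None
        return math.floor(p * 100.0) if truncate else p * 100.0


def _call_positions(
    calls: Iterable[SnpCall | tuple[str, int]],
) -> set[tuple[str, int]]:
    out: set[tuple[str, int]] = set()
    for c in calls:
        if isinstance(c, SnpCall):
            out.add((c.chrom, c.pos))
        else:
            out.add((c[0], c[1]))
    return out


def evaluate(
    ngs_calls: Iterable[SnpCall | tuple[str, int]], gold: GoldStandard
) -> EvalResult:
    """Classify every covered base as TP/FP/FN/TN.

    Calls outside the covered intervals are dropped (with a logged count)
    before counting; duplicate calls at one position count once.
    """
    covered_bases = gold.covered_bases
    if covered_bases == 0:
        raise ValueError("gold standard has zero covered bases")
    positions = _call_positions(ngs_calls)
    inside = {p for p in positions if gold.contains(*p)}
    dropped = len(positions) - len(inside)
    if dropped:
        logger.info("evaluate: dropped %d calls outside covered intervals", dropped)
    tp = len(inside & gold.truth_snps)
    fp = len(inside) - tp
    fn = len(gold.truth_snps) - tp
    tn = covered_bases - tp - fp - fn
    return EvalResult(tp=tp, fp=fp, fn=fn, tn=tn)


def threshold_sweep(
    ngs_calls: Sequence[SnpCall],
    gold: GoldStandard,
    snpq_grid: Sequence[float],
    method: int = 1,
) -> list[tuple[float, EvalResult]]:
    """Evaluate across a grid of SNPQ thresholds.

    Method 1 filters on SNPQ alone; Method 2 additionally requires the
    alternative allele to be supported by at least two reads, one per strand,
    before thresholding.  Returns (threshold, result) pairs, from which ROC
    (fpr, tpr) points can be read off for plotting.
    """
    if method not in (1, 2):
        raise ValueError("method must be 1 or 2")
    calls: Sequence[SnpCall] = ngs_calls
    if method == 2:
        calls = filter_strand_support(calls, FilterConfig())
    out = []
    for thr in snpq_grid:
        retained = [c for c in calls if c.snpq >= thr]
        out.append((thr, evaluate(retained, gold)))
    return out
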