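"""Pooled allele-frequency estimation and annotation-category summaries.

The alternative-allele frequency (AAF) of a pooled call is the proportion of
good-quality reads supporting the alternative allele; the depth emitted by the
caller is trusted (base-quality filtering happened upstream).  A SNP's mean
AAF averages the per-line estimates over the lines in which it was detected.
"Fixed or nearly fixed" means AAF strictly greater than 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    AA_ALTERING,
    CATEGORIES,
    NONCODING_CATEGORIES,
    AnnotatedSnp,
    SnpCall,
)

FIXATION_THRESHOLD = 0.9
MULTI_LINE_MIN = 10  # "detected from more than 10 lines"
BIN_WIDTH = 0.05


def estimate_aaf(call: SnpCall) -> float:
    """AAF = (alt_fwd + alt_rev) / depth."""
    if call.depth == 0:
        raise ValueError(f"zero depth at {call.chrom}:{call.pos}")
    return call.alt_reads / call.depth


def mean_aaf(snp: AnnotatedSnp) -> float:
    """Arithmetic mean AAF over the lines where the SNP was detected."""
    return snp.mean_aaf


@dataclass(frozen=True)
class SnpStatus:
    """Detection/fixation status of one SNP across lines."""

    n_lines_detected: int
    is_fixed_mean: bool  # mean AAF > threshold
    is_private: bool  # detected in exactly one line
    fixed_by_line: Mapping[str, bool]  # per-line AAF > threshold


def classify_status(
    snp: AnnotatedSnp,
    lines: Sequence[str],
    fixation_threshold: float = FIXATION_THRESHOLD,
    multi_line_min: int = MULTI_LINE_MIN,
) -> SnpStatus:
    """Per-SNP detection counts and fixation flags.

    ``multi_line_min`` is carried for callers that want the "> N lines"
    predicate: ``status.n_lines_detected > multi_line_min``.
    """
    del multi_line_min  # documented convention; predicate applied by callers
    fixed_by_line = {
        line: snp.aaf_by_line[line] > fixation_threshold
        for line in lines
        if line in snp.aaf_by_line
    }
    return SnpStatus(
        n_lines_detected=snp.n_lines_detected,
        is_fixed_mean=snp.mean_aaf > fixation_threshold,
        is_private=snp.n_lines_detected == 1,
        fixed_by_line=fixed_by_line,
    )


def _bin_edges(width: float = BIN_WIDTH) -> np.ndarray:
    n = int(round(1.0 / width))
    return np.linspace(0.0, 1.0, n + 1)


def bin_index(aaf: float, width: float = BIN_WIDTH) -> int:
    """Index of the half-open bin (lo, hi] containing ``aaf`` (aaf > 0)."""
    n = int(round(1.0 / width))
    idx = int(np.ceil(aaf / width)) - 1
    return min(max(idx, 0), n - 1)


def build_spectra(
    snps: Iterable[AnnotatedSnp],
    line_groups: Mapping[str, str],
    bin_width: float = BIN_WIDTH,
    per_line: bool = True,
) -> pd.DataFrame:
    """Per-group, per-category allele-frequency spectra.

    Each detected (SNP, line) pair contributes one observation to its line's
    group when ``per_line`` (default); otherwise each SNP contributes its mean
    AAF once per group in which it was detected.  Counts are normalized to
    percentages within each (group, category); bins are half-open (lo, hi]
    with the lowest bin starting at 0.

    Returns a long-format frame with columns
    ``group, category, bin_lo, bin_hi, n, pct``.
    """
    edges = _bin_edges(bin_width)
    nbins = len(edges) - 1
    counts: dict[tuple[str, str], np.ndarray] = {}
    for snp in snps:
        if per_line:
            obs = [
                (line_groups[line], aaf)
                for line, aaf in snp.aaf_by_line.items()
                if line in line_groups
            ]
        else:
            groups = {
                line_groups[line]
                for line in snp.aaf_by_line
                if line in line_groups
            }
            obs = [(g, snp.mean_aaf) for g in groups]
        for group, aaf in obs:
            key = (group, snp.category)
            if key not in counts:
                counts[key] = np.zeros(nbins, dtype=np.int64)
            counts[key][bin_index(aaf, bin_width)] += 1
    rows = []
    for (group, category), vec in sorted(counts.items()):
        total = vec.sum()
        for b in range(nbins):
            rows.append(
                {
                    "group": group,
                    "category": category,
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "n": int(vec[b]),
                    "pct": 100.0 * vec[b] / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)


def noncoding_coding_ratio(
    snps: Iterable[AnnotatedSnp], bin_width: float = BIN_WIDTH
) -> pd.DataFrame:
    """Ratio of non-coding to coding putatively functional variants per
    mean-AAF bin.

    Numerator: non-coding pfVars — intergenic/intronic/UTR/up-downstream
    variants inside a most conserved element, ncRNA variants, and non-coding
    variants predicted to alter RNA structure.  Denominator: AA-altering
    (including stop-gain/loss) plus splicing variants.  Bins with a zero
    denominator get a missing (NaN) ratio, never infinity.
    """
    edges = _bin_edges(bin_width)
    nbins = len(edges) - 1
    num = np.zeros(nbins, dtype=np.int64)
    den = np.zeros(nbins, dtype=np.int64)
    for snp in snps:
        if not snp.aaf_by_line:
            continue
        b = bin_index(snp.mean_aaf, bin_width)
        noncoding = snp.category in NONCODING_CATEGORIES and (
            snp.in_mce or snp.rna_struct or snp.category == "ncrna"
        )
        coding = snp.category in AA_ALTERING or snp.category == "splicing"
        if noncoding:
            num[b] += 1
        if coding:
            den[b] += 1
    ratio = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "n_noncoding_pfvar": num,
            "n_coding": den,
            "ratio": ratio,
        }
    )


@dataclass(frozen=True)
class CategorySummary:
    """One annotation-category row of the genome-wide SNP summary."""

    category: str
    n_snps: int
    pct_of_total: float
    mean_aaf: float  # mean over SNPs of per-SNP mean AAF; NaN when empty
    sd_aaf: float
    n_multi_line_fixed: int  # detected in > MULTI_LINE_MIN lines, mean AAF > 0.9
    n_all_lines_fixed: int  # detected in all lines, mean AAF > 0.9
    n_private_fixed: int  # detected in exactly 1 line with AAF > 0.9


def table1_summary(
    snps: Sequence[AnnotatedSnp],
    lines: Sequence[str],
    fixation_threshold: float = FIXATION_THRESHOLD,
    multi_line_min: int = MULTI_LINE_MIN,
) -> list[CategorySummary]:
    """Category-wise SNP counts, mean frequencies and fixation tallies.

    One row per annotation category, plus a ``within_mce`` overlay row
    covering all SNPs inside most conserved elements (the overlay is excluded
    from the category total).  Percentages are of the full input.
    """
    total = len(snps)
    n_lines = len(lines)

    def summarize(name: str, members: list[AnnotatedSnp]) -> CategorySummary:
        means = np.array([s.mean_aaf for s in members]) if members else np.array([])
        multi = all_fixed = private = 0
        for s in members:
            m = s.mean_aaf
            nd = s.n_lines_detected
            if m > fixation_threshold:
                if nd > multi_line_min:
                    multi += 1
                if nd == n_lines:
                    all_fixed += 1
            if nd == 1 and next(iter(s.aaf_by_line.values())) > fixation_threshold:
                private += 1
        return CategorySummary(
            category=name,
            n_snps=len(members),
            pct_of_total=100.0 * len(members) / total if total else 0.0,
            mean_aaf=float(means.mean()) if means.size else float("nan"),
            sd_aaf=float(means.std(ddof=1)) if means.size > 1 else float("nan"),
            n_multi_line_fixed=multi,
            n_all_lines_fixed=all_fixed,
            n_private_fixed=private,
        )

    rows = []
    for category in CATEGORIES:
        rows.append(summarize(category, [s for s in snps if s.category == category]))
    rows.append(summarize("within_mce", [s for s in snps if s.in_mce]))
    return rows


def summary_frame(rows: Sequence[CategorySummary]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
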