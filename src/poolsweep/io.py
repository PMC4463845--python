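"""Core record types and readers/writers for the formats the pipeline touches.

Coordinate convention: :class:`SnpCall.pos` and :class:`AnnotatedSnp.pos` are
1-based (VCF convention).  All window and region arithmetic elsewhere in the
package is 0-based half-open; the conversion happens exactly once, at the point
where calls are binned into windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

#: Closed vocabulary of functional annotation categories.
CATEGORIES = (
    "intergenic",
    "updownstream",
    "intronic",
    "nonsyn_intol",
    "nonsyn_tol",
    "stopgain_loss",
    "synonymous",
    "splicing",
    "utr",
    "ncrna",
)

#: Categories that make a SNP putatively functional by annotation alone.
PFVAR_CATEGORIES = frozenset(
    {"nonsyn_intol", "nonsyn_tol", "stopgain_loss", "splicing", "ncrna"}
)

#: Amino-acid-altering categories (stop-gain/loss counts as AA-altering).
AA_ALTERING = frozenset({"nonsyn_intol", "nonsyn_tol", "stopgain_loss"})

#: Non-coding categories for the non-coding/coding enrichment ratio.
NONCODING_CATEGORIES = frozenset(
    {"intergenic", "intronic", "utr", "updownstream", "ncrna"}
)

_BASES = frozenset("ACGT")


class VcfFormatError(ValueError):
    """Raised for VCF records missing required depth/strand fields."""


@dataclass(frozen=True)
class SnpCall:
    """One variant observation in one line (pool).

    ``snpq`` is the Phred-scaled variant quality (SNPQ), ``depth`` the total
    good-quality read depth at the site, and ``alt_fwd``/``alt_rev`` the number
    of reads supporting the alternative allele on each strand.
    """

    line_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    snpq: float
    depth: int
    alt_fwd: int
    alt_rev: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.depth < 0 or self.snpq < 0:
            raise ValueError("depth and snpq must be non-negative")
        if not (0 <= self.alt_fwd + self.alt_rev <= self.depth):
            raise ValueError(
                f"alt support {self.alt_fwd}+{self.alt_rev} outside [0, depth={self.depth}]"
            )
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"only single-base alleles allowed: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def alt_reads(self) -> int:
        return self.alt_fwd + self.alt_rev


@dataclass(frozen=True)
class LineStats:
    """Pool-level metadata for one sequenced line."""

    line_id: str
    group: str
    n_individuals: int
    mean_cov: float
    sd_cov: float

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.mean_cov < 0 or self.sd_cov < 0:
            raise ValueError("coverage statistics must be non-negative")


@dataclass
class AnnotatedSnp:
    """A genome-wide SNP with per-line alternative-allele frequencies.

    ``aaf_by_line`` holds an entry only for lines in which the SNP was
    detected; ``mean_aaf`` averages over those lines only.
    """

    chrom: str
    pos: int  # 1-based
    category: str
    in_mce: bool = False
    rna_struct: bool = False
    aaf_by_line: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown annotation category: {self.category!r}")
        for line_id, aaf in self.aaf_by_line.items():
            if not (0.0 <= aaf <= 1.0):
                raise ValueError(f"AAF for {line_id} outside [0,1]: {aaf}")

    @property
    def mean_aaf(self) -> float:
        if not self.aaf_by_line:
            raise ValueError(f"SNP {self.chrom}:{self.pos} detected in no line")
        return sum(self.aaf_by_line.values()) / len(self.aaf_by_line)

    @property
    def n_lines_detected(self) -> int:
        return len(self.aaf_by_line)

    @property
    def is_pfvar(self) -> bool:
        """Putatively functional: AA-altering, splicing or ncRNA category,
        inside a most conserved element, or predicted RNA-structure-altering."""
        return (
            self.category in PFVAR_CATEGORIES or self.in_mce or self.rna_struct
        )


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome identifiers and their lengths in bases."""

    lengths: Mapping[str, int]
    chroms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        chroms = self.chroms or tuple(self.lengths)
        if len(set(chroms)) != len(chroms):
            raise ValueError("duplicate chromosome identifiers")
        object.__setattr__(self, "chroms", chroms)
        for chrom in chroms:
            if self.lengths[chrom] <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column (chrom, length) table, no header."""
        lengths: dict[str, int] = {}
        order: list[str] = []
        with open(path) as fh:
            for raw in fh:
                raw = raw.strip()
                if not raw or raw.startswith("#"):
                    continue
                chrom, length = raw.split("\t")[:2]
                if chrom in lengths:
                    raise ValueError(f"duplicate chromosome {chrom} in {path}")
                lengths[chrom] = int(length)
                order.append(chrom)
        return cls(lengths=lengths, chroms=tuple(order))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                fh.write(f"{chrom}\t{self.lengths[chrom]}\n")


def _is_snp_allele(allele: str | None) -> bool:
    return allele is not None and len(allele) == 1 and allele.upper() in _BASES


def read_pool_vcf(path: str | Path, line_id: str) -> list[SnpCall]:
    """Read one line's pooled variant calls from a VCF.

    Emits one :class:`SnpCall` per biallelic SNP alt allele; multiallelic SNP
    records are split into one call per alternative allele.  Non-SNP alleles
    (indels, symbolic alleles) are skipped and counted.  Total depth is taken
    from ``INFO/DP`` and per-strand alternative-allele support from
    ``INFO/DP4`` (ref-fwd, ref-rev, alt-fwd, alt-rev, samtools mpileup style);
    records without both fields are rejected rather than guessed at.
    """
    calls: list[SnpCall] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not _is_snp_allele(rec.ref):
                skipped += 1
                continue
            alts = rec.alts or ()
            snp_alts = [a for a in alts if _is_snp_allele(a)]
            skipped += len(alts) - len(snp_alts)
            if not snp_alts:
                continue
            info = rec.info
            if "DP" not in info or "DP4" not in info:
                raise VcfFormatError(
                    f"record {rec.chrom}:{rec.pos} lacks INFO/DP or INFO/DP4; "
                    "per-strand alt depths are required"
                )
            dp4 = tuple(int(x) for x in info["DP4"])
            if len(dp4) != 4:
                raise VcfFormatError(
                    f"record {rec.chrom}:{rec.pos} has malformed DP4 {dp4}"
                )
            depth = int(info["DP"])
            qual = float(rec.qual) if rec.qual is not None else 0.0
            for alt in snp_alts:
                calls.append(
                    SnpCall(
                        line_id=line_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        snpq=qual,
                        depth=depth,
                        alt_fwd=dp4[2],
                        alt_rev=dp4[3],
                    )
                )
    if skipped:
        logger.info("read_pool_vcf(%s): skipped %d non-SNP alleles", path, skipped)
    read_pool_vcf.last_skipped = skipped  # type: ignore[attr-defined]
    return calls


def read_line_stats(path: str | Path) -> dict[str, LineStats]:
    """Read per-line pool statistics from a TSV with header
    ``line_id  group  n_individuals  mean_cov  sd_cov``."""
    stats: dict[str, LineStats] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for raw in fh:
            if not raw.strip():
                continue
            row = raw.rstrip("\n").split("\t")
            ls = LineStats(
                line_id=row[idx["line_id"]],
                group=row[idx["group"]],
                n_individuals=int(row[idx["n_individuals"]]),
                mean_cov=float(row[idx["mean_cov"]]),
                sd_cov=float(row[idx["sd_cov"]]),
            )
            stats[ls.line_id] = ls
    return stats


def read_annotation_table(path: str | Path) -> list[AnnotatedSnp]:
    """Read the annotation TSV: ``chrom  pos  category  in_mce  rna_struct``
    followed by one AAF column per line (empty cell = not detected)."""
    snps: list[AnnotatedSnp] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        fixed = ["chrom", "pos", "category", "in_mce", "rna_struct"]
        if header[: len(fixed)] != fixed:
            raise ValueError(
                f"annotation table header must start with {fixed}, got {header[:5]}"
            )
        line_ids = header[len(fixed) :]
        for rownum, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            row = raw.rstrip("\n").split("\t")
            aafs: dict[str, float] = {}
            for line_id, cell in zip(line_ids, row[len(fixed) :]):
                if cell == "":
                    continue
                aaf = float(cell)
                if not (0.0 <= aaf <= 1.0):
                    raise ValueError(
                        f"row {rownum}: AAF {aaf} for line {line_id} outside [0,1]"
                    )
                aafs[line_id] = aaf
            try:
                snp = AnnotatedSnp(
                    chrom=row[0],
                    pos=int(row[1]),
                    category=row[2],
                    in_mce=row[3] == "1",
                    rna_struct=row[4] == "1",
                    aaf_by_line=aafs,
                )
            except ValueError as exc:
                raise ValueError(f"row {rownum}: {exc}") from exc
            snps.append(snp)
    return snps


def write_annotation_table(
    snps: Iterable[AnnotatedSnp], line_ids: Sequence[str], path: str | Path
) -> None:
    """Write the annotation TSV (inverse of :func:`read_annotation_table`).

    AAFs are written with ``repr`` so a write/read round trip is bit-exact.
    """
    with open(path, "w") as fh:
        fh.write(
            "\t".join(["chrom", "pos", "category", "in_mce", "rna_struct", *line_ids])
            + "\n"
        )
        for snp in snps:
            cells = [
                snp.chrom,
                str(snp.pos),
                snp.category,
                "1" if snp.in_mce else "0",
                "1" if snp.rna_struct else "0",
            ]
            for line_id in line_ids:
                aaf = snp.aaf_by_line.get(line_id)
                cells.append("" if aaf is None else repr(aaf))
            fh.write("\t".join(cells) + "\n")


def write_bed(
    intervals: Iterable[tuple[str, int, int, str, float]], path: str | Path
) -> None:
    """Write BED5 (0-based half-open), intervals in input order."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score in intervals:
            if start >= end:
                raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, float]]:
    """Read BED3/BED5; missing name/score default to "." and 0."""
    out: list[tuple[str, int, int, str, float]] = []
    with open(path) as fh:
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            cols = raw.split("\t")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else "."
            score = float(cols[4]) if len(cols) > 4 else 0.0
            if start >= end:
                raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
            out.append((chrom, start, end, name, score))
    return out
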