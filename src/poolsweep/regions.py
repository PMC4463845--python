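"""Cross-line sweep-region calling.

Windows that are significant in every line of a group ("common windows") are
merged — overlapping or abutting windows join transitively — into discrete,
non-overlapping putative selective sweep (pSS) regions.  Regions are then
overlaid with QTL intervals (any shared base counts) and the putatively
functional variants (pfVars) inside each region are classified by their
fixation pattern across lines and groups.

All coordinates here are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .frequency import FIXATION_THRESHOLD
from .io import AnnotatedSnp


@dataclass
class SweepRegion:
    """A merged run of common significant windows."""

    chrom: str
    start: int
    end: int
    member_windows: list[tuple[int, int]]
    supporting_lines: tuple[str, ...] = ()
    group: str = ""
    qtls: list[str] = field(default_factory=list)
    pfvars: list["RegionPfVar"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"degenerate region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """1-based position inside the region?"""
        return chrom == self.chrom and self.start <= pos - 1 < self.end


@dataclass(frozen=True)
class RegionPfVar:
    """One putatively functional variant inside a sweep region."""

    chrom: str
    pos: int
    category: str
    label: str  # ubiquitous_fixed | group_specific | group_fixed | segregating
    fixed_groups: tuple[str, ...]  # groups in which every line is detected+fixed
    fixed_lines: tuple[str, ...]


def common_windows(
    flagged_by_line: Mapping[str, pd.DataFrame],
    group_lines: Sequence[str],
    require_all: bool = True,
    drop_lines: Sequence[str] = (),
) -> pd.DataFrame:
    """Windows significant in every required line of a group.

    ``flagged_by_line`` maps line id to a frame as produced by
    :func:`poolsweep.hpscan.significant_windows` (columns chrom, start, end,
    significant).  Lines in ``drop_lines`` are excluded from the comparison
    (as one does when a single line fails to elicit signal).  The window
    grids of all compared lines must be identical.
    """
    lines = [l for l in group_lines if l not in set(drop_lines)]
    if not lines:
        raise ValueError("no lines left to compare")
    missing = [l for l in lines if l not in flagged_by_line]
    if missing:
        raise ValueError(f"no flagged windows for lines: {missing}")
    key_cols = ["chrom", "start", "end"]
    grids = {}
    for line in lines:
        df = flagged_by_line[line]
        grids[line] = set(zip(df["chrom"], df["start"], df["end"]))
    ref = grids[lines[0]]
    for line in lines[1:]:
        if grids[line] != ref:
            raise ValueError(
                f"window grid of line {line} differs from line {lines[0]}"
            )
    if not require_all:
        raise NotImplementedError("only all-lines intersection is defined")
    flags = None
    base = flagged_by_line[lines[0]][key_cols].copy()
    for line in lines:
        df = flagged_by_line[line]
        sig = df.set_index(key_cols)["significant"]
        aligned = sig.loc[list(base.itertuples(index=False, name=None))].to_numpy()
        flags = aligned if flags is None else (flags & aligned)
    out = base[flags].reset_index(drop=True)
    return out.sort_values(key_cols, ignore_index=True)


def merge_regions(windows: pd.DataFrame | Iterable[tuple[str, int, int]]) -> list[SweepRegion]:
    """Merge overlapping or abutting windows into disjoint regions.

    Abutting means end-of-one equals start-of-next (joinable on the step
    grid).  The result is independent of input order and idempotent.
    """
    if isinstance(windows, pd.DataFrame):
        triples = list(zip(windows["chrom"], windows["start"], windows["end"]))
    else:
        triples = list(windows)
    triples.sort()
    regions: list[SweepRegion] = []
    for chrom, start, end in triples:
        if (
            regions
            and regions[-1].chrom == chrom
            and start <= regions[-1].end  # overlap or abut
        ):
            regions[-1].end = max(regions[-1].end, end)
            regions[-1].member_windows.append((start, end))
        else:
            regions.append(
                SweepRegion(chrom=chrom, start=start, end=end, member_windows=[(start, end)])
            )
    return regions


def qtl_overlap(
    regions: Sequence[SweepRegion],
    qtls: Sequence[tuple[str, int, int, str]] | Sequence[tuple[str, int, int, str, float]],
) -> float:
    """Annotate each region with the QTLs sharing at least one base with it
    and return the fraction of regions overlapping one or more QTLs."""
    for region in regions:
        region.qtls = [
            q[3]
            for q in qtls
            if q[0] == region.chrom and q[1] < region.end and q[2] > region.start
        ]
    if not regions:
        return 0.0
    return sum(1 for r in regions if r.qtls) / len(regions)


def _line_state(snp: AnnotatedSnp, line: str, thr: float) -> str:
    aaf = snp.aaf_by_line.get(line)
    if aaf is None:
        return "undetected"
    return "fixed" if aaf > thr else "segregating"


def classify_pfvar(
    snp: AnnotatedSnp,
    groups: Mapping[str, Sequence[str]],
    fixation_threshold: float = FIXATION_THRESHOLD,
) -> tuple[str, tuple[str, ...], tuple[str, ...]]:
    """Fixation-pattern label of one pfVar across line groups.

    Returns (label, wholly-fixed groups, fixed lines).  Labels:

    - ``ubiquitous_fixed``: detected in every group and fixed in every line
      where detected;
    - ``group_specific``: fixed in every line of exactly one group while
      undetected or segregating in every line of the other groups;
    - ``group_fixed``: fixed throughout at least one whole group (without
      meeting either stricter label);
    - ``segregating``: anything else.
    """
    states = {
        g: [_line_state(snp, line, fixation_threshold) for line in lines]
        for g, lines in groups.items()
    }
    fixed_lines = tuple(
        line
        for lines in groups.values()
        for line in lines
        if _line_state(snp, line, fixation_threshold) == "fixed"
    )
    wholly_fixed = tuple(
        g for g, st in states.items() if st and all(s == "fixed" for s in st)
    )
    detected_groups = [
        g for g, st in states.items() if any(s != "undetected" for s in st)
    ]
    all_detected_fixed = all(
        s == "fixed"
        for st in states.values()
        for s in st
        if s != "undetected"
    )
    if (
        len(detected_groups) == len(groups)
        and detected_groups
        and all_detected_fixed
    ):
        return "ubiquitous_fixed", wholly_fixed, fixed_lines
    if len(wholly_fixed) == 1:
        g0 = wholly_fixed[0]
        others_clear = all(
            s in ("undetected", "segregating")
            for g, st in states.items()
            if g != g0
            for s in st
        )
        if others_clear:
            return "group_specific", wholly_fixed, fixed_lines
    if wholly_fixed:
        return "group_fixed", wholly_fixed, fixed_lines
    return "segregating", wholly_fixed, fixed_lines


def prioritize_pfvars(
    regions: Sequence[SweepRegion],
    snps: Iterable[AnnotatedSnp],
    groups: Mapping[str, Sequence[str]],
    fixation_threshold: float = FIXATION_THRESHOLD,
) -> list[SweepRegion]:
    """Attach the classified pfVars falling inside each region.

    Non-pfVar SNPs are excluded.  Regions are modified in place and returned.
    """
    snps = [s for s in snps if s.is_pfvar]
    for region in regions:
        found = []
        for snp in snps:
            if not region.contains(snp.chrom, snp.pos):
                continue
            label, fixed_groups, fixed_lines = classify_pfvar(
                snp, groups, fixation_threshold
            )
            found.append(
                RegionPfVar(
                    chrom=snp.chrom,
                    pos=snp.pos,
                    category=snp.category,
                    label=label,
                    fixed_groups=fixed_groups,
                    fixed_lines=fixed_lines,
                )
            )
        region.pfvars = found
    return list(regions)


def window_sharing(
    common_by_group: Mapping[str, pd.DataFrame],
) -> dict[tuple[str, str], int]:
    """Number of common windows shared between each pair of groups
    (sharing is computed at the window level, not the region level)."""
    sets = {
        g: set(zip(df["chrom"], df["start"], df["end"]))
        for g, df in common_by_group.items()
    }
    names = sorted(sets)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[(a, b)] = len(sets[a] & sets[b])
    return out


def regions_frame(regions: Sequence[SweepRegion]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(regions):
        rows.append(
            {
                "region_id": f"R{i + 1:02d}",
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_windows": len(r.member_windows),
                "group": r.group,
                "n_qtls": len(r.qtls),
                "n_pfvars": len(r.pfvars),
                "n_pfvars_fixed": sum(
                    1 for p in r.pfvars if p.label != "segregating"
                ),
            }
        )
    return pd.DataFrame(rows)
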