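"""Reproducible calibration and recovery experiments.

These routines wire the generator and the scan together into the two
simulation studies that validate the method end to end:

- :func:`neutral_calibration` checks the chromosome-wise permutation
  threshold: under neutrality the fraction of chromosomes showing at least
  one significant window at level alpha should be close to alpha.
- :func:`sweep_recovery` checks power and the region-calling contract: a
  fully fixed interval injected into every line of a group should surface as
  a merged common region overlapping the injection.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hpscan import PooledHpScan, site_counts_from_calls
from .io import GenomeLayout
from .regions import common_windows, merge_regions
from .simulate import LineSpec, SimConfig, SweepSpec, simulate


@dataclass(frozen=True)
class CalibrationResult:
    n_chromosomes: int
    n_with_signal: int
    alpha: float

    @property
    def fraction(self) -> float:
        return self.n_with_signal / self.n_chromosomes


def neutral_calibration(
    seed: int,
    n_chromosomes: int = 200,
    chrom_length: int = 2_000_000,
    mean_depth: float = 12.0,
    snp_density_per_kb: float = 15.0,
    n_perm: int = 1_000,
    alpha: float = 0.05,
) -> CalibrationResult:
    """Fraction of neutral chromosomes with >= 1 significant window.

    Each chromosome is simulated independently (one pooled line, no sweeps),
    filtered with the default cascade, scanned, and tested against its own
    permutation threshold.  Under the null this fraction estimates alpha.
    """
    n_hit = 0
    for i in range(n_chromosomes):
        layout = GenomeLayout(lengths={"chr1": chrom_length})
        cfg = SimConfig(
            seed=seed + i,
            layout=layout,
            lines=(LineSpec("L1", "group", mean_depth=mean_depth),),
            snp_density_per_kb=snp_density_per_kb,
        )
        res = simulate(cfg, build_annotation=False, build_gold=False)
        sites = site_counts_from_calls(res.filtered_by_line["L1"])
        fit = PooledHpScan(sites, layout, line_id="L1").fit(
            n_perm=n_perm, alphas=(alpha,), seed=seed + 100_000 + i
        )
        if fit.significant(alpha)["significant"].any():
            n_hit += 1
    return CalibrationResult(n_chromosomes, n_hit, alpha)


@dataclass(frozen=True)
class RecoveryResult:
    n_replicates: int
    n_recovered: int
    region_counts: tuple[int, ...]
    common_window_counts: tuple[int, ...]

    @property
    def fraction_recovered(self) -> float:
        return self.n_recovered / self.n_replicates

    @property
    def regions_never_exceed_windows(self) -> bool:
        return all(
            r <= w or w == 0
            for r, w in zip(self.region_counts, self.common_window_counts)
        )


def sweep_recovery(
    seed: int,
    n_replicates: int = 50,
    n_lines: int = 4,
    chrom_length: int = 1_200_000,
    sweep_start: int = 500_000,
    sweep_end: int = 700_000,
    mean_depth: float = 12.0,
    snp_density_per_kb: float = 15.0,
    n_perm: int = 1_000,
    alpha: float = 0.05,
) -> RecoveryResult:
    """Recovery of an injected fully fixed interval shared by a line group.

    Per replicate: simulate the group on one chromosome with the interval
    driven to fixation in every line, filter, scan and test each line, take
    the windows significant in all lines, merge them into regions, and score
    a success when some region overlaps the injected interval.
    """
    lines = [f"L{i + 1}" for i in range(n_lines)]
    n_rec = 0
    region_counts = []
    window_counts = []
    for r in range(n_replicates):
        layout = GenomeLayout(lengths={"chr1": chrom_length})
        cfg = SimConfig(
            seed=seed + 10_000 + r,
            layout=layout,
            lines=tuple(
                LineSpec(l, "group", mean_depth=mean_depth) for l in lines
            ),
            snp_density_per_kb=snp_density_per_kb,
            sweep_specs=(SweepSpec("chr1", sweep_start, sweep_end),),
        )
        res = simulate(cfg, build_annotation=False, build_gold=False)
        flagged = {}
        for j, line_id in enumerate(lines):
            sites = site_counts_from_calls(res.filtered_by_line[line_id])
            fit = PooledHpScan(sites, layout, line_id=line_id).fit(
                n_perm=n_perm, alphas=(alpha,), seed=seed + 20_000 + r * 100 + j
            )
            flagged[line_id] = fit.significant(alpha)
        common = common_windows(flagged, lines)
        regions = merge_regions(common)
        region_counts.append(len(regions))
        window_counts.append(len(common))
        if any(
            reg.chrom == "chr1" and reg.start < sweep_end and reg.end > sweep_start
            for reg in regions
        ):
            n_rec += 1
    return RecoveryResult(
        n_replicates, n_rec, tuple(region_counts), tuple(window_counts)
    )
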