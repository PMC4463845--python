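"""Synthetic Pool-seq generator.

Emulates the study design the pipeline assumes: pooled DNA of 10-15 diploid
individuals per line, sequenced at modest depth (8-17X), with SNP calls
carrying per-strand alternative-allele support.  Reads at a site are drawn as
depth ~ Poisson(lambda) and alternative reads ~ Binomial(depth, true AAF),
each alternative read assigned a strand by a fair coin.  This ignores the
finite pool of 2n chromosomes (no hypergeometric double-sampling), which is
adequate for testing the pipeline's logic.

Sweep intervals drive the true AAF to 1.0 in the specified lines, producing
runs of zero pooled heterozygosity.  Error (false-positive) sites have true
AAF 0 in every line; their alternative reads land on a single strand half of
the time, exercising the strand filter's discrimination.  SNPQ is drawn high
(>= 40) for true sites and from a low-shifted law for error sites.

Everything is driven by one seeded generator: the same seed yields
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .filtering import FilterConfig, apply_filters_frame
from .goldstandard import GoldStandard
from .io import (
    CATEGORIES,
    AnnotatedSnp,
    GenomeLayout,
    LineStats,
    SnpCall,
    write_annotation_table,
)

#: Annotation-category proportions shaped after a commercial-chicken SNP set
#: (intergenic/intronic dominate; coding classes are rare), normalized to 1.
DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "intergenic": 0.5022,
    "updownstream": 0.0283,
    "intronic": 0.4335,
    "nonsyn_intol": 0.0058,
    "nonsyn_tol": 0.0061,
    "stopgain_loss": 0.0001,
    "synonymous": 0.0099,
    "splicing": 0.0009,
    "utr": 0.0134,
    "ncrna": 0.0002,
}

#: Beta(a, b) laws per category for the "per_category" AAF model: deleterious
#: classes left-skewed (AA-altering/splicing mean ~0.3-0.4), putatively
#: neutral classes mildly right-skewed (mean ~0.6).  Draws are rescaled to
#: [min_aaf, 1].
CATEGORY_AAF_BETA: dict[str, tuple[float, float]] = {
    "intergenic": (1.7, 1.0),
    "intronic": (1.7, 1.0),
    "updownstream": (1.5, 1.0),
    "utr": (1.45, 1.05),
    "synonymous": (1.45, 1.05),
    "ncrna": (1.3, 1.1),
    "nonsyn_tol": (1.05, 1.45),
    "stopgain_loss": (1.0, 1.6),
    "splicing": (0.9, 1.7),
    "nonsyn_intol": (0.75, 1.9),
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class LineSpec:
    """One pooled line: identifier, group, pool size, mean sequencing depth."""

    line_id: str
    group: str
    n_individuals: int = 12
    mean_depth: float = 12.0


@dataclass(frozen=True)
class SweepSpec:
    """An interval (0-based half-open) driven to fixation (true AAF 1.0) in
    the given lines (None = every line)."""

    chrom: str
    start: int
    end: int
    lines: tuple[str, ...] | None = None


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    ``aaf_law`` is "uniform" (true per-line AAF uniform on [min_aaf, 1]),
    "per_category" (Beta laws from :data:`CATEGORY_AAF_BETA`, the enrichment
    model used for frequency-spectrum contrasts), or "fixed" (every true AAF
    equal to ``aaf_value``, for closed-form oracle checks).
    ``fp_rate`` is the per-base, per-line probability of a false call.
    ``presence_prob`` is the probability that a true site segregates in any
    given line (most SNPs are shared between related lines; a minority are
    private).
    """

    seed: int
    layout: GenomeLayout
    lines: tuple[LineSpec, ...]
    snp_density_per_kb: float = 15.0
    aaf_law: str = "uniform"
    min_aaf: float = 0.05
    aaf_value: float | None = None  # used by aaf_law == "fixed"
    sweep_specs: tuple[SweepSpec, ...] = ()
    fp_rate: float = 0.002
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    presence_prob: float = 0.9
    mce_prob: float = 0.035
    rna_struct_prob: float = 0.003
    filter_config: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.fp_rate <= 1.0):
            raise ValueError("fp_rate must be in [0,1]")
        if not (0.0 < self.presence_prob <= 1.0):
            raise ValueError("presence_prob must be in (0,1]")
        total = sum(self.category_mix.values())
        # printed category percentages carry rounding; renormalized at draw time
        if abs(total - 1.0) > 5e-3:
            raise ValueError(f"category_mix proportions sum to {total}, not 1")
        unknown = set(self.category_mix) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in mix: {sorted(unknown)}")
        if self.aaf_law not in ("uniform", "per_category", "fixed"):
            raise ValueError(f"unknown aaf_law {self.aaf_law!r}")
        if self.aaf_law == "fixed" and not (
            self.aaf_value is not None and 0.0 < self.aaf_value <= 1.0
        ):
            raise ValueError("aaf_law 'fixed' requires aaf_value in (0,1]")
        for sw in self.sweep_specs:
            if sw.chrom not in self.layout:
                raise ValueError(f"sweep on unknown chromosome {sw.chrom}")
            if not (0 <= sw.start < sw.end <= self.layout[sw.chrom]):
                raise ValueError(
                    f"sweep interval {sw.chrom}:{sw.start}-{sw.end} outside chromosome"
                )
        line_ids = [l.line_id for l in self.lines]
        if len(set(line_ids)) != len(line_ids):
            raise ValueError("duplicate line ids")


@dataclass
class SimTruth:
    """Ground truth of one simulation.

    ``aaf``: frame with chrom, pos (1-based) plus one true-AAF column per
    line (0 = absent in that line).  ``error_sites``: per line, the (chrom,
    pos) identities of false calls (true AAF 0 everywhere).
    """

    aaf: pd.DataFrame
    sweep_specs: tuple[SweepSpec, ...]
    error_sites: dict[str, set[tuple[str, int]]]


@dataclass
class SimResult:
    """Everything one simulation produced."""

    config: SimConfig
    truth: SimTruth
    calls_by_line: dict[str, pd.DataFrame]  # raw emitted calls
    filtered_by_line: dict[str, pd.DataFrame]
    reports: dict[str, "object"]
    line_stats: dict[str, LineStats]
    annotation: list[AnnotatedSnp]
    gold: GoldStandard | None
    gold_line: str | None

    def calls_records(self, line_id: str, filtered: bool = True) -> list[SnpCall]:
        """Materialize one line's calls as :class:`SnpCall` records."""
        df = (self.filtered_by_line if filtered else self.calls_by_line)[line_id]
        return [
            SnpCall(
                line_id=line_id,
                chrom=r.chrom,
                pos=int(r.pos),
                ref=r.ref,
                alt=r.alt,
                snpq=float(r.snpq),
                depth=int(r.depth),
                alt_fwd=int(r.alt_fwd),
                alt_rev=int(r.alt_rev),
            )
            for r in df.itertuples()
        ]

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write VCFs, annotation table, truth JSON and gold-standard files.

        Returns a manifest mapping artifact names to paths.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, str] = {}
        for line_id, df in self.calls_by_line.items():
            path = out / f"{line_id}.vcf"
            write_line_vcf(df, self.config.layout, path)
            manifest[f"vcf:{line_id}"] = str(path)
        ann_path = out / "annotation.tsv"
        write_annotation_table(
            self.annotation, [l.line_id for l in self.config.lines], ann_path
        )
        manifest["annotation"] = str(ann_path)
        stats_path = out / "line_stats.tsv"
        with open(stats_path, "w") as fh:
            fh.write("line_id\tgroup\tn_individuals\tmean_cov\tsd_cov\n")
            for ls in self.line_stats.values():
                fh.write(
                    f"{ls.line_id}\t{ls.group}\t{ls.n_individuals}\t"
                    f"{ls.mean_cov:.4f}\t{ls.sd_cov:.4f}\n"
                )
        manifest["line_stats"] = str(stats_path)
        truth_path = out / "truth.json"
        with open(truth_path, "w") as fh:
            json.dump(
                {
                    "sweeps": [
                        {
                            "chrom": s.chrom,
                            "start": s.start,
                            "end": s.end,
                            "lines": list(s.lines) if s.lines else None,
                        }
                        for s in self.truth.sweep_specs
                    ],
                    "n_true_sites": int(len(self.truth.aaf)),
                    "n_error_sites": {
                        k: len(v) for k, v in self.truth.error_sites.items()
                    },
                },
                fh,
                indent=1,
            )
        manifest["truth"] = str(truth_path)
        if self.gold is not None:
            gt = out / "gold_truth.tsv"
            with open(gt, "w") as fh:
                fh.write("chrom\tpos\n")
                for chrom, pos in sorted(self.gold.truth_snps):
                    fh.write(f"{chrom}\t{pos}\n")
            gb = out / "gold_covered.bed"
            with open(gb, "w") as fh:
                for chrom, start, end in self.gold.covered:
                    fh.write(f"{chrom}\t{start}\t{end}\n")
            manifest["gold_truth"] = str(gt)
            manifest["gold_covered"] = str(gb)
        return manifest


def write_line_vcf(calls: pd.DataFrame, layout: GenomeLayout, path: str | Path) -> None:
    """Write one line's calls as a minimal VCF 4.2 with INFO DP and DP4."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">\n')
        fh.write(
            '##INFO=<ID=DP4,Number=4,Type=Integer,Description='
            '"Ref-forward, ref-reverse, alt-forward, alt-reverse read counts">\n'
        )
        for chrom in layout.chroms:
            fh.write(f"##contig=<ID={chrom},length={layout[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in calls.itertuples():
            ref_reads = int(r.depth) - int(r.alt_fwd) - int(r.alt_rev)
            ref_fwd = int(r.ref_fwd)
            fh.write(
                f"{r.chrom}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t{r.snpq:.2f}\t.\t"
                f"DP={int(r.depth)};"
                f"DP4={ref_fwd},{ref_reads - ref_fwd},{int(r.alt_fwd)},{int(r.alt_rev)}\n"
            )


def _draw_true_aafs(
    rng: np.random.Generator, categories: np.ndarray, config: SimConfig
) -> np.ndarray:
    n = len(categories)
    if config.aaf_law == "fixed":
        return np.full(n, config.aaf_value)
    if config.aaf_law == "uniform":
        base = rng.uniform(0.0, 1.0, size=n)
    else:
        base = np.empty(n)
        for cat, (a, b) in CATEGORY_AAF_BETA.items():
            mask = categories == cat
            k = int(mask.sum())
            if k:
                base[mask] = rng.beta(a, b, size=k)
    return config.min_aaf + (1.0 - config.min_aaf) * base


def _truth_tables(rng: np.random.Generator, config: SimConfig):
    """Site positions, categories/flags and the true per-line AAF matrix."""
    cats = np.array(list(config.category_mix.keys()))
    probs = np.array(list(config.category_mix.values()))
    probs = probs / probs.sum()
    chrom_col: list[np.ndarray] = []
    pos_col: list[np.ndarray] = []
    for chrom in config.layout.chroms:
        length = config.layout[chrom]
        n_sites = int(round(config.snp_density_per_kb * length / 1000.0))
        n_sites = min(n_sites, length)
        pos0 = np.sort(rng.choice(length, size=n_sites, replace=False))
        chrom_col.append(np.full(n_sites, chrom, dtype=object))
        pos_col.append(pos0 + 1)
    chrom_arr = np.concatenate(chrom_col) if chrom_col else np.array([], dtype=object)
    pos_arr = (
        np.concatenate(pos_col).astype(np.int64) if pos_col else np.array([], dtype=np.int64)
    )
    n = len(pos_arr)
    category = rng.choice(cats, size=n, p=probs)
    in_mce = rng.random(n) < config.mce_prob
    rna_struct = rng.random(n) < config.rna_struct_prob
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    aaf_cols: dict[str, np.ndarray] = {}
    for spec in config.lines:
        present = rng.random(n) < config.presence_prob
        aaf = np.where(present, _draw_true_aafs(rng, category, config), 0.0)
        aaf_cols[spec.line_id] = aaf
    # sweep overrides: complete fixation of the alternative allele
    for sw in config.sweep_specs:
        in_sweep = (chrom_arr == sw.chrom) & (pos_arr - 1 >= sw.start) & (
            pos_arr - 1 < sw.end
        )
        targets = (
            [l.line_id for l in config.lines]
            if sw.lines is None
            else list(sw.lines)
        )
        for line_id in targets:
            aaf_cols[line_id] = np.where(in_sweep, 1.0, aaf_cols[line_id])
    truth = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr, **aaf_cols})
    sites = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": pos_arr,
            "category": category,
            "in_mce": in_mce,
            "rna_struct": rna_struct,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )
    return sites, truth


def _sample_line_calls(
    rng: np.random.Generator,
    sites: pd.DataFrame,
    true_aaf: np.ndarray,
    spec: LineSpec,
    config: SimConfig,
) -> pd.DataFrame:
    """Emit one line's raw calls: true sites with >= 1 alt read, plus errors."""
    lam = spec.mean_depth
    present = true_aaf > 0
    idx = np.nonzero(present)[0]
    depth = rng.poisson(lam, size=idx.size)
    alt = rng.binomial(depth, true_aaf[idx])
    seen = alt >= 1
    idx, depth, alt = idx[seen], depth[seen], alt[seen]
    alt_fwd = rng.binomial(alt, 0.5)
    ref_reads = depth - alt
    ref_fwd = rng.binomial(ref_reads, 0.5)
    snpq = 40.0 + rng.exponential(60.0, size=idx.size)
    true_calls = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy()[idx],
            "pos": sites["pos"].to_numpy()[idx],
            "ref": sites["ref"].to_numpy()[idx],
            "alt": sites["alt"].to_numpy()[idx],
            "snpq": np.round(snpq, 2),
            "depth": depth,
            "alt_fwd": alt_fwd,
            "alt_rev": alt - alt_fwd,
            "ref_fwd": ref_fwd,
            "is_error": False,
        }
    )

    # error sites: uniform over the genome, away from true sites
    frames = [true_calls]
    truth_pos = {
        (c, int(p)) for c, p in zip(sites["chrom"], sites["pos"])
    }
    err_rows = []
    for chrom in config.layout.chroms:
        length = config.layout[chrom]
        n_err = rng.poisson(config.fp_rate * length)
        if n_err == 0:
            continue
        pos = np.sort(rng.integers(1, length + 1, size=n_err))
        for p in pos:
            if (chrom, int(p)) in truth_pos:
                continue
            d = rng.poisson(lam)
            a = min(1 + rng.poisson(0.7), d)
            if d == 0 or a == 0:
                continue
            if rng.random() < 0.5:  # single-strand support half of the time
                af = a if rng.random() < 0.5 else 0
            else:
                af = rng.binomial(a, 0.5)
            rb, ab = rng.integers(0, 4), rng.integers(1, 4)
            err_rows.append(
                (
                    chrom,
                    int(p),
                    _BASES[rb],
                    _BASES[(rb + ab) % 4],
                    round(float(rng.exponential(25.0)), 2),
                    int(d),
                    int(af),
                    int(a - af),
                    int(rng.binomial(d - a, 0.5)),
                    True,
                )
            )
    if err_rows:
        frames.append(
            pd.DataFrame(
                err_rows,
                columns=[
                    "chrom",
                    "pos",
                    "ref",
                    "alt",
                    "snpq",
                    "depth",
                    "alt_fwd",
                    "alt_rev",
                    "ref_fwd",
                    "is_error",
                ],
            )
        )
    calls = pd.concat(frames, ignore_index=True)
    chrom_order = {c: i for i, c in enumerate(config.layout.chroms)}
    calls["_corder"] = calls["chrom"].map(chrom_order)
    calls = calls.sort_values(["_corder", "pos"], kind="stable", ignore_index=True)
    return calls.drop(columns="_corder")


def _build_annotation(
    sites: pd.DataFrame, filtered_by_line: Mapping[str, pd.DataFrame]
) -> list[AnnotatedSnp]:
    """Annotation records for truth sites detected (post-filter) in >= 1 line."""
    aafs_at: dict[tuple[str, int], dict[str, float]] = {}
    for line_id, df in filtered_by_line.items():
        real = df[~df["is_error"]] if "is_error" in df.columns else df
        aaf = (real["alt_fwd"] + real["alt_rev"]) / real["depth"]
        for c, p, f in zip(real["chrom"], real["pos"], aaf):
            aafs_at.setdefault((c, int(p)), {})[line_id] = float(f)
    out = []
    for r in sites.itertuples():
        key = (r.chrom, int(r.pos))
        found = aafs_at.get(key)
        if not found:
            continue
        out.append(
            AnnotatedSnp(
                chrom=r.chrom,
                pos=int(r.pos),
                category=r.category,
                in_mce=bool(r.in_mce),
                rna_struct=bool(r.rna_struct),
                aaf_by_line=found,
            )
        )
    return out


def _build_gold(
    rng: np.random.Generator,
    config: SimConfig,
    truth: pd.DataFrame,
    line_id: str,
    n_regions: int = 25,
    min_len: int = 150,
    max_len: int = 500,
) -> GoldStandard:
    """Short covered intervals with the line's truth restricted to them."""
    covered: list[tuple[str, int, int]] = []
    chroms = config.layout.chroms
    for _ in range(n_regions):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(min_len, max_len + 1))
        length = min(length, config.layout[chrom])
        start = int(rng.integers(0, config.layout[chrom] - length + 1))
        covered.append((chrom, start, start + length))
    # drop overlaps among sampled intervals (rare; keep the first of a clash)
    covered.sort()
    pruned: list[tuple[str, int, int]] = []
    for iv in covered:
        if pruned and pruned[-1][0] == iv[0] and iv[1] < pruned[-1][2]:
            continue
        pruned.append(iv)
    truth_snps = set()
    line_aaf = truth[line_id].to_numpy()
    for chrom, pos, aaf in zip(truth["chrom"], truth["pos"], line_aaf):
        if aaf <= 0:
            continue
        p0 = int(pos) - 1
        for c, s, e in pruned:
            if c == chrom and s <= p0 < e:
                truth_snps.add((chrom, int(pos)))
                break
    return GoldStandard(truth_snps=frozenset(truth_snps), covered=tuple(pruned))


def simulate(
    config: SimConfig,
    build_annotation: bool = True,
    build_gold: bool = True,
) -> SimResult:
    """Run the generator: truth, per-line raw and filtered calls, annotation
    and a gold-standard fixture (for the first line).

    The same ``config.seed`` yields identical results; files written by
    :meth:`SimResult.write` are byte-identical across runs.
    """
    rng = np.random.default_rng(config.seed)
    sites, truth_aaf = _truth_tables(rng, config)

    calls_by_line: dict[str, pd.DataFrame] = {}
    filtered_by_line: dict[str, pd.DataFrame] = {}
    reports: dict[str, object] = {}
    line_stats: dict[str, LineStats] = {}
    error_sites: dict[str, set[tuple[str, int]]] = {}
    for spec in config.lines:
        calls = _sample_line_calls(
            rng, sites, truth_aaf[spec.line_id].to_numpy(), spec, config
        )
        calls_by_line[spec.line_id] = calls
        error_sites[spec.line_id] = {
            (c, int(p))
            for c, p, e in zip(calls["chrom"], calls["pos"], calls["is_error"])
            if e
        }
        depths = calls["depth"].to_numpy()
        stats = LineStats(
            line_id=spec.line_id,
            group=spec.group,
            n_individuals=spec.n_individuals,
            mean_cov=float(depths.mean()) if depths.size else 0.0,
            sd_cov=float(depths.std(ddof=1)) if depths.size > 1 else 0.0,
        )
        line_stats[spec.line_id] = stats
        filtered, report = apply_filters_frame(calls, stats, config.filter_config)
        filtered_by_line[spec.line_id] = filtered
        reports[spec.line_id] = report

    annotation = (
        _build_annotation(sites, filtered_by_line) if build_annotation else []
    )
    gold = None
    gold_line = None
    if build_gold and config.lines:
        gold_line = config.lines[0].line_id
        gold = _build_gold(rng, config, truth_aaf, gold_line)

    truth = SimTruth(
        aaf=truth_aaf, sweep_specs=config.sweep_specs, error_sites=error_sites
    )
    return SimResult(
        config=config,
        truth=truth,
        calls_by_line=calls_by_line,
        filtered_by_line=filtered_by_line,
        reports=reports,
        line_stats=line_stats,
        annotation=annotation,
        gold=gold,
        gold_line=gold_line,
    )


def expected_detection_loss(
    config: SimConfig, max_aaf: float | None = None
) -> float:
    """Fraction of true (site, line) variant pairs lost to the filters.

    Runs the generator under ``config`` and compares the truth to the
    post-filter calls; optionally restricted to pairs with true AAF at or
    below ``max_aaf`` (to quantify low-frequency loss specifically).
    """
    result = simulate(config, build_annotation=False, build_gold=False)
    total = 0
    lost = 0
    for spec in config.lines:
        aaf = result.truth.aaf[spec.line_id].to_numpy()
        mask = aaf > 0
        if max_aaf is not None:
            mask &= aaf <= max_aaf
        chroms = result.truth.aaf["chrom"].to_numpy()[mask]
        poss = result.truth.aaf["pos"].to_numpy()[mask]
        df = result.filtered_by_line[spec.line_id]
        kept = set(zip(df["chrom"], df["pos"].astype(int)))
        total += len(poss)
        lost += sum(
            1 for c, p in zip(chroms, poss) if (c, int(p)) not in kept
        )
    if total == 0:
        raise ValueError("no true variant pairs under the requested restriction")
    return lost / total
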