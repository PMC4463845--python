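"""End-to-end orchestration: validated run configuration, stage execution,
logging and a machine-readable manifest.

A run is a pure function of (inputs, configuration, seed); the manifest
records per-stage record counts and SHA-256 checksums of every output file so
reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .filtering import FilterConfig, apply_filters_frame
from .frequency import (
    FIXATION_THRESHOLD,
    build_spectra,
    noncoding_coding_ratio,
    summary_frame,
    table1_summary,
)
from .goldstandard import GoldStandard, threshold_sweep
from .hpscan import (
    DEFAULT_ALPHAS,
    MIN_SNPS,
    STEP,
    WINDOW,
    PooledHpScan,
    site_counts_from_calls,
)
from .io import (
    GenomeLayout,
    read_annotation_table,
    read_bed,
    read_line_stats,
    read_pool_vcf,
    write_bed,
)
from .regions import (
    common_windows,
    merge_regions,
    prioritize_pfvars,
    qtl_overlap,
    regions_frame,
)
from .simulate import LineSpec, SimConfig, SweepSpec, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    Inputs are either generated (``simulate`` section present) or read from
    the given paths.  All stage parameters default to the pipeline's standard
    values (SNPQ >= 40, depth >= 5 and <= mean + 3 SD, 2 alt reads on both
    strands, >1-base spacing, 10 SNPs / 50 bases density mask, 40 kb / 20 kb
    windows with > 10 SNPs, 10,000 permutations, fixation at AAF > 0.9).
    """

    out_dir: Path
    seed: int
    simulate: SimConfig | None = None
    vcfs: dict[str, Path] = field(default_factory=dict)  # line_id -> path
    line_stats_path: Path | None = None
    chrom_sizes: Path | None = None
    annotation: Path | None = None
    qtl_bed: Path | None = None
    gold_truth: Path | None = None
    gold_covered: Path | None = None
    groups: dict[str, list[str]] = field(default_factory=dict)
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    window: int = WINDOW
    step: int = STEP
    min_snps: int = MIN_SNPS
    n_perm: int = 10_000
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    region_alpha: float = 0.05
    fixation_threshold: float = FIXATION_THRESHOLD
    bin_width: float = 0.05
    chrom_blocklist: tuple[str, ...] = ()
    snpq_grid: tuple[float, ...] = tuple(float(q) for q in range(0, 110, 10))

    def validate(self) -> None:
        for alpha in self.alphas:
            if not (0.0 < alpha < 1.0):
                raise ValueError(f"alpha {alpha} outside (0,1)")
        if self.region_alpha not in self.alphas:
            raise ValueError("region_alpha must be one of alphas")
        if self.simulate is None:
            for name in ("vcfs", "line_stats_path", "chrom_sizes"):
                if not getattr(self, name):
                    raise ValueError(f"without a simulate section, {name} is required")
            paths = [*self.vcfs.values(), self.line_stats_path, self.chrom_sizes]
        else:
            paths = []
        for opt in (self.annotation, self.qtl_bed, self.gold_truth, self.gold_covered):
            if opt is not None:
                paths.append(opt)
        for p in paths:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        if (self.gold_truth is None) != (self.gold_covered is None):
            raise ValueError("gold_truth and gold_covered must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], base: Path = Path(".")) -> "RunConfig":
        def p(key: str) -> Path | None:
            v = raw.get(key)
            return None if v is None else base / v

        sim = None
        if "simulate" in raw:
            s = raw["simulate"]
            layout = GenomeLayout(lengths={k: int(v) for k, v in s["layout"].items()})
            lines = tuple(
                LineSpec(
                    line_id=l["line_id"],
                    group=l["group"],
                    n_individuals=int(l.get("n_individuals", 12)),
                    mean_depth=float(l.get("mean_depth", 12.0)),
                )
                for l in s["lines"]
            )
            sweeps = tuple(
                SweepSpec(
                    chrom=w["chrom"],
                    start=int(w["start"]),
                    end=int(w["end"]),
                    lines=tuple(w["lines"]) if w.get("lines") else None,
                )
                for w in s.get("sweeps", ())
            )
            sim = SimConfig(
                seed=int(raw["seed"]),
                layout=layout,
                lines=lines,
                snp_density_per_kb=float(s.get("snp_density_per_kb", 15.0)),
                aaf_law=s.get("aaf_law", "uniform"),
                sweep_specs=sweeps,
                fp_rate=float(s.get("fp_rate", 0.002)),
                presence_prob=float(s.get("presence_prob", 0.9)),
            )
        fc = FilterConfig(**raw.get("filter", {}))
        cfg = cls(
            out_dir=base / raw["out_dir"],
            seed=int(raw["seed"]),
            simulate=sim,
            vcfs={k: base / v for k, v in raw.get("vcfs", {}).items()},
            line_stats_path=p("line_stats"),
            chrom_sizes=p("chrom_sizes"),
            annotation=p("annotation"),
            qtl_bed=p("qtl_bed"),
            gold_truth=p("gold_truth"),
            gold_covered=p("gold_covered"),
            groups={k: list(v) for k, v in raw.get("groups", {}).items()},
            filter_config=fc,
            window=int(raw.get("window", WINDOW)),
            step=int(raw.get("step", STEP)),
            min_snps=int(raw.get("min_snps", MIN_SNPS)),
            n_perm=int(raw.get("n_perm", 10_000)),
            alphas=tuple(raw.get("alphas", DEFAULT_ALPHAS)),
            region_alpha=float(raw.get("region_alpha", 0.05)),
            fixation_threshold=float(raw.get("fixation_threshold", FIXATION_THRESHOLD)),
            bin_width=float(raw.get("bin_width", 0.05)),
            chrom_blocklist=tuple(raw.get("chrom_blocklist", ())),
        )
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _calls_frame_from_vcf(path: Path, line_id: str) -> pd.DataFrame:
    calls = read_pool_vcf(path, line_id)
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos": [c.pos for c in calls],
            "ref": [c.ref for c in calls],
            "alt": [c.alt for c in calls],
            "snpq": [c.snpq for c in calls],
            "depth": [c.depth for c in calls],
            "alt_fwd": [c.alt_fwd for c in calls],
            "alt_rev": [c.alt_rev for c in calls],
        }
    )


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the requested stages and return the manifest.

    Stage order: simulate? -> filter -> gold-standard evaluation? ->
    allele-frequency summaries? -> Hp scan + permutation per line ->
    cross-line region calling (per group, when groups are configured).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "counts": {},
        "checksums": {},
    }

    def record(stage: str, t0: float, **counts: int) -> None:
        manifest["stages"].append(stage)
        manifest["counts"].update(counts)
        logger.info("stage %s done in %.1fs %s", stage, time.time() - t0, counts)

    try:
        # --- inputs -------------------------------------------------------
        t0 = time.time()
        annotation = None
        gold = None
        qtls = None
        if config.simulate is not None:
            sim = simulate(config.simulate)
            sim.write(out / "sim")
            layout = config.simulate.layout
            raw_calls = sim.calls_by_line
            line_stats = sim.line_stats
            annotation = sim.annotation
            gold = sim.gold
            record("simulate", t0, n_true_sites=len(sim.truth.aaf))
        else:
            layout = GenomeLayout.from_tsv(config.chrom_sizes)
            line_stats = read_line_stats(config.line_stats_path)
            raw_calls = {
                line_id: _calls_frame_from_vcf(path, line_id)
                for line_id, path in config.vcfs.items()
            }
            record("load", t0, n_lines=len(raw_calls))
        if config.annotation is not None:
            annotation = read_annotation_table(config.annotation)
        if config.qtl_bed is not None:
            qtls = [(c, s, e, n) for c, s, e, n, _ in read_bed(config.qtl_bed)]
        if config.gold_truth is not None:
            truth = set()
            with open(config.gold_truth) as fh:
                header = fh.readline()
                for raw in fh:
                    if raw.strip():
                        c, p = raw.split("\t")[:2]
                        truth.add((c, int(p)))
            covered = tuple(
                (c, s, e) for c, s, e, _, _ in read_bed(config.gold_covered)
            )
            gold = GoldStandard(truth_snps=frozenset(truth), covered=covered)

        if config.chrom_blocklist:
            keep = [c for c in layout.chroms if c not in set(config.chrom_blocklist)]
            layout = GenomeLayout(
                lengths={c: layout[c] for c in keep}, chroms=tuple(keep)
            )
            raw_calls = {
                k: df[~df["chrom"].isin(set(config.chrom_blocklist))]
                for k, df in raw_calls.items()
            }

        # --- filter -------------------------------------------------------
        t0 = time.time()
        filtered: dict[str, pd.DataFrame] = {}
        reports = {}
        for line_id, df in raw_calls.items():
            f, rep = apply_filters_frame(df, line_stats[line_id], config.filter_config)
            filtered[line_id] = f
            reports[line_id] = rep.as_dict()
            f.to_csv(out / f"filtered_{line_id}.tsv", sep="\t", index=False)
        with open(out / "filter_reports.json", "w") as fh:
            json.dump(reports, fh, indent=1)
        record(
            "filter",
            t0,
            n_retained=sum(len(f) for f in filtered.values()),
        )

        # --- gold-standard evaluation --------------------------------------
        if gold is not None:
            t0 = time.time()
            line_id = next(iter(raw_calls))
            calls = [
                (c, int(p))
                for c, p in zip(
                    raw_calls[line_id]["chrom"], raw_calls[line_id]["pos"]
                )
            ]
            from .io import SnpCall  # records for the threshold sweep

            recs = [
                SnpCall(
                    line_id=line_id,
                    chrom=r.chrom,
                    pos=int(r.pos),
                    ref=str(r.ref),
                    alt=str(r.alt),
                    snpq=float(r.snpq),
                    depth=int(r.depth),
                    alt_fwd=int(r.alt_fwd),
                    alt_rev=int(r.alt_rev),
                )
                for r in raw_calls[line_id].itertuples()
                if gold.contains(r.chrom, int(r.pos))
            ]
            rows = []
            for method in (1, 2):
                for thr, res in threshold_sweep(recs, gold, config.snpq_grid, method):
                    rows.append(
                        {
                            "method": method,
                            "snpq": thr,
                            "tp": res.tp,
                            "fp": res.fp,
                            "fn": res.fn,
                            "tn": res.tn,
                            "tpr": res.sensitivity,
                            "fpr": res.fpr,
                            "fp_proportion": res.fp_proportion,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "fdr_sweep.tsv", sep="\t", index=False)
            record("fdr", t0, n_gold_truth=len(gold.truth_snps))

        # --- allele-frequency summaries ------------------------------------
        if annotation:
            t0 = time.time()
            line_ids = list(raw_calls)
            line_groups = {
                l: g for g, ls in config.groups.items() for l in ls
            } or {l: "all" for l in line_ids}
            summary_frame(
                table1_summary(
                    annotation, line_ids, config.fixation_threshold
                )
            ).to_csv(out / "category_summary.tsv", sep="\t", index=False)
            build_spectra(annotation, line_groups, config.bin_width).to_csv(
                out / "spectra.tsv", sep="\t", index=False
            )
            noncoding_coding_ratio(annotation, config.bin_width).to_csv(
                out / "noncoding_coding_ratio.tsv", sep="\t", index=False
            )
            record("afs", t0, n_annotated=len(annotation))

        # --- Hp scan + permutation -----------------------------------------
        t0 = time.time()
        flagged_by_line: dict[str, pd.DataFrame] = {}
        for i, (line_id, df) in enumerate(filtered.items()):
            sites = site_counts_from_calls(df)
            model = PooledHpScan(
                sites,
                layout,
                line_id=line_id,
                window=config.window,
                step=config.step,
                min_snps=config.min_snps,
            )
            fit = model.fit(
                n_perm=config.n_perm,
                alphas=config.alphas,
                seed=config.seed + 1000 + i,
            )
            flagged = fit.significant(config.region_alpha)
            flagged_by_line[line_id] = flagged
            flagged.to_csv(out / f"windows_{line_id}.tsv", sep="\t", index=False)
            fit.thresholds_frame.to_csv(
                out / f"critical_hp_{line_id}.tsv", sep="\t", index=False
            )
        record(
            "scan",
            t0,
            n_windows=sum(len(f) for f in flagged_by_line.values()),
            n_significant=sum(
                int(f["significant"].sum()) for f in flagged_by_line.values()
            ),
        )

        # --- region calling ------------------------------------------------
        if config.groups:
            t0 = time.time()
            all_regions = {}
            for group, lines in config.groups.items():
                common = common_windows(flagged_by_line, lines)
                regions = merge_regions(common)
                for r in regions:
                    r.group = group
                    r.supporting_lines = tuple(lines)
                frac = qtl_overlap(regions, qtls) if qtls else 0.0
                if annotation:
                    prioritize_pfvars(
                        regions, annotation, {group: lines}, config.fixation_threshold
                    )
                all_regions[group] = regions
                rf = regions_frame(regions)
                rf.to_csv(out / f"regions_{group}.tsv", sep="\t", index=False)
                if len(regions):
                    write_bed(
                        (
                            (r.chrom, r.start, r.end, f"{group}_R{i + 1}", 0.0)
                            for i, r in enumerate(regions)
                        ),
                        out / f"regions_{group}.bed",
                    )
                manifest["counts"][f"n_common_windows_{group}"] = len(common)
                manifest["counts"][f"n_regions_{group}"] = len(regions)
                manifest["counts"][f"qtl_overlap_{group}"] = frac
            record("regions", t0)

        manifest["status"] = "ok"
    except Exception as exc:  # record partial progress, then re-raise
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["checksums"][str(path.relative_to(out))] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
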