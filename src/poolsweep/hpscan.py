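"""Pooled-heterozygosity (Hp) sliding-window scan with permutation thresholds.

For a window, Hp = 2 * S_maj * S_min / (S_maj + S_min)^2 where S_maj and
S_min are the sums over window sites of the read counts supporting each
site's major and minor allele.  Hp ranges from 0 (every site locally fixed)
to 0.5 (balanced support overall); runs of unusually low Hp are candidate
selective sweeps.

Windows are tiled from coordinate 0 (default 40 kb windows, 20 kb step);
only windows holding strictly more than ``min_snps`` SNPs are analysable.
Significance cut-offs are empirical and chromosome-wise: the (n_maj, n_min)
count pairs are shuffled among the chromosome's SNP positions (positions
stay fixed), the scan is recomputed, and the minimum Hp over analysable
windows is recorded per shuffle; the alpha-quantile of those minima is the
critical Hp, and observed windows strictly below it are significant.

The module exposes both the low-level operations and a model/results pair
(:class:`PooledHpScan` / :class:`HpScanResults`) for one line's data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomeLayout, SnpCall

logger = logging.getLogger(__name__)

WINDOW = 40_000
STEP = 20_000
MIN_SNPS = 10
DEFAULT_ALPHAS = (0.001, 0.01, 0.05)
N_PERM = 10_000


@dataclass(frozen=True)
class SiteCounts:
    """Major/minor allele read counts at one site (pos is 1-based)."""

    chrom: str
    pos: int
    n_maj: int
    n_min: int

    def __post_init__(self) -> None:
        if not (self.n_maj >= self.n_min >= 0):
            raise ValueError(f"need n_maj >= n_min >= 0, got {self.n_maj},{self.n_min}")
        if self.n_maj + self.n_min == 0:
            raise ValueError("site with zero reads")


def site_counts(call: SnpCall) -> SiteCounts:
    """Orient a call's read support into (major, minor) counts.

    Alt reads = alt_fwd + alt_rev; ref reads = depth - alt reads.  Ties are
    allowed (assignment is irrelevant to Hp by symmetry).
    """
    if call.depth == 0:
        raise ValueError(f"zero depth at {call.chrom}:{call.pos}")
    alt = call.alt_reads
    ref = call.depth - alt
    return SiteCounts(
        chrom=call.chrom, pos=call.pos, n_maj=max(ref, alt), n_min=min(ref, alt)
    )


def site_counts_frame(
    sites: Iterable[SiteCounts | SnpCall],
) -> pd.DataFrame:
    """Tabulate sites as a frame with columns chrom, pos, n_maj, n_min."""
    rows = []
    for s in sites:
        if isinstance(s, SnpCall):
            s = site_counts(s)
        rows.append((s.chrom, s.pos, s.n_maj, s.n_min))
    return pd.DataFrame(rows, columns=["chrom", "pos", "n_maj", "n_min"])


def site_counts_from_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Orient a calls frame (columns chrom, pos, depth, alt_fwd, alt_rev)
    into a site-counts frame with n_maj/n_min columns."""
    alt = (calls["alt_fwd"] + calls["alt_rev"]).to_numpy()
    ref = calls["depth"].to_numpy() - alt
    return pd.DataFrame(
        {
            "chrom": calls["chrom"].to_numpy(),
            "pos": calls["pos"].to_numpy(),
            "n_maj": np.maximum(alt, ref),
            "n_min": np.minimum(alt, ref),
        }
    )


def hp(sites: Iterable[SiteCounts] | np.ndarray, n_min: np.ndarray | None = None) -> float:
    """Hp of one window: 2*S_maj*S_min / (S_maj + S_min)^2.

    Accepts either a sequence of :class:`SiteCounts` or two aligned arrays of
    major and minor counts.
    """
    if n_min is None:
        counts = list(sites)  # type: ignore[arg-type]
        if not counts:
            raise ValueError("hp of an empty window is undefined")
        s_maj = sum(c.n_maj for c in counts)
        s_min = sum(c.n_min for c in counts)
    else:
        n_maj = np.asarray(sites, dtype=float)
        if n_maj.size == 0:
            raise ValueError("hp of an empty window is undefined")
        s_maj = float(n_maj.sum())
        s_min = float(np.asarray(n_min, dtype=float).sum())
    tot = s_maj + s_min
    return 2.0 * s_maj * s_min / (tot * tot)


def window_grid(length: int, window: int = WINDOW, step: int = STEP) -> list[tuple[int, int]]:
    """Tile one chromosome with half-open windows anchored at 0.

    Full windows start every ``step`` bases while they fit; if the last full
    window does not reach the chromosome end, one partial terminal window is
    appended provided it is at least half a window long.
    """
    if length <= 0:
        raise ValueError("chromosome length must be positive")
    wins: list[tuple[int, int]] = []
    start = 0
    while start + window <= length:
        wins.append((start, start + window))
        start += step
    covered_to = wins[-1][1] if wins else 0
    if covered_to < length and length - start >= window // 2:
        wins.append((start, length))
    return wins


def _chrom_arrays(
    sites: pd.DataFrame, chrom: str, length: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sub = sites[sites["chrom"] == chrom]
    pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1  # to 0-based
    order = np.argsort(pos0, kind="stable")
    pos0 = pos0[order]
    if pos0.size and pos0[-1] >= length:
        raise ValueError(
            f"site at {chrom}:{pos0[-1] + 1} beyond chromosome length {length}"
        )
    maj = sub["n_maj"].to_numpy(dtype=np.int64)[order]
    mnr = sub["n_min"].to_numpy(dtype=np.int64)[order]
    return pos0, maj, mnr


def _window_bounds(
    pos0: np.ndarray, wins: Sequence[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    starts = np.array([w[0] for w in wins])
    ends = np.array([w[1] for w in wins])
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, ends, side="left")
    return lo, hi


def _window_hp(maj: np.ndarray, mnr: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    cmaj = np.concatenate(([0], np.cumsum(maj)))
    cmin = np.concatenate(([0], np.cumsum(mnr)))
    s_maj = (cmaj[hi] - cmaj[lo]).astype(float)
    s_min = (cmin[hi] - cmin[lo]).astype(float)
    tot = s_maj + s_min
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, 2.0 * s_maj * s_min / (tot * tot), np.nan)


def scan(
    sites: pd.DataFrame,
    layout: GenomeLayout,
    window: int = WINDOW,
    step: int = STEP,
    min_snps: int = MIN_SNPS,
) -> pd.DataFrame:
    """Sliding Hp scan over all chromosomes of the layout.

    Returns one row per window with columns ``chrom, start, end, n_snps, hp``;
    ``hp`` is NaN for windows with ``n_snps <= min_snps`` (not analysable).
    """
    frames = []
    for chrom in layout.chroms:
        wins = window_grid(layout[chrom], window, step)
        if not wins:
            continue
        pos0, maj, mnr = _chrom_arrays(sites, chrom, layout[chrom])
        lo, hi = _window_bounds(pos0, wins)
        n_snps = hi - lo
        hps = _window_hp(maj, mnr, lo, hi)
        hps = np.where(n_snps > min_snps, hps, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": [w[0] for w in wins],
                    "end": [w[1] for w in wins],
                    "n_snps": n_snps,
                    "hp": hps,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_snps", "hp"])
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CriticalHp:
    """Empirical chromosome-wise critical Hp for one line at one alpha."""

    line_id: str
    chrom: str
    alpha: float
    threshold: float
    n_perm: int


def _empirical_quantile(minima: np.ndarray, alpha: float) -> float:
    """Lower empirical quantile: order statistic at ceil(alpha * n)."""
    k = max(ceil(alpha * minima.size), 1)
    return float(np.sort(minima)[k - 1])


def permute_chromosome_minima(
    pos0: np.ndarray,
    maj: np.ndarray,
    mnr: np.ndarray,
    wins: Sequence[tuple[int, int]],
    min_snps: int,
    n_perm: int,
    rng: np.random.Generator,
    batch: int = 128,
) -> np.ndarray | None:
    """Minimum Hp over analysable windows for each of ``n_perm`` shuffles.

    The (n_maj, n_min) pairs are reassigned to the fixed SNP positions by a
    single shared permutation per shuffle, preserving the multiset of count
    pairs and each site's depth.  Returns None when no window is analysable.
    """
    lo, hi = _window_bounds(pos0, wins)
    analysable = (hi - lo) > min_snps
    if not analysable.any():
        return None
    lo, hi = lo[analysable], hi[analysable]
    n = pos0.size
    minima = np.empty(n_perm)
    done = 0
    base = np.arange(n)
    while done < n_perm:
        b = min(batch, n_perm - done)
        idx = np.tile(base, (b, 1))
        idx = rng.permuted(idx, axis=1)
        pm = maj[idx]  # (b, n)
        pn = mnr[idx]
        cmaj = np.concatenate((np.zeros((b, 1), dtype=np.int64), np.cumsum(pm, axis=1)), axis=1)
        cmin = np.concatenate((np.zeros((b, 1), dtype=np.int64), np.cumsum(pn, axis=1)), axis=1)
        s_maj = (cmaj[:, hi] - cmaj[:, lo]).astype(float)
        s_min = (cmin[:, hi] - cmin[:, lo]).astype(float)
        tot = s_maj + s_min
        hps = 2.0 * s_maj * s_min / (tot * tot)
        minima[done : done + b] = hps.min(axis=1)
        done += b
    return minima


def permute_thresholds(
    sites: pd.DataFrame,
    layout: GenomeLayout,
    n_perm: int = N_PERM,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    seed: int | None = None,
    line_id: str = "pool",
    window: int = WINDOW,
    step: int = STEP,
    min_snps: int = MIN_SNPS,
) -> list[CriticalHp]:
    """Chromosome-wise critical Hp values from ``n_perm`` shuffles.

    The critical value at ``alpha`` is the alpha-quantile of the per-shuffle
    minimum Hp over analysable windows (chromosome-wise control of the
    family of windows); chromosomes with no analysable window yield no
    thresholds and are logged.
    """
    if seed is None:
        raise ValueError("permutation requires an explicit seed")
    for a in alphas:
        if not (0.0 < a < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {a}")
    rng = np.random.default_rng(seed)
    out: list[CriticalHp] = []
    for chrom in layout.chroms:
        wins = window_grid(layout[chrom], window, step)
        pos0, maj, mnr = _chrom_arrays(sites, chrom, layout[chrom])
        if pos0.size == 0 or not wins:
            logger.info("permute_thresholds: chromosome %s has no sites", chrom)
            continue
        minima = permute_chromosome_minima(pos0, maj, mnr, wins, min_snps, n_perm, rng)
        if minima is None:
            logger.info(
                "permute_thresholds: chromosome %s has no analysable window", chrom
            )
            continue
        for a in sorted(alphas):
            out.append(
                CriticalHp(
                    line_id=line_id,
                    chrom=chrom,
                    alpha=a,
                    threshold=_empirical_quantile(minima, a),
                    n_perm=n_perm,
                )
            )
    return out


def permute_window_pvalues(
    sites: pd.DataFrame,
    layout: GenomeLayout,
    n_perm: int = N_PERM,
    seed: int | None = None,
    window: int = WINDOW,
    step: int = STEP,
    min_snps: int = MIN_SNPS,
) -> pd.DataFrame:
    """Per-window empirical P values (fallback mode).

    P for a window is the fraction of shuffles whose Hp at that window is
    less than or equal to the observed Hp.  No multiplicity control.
    """
    if seed is None:
        raise ValueError("permutation requires an explicit seed")
    rng = np.random.default_rng(seed)
    observed = scan(sites, layout, window, step, min_snps)
    pvals = np.full(len(observed), np.nan)
    for chrom in layout.chroms:
        mask = (observed["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        wins = list(
            zip(observed.loc[mask, "start"], observed.loc[mask, "end"])
        )
        pos0, maj, mnr = _chrom_arrays(sites, chrom, layout[chrom])
        if pos0.size == 0:
            continue
        lo, hi = _window_bounds(pos0, wins)
        analysable = (hi - lo) > min_snps
        obs_hp = observed.loc[mask, "hp"].to_numpy()
        count_le = np.zeros(len(wins))
        base = np.arange(pos0.size)
        done = 0
        while done < n_perm:
            b = min(128, n_perm - done)
            idx = rng.permuted(np.tile(base, (b, 1)), axis=1)
            pm, pn = maj[idx], mnr[idx]
            cmaj = np.concatenate((np.zeros((b, 1), dtype=np.int64), np.cumsum(pm, axis=1)), axis=1)
            cmin = np.concatenate((np.zeros((b, 1), dtype=np.int64), np.cumsum(pn, axis=1)), axis=1)
            s_maj = (cmaj[:, hi] - cmaj[:, lo]).astype(float)
            s_min = (cmin[:, hi] - cmin[:, lo]).astype(float)
            tot = s_maj + s_min
            with np.errstate(invalid="ignore", divide="ignore"):
                hps = np.where(tot > 0, 2.0 * s_maj * s_min / (tot * tot), np.nan)
            count_le += (hps <= obs_hp[None, :]).sum(axis=0)
            done += b
        p = count_le / n_perm
        p[~analysable] = np.nan
        pvals[mask] = p
    observed = observed.copy()
    observed["p_empirical"] = pvals
    return observed


def significant_windows(
    windows: pd.DataFrame,
    thresholds: Sequence[CriticalHp] | Mapping[str, float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag analysable windows with Hp strictly below the chromosome-matched
    critical value at ``alpha``.

    Windows on chromosomes without a threshold are marked untested
    (``tested`` False, ``significant`` False).
    """
    if isinstance(thresholds, Mapping):
        thr_by_chrom = dict(thresholds)
    else:
        thr_by_chrom = {
            t.chrom: t.threshold for t in thresholds if t.alpha == alpha
        }
    out = windows.copy()
    thr = out["chrom"].map(thr_by_chrom)
    defined = out["hp"].notna()
    tested = defined & thr.notna()
    out["threshold"] = thr
    out["tested"] = tested
    out["significant"] = tested & (out["hp"] < thr)
    return out


class PooledHpScan:
    """Sweep-scan model for one line's pooled allele counts.

    Parameters
    ----------
    sites : DataFrame with columns chrom, pos (1-based), n_maj, n_min, or an
        iterable of :class:`SiteCounts` / :class:`SnpCall`.
    layout : chromosome sizes.
    line_id : identifier carried into the thresholds.
    window, step, min_snps : scan geometry; windows with <= min_snps SNPs are
        excluded from testing.
    """

    def __init__(
        self,
        sites,
        layout: GenomeLayout,
        line_id: str = "pool",
        window: int = WINDOW,
        step: int = STEP,
        min_snps: int = MIN_SNPS,
    ) -> None:
        if not isinstance(sites, pd.DataFrame):
            sites = site_counts_frame(sites)
        required = {"chrom", "pos", "n_maj", "n_min"}
        if not required.issubset(sites.columns):
            raise ValueError(f"sites frame must have columns {sorted(required)}")
        self.sites = sites
        self.layout = layout
        self.line_id = line_id
        self.window = window
        self.step = step
        self.min_snps = min_snps

    @classmethod
    def from_calls(
        cls, calls: Iterable[SnpCall], layout: GenomeLayout, **kwargs
    ) -> "PooledHpScan":
        calls = list(calls)
        line_id = calls[0].line_id if calls else kwargs.pop("line_id", "pool")
        kwargs.setdefault("line_id", line_id)
        return cls(site_counts_frame(calls), layout, **kwargs)

    def scan(self) -> pd.DataFrame:
        return scan(self.sites, self.layout, self.window, self.step, self.min_snps)

    def fit(
        self,
        n_perm: int = N_PERM,
        alphas: Sequence[float] = DEFAULT_ALPHAS,
        seed: int | None = None,
    ) -> "HpScanResults":
        """Run the scan and the chromosome-wise permutation test."""
        windows = self.scan()
        thresholds = permute_thresholds(
            self.sites,
            self.layout,
            n_perm=n_perm,
            alphas=alphas,
            seed=seed,
            line_id=self.line_id,
            window=self.window,
            step=self.step,
            min_snps=self.min_snps,
        )
        return HpScanResults(self, windows, thresholds, tuple(sorted(alphas)), n_perm)


class HpScanResults:
    """Fitted scan: observed windows, critical Hp values and significance."""

    def __init__(
        self,
        model: PooledHpScan,
        windows: pd.DataFrame,
        thresholds: list[CriticalHp],
        alphas: tuple[float, ...],
        n_perm: int,
    ) -> None:
        self.model = model
        self.windows = windows
        self.thresholds = thresholds
        self.alphas = alphas
        self.n_perm = n_perm

    @property
    def thresholds_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.thresholds])

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Windows flagged against the critical Hp at ``alpha``."""
        if alpha not in self.alphas:
            raise ValueError(f"alpha {alpha} was not fitted (have {self.alphas})")
        return significant_windows(self.windows, self.thresholds, alpha)

    def summary(self) -> str:
        """Plain-text overview of the fitted scan."""
        w = self.windows
        analysable = w["hp"].notna()
        lines = [
            "Pooled heterozygosity scan",
            "==========================",
            f"line:            {self.model.line_id}",
            f"window/step:     {self.model.window}/{self.model.step} bp",
            f"min SNPs:        > {self.model.min_snps}",
            f"windows:         {len(w)} total, {int(analysable.sum())} analysable",
            f"mean Hp:         {w.loc[analysable, 'hp'].mean():.4f}"
            if analysable.any()
            else "mean Hp:         n/a",
            f"permutations:    {self.n_perm} per chromosome",
        ]
        for alpha in self.alphas:
            sig = self.significant(alpha)
            n_sig = int(sig["significant"].sum())
            lines.append(f"significant @ {alpha:<6}: {n_sig} windows")
        return "\n".join(lines)

    def to_bed(self, path, alpha: float = 0.05, only_significant: bool = True) -> None:
        from .io import write_bed

        sig = self.significant(alpha)
        if only_significant:
            sig = sig[sig["significant"]]
        write_bed(
            (
                (r.chrom, int(r.start), int(r.end), f"hp_{self.model.line_id}", float(r.hp))
                for r in sig.itertuples()
            ),
            path,
        )
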