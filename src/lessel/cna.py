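"""Single-cell copy-number engine for low-pass WGS.

Turns per-cell binned read counts into copy-number profiles and malignancy
calls. The chain, in running order:

1. fixed-width genomic bins (:func:`make_bins`) and read counting
   (:func:`count_in_bins`);
2. GC-bias correction by lowess regression (:func:`gc_normalize`) and
   conversion to sample-mean-normalized ratios (:func:`to_ratios`);
3. per-cell noise QC with the mean absolute pairwise difference
   (:func:`mapd`; cells above 0.45 fail);
4. circular binary segmentation of log2 ratios with a permutation test
   (:func:`segment_cbs`), gain/loss state calls (:func:`call_states`) and
   autosomal CNA burden (:func:`cna_burden`);
5. clonal-concordance malignancy calling: cells whose altered-genome log2
   profiles correlate strongly, in groups of at least two, are labeled
   malignant (:func:`concordance_score`, :func:`call_malignant`).

Coordinates are 0-based half-open throughout. Sex chromosomes are carried in
profiles but excluded from burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from . import config

log = logging.getLogger("lessel.cna")

_AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}

# ratios are floored here before taking log2, so zero-count bins stay finite
_MIN_RATIO = 2.0 ** -6


def is_autosome(chrom: str) -> bool:
    return str(chrom) in _AUTOSOMES


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeBins:
    """Fixed-width genomic bins with GC fraction.

    ``table`` columns: chrom (str), start, end (bp, 0-based half-open),
    gc (fraction in [0, 1]). Bins are sorted by (chrom, start) in the order
    chromosomes were supplied and never overlap.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "gc"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"bins table missing columns: {sorted(missing)}")
        if (self.table["end"] <= self.table["start"]).any():
            raise ValueError("bins must have end > start")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def start(self) -> np.ndarray:
        return self.table["start"].to_numpy()

    @property
    def end(self) -> np.ndarray:
        return self.table["end"].to_numpy()

    @property
    def gc(self) -> np.ndarray:
        return self.table["gc"].to_numpy(dtype=float)

    @property
    def widths(self) -> np.ndarray:
        return (self.table["end"] - self.table["start"]).to_numpy()

    @property
    def autosomal(self) -> np.ndarray:
        """Boolean mask of autosomal bins."""
        return np.array([is_autosome(c) for c in self.chrom])

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chrom, slice) runs in table order."""
        chroms = self.chrom
        out: list[tuple[str, slice]] = []
        i = 0
        for j in range(1, len(chroms) + 1):
            if j == len(chroms) or chroms[j] != chroms[i]:
                out.append((chroms[i], slice(i, j)))
                i = j
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeBins":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


@dataclass(frozen=True)
class BinCounts:
    """Per-cell integer read counts, one per bin."""

    cell_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path: str | Path, bins: GenomeBins) -> None:
        df = bins.table.copy()
        df["count"] = self.counts
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, cell_id: str | None = None) -> "BinCounts":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(cell_id or Path(path).stem, df["count"].to_numpy())


@dataclass(frozen=True)
class RatioTrack:
    """GC-corrected, sample-mean-normalized bin ratios for one cell."""

    cell_id: str
    ratios: np.ndarray
    mapd: float

    @property
    def qc_pass(self) -> bool:
        return self.mapd <= config.MAPD_MAX


@dataclass(frozen=True)
class Segment:
    chrom: str
    start_bin: int       # genome-wide bin index, half-open
    end_bin: int
    start_bp: int
    end_bp: int
    mean_log2: float
    state: str = "neutral"   # loss | neutral | gain

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class CnaProfile:
    """Segmented copy-number profile of one cell."""

    cell_id: str
    segments: tuple[Segment, ...]
    mapd: float
    burden: float = 0.0       # % of autosomal genome gained or lost

    @property
    def qc_pass(self) -> bool:
        return self.mapd <= config.MAPD_MAX

    @property
    def has_cna(self) -> bool:
        """True when at least one autosomal segment is non-neutral."""
        return any(s.state != "neutral" and is_autosome(s.chrom) for s in self.segments)

    def bin_log2(self, n_bins: int) -> np.ndarray:
        """Segment-mean log2 ratio projected back onto bins."""
        out = np.zeros(n_bins)
        for s in self.segments:
            out[s.start_bin:s.end_bin] = s.mean_log2
        return out

    def altered_bin_mask(self, n_bins: int) -> np.ndarray:
        out = np.zeros(n_bins, dtype=bool)
        for s in self.segments:
            if s.state != "neutral":
                out[s.start_bin:s.end_bin] = True
        return out


@dataclass(frozen=True)
class ConcordanceResult:
    """Pairwise clonal-concordance scores and the malignancy calls."""

    cell_ids: tuple[str, ...]
    scores: np.ndarray            # NaN where a pair is not eligible
    clusters: tuple[tuple[str, ...], ...]
    malignant_ids: frozenset[str]


# ---------------------------------------------------------------------------
# binning and counting
# ---------------------------------------------------------------------------

def make_bins(
    chrom_lengths: Mapping[str, int],
    target_width: int = config.BIN_WIDTH_BP,
    gc: Sequence[float] | None = None,
) -> GenomeBins:
    """Partition chromosomes into fixed-width bins.

    Each chromosome gets ``floor(length / target_width)`` bins of exactly
    ``target_width`` bp; a final remainder shorter than half the width is
    merged into the last bin, otherwise it becomes its own bin. A chromosome
    shorter than the width is a single bin.

    ``gc`` optionally supplies one GC fraction per resulting bin (defaults
    to 0.5 everywhere; synthetic references assign realistic values).
    """
    if target_width <= 0:
        raise ValueError("target_width must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        n_full = length // target_width
        if n_full == 0:
            edges = [0, length]
        else:
            edges = list(range(0, (n_full + 1) * target_width, target_width))
            remainder = length - edges[-1]
            if remainder == 0:
                pass
            elif remainder < target_width / 2:
                edges[-1] = length          # merge into last bin
            else:
                edges.append(length)        # remainder bin
        for s, e in zip(edges[:-1], edges[1:]):
            rows.append((str(chrom), s, e))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["gc"] = 0.5 if gc is None else np.asarray(gc, dtype=float)
    return GenomeBins(df)


def count_in_bins(
    positions: Iterable[tuple[str, int]] | pd.DataFrame,
    bins: GenomeBins,
    cell_id: str = "cell",
) -> BinCounts:
    """Count aligned read positions into bins (half-open membership).

    Positions on chromosomes absent from ``bins`` or outside chromosome
    bounds are skipped; the skipped total is logged.
    """
    if isinstance(positions, pd.DataFrame):
        pos_df = positions.rename(columns=dict(zip(positions.columns[:2], ["chrom", "pos"])))
    else:
        pos_df = pd.DataFrame(list(positions), columns=["chrom", "pos"])
    counts = np.zeros(len(bins), dtype=np.int64)
    skipped = 0
    for chrom, sl in bins.chrom_slices():
        sel = pos_df["chrom"].astype(str) == chrom
        if not sel.any():
            continue
        pos = pos_df.loc[sel, "pos"].to_numpy()
        starts = bins.start[sl]
        ends = bins.end[sl]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        skipped += int((~ok).sum())
        np.add.at(counts, sl.start + idx[ok], 1)
    n_unknown = int((~pos_df["chrom"].astype(str).isin(set(bins.chrom))).sum())
    if skipped or n_unknown:
        log.warning("count_in_bins: skipped %d positions (%d on unknown chromosomes)",
                    skipped + n_unknown, n_unknown)
    return BinCounts(cell_id, counts)


# ---------------------------------------------------------------------------
# normalization, ratios, MAPD
# ---------------------------------------------------------------------------

def gc_normalize(
    counts: BinCounts | np.ndarray,
    bins: GenomeBins,
    frac: float = config.LOWESS_FRAC,
) -> np.ndarray:
    """Remove GC bias with a lowess fit of count on GC fraction.

    Two-pass masked fit: a first lowess of count on GC flags bins whose
    corrected level sits far from the sample median (copy-number-altered
    bins would otherwise leak into the bias curve); the curve is then refit
    on the near-baseline bins only and applied everywhere. corrected =
    count * mean(fitted) / fitted(gc), rescaled so the mean count is
    preserved exactly. Requires at least 50 bins with positive counts.
    """
    raw = counts.counts if isinstance(counts, BinCounts) else np.asarray(counts, float)
    raw = raw.astype(float)
    if raw.sum() <= 0:
        raise ValueError("all counts are zero; cannot GC-normalize")
    pos = raw > 0
    if pos.sum() < 50:
        raise ValueError(f"need >= 50 bins with positive counts, got {int(pos.sum())}")
    gc = bins.gc

    def _fit(mask: np.ndarray) -> np.ndarray:
        fitted = _sm_lowess(raw[mask], gc[mask], frac=frac, it=2, xvals=gc)
        return np.clip(fitted, max(1e-8, 0.01 * fitted.mean()), None)

    fitted = _fit(np.ones(len(raw), dtype=bool))
    level = raw / fitted
    baseline = np.abs(level / np.median(level) - 1.0) < 0.25
    if 50 <= baseline.sum() < len(raw):
        fitted = _fit(baseline)
    corrected = raw * fitted.mean() / fitted
    corrected *= raw.mean() / corrected.mean()
    return corrected


def to_ratios(corrected: np.ndarray, bins: GenomeBins, cell_id: str = "cell") -> RatioTrack:
    """Divide corrected counts by their mean; attach the cell's MAPD."""
    corrected = np.asarray(corrected, dtype=float)
    m = corrected.mean()
    if m <= 0:
        raise ValueError("mean corrected count must be positive")
    ratios = corrected / m
    return RatioTrack(cell_id, ratios, mapd(ratios, bins.chrom))


def mapd(ratios: np.ndarray, chrom: np.ndarray | None = None) -> float:
    """Mean absolute pairwise difference of adjacent bin ratios.

    Adjacency is restricted to within-chromosome neighbors when ``chrom``
    is given. Low MAPD means a quiet profile; the QC gate is 0.45.
    """
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) < 2:
        raise ValueError("MAPD needs at least 2 bins")
    diffs = np.abs(np.diff(ratios))
    if chrom is not None:
        chrom = np.asarray(chrom)
        same = chrom[1:] == chrom[:-1]
        if not same.any():
            raise ValueError("no within-chromosome adjacent pairs")
        diffs = diffs[same]
    return float(diffs.mean())


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------

def _smooth_outliers(x: np.ndarray, radius: int = 2, trigger_sd: float = 4.0,
                     shrink_sd: float = 2.0) -> np.ndarray:
    """Shrink isolated single-bin outliers toward the local median.

    A point farther than ``trigger_sd`` noise SDs from the median of its
    +/-``radius`` neighborhood is moved to that median plus ``shrink_sd``
    SDs in its own direction. Dropout bins (zero counts floored before the
    log) otherwise dominate the segmentation statistic.
    """
    n = len(x)
    if n < 2 * radius + 1:
        return x
    d = np.abs(np.diff(x))
    sd = np.median(d) / (0.6745 * np.sqrt(2.0))
    if sd <= 0:
        return x
    out = x.copy()
    for i in range(n):
        lo, hi = max(0, i - radius), min(n, i + radius + 1)
        neigh = np.delete(x[lo:hi], i - lo)
        med = np.median(neigh)
        if abs(x[i] - med) > trigger_sd * sd:
            out[i] = med + np.sign(x[i] - med) * shrink_sd * sd
    return out


def _max_arc_stat(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Max over arcs [i, j) of the segment-vs-rest mean-difference statistic.

    Returns (stat, i, j). The statistic is |mean_in - mean_out| /
    sqrt(1/m + 1/(n-m)); the noise SD cancels in the permutation test.
    """
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    total = cs[-1]
    best, bi, bj = -1.0, 0, n
    for m in range(min_width, n - min_width + 1):
        seg = cs[m:] - cs[:-m]                     # all windows of length m
        rest = (total - seg) / (n - m)
        z = np.abs(seg / m - rest) / np.sqrt(1.0 / m + 1.0 / (n - m))
        k = int(np.argmax(z))
        if z[k] > best:
            best, bi, bj = float(z[k]), k, k + m
    return best, bi, bj


def _perm_max_stats(x: np.ndarray, min_width: int, n_perm: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Max arc statistics of ``n_perm`` permutations of x, vectorized."""
    n = len(x)
    perms = rng.permuted(np.broadcast_to(x, (n_perm, n)).copy(), axis=1)
    cs = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(perms, axis=1)], axis=1)
    total = cs[:, -1:]
    best = np.full(n_perm, -1.0)
    for m in range(min_width, n - min_width + 1):
        seg = cs[:, m:] - cs[:, :-m]
        z = np.abs(seg / m - (total - seg) / (n - m)) / np.sqrt(1.0 / m + 1.0 / (n - m))
        np.maximum(best, z.max(axis=1), out=best)
    return best


def _split_significant(x: np.ndarray, alpha: float, max_perm: int, min_width: int,
                       rng: np.random.Generator, chunk: int = 512) -> tuple[bool, int, int]:
    """Permutation test for the best arc split of x.

    Early-stops as soon as the exceedance count makes p <= alpha impossible
    (for alpha = 1e-4 and 10,000 permutations, the first exceedance).
    """
    n = len(x)
    if n < 2 * min_width or np.allclose(x, x[0]):
        return False, 0, n
    obs, i, j = _max_arc_stat(x, min_width)
    allowed = int(np.floor(alpha * (max_perm + 1))) - 1   # max exceedances still significant
    exceed = 0
    done = 0
    while done < max_perm:
        b = min(chunk, max_perm - done)
        stats = _perm_max_stats(x, min_width, b, rng)
        exceed += int((stats >= obs).sum())
        done += b
        if exceed > allowed:
            return False, i, j
    return (exceed + 1) / (max_perm + 1) <= alpha, i, j


def _segment_one_chrom(x: np.ndarray, alpha: float, max_perm: int, min_width: int,
                       rng: np.random.Generator) -> list[int]:
    """Recursive CBS on one chromosome; returns sorted breakpoints (internal)."""
    n = len(x)
    if n < 2 * min_width:
        return []
    sig, i, j = _split_significant(x, alpha, max_perm, min_width, rng)
    if not sig:
        return []
    bps = sorted({i, j} - {0, n})
    out = set(bps)
    edges = [0] + bps + [n]
    for a, b in zip(edges[:-1], edges[1:]):
        out |= {a + c for c in _segment_one_chrom(x[a:b], alpha, max_perm, min_width, rng)}
    return sorted(out)


def _refine_breakpoints(x: np.ndarray, bps: list[int], max_sweeps: int = 5) -> list[int]:
    """Re-locate each breakpoint at the two-sample-statistic optimum
    between its neighboring boundaries (standard post-split refinement)."""
    if not bps:
        return bps
    cs = np.concatenate([[0.0], np.cumsum(x)])
    bps = sorted(bps)
    n = len(x)
    for _ in range(max_sweeps):
        moved = False
        for k, bp in enumerate(bps):
            a = bps[k - 1] if k > 0 else 0
            b = bps[k + 1] if k + 1 < len(bps) else n
            cand = np.arange(a + 1, b)
            n1 = cand - a
            n2 = b - cand
            m1 = (cs[cand] - cs[a]) / n1
            m2 = (cs[b] - cs[cand]) / n2
            t = np.abs(m1 - m2) / np.sqrt(1.0 / n1 + 1.0 / n2)
            new = int(cand[np.argmax(t)])
            if new != bp:
                bps[k] = new
                moved = True
        bps = sorted(set(bps))
        if not moved:
            break
    return bps


def _undo_merge(x: np.ndarray, bps: list[int], undo_sd: float) -> list[int]:
    """Merge adjacent segments whose mean difference is below undo_sd * noise SD."""
    if not bps or undo_sd <= 0:
        return bps
    d = np.abs(np.diff(x))
    sd = np.median(d) / (0.6745 * np.sqrt(2.0)) if len(d) else 0.0
    bps = list(bps)
    while bps:
        edges = [0] + bps + [len(x)]
        means = [x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
        gaps = [abs(means[k + 1] - means[k]) for k in range(len(means) - 1)]
        k = int(np.argmin(gaps))
        if gaps[k] >= undo_sd * sd:
            break
        bps.pop(k)
    return bps


def segment_cbs(
    track: RatioTrack | np.ndarray,
    bins: GenomeBins,
    alpha: float = config.CBS_ALPHA,
    undo_sd: float = config.CBS_UNDO_SD,
    max_perm: int = config.CBS_MAX_PERM,
    min_width: int = 2,
    seed: int = 0,
    cell_id: str | None = None,
) -> CnaProfile:
    """Circular binary segmentation of log2 bin ratios, per chromosome.

    Candidate splits are the best circular arc (segment vs rest of the
    chromosome); a split is accepted when its permutation p-value is at most
    ``alpha`` (up to ``max_perm`` permutations with early stopping, seeded).
    Accepted splits recurse; the undo step then merges adjacent segments
    whose mean difference is less than ``undo_sd`` noise SDs. States and
    burden are not assigned here — see :func:`call_states`.
    """
    if isinstance(track, RatioTrack):
        ratios, cid, m = track.ratios, track.cell_id, track.mapd
    else:
        ratios = np.asarray(track, dtype=float)
        cid, m = cell_id or "cell", mapd(ratios, bins.chrom)
    x = np.log2(np.clip(ratios, _MIN_RATIO, None))
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    for chrom, sl in bins.chrom_slices():
        xs = _smooth_outliers(x[sl])
        bps = _segment_one_chrom(xs, alpha, max_perm, min_width, rng)
        bps = _refine_breakpoints(xs, bps)
        bps = _undo_merge(xs, bps, undo_sd)
        edges = [0] + bps + [len(xs)]
        for a, b in zip(edges[:-1], edges[1:]):
            segments.append(Segment(
                chrom=chrom,
                start_bin=sl.start + a,
                end_bin=sl.start + b,
                start_bp=int(bins.start[sl.start + a]),
                end_bp=int(bins.end[sl.start + b - 1]),
                mean_log2=float(xs[a:b].mean()),
            ))
    return CnaProfile(cell_id=cid, segments=tuple(segments), mapd=m)


# ---------------------------------------------------------------------------
# state calls, burden, concordance
# ---------------------------------------------------------------------------

def _neutral_center(segments: Sequence[Segment], window: float = 0.1) -> float:
    """log2 offset of the diploid baseline: the largest-mass segment mode.

    For each segment mean, the total bin mass of segments within ``window``
    of it is accumulated; the center is the mass-weighted mean around the
    best candidate. Near-diploid cells thus center on their dominant state.
    """
    means = np.array([s.mean_log2 for s in segments])
    mass = np.array([s.n_bins for s in segments], dtype=float)
    best_mass, center = -1.0, 0.0
    for mu in means:
        sel = np.abs(means - mu) <= window
        mm = mass[sel].sum()
        if mm > best_mass:
            best_mass = mm
            center = float(np.average(means[sel], weights=mass[sel]))
    return center


def call_states(
    profile: CnaProfile,
    gain: float = config.GAIN_LOG2,
    loss: float = config.LOSS_LOG2,
    center: bool = True,
) -> CnaProfile:
    """Label segments loss/neutral/gain after centering on the diploid mode.

    A segment is a gain when its centered mean log2 ratio is >= ``gain``,
    a loss when <= ``loss`` (defaults +/-0.25, midway between neutral and a
    single-copy change).
    """
    offset = _neutral_center(profile.segments) if center else 0.0
    segs = []
    for s in profile.segments:
        m = s.mean_log2 - offset
        state = "gain" if m >= gain else ("loss" if m <= loss else "neutral")
        segs.append(Segment(s.chrom, s.start_bin, s.end_bin, s.start_bp, s.end_bp, m, state))
    out = CnaProfile(profile.cell_id, tuple(segs), profile.mapd)
    return CnaProfile(profile.cell_id, tuple(segs), profile.mapd, burden=cna_burden(out))


def cna_burden(profile: CnaProfile) -> float:
    """Percent of the autosomal genome covered by gained or lost segments."""
    auto = [s for s in profile.segments if is_autosome(s.chrom)]
    if not auto:
        raise ValueError("profile has no autosomal segments")
    total = sum(s.length_bp for s in auto)
    altered = sum(s.length_bp for s in auto if s.state != "neutral")
    return 100.0 * altered / total


def concordance_score(a: CnaProfile, b: CnaProfile, n_bins: int) -> float | None:
    """Pearson correlation of segment-projected log2 ratios over altered bins.

    The support is the union of bins altered in either cell; cells with no
    altered autosomal segment are not eligible (returns None). Identical
    profiles score 1, mirrored gain/loss profiles score -1, independent
    profiles score ~0. When a projected vector is constant over the support
    (a single altered segment), Pearson is undefined and the uncentered
    (cosine) correlation is used instead, which preserves those limits.
    """
    if not (a.has_cna and b.has_cna):
        return None
    support = a.altered_bin_mask(n_bins) | b.altered_bin_mask(n_bins)
    xa = a.bin_log2(n_bins)[support]
    xb = b.bin_log2(n_bins)[support]
    if xa.std() > 0 and xb.std() > 0:
        return float(np.corrcoef(xa, xb)[0, 1])
    na, nb = np.linalg.norm(xa), np.linalg.norm(xb)
    if na == 0 or nb == 0:
        return 0.0
    return float(xa @ xb / (na * nb))


def call_malignant(
    profiles: Sequence[CnaProfile],
    n_bins: int,
    score_threshold: float = config.CONCORDANCE_MIN,
    min_cluster: int = config.MIN_CLUSTER,
    require_qc: bool = True,
) -> ConcordanceResult:
    """Label cells malignant by clonal concordance.

    QC-passing cells with detectable CNAs are linked whenever their pairwise
    concordance reaches ``score_threshold``; single-linkage connected
    components of at least ``min_cluster`` cells are called malignant.
    Flat cells (no detectable CNA) are always benign.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    ids = tuple(p.cell_id for p in profiles)
    n = len(profiles)
    eligible = [p.has_cna and (p.qc_pass or not require_qc) for p in profiles]
    scores = np.full((n, n), np.nan)
    for i in range(n):
        if eligible[i]:
            scores[i, i] = 1.0
        for j in range(i + 1, n):
            if eligible[i] and eligible[j]:
                s = concordance_score(profiles[i], profiles[j], n_bins)
                scores[i, j] = scores[j, i] = np.nan if s is None else s
    # single-linkage components over the threshold graph
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if eligible[i] and eligible[j] and np.isfinite(scores[i, j]) \
                    and scores[i, j] >= score_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        if eligible[i]:
            groups.setdefault(find(i), []).append(i)
    clusters = tuple(tuple(ids[i] for i in g) for g in groups.values())
    malignant = frozenset(cid for cl in clusters if len(cl) >= min_cluster for cid in cl)
    return ConcordanceResult(ids, scores, clusters, malignant)


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def profile_to_frame(profile: CnaProfile) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chrom, s.start_bp, s.end_bp, s.mean_log2, s.state) for s in profile.segments],
        columns=["chrom", "start", "end", "log2", "state"],
    )


def write_qc_report(profiles: Sequence[CnaProfile], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(
        [(p.cell_id, p.mapd, p.qc_pass, p.burden) for p in profiles],
        columns=["cell_id", "mapd", "qc_pass", "burden_pct"],
    )
    df.to_csv(path, index=False)
    return df


def write_concordance(result: ConcordanceResult, path: str | Path) -> None:
    pd.DataFrame(result.scores, index=result.cell_ids,
                 columns=result.cell_ids).to_csv(path)


def write_calls(result: ConcordanceResult, path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(
        [(cid, cid in result.malignant_ids) for cid in result.cell_ids],
        columns=["cell_id", "malignant"],
    )
    df.to_csv(path, index=False)
    return df
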