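"""Block-based peak calling against input, with iterative border refinement.

The genome is tiled into fixed-size blocks (twice, with a half-block
offset), blocks are selected by a raw-count floor followed by a
log/quantile-normalised ChIP-input contrast, passing blocks from the two
tilings are merged, and merged regions are narrowed by repeatedly trimming
the emptier border while most of the reads are retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_BLOCK_SIZE = 500
DEFAULT_MIN_SIGNAL = 40.0
DEFAULT_PSEUDO = 1.0
DEFAULT_LOG2_THRESHOLD = 2.0
DEFAULT_INIT_BORDER = 50
DEFAULT_RETAIN = 0.75
DEFAULT_MIN_BORDER = 10


@dataclass
class PeakRegion:
    """A called peak: refined interval plus its pre-refinement extent."""

    chrom: str
    start: int
    end: int
    raw_start: int
    raw_end: int
    signal: np.ndarray | None = None
    refinement_steps: list = field(default_factory=list)
    name: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def tile_counts(
    tags_by_time: list[pd.DataFrame],
    block_size: int = DEFAULT_BLOCK_SIZE,
    offset: int = 0,
    labels: list | None = None,
) -> pd.DataFrame:
    """Accumulate weighted tag counts into fixed-size blocks.

    Blocks start at ``offset + k * block_size``; with a nonzero offset the
    partial leading block is clipped to start at 0, so every tag lands in
    exactly one block and total weight is conserved.

    Returns a DataFrame indexed by (chrom, start) with one count column per
    library.
    """
    if offset < 0 or offset >= block_size:
        raise ValueError("offset must be in [0, block_size)")
    if labels is None:
        labels = list(range(len(tags_by_time)))
    per_chrom: dict[str, dict] = {}
    for col, tags in zip(labels, tags_by_time):
        if len(tags) == 0:
            continue
        base = -1 if offset > 0 else 0
        for chrom, grp in tags.groupby("chrom", sort=True, observed=True):
            pos = grp["pos"].to_numpy()
            idx = (pos - offset) // block_size  # pos < offset -> idx -1
            counts = np.bincount(idx - base, weights=grp["weight"].to_numpy())
            d = per_chrom.setdefault(chrom, {})
            prev = d.get(col)
            if prev is None:
                d[col] = counts
            else:
                n = max(len(prev), len(counts))
                merged = np.zeros(n)
                merged[: len(prev)] += prev
                merged[: len(counts)] += counts
                d[col] = merged
    frames = []
    base = -1 if offset > 0 else 0
    for chrom in sorted(per_chrom):
        d = per_chrom[chrom]
        n = max(len(v) for v in d.values())
        mat = np.zeros((n, len(labels)))
        for j, col in enumerate(labels):
            v = d.get(col)
            if v is not None:
                mat[: len(v), j] = v
        starts = np.maximum((np.arange(n) + base) * block_size + offset, 0)
        frames.append(
            pd.DataFrame(
                mat,
                index=pd.MultiIndex.from_arrays(
                    [[chrom] * n, starts], names=["chrom", "start"]
                ),
                columns=labels,
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=labels,
            index=pd.MultiIndex.from_arrays([[], []], names=["chrom", "start"]),
        )
    return pd.concat(frames)


def quantile_normalize(m: np.ndarray) -> np.ndarray:
    """Quantile-normalise columns to the mean quantile distribution.

    Ties within a column receive the mean of the tied quantile values
    (average ranks, linearly interpolated into the reference distribution).
    """
    m = np.asarray(m, dtype=float)
    ref = np.sort(m, axis=0).mean(axis=1)
    cum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        col = m[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        lo = np.searchsorted(sorted_col, sorted_col, side="left")
        hi = np.searchsorted(sorted_col, sorted_col, side="right")
        out[order, j] = (cum[hi] - cum[lo]) / (hi - lo)
    return out


def select_blocks(
    chip_blocks: pd.DataFrame,
    input_blocks: pd.DataFrame,
    block_size: int = DEFAULT_BLOCK_SIZE,
    min_signal: float = DEFAULT_MIN_SIGNAL,
    pseudo: float = DEFAULT_PSEUDO,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
    qn_mode: str = "separate",
) -> pd.DataFrame:
    """Select ChIP-enriched blocks against input.

    Steps: (i) keep blocks whose raw ChIP count reaches ``min_signal`` at
    >= 1 time point; (ii) log2(count + pseudo); (iii) quantile
    normalisation over libraries; (iv) keep blocks where normalised ChIP -
    normalised input exceeds ``log2_threshold`` at >= 1 time point.

    ``qn_mode``: "separate" (default) normalises the ChIP libraries and the
    input libraries as two sets, which removes depth differences without
    averaging the ChIP signal tail into the tail-less input distribution;
    "joint" normalises all columns to one common reference.

    Returns a DataFrame of passing intervals (chrom, start, end).
    """
    idx = chip_blocks.index.union(input_blocks.index)
    chip = chip_blocks.reindex(idx, fill_value=0.0)
    inp = input_blocks.reindex(idx, fill_value=0.0)

    keep = chip.to_numpy().max(axis=1) >= min_signal
    if keep.sum() < 2:
        warnings.warn("fewer than 2 blocks pass the raw-count floor; no peaks called")
        return pd.DataFrame(columns=["chrom", "start", "end"])
    chip = chip.loc[keep]
    inp = inp.loc[keep]

    c = np.log2(chip.to_numpy() + pseudo)
    i = np.log2(inp.to_numpy() + pseudo)
    if qn_mode == "separate":
        nc = quantile_normalize(c)
        ni = quantile_normalize(i)
    elif qn_mode == "joint":
        both = quantile_normalize(np.hstack([c, i]))
        nc, ni = both[:, : c.shape[1]], both[:, c.shape[1] :]
    else:
        raise ValueError(f"unknown qn_mode {qn_mode!r}")
    enriched = (nc - ni > log2_threshold).any(axis=1)

    sel = chip.index[enriched]
    chroms = sel.get_level_values("chrom")
    starts = sel.get_level_values("start").to_numpy()
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": starts + block_size}
    ).reset_index(drop=True)


def merge_offset_tilings(
    pass_set_0: pd.DataFrame, pass_set_half: pd.DataFrame
) -> pd.DataFrame:
    """Union the passing blocks of the two tilings and merge overlapping or
    adjacent intervals into maximal regions."""
    both = pd.concat([pass_set_0, pass_set_half], ignore_index=True)
    if len(both) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    both = both.sort_values(["chrom", "start", "end"], kind="stable")
    out = []
    for chrom, grp in both.groupby("chrom", sort=True, observed=True):
        cur_start = cur_end = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_start is None:
                cur_start, cur_end = s, e
            elif s <= cur_end:  # overlap or touching
                cur_end = max(cur_end, e)
            else:
                out.append((chrom, cur_start, cur_end))
                cur_start, cur_end = s, e
        out.append((chrom, cur_start, cur_end))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def refine_peak(
    start: int,
    end: int,
    density: np.ndarray,
    init_border: int = DEFAULT_INIT_BORDER,
    retain: float = DEFAULT_RETAIN,
    min_border: int = DEFAULT_MIN_BORDER,
) -> tuple[int, int, list[tuple[int, str, float]]]:
    """Trim peak borders to the shortest interval keeping most of the reads.

    ``density`` is the per-base weighted tag density over [start, end),
    summed over time points. At each border width w (starting at
    ``init_border``): count reads in the leftmost and rightmost w nt of the
    current interval, pick the border with fewer reads (tie -> left), and
    trim it if the remaining interval still holds at least ``retain`` of
    the current reads; otherwise halve w. Stops when w < ``min_border``.

    Returns (new_start, new_end, steps) where each step is
    (border_width, side, retained_fraction).
    """
    density = np.asarray(density, dtype=float)
    if len(density) != end - start:
        raise ValueError("density length must equal region length")
    total = density.sum()
    steps: list[tuple[int, str, float]] = []
    if total <= 0:
        warnings.warn(f"region [{start},{end}) has zero counts; not refined")
        return start, end, steps
    lo, hi = 0, end - start  # offsets into density
    w = init_border
    while w >= min_border:
        if hi - lo <= 2 * w:
            w //= 2
            continue
        cur_total = density[lo:hi].sum()
        if cur_total <= 0:
            break
        left = density[lo : lo + w].sum()
        right = density[hi - w : hi].sum()
        side = "left" if left <= right else "right"
        border = left if side == "left" else right
        retained = (cur_total - border) / cur_total
        if retained >= retain:
            if side == "left":
                lo += w
            else:
                hi -= w
            steps.append((w, side, float(retained)))
        else:
            w //= 2
    return start + lo, start + hi, steps


def region_density(
    tags_by_time: list[pd.DataFrame], chrom: str, start: int, end: int
) -> np.ndarray:
    """Per-base weighted tag density over [start, end), pooled over libraries."""
    dens = np.zeros(end - start)
    for tags in tags_by_time:
        sub = tags.loc[
            (tags["chrom"] == chrom) & (tags["pos"] >= start) & (tags["pos"] < end)
        ]
        if len(sub):
            dens += np.bincount(
                sub["pos"].to_numpy() - start,
                weights=sub["weight"].to_numpy(),
                minlength=end - start,
            )
    return dens


class _ChromIndex:
    """Sorted per-chromosome position index for fast interval weight sums."""

    def __init__(self, tags: pd.DataFrame):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in tags.groupby("chrom", sort=False, observed=True):
            pos = grp["pos"].to_numpy()
            w = grp["weight"].to_numpy()
            order = np.argsort(pos, kind="stable")
            pos, w = pos[order], w[order]
            self.by_chrom[chrom] = (pos, np.concatenate([[0.0], np.cumsum(w)]))

    def weight_in(self, chrom: str, start: int, end: int) -> float:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return 0.0
        pos, cw = entry
        i = np.searchsorted(pos, start, side="left")
        j = np.searchsorted(pos, end, side="left")
        return float(cw[j] - cw[i])


def quantify_regions(
    tags_by_time: list[pd.DataFrame],
    regions: pd.DataFrame,
    totals_by_time: list[float],
) -> np.ndarray:
    """Weighted tag counts per region x library, depth-normalised.

    Each entry is the weighted tag count in the region scaled by
    (mean library total / library total), so libraries sequenced deeper do
    not look more bound.
    """
    totals = np.asarray(totals_by_time, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("library totals must be positive")
    ref = totals.mean()
    mat = np.zeros((len(regions), len(tags_by_time)))
    for t, tags in enumerate(tags_by_time):
        index = _ChromIndex(tags)
        for r, (chrom, s, e) in enumerate(
            zip(regions["chrom"], regions["start"], regions["end"])
        ):
            mat[r, t] = index.weight_in(chrom, int(s), int(e))
        mat[:, t] *= ref / totals[t]
    return mat


def call_peaks(
    chip_libs,
    input_libs,
    block_size: int = DEFAULT_BLOCK_SIZE,
    min_signal: float = DEFAULT_MIN_SIGNAL,
    pseudo: float = DEFAULT_PSEUDO,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
    init_border: int = DEFAULT_INIT_BORDER,
    retain: float = DEFAULT_RETAIN,
    min_border: int = DEFAULT_MIN_BORDER,
    qn_mode: str = "separate",
) -> tuple[list[PeakRegion], np.ndarray, list[float]]:
    """Full peak-calling stage on prepared (shifted, deduplicated) libraries.

    Returns (peaks, signal matrix of peaks x time, time labels).
    """
    chip_tags = [lib.tags for lib in chip_libs]
    input_tags = [lib.tags for lib in input_libs]
    labels = [lib.label for lib in chip_libs]

    passing = []
    for offset in (0, block_size // 2):
        cb = tile_counts(chip_tags, block_size, offset, labels=labels)
        ib = tile_counts(input_tags, block_size, offset, labels=labels)
        passing.append(
            select_blocks(
                cb, ib, block_size, min_signal, pseudo, log2_threshold, qn_mode
            )
        )
    regions = merge_offset_tilings(*passing)

    peaks: list[PeakRegion] = []
    for i, (chrom, s, e) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"])
    ):
        s, e = int(s), int(e)
        dens = region_density(chip_tags, chrom, s, e)
        rs, re_, steps = refine_peak(s, e, dens, init_border, retain, min_border)
        peaks.append(
            PeakRegion(
                chrom=chrom,
                start=rs,
                end=re_,
                raw_start=s,
                raw_end=e,
                refinement_steps=steps,
                name=f"peak_{i + 1}",
            )
        )

    refined = pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
        }
    )
    totals = [lib.total_nonredundant for lib in chip_libs]
    signal = (
        quantify_regions(chip_tags, refined, totals)
        if len(peaks)
        else np.zeros((0, len(chip_tags)))
    )
    for p, row in zip(peaks, signal):
        p.signal = row
    return peaks, signal, labels


def peaks_to_frame(peaks: list[PeakRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "name": [p.name for p in peaks],
            "score": [
                float(np.max(p.signal)) if p.signal is not None else 0.0
                for p in peaks
            ],
        }
    )
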