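"""Mapped-tag processing: loading, multi-hit weighting, deduplication, strand shifting.

Tags are held in a pandas DataFrame with columns ``chrom`` (str), ``pos``
(int, 0-based leftmost coordinate), ``strand`` ('+' or '-'), ``weight``
(float in (0, 1], equal to 1 / number of genomic hits of the read) and
``n_hits`` (int). All coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

TAG_COLUMNS = ["chrom", "pos", "strand", "weight", "n_hits"]

DEFAULT_MAX_HITS = 5
DEFAULT_READ_LENGTH = 80


class MalformedRecordError(ValueError):
    """A tag record is missing or has an invalid field; carries the record index."""

    def __init__(self, index: int, message: str):
        self.index = index
        super().__init__(f"record {index}: {message}")


@dataclass(frozen=True)
class MappedTag:
    """One aligned read anchor.

    ``pos`` is the 0-based leftmost coordinate; ``weight`` is the density
    contribution 1/n_hits of a read mapping to ``n_hits`` genomic places.
    """

    chrom: str
    pos: int
    strand: str
    n_hits: int = 1

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")

    @property
    def weight(self) -> float:
        return 1.0 / self.n_hits


@dataclass
class TimePointLibrary:
    """A ZT-labelled tag collection with its fragment-size metadata.

    ``total_nonredundant`` is the tag count after deduplication and is the
    depth used for between-library normalisation.
    """

    label: float
    tags: pd.DataFrame
    avg_fragment_size: int
    read_length: int = DEFAULT_READ_LENGTH
    total_nonredundant: int = field(default=0)

    def __post_init__(self):
        if self.avg_fragment_size <= 0 or self.read_length <= 0:
            raise ValueError("fragment size and read length must be positive")
        if not 0 <= self.label < 24:
            self.label = self.label % 24

    @property
    def shift(self) -> int:
        return compute_shift(self.avg_fragment_size, self.read_length)


def empty_tags() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "weight": pd.Series(dtype=float),
            "n_hits": pd.Series(dtype=np.int64),
        }
    )


def _iter_record_tuples(records: Iterable) -> Iterator[tuple]:
    for rec in records:
        if isinstance(rec, MappedTag):
            yield rec.chrom, rec.pos, rec.strand, rec.n_hits
        elif isinstance(rec, dict):
            yield (
                rec.get("chrom"),
                rec.get("pos"),
                rec.get("strand"),
                rec.get("n_hits", 1),
            )
        else:
            t = tuple(rec)
            if len(t) == 3:
                t = t + (1,)
            yield t


def load_mapped_tags(
    records: Iterable,
    max_hits: int = DEFAULT_MAX_HITS,
    valid_chroms: set[str] | None = None,
) -> pd.DataFrame:
    """Build a tag table from alignment records, dropping reads with too many hits.

    Parameters
    ----------
    records
        Iterable of ``MappedTag``, dicts, or ``(chrom, pos, strand[, n_hits])``
        tuples. Every alignment of a multi-hit read appears as its own record;
        each retained alignment receives weight ``1/n_hits``.
    max_hits
        Reads aligning to more than this many genomic places are discarded.
    valid_chroms
        Optional whitelist; records on unknown chromosomes are rejected.

    Raises
    ------
    MalformedRecordError
        On a record with missing/invalid strand or position, or an unknown
        chromosome; the exception carries the 0-based record index.
    """
    chroms: list[str] = []
    poss: list[int] = []
    strands: list[str] = []
    hits: list[int] = []
    for i, (chrom, pos, strand, n_hits) in enumerate(_iter_record_tuples(records)):
        if chrom is None or not isinstance(chrom, str) or chrom == "":
            raise MalformedRecordError(i, "missing chromosome")
        if valid_chroms is not None and chrom not in valid_chroms:
            raise MalformedRecordError(i, f"unknown chromosome {chrom!r}")
        if strand not in ("+", "-"):
            raise MalformedRecordError(i, f"invalid strand {strand!r}")
        try:
            pos = int(pos)
        except (TypeError, ValueError):
            raise MalformedRecordError(i, f"invalid position {pos!r}") from None
        if pos < 0:
            raise MalformedRecordError(i, f"negative position {pos}")
        n_hits = int(n_hits) if n_hits is not None else 1
        if n_hits < 1:
            raise MalformedRecordError(i, f"invalid n_hits {n_hits}")
        if n_hits > max_hits:
            continue
        chroms.append(chrom)
        poss.append(pos)
        strands.append(strand)
        hits.append(n_hits)
    if not chroms:
        return empty_tags()
    hits_arr = np.asarray(hits, dtype=np.int64)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "strand": strands,
            "weight": 1.0 / hits_arr,
            "n_hits": hits_arr,
        }
    )


def deduplicate(tags: pd.DataFrame) -> pd.DataFrame:
    """Keep one tag per (chrom, pos, strand).

    The survivor is the first tag in sorted (chrom, pos, strand, weight)
    order, which makes the result deterministic and the operation
    idempotent. The survivor keeps its own weight.
    """
    if len(tags) == 0:
        return tags.reset_index(drop=True)
    out = tags.sort_values(
        ["chrom", "pos", "strand", "weight"], kind="stable"
    ).drop_duplicates(subset=["chrom", "pos", "strand"], keep="first")
    return out.reset_index(drop=True)


def compute_shift(avg_fragment_size: float, read_length: float) -> int:
    """Tag shift: half the fragment size minus half the read length.

    Rounded to the nearest integer, halves away from zero (199 nt fragments
    with 80 nt reads give 99.5 - 40 = 59.5 -> 60).
    """
    if avg_fragment_size <= 0 or read_length <= 0:
        raise ValueError("fragment size and read length must be positive")
    x = avg_fragment_size / 2.0 - read_length / 2.0
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def shift_tags(tags: pd.DataFrame, shift: int) -> pd.DataFrame:
    """Move + strand tags right and - strand tags left by ``shift`` nt.

    Positions are clipped at 0; weights are untouched.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    out = tags.copy()
    if len(out) == 0:
        return out
    sign = np.where(out["strand"].to_numpy() == "+", 1, -1)
    out["pos"] = np.maximum(out["pos"].to_numpy() + sign * shift, 0)
    return out


def prepare_library(
    records: Iterable,
    label: float,
    avg_fragment_size: int,
    read_length: int = DEFAULT_READ_LENGTH,
    max_hits: int = DEFAULT_MAX_HITS,
    valid_chroms: set[str] | None = None,
) -> TimePointLibrary:
    """Load, deduplicate and shift one time-point library in the standard order."""
    tags = load_mapped_tags(records, max_hits=max_hits, valid_chroms=valid_chroms)
    tags = deduplicate(tags)
    total = len(tags)
    shifted = shift_tags(tags, compute_shift(avg_fragment_size, read_length))
    return TimePointLibrary(
        label=label,
        tags=shifted,
        avg_fragment_size=avg_fragment_size,
        read_length=read_length,
        total_nonredundant=total,
    )


def strand_cross_correlation_shift(
    tags: pd.DataFrame, max_lag: int = 400
) -> int:
    """Estimate the +/- strand density displacement by cross-correlation.

    Returns half the lag that maximises the correlation between + and -
    strand per-base densities, i.e. the shift to apply per strand so the
    two density modes coincide.
    """
    plus = tags.loc[tags["strand"] == "+"]
    minus = tags.loc[tags["strand"] == "-"]
    if len(plus) == 0 or len(minus) == 0:
        raise ValueError("both strands required")
    lo = int(min(plus["pos"].min(), minus["pos"].min()))
    hi = int(max(plus["pos"].max(), minus["pos"].max())) + 1
    n = hi - lo
    dp = np.bincount(plus["pos"].to_numpy() - lo, weights=plus["weight"], minlength=n)
    dm = np.bincount(minus["pos"].to_numpy() - lo, weights=minus["weight"], minlength=n)
    best_lag, best_val = 0, -np.inf
    for lag in range(0, max_lag + 1):
        # correlate dm shifted left by `lag` against dp
        v = float(np.dot(dp[: n - lag], dm[lag:])) if lag < n else 0.0
        if v > best_val:
            best_val, best_lag = v, lag
    return best_lag // 2
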