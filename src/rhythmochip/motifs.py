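"""Motif scanning and empirical enrichment against matched random regions.

Matching is plumbing (the discovery step is an external tool); the
statistics are the point: the observed number of motif-bearing regions is
ranked within null counts from random region groups matched on size, TSS
distance and gene expression, and cluster-level motif frequencies are
compared with Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """A motif as an IUPAC consensus or a position weight matrix.

    PWM rows are per-position probabilities over (A, C, G, T);
    ``match_threshold`` is the fraction of the maximal log-odds score (vs a
    uniform background) a window must reach to count as a match.
    """

    name: str
    consensus: str | None = None
    pwm: np.ndarray | None = None
    match_threshold: float = 0.8

    def __post_init__(self):
        if self.consensus is None and self.pwm is None:
            raise ValueError("motif needs a consensus or a PWM")
        if self.consensus is not None:
            self.consensus = self.consensus.upper()
            if len(self.consensus) == 0:
                raise ValueError("empty motif")
            bad = set(self.consensus) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC letters {sorted(bad)}")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[1] != 4 or self.pwm.shape[0] == 0:
                raise ValueError("PWM must be L x 4 and non-empty")
            if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("PWM columns must sum to 1")

    def __len__(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pwm.shape[0]


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to 0..3 for ACGT and 4 for anything else (incl. N)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def _consensus_match_starts(enc: np.ndarray, consensus: str) -> np.ndarray:
    """Start positions of exact degenerate matches on the encoded + strand."""
    L = len(consensus)
    n = len(enc)
    if n < L:
        return np.array([], dtype=np.int64)
    ok = np.ones(n - L + 1, dtype=bool)
    for offset, letter in enumerate(consensus):
        allowed = np.zeros(5, dtype=bool)
        for b in IUPAC[letter]:
            allowed[_BASE_INDEX[b]] = True
        ok &= allowed[enc[offset : offset + n - L + 1]]
    return np.flatnonzero(ok).astype(np.int64)


def _pwm_match_starts(enc: np.ndarray, pwm: np.ndarray, threshold: float) -> np.ndarray:
    L, n = pwm.shape[0], len(enc)
    if n < L:
        return np.array([], dtype=np.int64)
    logodds = np.log2(np.maximum(pwm, 1e-9) / 0.25)
    max_score = float(logodds.max(axis=1).sum())
    cutoff = threshold * max_score
    padded = np.vstack([logodds.T, np.full((1, L), -np.inf)])  # row 4 = N
    scores = np.zeros(n - L + 1)
    for offset in range(L):
        scores += padded[enc[offset : offset + n - L + 1], offset]
    return np.flatnonzero(scores >= cutoff).astype(np.int64)


def match_positions(seq: str, motif: MotifModel) -> list[tuple[int, str]]:
    """All (start, strand) matches of the motif in one sequence, both strands.

    Starts refer to the forward sequence; an N in the sequence never matches.
    """
    enc = _encode(seq)
    if motif.consensus is not None:
        fwd = _consensus_match_starts(enc, motif.consensus)
        rc = _consensus_match_starts(enc, reverse_complement(motif.consensus))
    else:
        fwd = _pwm_match_starts(enc, motif.pwm, motif.match_threshold)
        rc_pwm = motif.pwm[::-1, ::-1]
        rc = _pwm_match_starts(enc, rc_pwm, motif.match_threshold)
    out = [(int(p), "+") for p in fwd]
    out += [(int(p), "-") for p in rc]
    out.sort()
    return out


def scan_motif(sequences, motif: MotifModel) -> dict[str, list[tuple[int, str]]]:
    """Scan named sequences for a motif on both strands.

    ``sequences`` is a mapping name -> sequence, or an iterable of
    (name, sequence) pairs / Biopython SeqRecords. Returns
    name -> list of (start, strand).
    """
    if hasattr(sequences, "items"):
        items = sequences.items()
    else:
        items = []
        for rec in sequences:
            if hasattr(rec, "id") and hasattr(rec, "seq"):
                items.append((rec.id, str(rec.seq)))
            else:
                items.append(tuple(rec))
    return {name: match_positions(str(seq), motif) for name, seq in items}


def genome_match_index(genome: dict[str, str], motif: MotifModel) -> dict[str, np.ndarray]:
    """Precompute sorted motif match start positions per chromosome (both strands)."""
    index = {}
    for chrom, seq in genome.items():
        hits = match_positions(seq, motif)
        index[chrom] = np.array(sorted({p for p, _ in hits}), dtype=np.int64)
    return index


def regions_with_match(
    regions: pd.DataFrame, match_index: dict[str, np.ndarray], motif_len: int
) -> np.ndarray:
    """Boolean flag per region: >= 1 motif instance fully inside the region."""
    flags = np.zeros(len(regions), dtype=bool)
    chroms = np.asarray(regions["chrom"])
    starts = np.asarray(regions["start"], dtype=np.int64)
    ends = np.asarray(regions["end"], dtype=np.int64)
    for chrom in np.unique(chroms):
        hits = match_index.get(chrom)
        if hits is None or len(hits) == 0:
            continue
        sel = chroms == chrom
        lo = np.searchsorted(hits, starts[sel], side="left")
        hi = np.searchsorted(hits, ends[sel] - motif_len, side="right")
        flags[sel] = hi > lo
    return flags


@dataclass
class MotifEnrichmentResult:
    """Observed motif-bearing region count against matched-background nulls."""

    motif: str
    observed: int
    null_counts: np.ndarray
    empirical_p: float = field(init=False)
    report_string: str = field(init=False)

    def __post_init__(self):
        self.null_counts = np.asarray(self.null_counts)
        n = len(self.null_counts)
        if n < 1:
            raise ValueError("need at least one null group")
        ge = int(np.sum(self.null_counts >= self.observed))
        if ge == 0:
            self.empirical_p = 1.0 / n
            self.report_string = f"<{1.0 / n:g}"
        else:
            self.empirical_p = ge / n
            self.report_string = f"{self.empirical_p:g}"

    @property
    def n_groups(self) -> int:
        return len(self.null_counts)


def empirical_enrichment_p(observed: int, null_counts) -> MotifEnrichmentResult:
    """Empirical p-value: fraction of null groups with at least as many matches.

    When no null group reaches the observed count the p-value is reported
    as a bound "< 1/n_groups" (and stored as 1/n_groups); it is never 0.
    """
    return MotifEnrichmentResult(motif="", observed=int(observed), null_counts=null_counts)


def sample_matched_regions(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    expression: pd.Series | dict | None = None,
    n_groups: int = 1000,
    expressed_quantile: float = 0.5,
    seed: int = 0,
    chrom_sizes: dict[str, int] | None = None,
) -> list[pd.DataFrame]:
    """Random region groups matched to the peaks on length and TSS distance.

    Each group has as many regions as there are peaks. A region copies the
    length and signed TSS distance of one peak (drawn with replacement from
    the peaks' empirical joint distribution) and is anchored at a random
    TSS of a gene whose expression exceeds the ``expressed_quantile`` of all
    gene expression levels. Distances are signed relative to gene
    orientation (negative = upstream). Fully seeded and deterministic.

    ``peaks`` needs columns chrom/start/end and ``tss_distance`` (signed,
    from peak midpoint); ``tss`` needs gene/chrom/tss/strand.
    """
    if "tss_distance" not in peaks.columns:
        raise ValueError("peaks must carry a 'tss_distance' column")
    if expression is not None:
        expr = pd.Series(expression)
        levels = expr.reindex(tss["gene"]).to_numpy(dtype=float)
        cut = np.nanquantile(expr.to_numpy(dtype=float), expressed_quantile)
        eligible = tss.loc[np.nan_to_num(levels, nan=-np.inf) > cut]
    else:
        eligible = tss
    if len(eligible) == 0:
        raise ValueError("no eligible TSS above the expression quantile")

    lengths = (peaks["end"] - peaks["start"]).to_numpy()
    dists = peaks["tss_distance"].to_numpy(dtype=float)
    n = len(peaks)
    tss_pos = eligible["tss"].to_numpy()
    tss_chrom = eligible["chrom"].to_numpy()
    tss_sign = np.where(eligible["strand"].to_numpy() == "+", 1, -1)

    rng = np.random.default_rng(seed)
    groups = []
    for _ in range(n_groups):
        pi = rng.integers(0, n, size=n)
        ti = rng.integers(0, len(eligible), size=n)
        center = tss_pos[ti] + tss_sign[ti] * dists[pi].astype(np.int64)
        ln = lengths[pi]
        start = center - ln // 2
        end = start + ln
        chroms = tss_chrom[ti]
        if chrom_sizes is not None:
            size = np.array([chrom_sizes.get(c, np.iinfo(np.int64).max) for c in chroms])
            end = np.minimum(end, size)
        start = np.maximum(start, 0)
        end = np.maximum(end, start + 1)
        groups.append(pd.DataFrame({"chrom": chroms, "start": start, "end": end}))
    return groups


def enrich_motif(
    peaks: pd.DataFrame,
    genome: dict[str, str],
    motif: MotifModel,
    tss: pd.DataFrame,
    expression=None,
    n_groups: int = 1000,
    expressed_quantile: float = 0.5,
    seed: int = 0,
) -> MotifEnrichmentResult:
    """Observed motif-bearing peak count vs matched random region groups."""
    index = genome_match_index(genome, motif)
    L = len(motif)
    observed = int(regions_with_match(peaks, index, L).sum())
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    groups = sample_matched_regions(
        peaks, tss, expression, n_groups, expressed_quantile, seed, chrom_sizes
    )
    nulls = np.array([int(regions_with_match(g, index, L).sum()) for g in groups])
    res = MotifEnrichmentResult(motif=motif.name, observed=observed, null_counts=nulls)
    return res


def motif_frequency_test(
    cluster_labels, match_flags, focal_cluster
) -> tuple[float, float]:
    """Fisher's exact test for motif frequency in one cluster vs the rest.

    Returns (odds_ratio, two_sided_p). The odds ratio uses the Haldane
    0.5 correction when any cell is zero. A degenerate table (an empty
    margin) returns p = 1 with a warning.
    """
    labels = np.asarray(cluster_labels)
    flags = np.asarray(match_flags, dtype=bool)
    if labels.shape != flags.shape:
        raise ValueError("labels and flags must align")
    focal = labels == focal_cluster
    a = int(np.sum(focal & flags))
    b = int(np.sum(focal & ~flags))
    c = int(np.sum(~focal & flags))
    d = int(np.sum(~focal & ~flags))
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warnings.warn("degenerate 2x2 table; p = 1")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:  # pragma: no cover
            orr = (a * d) / (b * c)
        return float(orr), 1.0
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return float(orr), float(p)
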