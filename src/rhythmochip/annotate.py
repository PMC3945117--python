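"""Peak annotation: nearest-TSS assignment, descriptive features, cistrome overlap."""

from __future__ import annotations

import numpy as np
import pandas as pd


def nearest_tss(peaks: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Assign each peak the nearest TSS on its chromosome and a signed distance.

    Distance runs from the peak midpoint to the TSS and is signed by gene
    orientation: negative = the peak lies upstream of the gene. Equidistant
    TSSs resolve to the one with the smaller coordinate. Peaks on
    chromosomes without any annotated TSS get no assignment (gene = None).

    ``annotation`` needs columns gene/chrom/tss/strand.
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    by_chrom = {}
    for chrom, grp in annotation.groupby("chrom", sort=False, observed=True):
        g = grp.sort_values(["tss", "gene"], kind="stable")
        by_chrom[chrom] = (
            g["tss"].to_numpy(),
            g["gene"].to_numpy(),
            g["strand"].to_numpy(),
        )
    genes, dists = [], []
    for chrom, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"]):
        entry = by_chrom.get(chrom)
        if entry is None:
            genes.append(None)
            dists.append(np.nan)
            continue
        tss, gname, strand = entry
        mid = (int(s) + int(e)) // 2
        j = np.searchsorted(tss, mid)
        candidates = [i for i in (j - 1, j) if 0 <= i < len(tss)]
        best = min(
            candidates, key=lambda i: (abs(int(tss[i]) - mid), int(tss[i]))
        )
        raw = mid - int(tss[best])
        signed = raw if strand[best] == "+" else -raw
        genes.append(gname[best])
        dists.append(signed)
    out = peaks.copy()
    out["gene"] = genes
    out["tss_distance"] = dists
    return out


def peak_features(
    peaks: pd.DataFrame,
    fits=None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-peak descriptive table: length, fitted oscillation amplitude,
    phase, amplitude p-value, and signed TSS distance when available."""
    out = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"],
            "end": peaks["end"],
            "length": peaks["end"] - peaks["start"],
        }
    )
    if "name" in peaks.columns:
        out.insert(0, "name", peaks["name"])
    if fits is not None:
        out["amplitude"] = [f.b1 for f in fits]
        out["phase_hours"] = [f.phase_hours for f in fits]
        out["amplitude_p"] = [f.amplitude_p for f in fits]
    if annotation is not None:
        ann = nearest_tss(peaks, annotation)
        out["gene"] = ann["gene"].to_numpy()
        out["tss_distance"] = ann["tss_distance"].to_numpy()
    elif "tss_distance" in peaks.columns:
        out["tss_distance"] = peaks["tss_distance"]
    return out


def _overlap_flags(peaks: pd.DataFrame, others: pd.DataFrame) -> np.ndarray:
    flags = np.zeros(len(peaks), dtype=bool)
    by_chrom = {}
    for chrom, grp in others.groupby("chrom", sort=False, observed=True):
        g = grp.sort_values("start", kind="stable")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
    for i, (chrom, s, e) in enumerate(
        zip(peaks["chrom"], peaks["start"], peaks["end"])
    ):
        entry = by_chrom.get(chrom)
        if entry is None:
            continue
        starts, maxend = entry
        j = np.searchsorted(starts, int(e), side="left")  # others with start < e
        flags[i] = j > 0 and maxend[j - 1] > int(s)
    return flags


def overlap_count(
    peaks: pd.DataFrame,
    other_regions: pd.DataFrame,
    mode: str = "overlapping",
    annotation: pd.DataFrame | None = None,
    window: int = 1000,
) -> dict:
    """Count peaks supported by another region set.

    mode="overlapping": a peak counts if it shares >= 1 nt with any other
    region. mode="near_promoter": a peak counts if any other region falls
    within ``window`` nt of the TSS of the peak's assigned nearest gene
    (requires ``annotation``).

    Returns {"count", "total", "fraction", "flags"}.
    """
    if mode == "overlapping":
        flags = _overlap_flags(peaks, other_regions)
    elif mode == "near_promoter":
        if annotation is None:
            raise ValueError("near_promoter mode requires an annotation")
        ann = nearest_tss(peaks, annotation)
        tss_by_gene = dict(zip(annotation["gene"], zip(annotation["chrom"], annotation["tss"])))
        promoters = []
        for gene in ann["gene"]:
            if gene is None:
                promoters.append(("", -1, -1))
            else:
                chrom, tss = tss_by_gene[gene]
                promoters.append((chrom, max(int(tss) - window, 0), int(tss) + window))
        prom_df = pd.DataFrame(promoters, columns=["chrom", "start", "end"])
        flags = _overlap_flags(prom_df, other_regions)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = len(peaks)
    count = int(flags.sum())
    return {
        "count": count,
        "total": n,
        "fraction": count / n if n else float("nan"),
        "flags": flags,
    }
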