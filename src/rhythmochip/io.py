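"""Readers and writers for the plain-text formats used throughout.

Conventions: BED intervals are 0-based half-open; SAM positions are
converted from pysam's 0-based ``reference_start`` (already half-open
compatible); tag tables are 4-column tab text ``chrom pos strand n_hits``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from rhythmochip.tagproc import empty_tags


def read_tag_table(path) -> Iterator[tuple]:
    """Yield (chrom, pos, strand, n_hits) from 4-column tab-separated text."""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            chrom, pos, strand = parts[0], int(parts[1]), parts[2]
            n_hits = int(parts[3]) if len(parts) > 3 else 1
            yield chrom, pos, strand, n_hits


def read_sam_tags(path) -> Iterator[tuple]:
    """Yield (chrom, pos, strand, n_hits) from a SAM/BAM file.

    The NH tag provides n_hits when present (default 1). Unmapped reads are
    skipped. Positions are 0-based leftmost coordinates.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            n_hits = aln.get_tag("NH") if aln.has_tag("NH") else 1
            strand = "-" if aln.is_reverse else "+"
            yield aln.reference_name, aln.reference_start, strand, int(n_hits)


def read_tags_any(path) -> Iterator[tuple]:
    p = str(path)
    if p.endswith((".sam", ".bam")):
        return read_sam_tags(path)
    return read_tag_table(path)


def write_tag_table(tags: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, strand, n_hits in zip(
            tags["chrom"], tags["pos"], tags["strand"], tags["n_hits"]
        ):
            fh.write(f"{chrom}\t{pos}\t{strand}\t{n_hits}\n")


def write_tag_bed(tags: pd.DataFrame, path, read_length: int = 1) -> None:
    """Write tags as 6-column BED; score = weight * 1000."""
    with open(path, "w") as fh:
        for chrom, pos, strand, weight in zip(
            tags["chrom"], tags["pos"], tags["strand"], tags["weight"]
        ):
            fh.write(
                f"{chrom}\t{pos}\t{pos + read_length}\ttag\t{int(round(weight * 1000))}\t{strand}\n"
            )


def read_bed(path) -> pd.DataFrame:
    """Read a BED file into a DataFrame with at least chrom/start/end."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            row = {
                "chrom": parts[0],
                "start": int(parts[1]),
                "end": int(parts[2]),
            }
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 4:
                try:
                    row["score"] = float(parts[4])
                except ValueError:
                    row["score"] = 0.0
            if len(parts) > 5:
                row["strand"] = parts[5]
            rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.DataFrame(rows)


def write_bed(regions: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"]
    opt = [c for c in ["name", "score", "strand"] if c in regions.columns]
    with open(path, "w") as fh:
        for _, row in regions.iterrows():
            fields = [str(row[c]) for c in cols]
            for c in opt:
                v = row[c]
                fields.append(str(int(v)) if c == "score" and float(v).is_integer() else str(v))
            fh.write("\t".join(fields) + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a row-labelled TSV matrix (first column = row id, header = columns)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_gff_tss(path) -> pd.DataFrame:
    """Extract TSSs from a GFF3 file (gene/transcript/mRNA features).

    Returns a DataFrame with gene, chrom, tss (0-based), strand. The TSS is
    the start for + features and end-1 for - features.
    """
    rows = []
    wanted = {"gene", "transcript", "mRNA"}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in wanted:
                continue
            chrom, start, end, strand = parts[0], int(parts[3]), int(parts[4]), parts[6]
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name") or f"{chrom}:{start}"
            tss = start - 1 if strand == "+" else end - 1
            rows.append({"gene": gene, "chrom": chrom, "tss": tss, "strand": strand})
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


def read_tss_bed(path) -> pd.DataFrame:
    """Read a TSS annotation from BED (name = gene id; start = TSS for +, end-1 for -)."""
    bed = read_bed(path)
    if len(bed) == 0:
        return pd.DataFrame(columns=["gene", "chrom", "tss", "strand"])
    strand = bed["strand"] if "strand" in bed.columns else pd.Series(["+"] * len(bed))
    tss = np.where(strand == "+", bed["start"], bed["end"] - 1)
    name = bed["name"] if "name" in bed.columns else [f"g{i}" for i in range(len(bed))]
    return pd.DataFrame(
        {"gene": name, "chrom": bed["chrom"], "tss": tss, "strand": strand}
    )


def read_motif_file(path) -> list:
    """Read motifs from simple tab format.

    Consensus rows: ``name<TAB>IUPAC``. PWM blocks: a header row
    ``name<TAB>PWM<TAB>length`` followed by ``length`` rows of four
    tab-separated probabilities (A C G T).
    """
    from rhythmochip.motifs import MotifModel

    motifs = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("#")]
    i = 0
    while i < len(lines):
        parts = lines[i].split("\t")
        if len(parts) >= 3 and parts[1].upper() == "PWM":
            name, length = parts[0], int(parts[2])
            rows = [
                [float(x) for x in lines[i + 1 + j].split("\t")] for j in range(length)
            ]
            motifs.append(MotifModel(name=name, pwm=np.asarray(rows)))
            i += 1 + length
        else:
            motifs.append(MotifModel(name=parts[0], consensus=parts[1]))
            i += 1
    return motifs


def load_tags_df(path) -> pd.DataFrame:
    from rhythmochip.tagproc import load_mapped_tags

    tags = load_mapped_tags(read_tags_any(path), max_hits=10**9)
    return tags if len(tags) else empty_tags()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
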