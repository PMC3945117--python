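"""Ground-truthed synthetic fixtures: genomes, rhythmic ChIP/input libraries,
motif-embedded sequences and clustered expression matrices.

Site occupancy follows baseline * fold * (1 + rel_amplitude * cos(2*pi*(t -
phase)/24)); reads are placed strand-separated at +/- fragment/2 around the
site center with truncated-Gaussian jitter and Poisson-sampled depth; input
libraries are uniform background. Everything is a pure function of
(config, seed): the same seed reproduces the fixture byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rhythmochip import io as rio

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_TIME_POINTS = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0, 26.0)


@dataclass
class ExpressionCluster:
    phase: float
    amplitude: float = 1.0
    sigma: float = 0.2
    mean: float = 8.0


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset; ``seed`` fixes every draw."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_background_chromosomes: int = 1  # trailing chromosomes carry no sites
    n_sites: int = 50
    background_rate: float = 0.05  # ChIP background tags per bp per library
    input_rate: float = 0.05
    site_baseline: float = 25.0  # expected tags per library at fold 1
    fold_range: tuple[float, float] = (4.0, 12.0)
    amp_range: tuple[float, float] = (0.4, 1.0)
    phase_range: tuple[float, float] = (12.0, 20.0)
    fragment_size: int = 190
    read_length: int = 80
    depth_scale: float = 1.0
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    multimapper_fraction: float = 0.0
    overdispersion: float | None = None  # NB dispersion; None = Poisson
    n_genes: int = 200
    motif: str = "ATCACCCCAC"
    motif_fraction: float = 0.6
    background_motif_rate: float = 0.05
    expression_clusters: tuple = (
        ExpressionCluster(phase=16.0),
        ExpressionCluster(phase=20.0),
        ExpressionCluster(phase=0.0),
    )
    batch_offsets: tuple[float, ...] = (0.0, 1.0)
    ko_phase_shift: float = 4.0
    period: float = 24.0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def site_chroms(self) -> list[str]:
        n = self.n_chromosomes - self.n_background_chromosomes
        return self.chrom_names()[: max(n, 1)]

    @property
    def jitter_sd(self) -> float:
        return self.fragment_size / 4.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["expression_clusters"] = [dataclasses.asdict(c) if not isinstance(c, dict) else c
                                    for c in d["expression_clusters"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "expression_clusters" in d:
            d["expression_clusters"] = tuple(
                ExpressionCluster(**c) if isinstance(c, dict) else c
                for c in d["expression_clusters"]
            )
        for key in ("fold_range", "amp_range", "phase_range", "time_points", "batch_offsets"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure: one row per site and per gene."""

    sites: pd.DataFrame
    genes: pd.DataFrame
    config: SimulationConfig = None

    def to_dict(self) -> dict:
        return {
            "sites": self.sites.to_dict(orient="list"),
            "genes": self.genes.to_dict(orient="list"),
        }


def _rng(config: SimulationConfig, *stream) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def build_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the planted site and gene tables (deterministic in the seed)."""
    rng = _rng(config, 0)
    site_chroms = config.site_chroms()
    margin = config.fragment_size * 3
    n = config.n_sites
    chroms = [site_chroms[i % len(site_chroms)] for i in range(n)]
    centers = rng.integers(margin, config.chrom_length - margin, size=n)
    folds = rng.uniform(*config.fold_range, size=n)
    amps = rng.uniform(*config.amp_range, size=n)
    phases = rng.uniform(*config.phase_range, size=n) % config.period
    has_motif = rng.random(n) < config.motif_fraction

    genes_per_chrom = max(config.n_genes // config.n_chromosomes, 1)
    g_chrom, g_tss, g_strand = [], [], []
    for chrom in config.chrom_names():
        pos = np.sort(rng.integers(1000, config.chrom_length - 1000, size=genes_per_chrom))
        g_chrom += [chrom] * genes_per_chrom
        g_tss += pos.tolist()
        g_strand += rng.choice(["+", "-"], size=genes_per_chrom).tolist()
    n_genes = len(g_tss)
    clusters = rng.integers(0, len(config.expression_clusters), size=n_genes)
    expr_level = rng.uniform(2.0, 14.0, size=n_genes)
    gene_motif = rng.random(n_genes) < config.background_motif_rate

    sites = pd.DataFrame(
        {
            "site": [f"site_{i + 1}" for i in range(n)],
            "chrom": chroms,
            "center": centers,
            "fold": folds,
            "rel_amplitude": amps,
            "phase": phases,
            "has_motif": has_motif,
        }
    ).sort_values(["chrom", "center"], kind="stable").reset_index(drop=True)
    genes = pd.DataFrame(
        {
            "gene": [f"gene_{i + 1}" for i in range(n_genes)],
            "chrom": g_chrom,
            "tss": g_tss,
            "strand": g_strand,
            "cluster": clusters,
            "expression": expr_level,
            "has_motif": gene_motif,
        }
    )
    return GroundTruth(sites=sites, genes=genes, config=config)


def simulate_genome(config: SimulationConfig, truth: GroundTruth) -> dict[str, str]:
    """Random genome with the motif embedded under flagged sites and at the
    configured fraction of TSS windows."""
    rng = _rng(config, 1)
    genome = {}
    for chrom in config.chrom_names():
        idx = rng.integers(0, 4, size=config.chrom_length)
        genome[chrom] = BASES[idx].tobytes().decode("ascii")
    motif = config.motif.upper()

    def embed(chrom: str, pos: int):
        seq = genome[chrom]
        pos = int(np.clip(pos, 0, len(seq) - len(motif)))
        genome[chrom] = seq[:pos] + motif + seq[pos + len(motif):]

    for _, row in truth.sites.iterrows():
        if row["has_motif"]:
            embed(row["chrom"], int(row["center"]) - len(motif) // 2)
    for _, row in truth.genes.iterrows():
        if row["has_motif"]:
            offset = int(rng.integers(-80, 80))
            embed(row["chrom"], int(row["tss"]) + offset)
    return genome


def _draw_counts(rng: np.random.Generator, lam: np.ndarray, dispersion: float | None):
    lam = np.maximum(np.asarray(lam, dtype=float), 0.0)
    if dispersion is None:
        return rng.poisson(lam)
    # negative binomial with mean lam, variance lam + lam^2/dispersion
    r = dispersion
    p = r / (r + lam)
    return rng.negative_binomial(r, np.clip(p, 1e-12, 1.0))


def _uniform_tags(
    rng: np.random.Generator, config: SimulationConfig, rate: float
) -> pd.DataFrame:
    frames = []
    for chrom in config.chrom_names():
        n = int(rng.poisson(rate * config.chrom_length * config.depth_scale))
        pos = rng.integers(0, config.chrom_length, size=n)
        strand = rng.choice(["+", "-"], size=n)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand}))
    df = pd.concat(frames, ignore_index=True)
    df["weight"] = 1.0
    df["n_hits"] = 1
    return df


def _site_tags(
    rng: np.random.Generator, config: SimulationConfig, truth: GroundTruth, t: float,
    phase_shift: float = 0.0,
) -> pd.DataFrame:
    w = 2 * math.pi / config.period
    half_frag = config.fragment_size // 2
    sd = config.jitter_sd
    rows = []
    for _, s in truth.sites.iterrows():
        lam = (
            config.depth_scale
            * config.site_baseline
            * s["fold"]
            * (1.0 + s["rel_amplitude"] * math.cos(w * (t - s["phase"] - phase_shift)))
        )
        n = int(_draw_counts(rng, np.array([lam]), config.overdispersion)[0])
        if n == 0:
            continue
        n_plus = int(rng.binomial(n, 0.5))
        jit = np.clip(rng.normal(0.0, sd, size=n), -2 * sd, 2 * sd).round().astype(int)
        center = int(s["center"])
        pos_plus = center - half_frag + jit[:n_plus]
        pos_minus = center + half_frag - config.read_length + jit[n_plus:]
        pos = np.concatenate([pos_plus, pos_minus])
        strand = np.array(["+"] * n_plus + ["-"] * (n - n_plus))
        pos = np.clip(pos, 0, config.chrom_length - 1)
        rows.append(pd.DataFrame({"chrom": s["chrom"], "pos": pos, "strand": strand}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "weight", "n_hits"])
    df = pd.concat(rows, ignore_index=True)
    df["weight"] = 1.0
    df["n_hits"] = 1
    return df


def _apply_multimappers(
    rng: np.random.Generator, config: SimulationConfig, df: pd.DataFrame
) -> pd.DataFrame:
    frac = config.multimapper_fraction
    if frac <= 0 or len(df) == 0:
        return df
    mask = rng.random(len(df)) < frac
    n = int(mask.sum())
    if n == 0:
        return df
    df = df.copy()
    df.loc[mask, "n_hits"] = 2
    df.loc[mask, "weight"] = 0.5
    shadow = df.loc[mask].copy()
    shadow["chrom"] = rng.choice(config.chrom_names(), size=n)
    shadow["pos"] = rng.integers(0, config.chrom_length, size=n)
    return pd.concat([df, shadow], ignore_index=True)


def simulate_chip_library(
    config: SimulationConfig, t: float, truth: GroundTruth | None = None,
    genotype: str = "WT",
) -> pd.DataFrame:
    """Raw (unshifted, with duplicates) ChIP tags for one time point.

    KO genotype delays every site's phase by ``ko_phase_shift`` hours.
    """
    if truth is None:
        truth = build_truth(config)
    rng = _rng(config, 2, int(round(t * 10)), 0 if genotype == "WT" else 1)
    shift = config.ko_phase_shift if genotype != "WT" else 0.0
    bg = _uniform_tags(rng, config, config.background_rate)
    sites = _site_tags(rng, config, truth, t, phase_shift=shift)
    df = pd.concat([bg, sites], ignore_index=True)
    return _apply_multimappers(rng, config, df)


def simulate_input_library(config: SimulationConfig, t: float) -> pd.DataFrame:
    """Uniform-background input tags for one time point (no site signal)."""
    rng = _rng(config, 3, int(round(t * 10)))
    if config.input_rate <= 0 or config.depth_scale <= 0:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "weight", "n_hits"])
    return _uniform_tags(rng, config, config.input_rate)


def simulate_expression(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    genotype: str = "WT",
    batch_labels=None,
) -> pd.DataFrame:
    """Expression matrix (genes x time points) with cluster phases, optional
    batch offsets per sample and a KO phase collapse toward the binding phase."""
    if truth is None:
        truth = build_truth(config)
    rng = _rng(config, 4, 0 if genotype == "WT" else 1)
    times = np.asarray(config.time_points, dtype=float)
    w = 2 * math.pi / config.period
    if batch_labels is None:
        batch_labels = np.zeros(len(times), dtype=int)
    batch_labels = np.asarray(batch_labels)
    offsets = np.array([config.batch_offsets[b] for b in batch_labels])

    ref_phase = float(np.mean([c.phase for c in config.expression_clusters]))
    mat = np.zeros((len(truth.genes), len(times)))
    for i, row in truth.genes.iterrows():
        cl = config.expression_clusters[int(row["cluster"])]
        phase = cl.phase
        if genotype != "WT":
            phase = ref_phase + config.ko_phase_shift
        mat[i] = (
            cl.mean
            + cl.amplitude * np.cos(w * (times - phase))
            + offsets
            + rng.normal(0.0, cl.sigma, size=len(times))
        )
    return pd.DataFrame(
        mat, index=truth.genes["gene"], columns=[f"ZT{t:g}" for t in times]
    )


def write_fixture(config: SimulationConfig, outdir) -> GroundTruth:
    """Write a complete, self-contained text fixture to ``outdir``.

    Emits: genome.fa, chip_ZT*.tags / input_ZT*.tags (4-column tag text),
    tss.bed, expression.tsv, truth.json, config.json. Byte-identical for a
    fixed (config, seed).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = build_truth(config)
    genome = simulate_genome(config, truth)
    rio.write_fasta(genome, out / "genome.fa")
    for t in config.time_points:
        chip = simulate_chip_library(config, t, truth)
        rio.write_tag_table(chip, out / f"chip_ZT{t:g}.tags")
        inp = simulate_input_library(config, t)
        rio.write_tag_table(inp, out / f"input_ZT{t:g}.tags")
    tss_bed = pd.DataFrame(
        {
            "chrom": truth.genes["chrom"],
            "start": truth.genes["tss"],
            "end": truth.genes["tss"] + 1,
            "name": truth.genes["gene"],
            "score": truth.genes["expression"].round(4),
            "strand": truth.genes["strand"],
        }
    )
    rio.write_bed(tss_bed, out / "tss.bed")
    expr = simulate_expression(config, truth)
    rio.write_matrix_tsv(expr, out / "expression.tsv")
    rio.write_json(
        {"version": 1, **truth.to_dict()},
        out / "truth.json",
    )
    rio.write_json(config.to_dict(), out / "config.json")
    return truth
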