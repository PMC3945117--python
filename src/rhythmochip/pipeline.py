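"""End-to-end orchestration of the analysis stages with provenance records.

Stage order: tag preparation -> block peak calling -> region quantification
-> cosinor fitting -> clustering -> annotation -> motif enrichment. No
stage mutates its inputs; every output file gets a JSON provenance record
(config hash, seed, package/library versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import rhythmochip
from rhythmochip import annotate as rann
from rhythmochip import io as rio
from rhythmochip import motifs as rmot
from rhythmochip import peakcall as rpk
from rhythmochip import rhythm as rr
from rhythmochip import tagproc as rtag

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run."""

    chip_files: list = field(default_factory=list)
    input_files: list = field(default_factory=list)
    time_points: list = field(default_factory=list)
    fragment_sizes: list = field(default_factory=list)
    read_length: int = rtag.DEFAULT_READ_LENGTH
    max_hits: int = rtag.DEFAULT_MAX_HITS
    block_size: int = rpk.DEFAULT_BLOCK_SIZE
    min_signal: float = rpk.DEFAULT_MIN_SIGNAL
    pseudo: float = rpk.DEFAULT_PSEUDO
    log2_threshold: float = rpk.DEFAULT_LOG2_THRESHOLD
    init_border: int = rpk.DEFAULT_INIT_BORDER
    retain: float = rpk.DEFAULT_RETAIN
    min_border: int = rpk.DEFAULT_MIN_BORDER
    period: float = rr.DEFAULT_PERIOD
    k_clusters: int = 4
    pcut_binding: float = 0.1
    pcut_expression: float = 0.05
    n_groups: int = 1000
    expressed_quantile: float = 0.5
    genome_fasta: str | None = None
    tss_file: str | None = None
    expression_file: str | None = None
    motif_file: str | None = None
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        if len(self.chip_files) == 0:
            raise ValueError("no ChIP libraries configured")
        if len(self.chip_files) != len(self.input_files):
            raise ValueError("chip and input library counts differ")
        if len(self.time_points) != len(self.chip_files):
            raise ValueError("one time point per library required")
        if len(self.fragment_sizes) != len(self.chip_files):
            raise ValueError("one fragment size per library required")
        for name in ("block_size", "min_signal", "retain", "period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.retain <= 1:
            raise ValueError("retain must be in (0, 1]")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def provenance_record(config: RunConfig, stage: str) -> dict:
    import scipy

    return {
        "stage": stage,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "versions": {
            "rhythmochip": rhythmochip.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }


def load_libraries(config: RunConfig, files: list, kind: str) -> list[rtag.TimePointLibrary]:
    libs = []
    for path, t, frag in zip(files, config.time_points, config.fragment_sizes):
        if not Path(path).exists():
            raise FileNotFoundError(f"{kind} library for ZT{t:g} missing: {path}")
        lib = rtag.prepare_library(
            rio.read_tags_any(path),
            label=float(t),
            avg_fragment_size=int(frag),
            read_length=config.read_length,
            max_hits=config.max_hits,
        )
        libs.append(lib)
    return libs


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the result bundle to ``config.outdir``.

    Returns a dict with the in-memory results (peaks, signal, fits, labels,
    annotation, enrichments). A stage failure raises with the stage name.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    chip_libs = _stage("tags/chip", lambda: load_libraries(config, config.chip_files, "ChIP"))
    input_libs = _stage("tags/input", lambda: load_libraries(config, config.input_files, "input"))

    peaks, signal, labels = _stage(
        "callpeaks",
        lambda: rpk.call_peaks(
            chip_libs,
            input_libs,
            block_size=config.block_size,
            min_signal=config.min_signal,
            pseudo=config.pseudo,
            log2_threshold=config.log2_threshold,
            init_border=config.init_border,
            retain=config.retain,
            min_border=config.min_border,
        ),
    )
    results["peaks"] = peaks
    results["signal"] = signal
    peak_frame = rpk.peaks_to_frame(peaks)
    rio.write_bed(peak_frame, out / "peaks.bed")
    sig_df = pd.DataFrame(
        signal,
        index=peak_frame["name"],
        columns=[f"ZT{t:g}" for t in labels],
    )
    rio.write_matrix_tsv(sig_df, out / "peak_signal.tsv")

    fits = _stage("rhythm", lambda: rr.fit_matrix(signal, labels, period=config.period))
    results["fits"] = fits
    fit_df = pd.DataFrame(
        {
            "name": peak_frame["name"],
            "b0": [f.b0 for f in fits],
            "amplitude": [f.b1 for f in fits],
            "phase_hours": [f.phase_hours for f in fits],
            "amplitude_p": [f.amplitude_p for f in fits],
            "ci_lo": [f.ci_phase[0] if f.ci_phase else np.nan for f in fits],
            "ci_hi": [f.ci_phase[1] if f.ci_phase else np.nan for f in fits],
        }
    ).set_index("name")
    rio.write_matrix_tsv(fit_df, out / "cosine_fits.tsv")

    if len(signal) >= config.k_clusters and len(signal) > 1:
        labels_arr = _stage(
            "cluster", lambda: rr.cluster_profiles(signal, k=config.k_clusters)
        )
    else:
        labels_arr = np.ones(len(signal), dtype=int)
    results["cluster_labels"] = labels_arr

    annotation = None
    if config.tss_file:
        tss_path = str(config.tss_file)
        annotation = (
            rio.read_gff_tss(tss_path)
            if tss_path.endswith((".gff", ".gff3"))
            else rio.read_tss_bed(tss_path)
        )
        ann_df = _stage(
            "annotate",
            lambda: rann.peak_features(
                peak_frame.assign(cluster=labels_arr), fits=fits, annotation=annotation
            ),
        )
        ann_df["cluster"] = labels_arr
        results["annotation"] = ann_df
        rio.write_matrix_tsv(ann_df.set_index("name"), out / "peak_annotation.tsv")

    if config.genome_fasta and config.motif_file and annotation is not None:
        genome = rio.read_fasta(config.genome_fasta)
        motifs = rio.read_motif_file(config.motif_file)
        expression = None
        if config.expression_file:
            em = rio.read_matrix_tsv(config.expression_file)
            expression = em.mean(axis=1)
        peaks_ann = rann.nearest_tss(peak_frame, annotation)
        enrichments = _stage(
            "motifs",
            lambda: [
                rmot.enrich_motif(
                    peaks_ann,
                    genome,
                    m,
                    annotation,
                    expression,
                    n_groups=config.n_groups,
                    expressed_quantile=config.expressed_quantile,
                    seed=config.seed,
                )
                for m in motifs
            ],
        )
        results["enrichments"] = enrichments
        rows = [
            {
                "motif": e.motif,
                "observed": e.observed,
                "n_groups": e.n_groups,
                "empirical_p": e.empirical_p,
                "report": e.report_string,
            }
            for e in enrichments
        ]
        pd.DataFrame(rows).to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)

    rio.write_json(provenance_record(config, "run"), out / "provenance.json")
    rio.write_json(config.to_dict(), out / "run_config.json")
    return results
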