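import numpy as np
import pandas as pd
import pytest

from rhythmochip import peakcall as rpk
from rhythmochip import rhythm as rr
from rhythmochip import tagproc as rtag
from rhythmochip.synthetic_data import (
    SimulationConfig,
    build_truth,
    simulate_chip_library,
    simulate_input_library,
)


def prepare_sim_library(cfg: SimulationConfig, raw: pd.DataFrame, t: float):
    """Dedup + shift one simulated raw tag table into a TimePointLibrary."""
    tags = rtag.deduplicate(raw)
    total = len(tags)
    shifted = rtag.shift_tags(tags, rtag.compute_shift(cfg.fragment_size, cfg.read_length))
    return rtag.TimePointLibrary(
        label=t % 24.0,
        tags=shifted,
        avg_fragment_size=cfg.fragment_size,
        read_length=cfg.read_length,
        total_nonredundant=total,
    )


def run_synthetic_pipeline(cfg: SimulationConfig):
    """Simulate -> prepare -> call peaks -> fit cosines. Returns a result dict."""
    truth = build_truth(cfg)
    chip_libs = [
        prepare_sim_library(cfg, simulate_chip_library(cfg, t, truth), t)
        for t in cfg.time_points
    ]
    input_libs = [
        prepare_sim_library(cfg, simulate_input_library(cfg, t), t)
        for t in cfg.time_points
    ]
    peaks, signal, labels = rpk.call_peaks(chip_libs, input_libs)
    fits = rr.fit_matrix(signal, labels) if len(signal) else []
    return {
        "config": cfg,
        "truth": truth,
        "chip_libs": chip_libs,
        "input_libs": input_libs,
        "peaks": peaks,
        "frame": rpk.peaks_to_frame(peaks),
        "signal": signal,
        "labels": labels,
        "fits": fits,
    }


def match_peaks_to_sites(result, tolerance: int = 250):
    """Pair called peaks with planted sites (mode offset read_length/2 corrected).

    Returns (recovered_fraction, fitted_phases, planted_phases, background_calls).
    """
    cfg = result["config"]
    truth = result["truth"]
    frame = result["frame"]
    offset = cfg.read_length // 2  # density modes sit at center - read_length/2
    site_chroms = set(cfg.site_chroms())
    bg_calls = int((~frame["chrom"].isin(site_chroms)).sum())

    mids = ((frame["start"] + frame["end"]) // 2).to_numpy()
    recovered = 0
    fitted, planted = [], []
    centers = truth.sites["center"].to_numpy()
    site_chrom = truth.sites["chrom"].to_numpy()
    for c, ch in zip(centers, site_chrom):
        on = (frame["chrom"] == ch).to_numpy()
        if on.any() and np.abs(mids[on] - (c - offset)).min() <= tolerance:
            recovered += 1
    for (ch, mid), fit in zip(zip(frame["chrom"], mids), result["fits"]):
        mask = site_chrom == ch
        if not mask.any():
            continue
        d = np.abs(centers[mask] - (mid + offset))
        j = int(np.argmin(d))
        if d[j] <= tolerance:
            fitted.append(fit.phase_hours)
            planted.append(float(truth.sites["phase"].to_numpy()[mask][j]))
    return recovered / len(centers), np.array(fitted), np.array(planted), bg_calls


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default fixture (seed 1), shared by tests."""
    return run_synthetic_pipeline(SimulationConfig(seed=1))


@pytest.fixture
def tiny_config():
    return SimulationConfig(
        seed=11,
        n_chromosomes=2,
        chrom_length=100_000,
        n_sites=5,
        n_genes=30,
        background_rate=0.05,
        input_rate=0.05,
    )
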