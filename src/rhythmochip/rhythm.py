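"""Cosinor rhythmicity estimation, temporal clustering and circular phase statistics.

The single-condition model is x(t) = b0 + b1*cos(b3 + 2*pi*t/period). The
fit is obtained by Gauss-Newton iteration initialised from the closed-form
linear harmonic regression x = b0 + a*cos(wt) + c*sin(wt) (the two
parameterisations describe the same model, so the optimum coincides).
``phase_hours`` is the peak time of the fitted cosine: the maximum of
cos(b3 + wt) occurs at t = (-b3 mod 2*pi)/w.

The amplitude p-value is the F-test of the 2-df harmonic terms against an
intercept-only model; the phase confidence interval comes from the delta
method on the (a, c) covariance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import f as f_dist
from scipy.stats import norm

DEFAULT_PERIOD = 24.0


@dataclass
class CosineFit:
    """Cosinor fit for one time series."""

    b0: float
    b1: float
    b3: float
    period: float = DEFAULT_PERIOD
    amplitude_p: float = 1.0
    ci_phase: tuple[float, float] | None = None
    rss: float = float("nan")
    dof: int = 0
    flagged: bool = False

    @property
    def phase_hours(self) -> float:
        return ((-self.b3) % (2 * math.pi)) * self.period / (2 * math.pi)

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        w = 2 * math.pi / self.period
        return self.b0 + self.b1 * np.cos(self.b3 + w * t)


@dataclass
class GenotypeCosineFit:
    """Joint cosinor fit of two genotypes with additive batch offsets.

    The baseline coefficients describe the reference genotype; the ``_gt``
    coefficients are the genotype-interaction differences (all zero when
    the two genotypes share one curve).
    """

    b0: float
    b1: float
    b3: float
    b0_gt: float
    b1_gt: float
    b3_gt: float
    batch_coefs: np.ndarray
    period: float = DEFAULT_PERIOD
    amplitude_p: dict = field(default_factory=dict)
    rss: float = float("nan")
    dof: int = 0

    @property
    def fit_ref(self) -> CosineFit:
        return CosineFit(self.b0, self.b1, self.b3, self.period)

    @property
    def fit_alt(self) -> CosineFit:
        return CosineFit(
            self.b0 + self.b0_gt, self.b1 + self.b1_gt, self.b3 + self.b3_gt, self.period
        )

    @property
    def phase_shift_hours(self) -> float:
        """Peak-time difference alt - ref, wrapped to (-period/2, period/2]."""
        d = self.fit_alt.phase_hours - self.fit_ref.phase_hours
        half = self.period / 2
        return ((d + half) % self.period) - half


@dataclass
class PhaseInterval:
    """Shortest circular arc containing a given fraction of phases."""

    start_zt: float
    end_zt: float
    length: float
    coverage: float


def _canonicalize(b1: float, b3: float) -> tuple[float, float]:
    """Fold negative amplitudes into the phase; wrap b3 to (-pi, pi]."""
    if b1 < 0:
        b1, b3 = -b1, b3 + math.pi
    b3 = (b3 + math.pi) % (2 * math.pi) - math.pi
    if b3 == -math.pi:
        b3 = math.pi
    return b1, b3


def _linear_harmonic(t: np.ndarray, x: np.ndarray, w: float):
    """Closed-form least squares of x = b0 + a cos(wt) + c sin(wt)."""
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    resid = x - X @ beta
    return beta, X, float(resid @ resid)


def fit_cosine(
    t, x, period: float = DEFAULT_PERIOD, max_iter: int = 50, tol: float = 1e-12
) -> CosineFit:
    """Fit x(t) = b0 + b1*cos(b3 + 2*pi*t/period) by least squares.

    Gauss-Newton iteration starts from the exact linear harmonic solution.
    Series with fewer than 4 distinct time points, or no variance, return a
    flagged fit with amplitude_p = 1.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.shape != x.shape:
        raise ValueError("t and x must have the same length")
    n = len(x)
    w = 2 * math.pi / period
    distinct = len(np.unique(np.mod(t, period)))
    if distinct < 4 or np.ptp(x) == 0:
        return CosineFit(
            b0=float(np.mean(x)) if n else 0.0,
            b1=0.0,
            b3=0.0,
            period=period,
            amplitude_p=1.0,
            flagged=True,
            dof=max(n - 3, 0),
        )

    beta, X, rss_lin = _linear_harmonic(t, x, w)
    b0 = float(beta[0])
    a, c = float(beta[1]), float(beta[2])
    b1 = math.hypot(a, c)
    b3 = math.atan2(-c, a)

    # Gauss-Newton refinement in the (b0, b1, b3) parameterisation
    params = np.array([b0, b1, b3])
    rss = rss_lin
    for _ in range(max_iter):
        b0_, b1_, b3_ = params
        arg = b3_ + w * t
        r = x - (b0_ + b1_ * np.cos(arg))
        J = np.column_stack([np.ones_like(t), np.cos(arg), -b1_ * np.sin(arg)])
        try:
            step, *_ = np.linalg.lstsq(J, r, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        new = params + step
        arg_new = new[2] + w * t
        r_new = x - (new[0] + new[1] * np.cos(arg_new))
        rss_new = float(r_new @ r_new)
        if rss_new <= rss + tol:
            params = new
            if rss - rss_new < tol:
                rss = rss_new
                break
            rss = rss_new
        else:
            break
    b0, b1, b3 = params
    b1, b3 = _canonicalize(float(b1), float(b3))
    b0 = float(b0)

    dof = n - 3
    rss0 = float(np.sum((x - x.mean()) ** 2))
    if dof <= 0:
        p = float("nan")
    elif rss <= 0:
        p = 0.0
    elif rss0 <= rss:
        p = 1.0
    else:
        F = ((rss0 - rss) / 2.0) / (rss / dof)
        p = float(f_dist.sf(F, 2, dof))

    ci = _phase_ci(t, x, w, b0, b1, b3, rss, dof, period)
    return CosineFit(
        b0=b0, b1=b1, b3=float(b3), period=period, amplitude_p=p,
        ci_phase=ci, rss=rss, dof=max(dof, 0),
    )


def _phase_ci(t, x, w, b0, b1, b3, rss, dof, period, level=0.95):
    """Delta-method confidence interval for the peak time (hours, mod period)."""
    if dof <= 0 or b1 <= 0:
        return None
    arg = b3 + w * t
    J = np.column_stack([np.ones_like(t), np.cos(arg), -b1 * np.sin(arg)])
    sigma2 = rss / dof if rss > 0 else 0.0
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return None
    sd_b3 = math.sqrt(max(cov[2, 2], 0.0))
    sd_hours = sd_b3 * period / (2 * math.pi)
    z = norm.ppf(0.5 + level / 2)
    ph = ((-b3) % (2 * math.pi)) * period / (2 * math.pi)
    return ((ph - z * sd_hours) % period, (ph + z * sd_hours) % period)


def fit_cosine_genotype(
    series_ref,
    series_alt,
    batch_labels=None,
    period: float = DEFAULT_PERIOD,
) -> GenotypeCosineFit:
    """Joint fit of two genotypes with genotype-specific mean/amplitude/phase
    and additive batch offsets.

    ``series_ref`` and ``series_alt`` are (t, x) pairs for the reference and
    alternate genotype. ``batch_labels`` (optional) is a label per sample,
    concatenated in (ref, alt) order; the first label in sorted order is
    the reference batch and the others get dummy-coded offsets.

    The model x = m_g + A_g*cos(phi_g + wt) + batch offsets is linear in
    (m_g, A_g*cos(phi_g), -A_g*sin(phi_g)) for each genotype g, so the joint
    nonlinear least-squares optimum is computed exactly by linear least
    squares on that parameterisation. Per-genotype amplitude p-values are
    F-tests dropping that genotype's two harmonic columns.
    """
    t_ref, x_ref = (np.asarray(v, dtype=float) for v in series_ref)
    t_alt, x_alt = (np.asarray(v, dtype=float) for v in series_alt)
    for tv in (t_ref, t_alt):
        if len(np.unique(np.mod(tv, period))) < 4:
            raise ValueError("each genotype needs >= 4 distinct time points")
    t = np.concatenate([t_ref, t_alt])
    x = np.concatenate([x_ref, x_alt])
    gt = np.concatenate([np.zeros(len(t_ref)), np.ones(len(t_alt))])
    w = 2 * math.pi / period

    cols = [
        1.0 - gt,
        gt,
        (1.0 - gt) * np.cos(w * t),
        (1.0 - gt) * np.sin(w * t),
        gt * np.cos(w * t),
        gt * np.sin(w * t),
    ]
    names = ["m_ref", "m_alt", "a_ref", "c_ref", "a_alt", "c_alt"]

    batch_names: list = []
    if batch_labels is not None:
        labels = np.asarray(batch_labels)
        if len(labels) != len(t):
            raise ValueError("batch_labels length must match total sample count")
        levels = sorted(set(labels.tolist()))
        for lev in levels[1:]:
            col = (labels == lev).astype(float)
            X_try = np.column_stack(cols + [col])
            if np.linalg.matrix_rank(X_try) <= np.linalg.matrix_rank(
                np.column_stack(cols)
            ):
                warnings.warn(f"batch level {lev!r} collinear with design; dropped")
                continue
            cols.append(col)
            batch_names.append(lev)

    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    resid = x - X @ beta
    rss = float(resid @ resid)
    dof = len(x) - X.shape[1]

    m_ref, m_alt, a_ref, c_ref, a_alt, c_alt = beta[:6]
    b1_ref, b3_ref = _canonicalize(math.hypot(a_ref, c_ref), math.atan2(-c_ref, a_ref))
    b1_alt, b3_alt = _canonicalize(math.hypot(a_alt, c_alt), math.atan2(-c_alt, a_alt))

    amp_p = {}
    for label, drop in (("ref", (2, 3)), ("alt", (4, 5))):
        keep = [j for j in range(X.shape[1]) if j not in drop]
        Xr = X[:, keep]
        br, *_ = np.linalg.lstsq(Xr, x, rcond=None)
        rr = x - Xr @ br
        rss_r = float(rr @ rr)
        if dof <= 0:
            amp_p[label] = float("nan")
        elif rss <= 0:
            amp_p[label] = 0.0 if rss_r > 0 else 1.0
        elif rss_r <= rss:
            amp_p[label] = 1.0
        else:
            F = ((rss_r - rss) / 2.0) / (rss / dof)
            amp_p[label] = float(f_dist.sf(F, 2, dof))

    d_b3 = (b3_alt - b3_ref + math.pi) % (2 * math.pi) - math.pi
    return GenotypeCosineFit(
        b0=float(m_ref),
        b1=float(b1_ref),
        b3=float(b3_ref),
        b0_gt=float(m_alt - m_ref),
        b1_gt=float(b1_alt - b1_ref),
        b3_gt=float(d_b3),
        batch_coefs=np.asarray(beta[6:], dtype=float),
        period=period,
        amplitude_p=amp_p,
        rss=rss,
        dof=max(dof, 0),
    )


def cluster_profiles(matrix, k: int, linkage: str = "average") -> np.ndarray:
    """Hierarchical clustering of temporal profiles with 1 - Pearson distance.

    Returns integer labels in 1..k, deterministic for a fixed row order.
    Rows with zero variance (Pearson undefined) are assigned post hoc to the
    cluster whose mean profile is nearest in Euclidean distance.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D")
    n = m.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.ones(n, dtype=int)

    var = m.var(axis=1)
    ok = var > 0
    labels = np.zeros(n, dtype=int)
    idx_ok = np.flatnonzero(ok)
    if len(idx_ok) < k:
        raise ValueError("not enough rows with nonzero variance for k clusters")
    d = pdist(m[idx_ok], metric="correlation")
    Z = hierarchy.linkage(d, method=linkage)
    labels[idx_ok] = hierarchy.fcluster(Z, k, criterion="maxclust")

    if (~ok).any():
        centroids = np.vstack([m[labels == c].mean(axis=0) for c in range(1, k + 1)])
        for i in np.flatnonzero(~ok):
            labels[i] = 1 + int(
                np.argmin(np.linalg.norm(centroids - m[i], axis=1))
            )
    return labels


def shortest_phase_interval(
    phases, coverage: float = 0.5, period: float = DEFAULT_PERIOD
) -> PhaseInterval:
    """Minimal-length circular arc containing at least ``coverage`` of the phases.

    Ties are broken by the earliest arc start. Arcs are anchored at data
    points; with m = ceil(coverage * n) points required, the arc from the
    i-th sorted phase to the (i+m-1)-th (circularly) is examined for all i.
    """
    ph = np.sort(np.mod(np.asarray(phases, dtype=float), period))
    n = len(ph)
    if n == 0:
        raise ValueError("need at least one phase")
    m = max(1, math.ceil(coverage * n))
    ext = np.concatenate([ph, ph + period])
    best_i, best_len = 0, float("inf")
    for i in range(n):
        length = ext[i + m - 1] - ext[i]
        if length < best_len - 1e-12:
            best_len, best_i = length, i
    start = ph[best_i]
    end = (start + best_len) % period
    inside = np.mod(ph - start, period) <= best_len + 1e-12
    return PhaseInterval(
        start_zt=float(start),
        end_zt=float(end),
        length=float(best_len),
        coverage=float(inside.sum()) / n,
    )


def phase_density(
    phases,
    bandwidth: float = 1.0,
    period: float = DEFAULT_PERIOD,
    grid_size: int = 240,
    n_wraps: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Wrapped-Gaussian kernel density of phases on the circle.

    Returns (grid, density); the density integrates to 1 over one period.
    """
    ph = np.mod(np.asarray(phases, dtype=float), period)
    if len(ph) < 2:
        raise ValueError("need at least two phases")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(0.0, period, grid_size, endpoint=False)
    dens = np.zeros_like(grid)
    for kk in range(-n_wraps, n_wraps + 1):
        dens += norm.pdf(grid[:, None], ph[None, :] + kk * period, bandwidth).sum(axis=1)
    dens /= len(ph)
    return grid, dens


def circular_correlation(a, b, period: float = DEFAULT_PERIOD) -> float:
    """Fisher-Lee circular correlation between two sets of phases (hours)."""
    a = np.asarray(a, dtype=float) * 2 * math.pi / period
    b = np.asarray(b, dtype=float) * 2 * math.pi / period
    da = a - math.atan2(np.sin(a).sum(), np.cos(a).sum())
    db = b - math.atan2(np.sin(b).sum(), np.cos(b).sum())
    num = np.sum(np.sin(da) * np.sin(db))
    den = math.sqrt(np.sum(np.sin(da) ** 2) * np.sum(np.sin(db) ** 2))
    return float(num / den) if den > 0 else float("nan")


def fit_matrix(matrix, times, period: float = DEFAULT_PERIOD) -> list[CosineFit]:
    """Fit every row of a profiles x times matrix."""
    m = np.asarray(matrix, dtype=float)
    return [fit_cosine(times, row, period=period) for row in m]
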