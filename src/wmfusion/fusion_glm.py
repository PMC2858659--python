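"""Mass-univariate GLM engine for EEG-informed fMRI analysis.

Implements the first- and second-level model: task-phase boxcars and
per-trial band-power parametric modulators convolved with a canonical
double-gamma HRF at microtime resolution, a discrete-cosine high-pass
drift basis (128 s cutoff), AR(1) prewhitening with a single pooled
autocorrelation estimate, voxelwise t contrasts, random-effects group
maps, and Bonferroni / Benjamini-Hochberg / Monte-Carlo cluster-extent
multiple-comparison control.

Parametric modulators are mean-centred per band per load and not serially
orthogonalized against each other (order independence); serial
orthogonalization is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .spectral import BandPowerTable

__all__ = [
    "HRFParams",
    "DesignMatrix",
    "GLMFit",
    "StatMap",
    "ThresholdSpec",
    "canonical_hrf",
    "build_design_matrix",
    "fit_glm_ar1",
    "contrast_map",
    "group_onesample",
    "threshold_fdr",
    "threshold_fwe",
    "cluster_extent_mc",
    "label_clusters",
]


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF parameters (seconds)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    ratio: float = 6.0
    length_s: float = 32.0


def canonical_hrf(dt_s: float, params: HRFParams | None = None) -> np.ndarray:
    """Double-gamma HRF sampled on [0, length_s], scaled to peak 1.

    h(t) = Gamma(t; peak) - Gamma(t; undershoot)/ratio; with the defaults
    the kernel peaks near 5 s and undershoots around 15 s.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    p = params or HRFParams()
    t = np.arange(0.0, p.length_s + dt_s / 2, dt_s)
    peak = stats.gamma.pdf(t, p.peak_delay_s / p.peak_disp, scale=p.peak_disp)
    under = stats.gamma.pdf(t, p.undershoot_delay_s / p.undershoot_disp, scale=p.undershoot_disp)
    h = peak - under / p.ratio
    return h / h.max()


@dataclass
class DesignMatrix:
    """Scan x regressor matrix with labelled columns."""

    X: np.ndarray
    names: list[str]
    tr_s: float
    microtime_bins: int
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[1] != len(self.names):
            raise ValueError("one name per column required")

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]

    def contrast(self, weights: dict[str, float]) -> np.ndarray:
        """Contrast vector from {column name: weight}."""
        c = np.zeros(len(self.names))
        for name, w in weights.items():
            c[self.names.index(name)] = w
        return c


def _hires_regressor(events, values, n_hires, dt):
    """Boxcar at microtime resolution; each event weighted by its value."""
    reg = np.zeros(n_hires)
    for ev, v in zip(events, values):
        a = int(np.floor(ev.onset_s / dt))
        b = int(np.floor((ev.onset_s + ev.duration_s) / dt))
        reg[a : min(b, n_hires)] += v
    return reg


def dct_drift_basis(n_scans: int, tr_s: float, hp_cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift regressors with periods >= the cutoff.

    The number of columns is floor(2 * n_scans * tr / cutoff); the basis is
    orthonormal and excludes the constant term.
    """
    k_max = int(np.floor(2.0 * n_scans * tr_s / hp_cutoff_s))
    n = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * n + 1) * k / (2.0 * n_scans))
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def build_design_matrix(
    schedule,
    trial_power: BandPowerTable,
    tr_s: float,
    n_scans: int,
    hp_cutoff_s: float = 128.0,
    microtime_bins: int = 16,
    hrf_params: HRFParams | None = None,
    loads: tuple[str, ...] = ("ss2", "ss5"),
    phases: tuple[str, ...] = ("encoding", "retention", "retrieval"),
    drop_constant_modulators: bool = True,
    orthogonalize_modulators: bool = False,
) -> DesignMatrix:
    """Task-phase and band-modulator regressors plus drift and intercept.

    Per load condition: one HRF-convolved boxcar per task phase and one
    parametric modulator per band (the retention boxcar weighted by that
    trial's mean-centred RMS band power) — nine task/modulator columns per
    load with the default six bands.  Regressors are built at
    ``microtime_bins`` bins per TR and sampled at the middle bin of each
    scan.  A constant (all-zero after centring) modulator is dropped with a
    warning unless ``drop_constant_modulators`` is false.
    """
    dt = tr_s / microtime_bins
    n_hires = n_scans * microtime_bins
    hrf = canonical_hrf(dt, hrf_params)
    sample_idx = np.arange(n_scans) * microtime_bins + microtime_bins // 2

    def convolve_sample(hires):
        return np.convolve(hires, hrf)[:n_hires][sample_idx] * dt

    ret_events = schedule.retention_events()
    if trial_power.n_trials != len(ret_events):
        raise ValueError(
            f"trial_power has {trial_power.n_trials} rows but the schedule "
            f"has {len(ret_events)} retention events"
        )
    loads_arr = np.asarray([e.load for e in ret_events])
    cols, names = [], []
    dropped: list[str] = []
    for load in loads:
        for phase in phases:
            evs = schedule.events_of(phase, load)
            cols.append(convolve_sample(_hires_regressor(evs, np.ones(len(evs)), n_hires, dt)))
            names.append(f"{load}_{phase}")
        sel = loads_arr == load
        evs = [e for e in ret_events if e.load == load]
        mod_block = []
        for b in trial_power.bands:
            v = trial_power.values_for(b)[sel]
            v = v - v.mean()
            name = f"{load}_mod_{b}"
            if drop_constant_modulators and np.allclose(v, 0.0):
                warnings.warn(f"modulator {name} is constant; column dropped")
                dropped.append(name)
                continue
            mod_block.append((name, convolve_sample(_hires_regressor(evs, v, n_hires, dt))))
        if orthogonalize_modulators:
            prev: list[np.ndarray] = []
            ortho_block = []
            for name, col in mod_block:
                for q in prev:
                    col = col - q * (q @ col)
                nrm = np.linalg.norm(col)
                if nrm > 0:
                    prev.append(col / nrm)
                ortho_block.append((name, col))
            mod_block = ortho_block
        for name, col in mod_block:
            cols.append(col)
            names.append(name)
    drift = dct_drift_basis(n_scans, tr_s, hp_cutoff_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
    cols.append(np.ones(n_scans))
    names.append("intercept")
    return DesignMatrix(
        X=np.column_stack(cols),
        names=names,
        tr_s=tr_s,
        microtime_bins=microtime_bins,
        dropped=dropped,
    )


@dataclass
class GLMFit:
    """AR(1)-prewhitened least-squares fit of one subject's run."""

    betas: np.ndarray  # (n_regressors, n_voxels)
    sigma2: np.ndarray  # (n_voxels,)
    rho_hat: float
    df: int
    names: list[str]
    xtx_inv: np.ndarray
    grid_shape: tuple[int, int, int] | None = None
    voxel_mm: tuple[float, float, float] | None = None

    def beta_map(self, name: str) -> np.ndarray:
        b = self.betas[self.names.index(name)]
        if self.grid_shape is not None:
            return b.reshape(self.grid_shape)
        return b


def _whiten(A: np.ndarray, rho: float) -> np.ndarray:
    """Apply the AR(1) inverse square-root operator along axis 0."""
    W = np.empty_like(A, dtype=float)
    W[0] = np.sqrt(1.0 - rho**2) * A[0]
    W[1:] = A[1:] - rho * A[:-1]
    return W


def _diag_sums(A: np.ndarray) -> np.ndarray:
    """c[d] = sum of A's d-th super+sub diagonals (d=0: main diagonal)."""
    n = A.shape[0]
    c = np.empty(n)
    c[0] = np.trace(A)
    for d in range(1, n):
        c[d] = 2.0 * np.trace(A, offset=d)
    return c


def _debias_rho(rho_raw: float, X: np.ndarray) -> float:
    """Invert the attenuation of residual lag-1 autocorrelation.

    OLS residuals r = M y (M the residual-forming projection) understate the
    noise autocorrelation.  Under AR(1) noise with parameter ρ the expected
    pooled raw estimate is tr(M L M Γρ) / tr(M Γρ) with L the symmetrized
    lag-1 shift; both traces are polynomials in ρ with coefficients given by
    diagonal sums, so the moment equation is solved by bisection.
    """
    n = X.shape[0]
    M = np.eye(n) - X @ np.linalg.pinv(X)
    LM = 0.5 * (np.vstack([M[1:], np.zeros((1, n))]) + np.vstack([np.zeros((1, n)), M[:-1]]))
    A = M @ LM
    cA = _diag_sums(0.5 * (A + A.T))
    cM = _diag_sums(M)
    d = np.arange(n)

    def predicted(rho: float) -> float:
        powers = rho ** d
        return float((cA @ powers) / (cM @ powers))

    lo, hi = -0.98, 0.98
    if not predicted(lo) < rho_raw < predicted(hi):
        return float(np.clip(rho_raw, lo, hi))
    from scipy.optimize import brentq

    return float(brentq(lambda r: predicted(r) - rho_raw, lo, hi, xtol=1e-4))


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    from scipy.linalg import qr

    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise ValueError(f"design matrix is rank deficient; dependent columns: {bad}")


def fit_glm_ar1(
    Y,
    dm: DesignMatrix,
    mask: np.ndarray | None = None,
    debias_rho: bool = True,
    rho: float | None = None,
) -> GLMFit:
    """Fit the GLM with a single pooled AR(1) prewhitening step.

    OLS residuals (pooled over in-mask voxels) give one global lag-1
    autocorrelation estimate, corrected for the attenuation induced by the
    residual-forming projection; both data and design are prewhitened by
    the AR(1) inverse square-root operator and refit by least squares.
    Accepts a (n_scans, n_voxels) matrix or a BoldSeries.  Passing ``rho``
    skips estimation and whitens with the given value (0 reduces the fit
    to ordinary least squares exactly).
    """
    grid_shape = voxel_mm = None
    if hasattr(Y, "as_matrix"):  # BoldSeries
        grid_shape, voxel_mm = Y.grid_shape, Y.voxel_mm
        Y = Y.as_matrix()
    Y = np.ascontiguousarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = dm.X
    if Y.shape[0] <= X.shape[1]:
        raise ValueError("need more scans than regressors")
    _check_rank(X, dm.names)
    if rho is None:
        pinv = np.linalg.pinv(X)
        resid = Y - X @ (pinv @ Y)
        if mask is not None:
            resid_pool = resid[:, np.asarray(mask).ravel()]
        else:
            resid_pool = resid
        denom = np.sum(resid_pool**2)
        rho = float(np.sum(resid_pool[1:] * resid_pool[:-1]) / denom) if denom > 0 else 0.0
        if debias_rho and denom > 0:
            rho = _debias_rho(rho, X)
    rho = float(np.clip(rho, -0.99, 0.99))
    Xw = _whiten(X, rho)
    Yw = _whiten(Y, rho)
    pinv_w = np.linalg.pinv(Xw)
    betas = pinv_w @ Yw
    resid_w = Yw - Xw @ betas
    df = Y.shape[0] - np.linalg.matrix_rank(X)
    sigma2 = np.sum(resid_w**2, axis=0) / df
    return GLMFit(
        betas=betas,
        sigma2=sigma2,
        rho_hat=rho,
        df=df,
        names=list(dm.names),
        xtx_inv=np.linalg.inv(Xw.T @ Xw),
        grid_shape=grid_shape,
        voxel_mm=voxel_mm,
    )


@dataclass
class StatMap:
    """Voxelwise t-statistics with degrees of freedom."""

    t: np.ndarray
    df: int
    voxel_mm: tuple[float, float, float] | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.t) | np.isinf(self.t)
        self.mask = np.asarray(self.mask, dtype=bool)

    def p_values(self, tail: str = "greater") -> np.ndarray:
        """Per-voxel p-values (NaN outside the mask)."""
        p = np.full(self.t.shape, np.nan)
        t = self.t[self.mask]
        dist = stats.t(df=self.df)
        if tail == "greater":
            p[self.mask] = dist.sf(t)
        elif tail == "less":
            p[self.mask] = dist.cdf(t)
        elif tail == "two-sided":
            p[self.mask] = 2 * dist.sf(np.abs(t))
        else:
            raise ValueError("tail must be greater, less or two-sided")
        return p


def contrast_map(fit: GLMFit, c) -> StatMap:
    """t = c'β / sqrt(σ² c'(X'X)⁻¹c) per voxel on the whitened design."""
    if isinstance(c, dict):
        vec = np.zeros(len(fit.names))
        for name, w in c.items():
            vec[fit.names.index(name)] = w
        c = vec
    c = np.asarray(c, dtype=float)
    if c.shape != (len(fit.names),):
        raise ValueError("contrast length must equal the regressor count")
    if not np.any(c):
        raise ValueError("contrast vector must be nonzero")
    eff = c @ fit.betas
    var_c = float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / np.sqrt(fit.sigma2 * var_c)
    t = np.where(fit.sigma2 > 0, t, np.sign(eff) * np.inf)
    t = np.where((fit.sigma2 > 0) | (eff != 0), t, 0.0)
    if fit.grid_shape is not None:
        t = t.reshape(fit.grid_shape)
    return StatMap(t=t, df=fit.df, voxel_mm=fit.voxel_mm)


def group_onesample(maps, voxel_mm=None) -> StatMap:
    """Random-effects voxelwise one-sample t across subjects (df = n-1).

    ``maps`` is a sequence of per-subject voxel arrays on a common grid.
    Zero-variance voxels get sentinel values (signed infinite t, or 0 when
    the mean is also zero) instead of raising.
    """
    arrs = [np.asarray(m, dtype=float) for m in maps]
    if len(arrs) < 2:
        raise ValueError("need at least 2 subjects")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("subject maps must share one grid")
    stack = np.stack(arrs)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd > 0, t, np.sign(mean) * np.inf)
    t = np.where((sd > 0) | (mean != 0), t, 0.0)
    return StatMap(t=t, df=n - 1, voxel_mm=voxel_mm)


@dataclass
class ThresholdSpec:
    """How a statistical map is thresholded."""

    method: str = "cluster_mc"  # fwe_bonferroni | fdr_bh | cluster_mc
    voxel_p: float = 0.001
    cluster_alpha: float = 0.01
    k_voxels: int = 27
    fdr_q: float = 0.005

    def validate(self) -> list[str]:
        v = []
        for name in ("voxel_p", "cluster_alpha", "fdr_q"):
            x = getattr(self, name)
            if not 0.0 < x < 1.0:
                v.append(f"{name}: must be in (0, 1)")
        if self.k_voxels < 1:
            v.append("k_voxels: must be >= 1")
        if self.method not in ("fwe_bonferroni", "fdr_bh", "cluster_mc"):
            v.append("method: unknown")
        return v


def threshold_fdr(stat_map: StatMap, q: float, tail: str = "greater") -> np.ndarray:
    """Benjamini-Hochberg step-up over in-mask voxel p-values."""
    if not np.any(stat_map.mask):
        raise ValueError("empty mask")
    p = stat_map.p_values(tail)
    rej = np.zeros(stat_map.t.shape, dtype=bool)
    pv = p[stat_map.mask]
    rej_in, _, _, _ = multipletests(pv, alpha=q, method="fdr_bh")
    rej[stat_map.mask] = rej_in
    return rej


def threshold_fwe(stat_map: StatMap, alpha: float, tail: str = "greater") -> np.ndarray:
    """Bonferroni family-wise control: p <= alpha / n in-mask voxels."""
    n = int(np.sum(stat_map.mask))
    if n == 0:
        raise ValueError("empty mask")
    p = stat_map.p_values(tail)
    out = np.zeros(stat_map.t.shape, dtype=bool)
    out[stat_map.mask] = p[stat_map.mask] <= alpha / n
    return out


def _connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, order)


def label_clusters(mask: np.ndarray, t: np.ndarray | None = None, connectivity: int = 18) -> pd.DataFrame:
    """Connected components of a binary mask with sizes and peaks."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_connectivity_structure(connectivity))
    rows = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        size = len(idx)
        peak_t = np.nan
        peak = tuple(idx[0])
        if t is not None:
            vals = np.asarray(t)[tuple(idx.T)]
            j = int(np.argmax(np.abs(vals)))
            peak_t = float(vals[j])
            peak = tuple(idx[j])
        rows.append((lab, size, peak_t, peak))
    return pd.DataFrame(rows, columns=["label", "size", "peak_t", "peak_index"])


def cluster_labels_array(mask: np.ndarray, connectivity: int = 18):
    """Label array companion to :func:`label_clusters`."""
    labels, n = ndimage.label(
        np.asarray(mask, dtype=bool), structure=_connectivity_structure(connectivity)
    )
    return labels, n


def cluster_extent_mc(
    grid_shape: tuple[int, int, int],
    voxel_mm,
    fwhm_mm: float,
    voxel_p: float,
    cluster_alpha: float,
    n_iter: int = 1000,
    rng: np.random.Generator | None = None,
    connectivity: int = 18,
    full_output: bool = False,
):
    """Monte-Carlo cluster-extent threshold for smoothed Gaussian noise.

    Per iteration a Gaussian white-noise volume is smoothed to ``fwhm_mm``
    (generated with a stationarity pad that is cropped after smoothing),
    standardized to unit variance, and thresholded one-tailed at the
    ``voxel_p`` quantile; the maximum cluster extent is recorded.  Returns
    the smallest k for which the fraction of iterations whose maximum
    cluster reaches k is below ``cluster_alpha``.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if n_iter < 100:
        raise ValueError("need at least 100 iterations")
    if not 0.0 < voxel_p < 0.5:
        raise ValueError("voxel_p must be in (0, 0.5)")
    if not 0.0 < cluster_alpha < 1.0:
        raise ValueError("cluster_alpha must be in (0, 1)")
    rng = rng or np.random.default_rng()
    voxel_mm = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    sigma_vox = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / voxel_mm
    pad = int(np.ceil(4 * sigma_vox.max())) if fwhm_mm > 0 else 0
    shape_p = tuple(g + 2 * pad for g in grid_shape)
    z_thr = stats.norm.isf(voxel_p)
    structure = _connectivity_structure(connectivity)
    crop = tuple(slice(pad, pad + g) for g in grid_shape)
    max_sizes = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        vol = rng.standard_normal(shape_p)
        if fwhm_mm > 0:
            vol = ndimage.gaussian_filter(vol, sigma=sigma_vox)
        vol = vol[crop]
        vol = (vol - vol.mean()) / vol.std()
        labels, n = ndimage.label(vol > z_thr, structure=structure)
        if n:
            max_sizes[it] = np.bincount(labels.ravel())[1:].max()
    k = 1
    while np.mean(max_sizes >= k) >= cluster_alpha:
        k += 1
    if full_output:
        return k, max_sizes
    return k
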