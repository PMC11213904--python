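"""First-level GLM, quality metrics, ROI logic and preference maps.

The model is the standard blocked-design GLM: per-condition boxcars
convolved with a canonical double-gamma HRF, six motion parameters as
nuisance regressors plus an intercept, fitted voxel-wise to percent-
signal-change-normalised time courses with AR(1) prewhitening for serial
correlations.  Downstream utilities cover contrast t-maps, conjunction
ROIs (minimum-statistic over pairwise contrasts), temporal SNR, ROI
overlap removal, winner-take-all eccentricity preference maps with a
top1 - top2 preference strength, and the balanced two-way ROI ANOVA
(size x content) with eta-squared effect sizes.

Data containers are plain arrays (voxel x time), with NIfTI import and
export helpers; events come from BIDS-style tables
(:func:`fullfield.design.read_events`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BOLDSeries",
    "DesignMatrix",
    "BetaMap",
    "PreferenceMap",
    "ROIMask",
    "canonical_hrf",
    "build_design_matrix",
    "fit_glm",
    "contrast_tmap",
    "conjunction_mask",
    "preference_map",
    "compute_tsnr",
    "subtract_overlap",
    "roi_anova",
    "load_bold_nifti",
    "save_map_nifti",
]

HRF_KERNEL_ID = "double-gamma(peak=6,undershoot=16,ratio=6)"


@dataclass
class BOLDSeries:
    """Voxel x time BOLD matrix sampled at TR, with mask and motion."""

    data: np.ndarray
    tr_s: float = 2.0
    mask: np.ndarray | None = None
    motion: np.ndarray | None = None  # time x 6

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be voxel x time")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(~np.isfinite(self.data[self.mask])):
            raise ValueError("non-finite values inside the mask")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape[0] != self.data.shape[1]:
                raise ValueError("motion rows must equal time points")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_scans(self) -> int:
        return self.data.shape[1]


@dataclass
class DesignMatrix:
    """Time x regressor matrix with labels; condition columns first."""

    X: np.ndarray
    labels: list[str]
    condition_labels: list[str]
    kernel_id: str = HRF_KERNEL_ID

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)


@dataclass
class BetaMap:
    """Per-voxel condition coefficients in percent signal change."""

    betas: np.ndarray  # voxel x condition
    condition_labels: list[str]
    residual_var: np.ndarray
    ar1: np.ndarray
    dof: float
    design_X: np.ndarray = field(repr=False, default=None)
    mask: np.ndarray = None
    all_betas: np.ndarray = field(repr=False, default=None)
    kernel_id: str = HRF_KERNEL_ID


@dataclass
class PreferenceMap:
    """Winner-take-all preferred condition and top1 - top2 strength."""

    index: np.ndarray  # 0-based preferred condition per voxel
    strength: np.ndarray
    condition_labels: list[str]


@dataclass
class ROIMask:
    """Voxel membership plus the contrast/threshold that defined it."""

    mask: np.ndarray
    contrast: str = ""
    threshold_p: float | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# HRF and design matrix
# ---------------------------------------------------------------------------


def canonical_hrf(t: np.ndarray | float) -> np.ndarray | float:
    """Canonical double-gamma HRF evaluated at ``t`` seconds.

    Response gamma peaking near 5 s, undershoot gamma at 16 s with 1/6
    amplitude, h(0) = 0, normalised to unit peak.  The kernel id is
    recorded on design matrices and beta maps.
    """
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    h = np.zeros_like(tt)
    pos = tt >= 0
    h[pos] = stats.gamma.pdf(tt[pos], a=6, scale=1.0) - stats.gamma.pdf(
        tt[pos], a=16, scale=1.0
    ) / 6.0
    peak = stats.gamma.pdf(5.0, a=6) - stats.gamma.pdf(5.0, a=16) / 6.0
    h = h / peak
    return h if np.ndim(t) else float(h[0])


def _convolved_regressor(onsets, durations, tr_s, n_scans, oversample=16):
    """HRF-convolved boxcar sampled at TR, peak-normalised to 1."""
    dt = tr_s / oversample
    n_fine = n_scans * oversample
    box = np.zeros(n_fine)
    for on, du in zip(onsets, durations):
        i0 = int(round(on / dt))
        i1 = int(round((on + du) / dt))
        box[i0:min(i1, n_fine)] = 1.0
    t_h = np.arange(0, 32, dt)
    h = canonical_hrf(t_h)
    reg = np.convolve(box, h)[:n_fine] * dt
    reg = reg[oversample // 2::oversample][:n_scans]
    # normalise an isolated-block response peak to ~1 so betas read as PSC
    ref = np.convolve(
        np.ones(int(round(np.median(durations) / dt))), h
    ).max() * dt
    return reg / ref


def build_design_matrix(
    events: pd.DataFrame,
    tr_s: float,
    n_scans: int,
    motion: np.ndarray | None = None,
    rest_labels: tuple[str, ...] = ("rest", "fixation"),
) -> DesignMatrix:
    """One HRF-convolved column per condition + nuisance + intercept.

    Convolution runs on a 16x supersampled time grid.  Zero-variance
    nuisance columns are dropped with a warning; rank deficiency among
    the remaining columns raises, naming the collinear columns.
    """
    ev = events[~events["trial_type"].isin(rest_labels)]
    if len(ev) and ev["onset"].max() >= n_scans * tr_s:
        raise ValueError("events extend beyond the scan")
    conditions = sorted(ev["trial_type"].unique())
    cols, labels = [], []
    for cond in conditions:
        sel = ev[ev["trial_type"] == cond]
        cols.append(
            _convolved_regressor(
                sel["onset"].values, sel["duration"].values, tr_s, n_scans
            )
        )
        labels.append(cond)
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_scans:
            raise ValueError("motion parameter rows must equal n_scans")
        keep = motion.std(axis=0) > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance motion regressors"
            )
        for j in np.flatnonzero(keep):
            m = motion[:, j]
            cols.append((m - m.mean()) / m.std())
            labels.append(f"motion{j}")
    cols.append(np.ones(n_scans))
    labels.append("intercept")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by leave-one-in correlation
        corr = np.corrcoef(X[:, :-1].T)
        bad = [
            (labels[i], labels[j])
            for i in range(len(labels) - 1)
            for j in range(i + 1, len(labels) - 1)
            if abs(corr[i, j]) > 0.999
        ]
        raise np.linalg.LinAlgError(f"design matrix rank deficient; collinear: {bad}")
    return DesignMatrix(X=X, labels=labels, condition_labels=conditions)


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------


def fit_glm(bold: BOLDSeries, design: DesignMatrix) -> BetaMap:
    """Voxel-wise prewhitened least squares in percent-signal-change units.

    The fit runs in raw units; betas are then expressed as percent
    signal change of the voxel's estimated baseline (the intercept
    coefficient), which recovers planted PSC amplitudes exactly rather
    than carrying the small bias of dividing by the raw temporal mean.
    OLS residuals give a voxel-wise lag-1 autocorrelation estimate; one
    Cochrane-Orcutt iteration prewhitens data and design before the
    final fit.  Voxels with non-positive mean signal are masked out (and
    counted); betas for nuisance columns are retained on ``all_betas``.
    """
    X = design.X
    if bold.n_scans != X.shape[0]:
        raise ValueError("time dimensions of data and design differ")
    if "intercept" not in design.labels:
        raise ValueError("design matrix must include an intercept column")
    icol = design.labels.index("intercept")
    Y = bold.data.copy()
    mean = Y.mean(axis=1)
    bad = (mean <= 0) & bold.mask
    if bad.any():
        warnings.warn(f"masking {int(bad.sum())} voxels with non-positive mean")
    mask = bold.mask & (mean > 0)
    psc = Y[mask]

    pinv = np.linalg.pinv(X)
    beta_ols = psc @ pinv.T
    resid = psc - beta_ols @ X.T
    num = np.sum(resid[:, 1:] * resid[:, :-1], axis=1)
    den = np.sum(resid**2, axis=1)
    rho = np.where(den > 0, num / np.maximum(den, 1e-30), 0.0)
    rho = np.clip(rho, -0.95, 0.95)

    n, p = X.shape
    nv = psc.shape[0]
    betas = np.empty((nv, p))
    rvar = np.empty(nv)
    # prewhiten per distinct rho bin to keep it vectorised
    bins = np.round(rho, 2)
    for r in np.unique(bins):
        idx = bins == r
        Xw = X.copy()
        Yw = psc[idx].copy()
        Xw[1:] = X[1:] - r * X[:-1]
        Xw[0] = X[0] * np.sqrt(1 - r**2)
        Yw[:, 1:] = psc[idx][:, 1:] - r * psc[idx][:, :-1]
        Yw[:, 0] = psc[idx][:, 0] * np.sqrt(1 - r**2)
        pw = np.linalg.pinv(Xw)
        b = Yw @ pw.T
        res = Yw - b @ Xw.T
        betas[idx] = b
        rvar[idx] = np.sum(res**2, axis=1) / (n - p)

    # express betas in percent signal change of the estimated baseline
    baseline = betas[:, icol].copy()
    low = baseline <= 0
    if low.any():
        warnings.warn(f"{int(low.sum())} voxels with non-positive baseline masked")
        baseline[low] = np.nan
    scale = 100.0 / baseline
    betas = betas * scale[:, None]
    rvar = rvar * scale**2

    nc = design.n_conditions
    full_b = np.full((bold.n_voxels, p), np.nan)
    full_b[mask] = betas
    full_rvar = np.full(bold.n_voxels, np.nan)
    full_rvar[mask] = rvar
    full_rho = np.full(bold.n_voxels, np.nan)
    full_rho[mask] = rho
    return BetaMap(
        betas=full_b[:, :nc],
        condition_labels=design.condition_labels,
        residual_var=full_rvar,
        ar1=full_rho,
        dof=float(n - p),
        design_X=X,
        mask=mask,
        all_betas=full_b,
        kernel_id=design.kernel_id,
    )


def contrast_tmap(betamap: BetaMap, contrast: np.ndarray) -> np.ndarray:
    """Voxel-wise t statistics for a condition contrast vector.

    Variance uses the prewhitened design: c'(Xw'Xw)^-1 c with each
    voxel's AR(1) coefficient (binned to 0.01 as in the fit).
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(betamap.condition_labels),):
        raise ValueError("contrast length must equal number of conditions")
    if np.all(c == 0):
        raise ValueError("contrast vector is all zeros")
    X = betamap.design_X
    p = X.shape[1]
    cf = np.zeros(p)
    cf[: len(c)] = c
    eff = betamap.all_betas @ cf
    cvar = np.full(betamap.all_betas.shape[0], np.nan)
    bins = np.round(betamap.ar1, 2)
    for r in np.unique(bins[np.isfinite(bins)]):
        idx = bins == r
        Xw = X.copy()
        Xw[1:] = X[1:] - r * X[:-1]
        Xw[0] = X[0] * np.sqrt(1 - r**2)
        cvar[idx] = cf @ np.linalg.inv(Xw.T @ Xw) @ cf
    var = betamap.residual_var * cvar
    with np.errstate(invalid="ignore", divide="ignore"):
        t = eff / np.sqrt(var)
    return t


def _t_threshold(alpha: float, dof: float) -> float:
    return float(stats.t.isf(alpha, dof))


def conjunction_mask(
    betamap: BetaMap,
    target_condition: int | str,
    others: list[int | str] | None = None,
    alpha: float = 0.0001,
) -> ROIMask:
    """Minimum-statistic conjunction of pairwise (target - other) contrasts.

    A voxel survives only if every pairwise contrast between the target
    condition and each other condition exceeds the one-sided threshold
    at ``alpha`` — equivalently the minimum pairwise t beats it.
    """
    labels = betamap.condition_labels
    ti = labels.index(target_condition) if isinstance(target_condition, str) else target_condition
    if others is None:
        others = [i for i in range(len(labels)) if i != ti]
    others = [labels.index(o) if isinstance(o, str) else o for o in others]
    if len(others) == 0:
        raise ValueError("need at least one comparison condition")
    thr = _t_threshold(alpha, betamap.dof)
    tmin = None
    for oi in others:
        c = np.zeros(len(labels))
        c[ti], c[oi] = 1.0, -1.0
        t = contrast_tmap(betamap, c)
        tmin = t if tmin is None else np.minimum(tmin, t)
    mask = np.where(np.isfinite(tmin), tmin > thr, False)
    if not mask.any():
        warnings.warn("conjunction mask is empty")
    return ROIMask(
        mask=mask,
        contrast=f"conjunction[{labels[ti]} > each other]",
        threshold_p=alpha,
    )


# ---------------------------------------------------------------------------
# maps and metrics
# ---------------------------------------------------------------------------


def preference_map(
    condition_means: np.ndarray, condition_labels: list[str] | None = None
) -> PreferenceMap:
    """Winner-take-all preferred condition per voxel.

    ``condition_means`` is voxel x condition (for group maps, average
    betas across subjects first).  Strength is the margin between the
    highest and second-highest response; exact ties take the
    lowest-index condition and have strength 0.
    """
    m = np.asarray(condition_means, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need voxel x condition with >= 2 conditions")
    idx = np.argmax(m, axis=1)  # argmax takes the first (lowest) index on ties
    part = np.partition(m, -2, axis=1)
    strength = part[:, -1] - part[:, -2]
    labels = condition_labels or [f"cond{i}" for i in range(m.shape[1])]
    return PreferenceMap(index=idx, strength=strength, condition_labels=labels)


def compute_tsnr(bold: BOLDSeries) -> np.ndarray:
    """Temporal SNR: voxel mean over voxel standard deviation.

    Constant time series (zero SD) yield +/-inf and are counted in a
    warning; a single time point is an error.
    """
    if bold.n_scans < 2:
        raise ValueError("tSNR needs at least two time points")
    mean = bold.data.mean(axis=1)
    sd = bold.data.std(axis=1, ddof=1)
    zero = (sd == 0) & bold.mask
    if zero.any():
        warnings.warn(f"{int(zero.sum())} constant time series (infinite tSNR)")
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = mean / sd
    tsnr[~bold.mask] = np.nan
    return tsnr


def subtract_overlap(roi_a: ROIMask, roi_b: ROIMask) -> tuple[ROIMask, float]:
    """Remove from ``roi_a`` the voxels it shares with ``roi_b``.

    Returns the reduced ROI and the overlap fraction (shared voxels over
    ``roi_a`` size; 0 for an empty ``roi_a``).
    """
    if roi_a.mask.shape != roi_b.mask.shape:
        raise ValueError("ROI grids differ")
    inter = roi_a.mask & roi_b.mask
    n_a = roi_a.n_voxels
    frac = float(inter.sum() / n_a) if n_a else 0.0
    return ROIMask(
        mask=roi_a.mask & ~roi_b.mask,
        contrast=f"{roi_a.contrast} minus {roi_b.contrast}",
        threshold_p=roi_a.threshold_p,
    ), frac


def roi_anova(table: pd.DataFrame) -> pd.DataFrame:
    """Balanced two-way (size x content) ANOVA on per-subject ROI means.

    ``table`` needs columns ``subject``, ``size``, ``content``, ``beta``
    with exactly one observation per subject and cell.  Returns F, p and
    eta-squared (SS_effect / SS_total) for the two main effects and the
    interaction, treating subject-cell means as independent observations
    (each effect tested against the residual error).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    counts = table.groupby(["size", "content"])["beta"].count()
    if counts.nunique() != 1:
        raise ValueError("unbalanced cells: the design requires equal cell counts")
    if table["beta"].std(ddof=0) == 0:
        raise ValueError("zero-variance data: F undefined")
    model = ols("beta ~ C(size) * C(content)", data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    ss_total = aov["sum_sq"].sum()
    out = aov.rename(
        index={
            "C(size)": "size",
            "C(content)": "content",
            "C(size):C(content)": "size x content",
            "Residual": "residual",
        }
    )
    out["eta_sq"] = out["sum_sq"] / ss_total
    return out[["sum_sq", "df", "F", "PR(>F)", "eta_sq"]]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def load_bold_nifti(
    path, mask_path=None, tr_s: float | None = None, motion: np.ndarray | None = None
) -> tuple[BOLDSeries, tuple]:
    """Load a 4-D NIfTI into a voxel x time series (plus volume shape)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D BOLD NIfTI")
    vol_shape = data.shape[:3]
    series = data.reshape(-1, data.shape[3])
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        mask = mask.reshape(-1)
    else:
        mask = np.ones(series.shape[0], dtype=bool)
    if tr_s is None:
        tr_s = float(img.header.get_zooms()[3]) or 2.0
    return BOLDSeries(series, tr_s=tr_s, mask=mask, motion=motion), vol_shape


def save_map_nifti(values: np.ndarray, vol_shape: tuple, path, affine=None) -> None:
    """Write a per-voxel map back to a 3-D (or 4-D) NIfTI volume."""
    values = np.asarray(values, dtype=float)
    arr = values.reshape(vol_shape + values.shape[1:])
    nib.save(nib.Nifti1Image(arr, affine if affine is not None else np.eye(4)), str(path))
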