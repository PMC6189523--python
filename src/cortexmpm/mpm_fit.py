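"""Estimation of the four quantitative maps from weighted multi-echo data.

Pipeline order: joint log-linear R2* fit with one decay slope shared
across weightings -> echo averaging -> variable-flip-angle R1/amplitude
via the rational approximation of the Ernst equation -> semi-quantitative
MT saturation -> white-matter-calibrated effective proton density.

The averaged volumes are deliberately NOT corrected for R2* decay, which
is why the calibrated amplitude map is only an *effective* proton density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import FieldMaps, WeightedVolumeSet
from .protocols import WEIGHTINGS, AcquisitionProtocol

__all__ = [
    "EstaticsFit",
    "ParameterMaps",
    "fit_r2star_estatics",
    "average_echoes",
    "fit_r1_vfa",
    "compute_mtsat",
    "mtsat_b1_bias_correction",
    "calibrate_pdstar",
    "fit_all_maps",
    "WM_PDSTAR_PU",
]

#: published mean white-matter effective proton density (percent units)
WM_PDSTAR_PU = 69.0


@dataclass
class EstaticsFit:
    """Joint multi-weighting log-linear decay fit."""

    r2star: np.ndarray  # shared decay slope, s^-1
    ln_intercepts: dict  # weighting -> ln A_w volume
    rss: np.ndarray  # residual sum of squares (log domain)
    dof: int  # observations minus parameters per voxel
    valid: np.ndarray  # bool mask of fitted voxels


@dataclass
class ParameterMaps:
    """Voxelwise quantitative maps."""

    r1: np.ndarray  # s^-1
    r2star: np.ndarray  # s^-1
    mtsat: np.ndarray  # percent units (100 * delta)
    pdstar: np.ndarray  # percent units, WM mean calibrated to 69
    a: np.ndarray  # uncalibrated amplitude (intercept scale)
    valid: np.ndarray
    affine: np.ndarray | None = None


def fit_r2star_estatics(
    volumes: WeightedVolumeSet, mask: np.ndarray | None = None
) -> EstaticsFit:
    """Ordinary-least-squares joint fit of ln S_w(TE) = ln A_w - TE * R2*.

    One decay slope is shared across all weightings; each weighting keeps
    its own intercept.  Solved in closed form via the normal equations
    (identical design for every voxel).  Voxels containing any
    non-positive signal are masked out, not clamped; voxels with fewer
    than three usable echo points are likewise invalidated.
    """
    shape = volumes.shape
    if mask is None:
        mask = volumes.tissue_mask
    valid = mask.copy()
    present = [w for w in WEIGHTINGS if w in volumes.signals]
    if not present:
        raise ValueError("volume set contains no weightings")
    rows = []
    te_all = []
    for w in present:
        sig = volumes.signals[w]
        valid &= np.all(sig > 0, axis=-1)
        te_all.extend(volumes.protocol[w].te_s)
        rows.append(sig.reshape(-1, sig.shape[-1]))
    n_obs = len(te_all)
    n_par = 1 + len(present)
    if n_obs < max(2, n_par):
        raise ValueError(
            "ESTATICS needs at least as many echo observations as parameters "
            f"(got {n_obs} observations for {n_par} parameters)"
        )

    # design: y = X beta with beta = [R2*, lnA_PDw, lnA_T1w, lnA_MTw]
    x = np.zeros((n_obs, n_par))
    x[:, 0] = -np.asarray(te_all)
    pos = 0
    for j, w in enumerate(present):
        n = volumes.protocol[w].n_echoes
        x[pos : pos + n, 1 + j] = 1.0
        pos += n

    flat_valid = valid.ravel()
    y = np.concatenate([r[flat_valid].T for r in rows], axis=0)  # (n_obs, n_valid)
    y = np.log(y)
    beta = np.linalg.pinv(x) @ y
    resid = y - x @ beta
    rss_flat = np.sum(resid**2, axis=0)

    r2star = np.full(shape, np.nan)
    r2star.ravel()[flat_valid] = beta[0]
    ln_int = {}
    for j, w in enumerate(present):
        m = np.full(shape, np.nan)
        m.ravel()[flat_valid] = beta[1 + j]
        ln_int[w] = m
    rss = np.full(shape, np.nan)
    rss.ravel()[flat_valid] = rss_flat
    return EstaticsFit(
        r2star=r2star, ln_intercepts=ln_int, rss=rss, dof=n_obs - n_par, valid=valid
    )


def average_echoes(
    volumes: WeightedVolumeSet, n_echoes_used: int | dict | None = None
) -> dict:
    """Arithmetic mean over the first ``n_echoes_used`` echoes per weighting.

    Defaults to the cohort preset: the first six echoes for cohort 2,
    all echoes for cohort 1.
    """
    if n_echoes_used is None:
        n_echoes_used = volumes.protocol.n_echoes_for_averaging
    present = [w for w in WEIGHTINGS if w in volumes.signals]
    if isinstance(n_echoes_used, int):
        n_echoes_used = {w: n_echoes_used for w in present}
    out = {}
    for w in present:
        n = min(n_echoes_used[w], volumes.protocol[w].n_echoes)
        if n_echoes_used[w] < 1:
            raise ValueError("n_echoes_used must be >= 1")
        if n_echoes_used[w] > volumes.protocol[w].n_echoes:
            raise ValueError(
                f"{w}: requested {n_echoes_used[w]} echoes, only "
                f"{volumes.protocol[w].n_echoes} available"
            )
        out[w] = volumes.signals[w][..., :n].mean(axis=-1)
    return out


def fit_r1_vfa(
    s_pd: np.ndarray,
    s_t1: np.ndarray,
    protocol: AcquisitionProtocol,
    f_transmit: np.ndarray | float = 1.0,
    mask: np.ndarray | None = None,
):
    """Variable-flip-angle R1 and amplitude from the rational approximation.

        R1 = (S_t1 a_t1/TR_t1 - S_pd a_pd/TR_pd) / (2 (S_pd/a_pd - S_t1/a_t1))
        A  = S_pd S_t1 (TR_pd a_t1/a_pd - TR_t1 a_pd/a_t1)
             / (S_t1 TR_pd a_t1 - S_pd TR_t1 a_pd)

    with local true flip angles a_w = f_transmit * nominal.  TRs are
    converted to seconds so R1 is in s^-1.  Voxels whose denominator is
    numerically degenerate are invalidated rather than clamped.

    Returns ``(r1, a, valid)``.
    """
    a_pd_nom = protocol["PDw"].flip_angle_rad
    a_t1_nom = protocol["T1w"].flip_angle_rad
    if np.isclose(a_pd_nom, a_t1_nom):
        raise ValueError("PDw and T1w flip angles are equal: R1 is unidentifiable")
    if s_pd.shape != s_t1.shape:
        raise ValueError("averaged PDw and T1w volumes are not congruent")
    tr_pd = protocol["PDw"].tr_s
    tr_t1 = protocol["T1w"].tr_s
    ft = np.asarray(f_transmit, dtype=float)
    a_pd = ft * a_pd_nom
    a_t1 = ft * a_t1_nom

    with np.errstate(divide="ignore", invalid="ignore"):
        den_r1 = s_pd / a_pd - s_t1 / a_t1
        r1 = 0.5 * (s_t1 * a_t1 / tr_t1 - s_pd * a_pd / tr_pd) / den_r1
        den_a = s_t1 * tr_pd * a_t1 - s_pd * tr_t1 * a_pd
        a = s_pd * s_t1 * (tr_pd * a_t1 / a_pd - tr_t1 * a_pd / a_t1) / den_a

    scale = np.maximum(np.abs(s_pd / a_pd), np.abs(s_t1 / a_t1))
    valid = (
        (s_pd > 0)
        & (s_t1 > 0)
        & (np.abs(den_r1) > 1e-12 * np.maximum(scale, 1e-300))
        & np.isfinite(r1)
        & np.isfinite(a)
        & (r1 > 0)
    )
    if mask is not None:
        valid &= mask
    r1 = np.where(valid, r1, np.nan)
    a = np.where(valid, a, np.nan)
    return r1, a, valid


def compute_mtsat(
    s_mt: np.ndarray,
    a: np.ndarray,
    r1: np.ndarray,
    protocol: AcquisitionProtocol,
    f_transmit: np.ndarray | float = 1.0,
    mask: np.ndarray | None = None,
    b1_correction_c: float | None = None,
):
    """Semi-quantitative MT saturation map in percent units.

        delta = (A a_mt / S_mt - 1) R1 TR_mt - a_mt^2 / 2

    with a_mt = f_transmit * nominal MT-weighting excitation angle and
    TR_mt in seconds.  This is the percentage loss of longitudinal
    magnetisation per TR caused by the MT pre-pulse, explicitly accounting
    for the spatially varying R1 and flip angle.  An optional empirical
    residual-B1-bias correction ``delta * (1 - C) / (1 - C * f_T)`` is off
    by default.

    Returns ``(mtsat_pu, valid)``.
    """
    wp = protocol["MTw"]
    ft = np.asarray(f_transmit, dtype=float)
    a_mt = ft * wp.flip_angle_rad
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (a * a_mt / s_mt - 1.0) * r1 * wp.tr_s - a_mt**2 / 2.0
    valid = (s_mt > 0) & np.isfinite(delta)
    if mask is not None:
        valid &= mask
    if b1_correction_c is not None:
        delta = mtsat_b1_bias_correction(delta, ft, b1_correction_c)
    mtsat = np.where(valid, 100.0 * delta, np.nan)
    return mtsat, valid


def mtsat_b1_bias_correction(delta, f_transmit, c: float = 0.4):
    """Empirical residual transmit-bias correction of the MT saturation."""
    return delta * (1.0 - c) / (1.0 - c * np.asarray(f_transmit, dtype=float))


def calibrate_pdstar(
    a: np.ndarray, g_receive: np.ndarray | float, wm_mask: np.ndarray
) -> np.ndarray:
    """Receive-bias-corrected amplitude scaled so mean WM value is 69 pu.

    The known synthetic receive field is divided out (standing in for a
    UNICORT-style estimate), then the map is scaled subject-wise so that
    its mean over the white-matter mask equals exactly 69.  Idempotent.
    """
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if a.shape != wm_mask.shape:
        raise ValueError("amplitude map and WM mask are not congruent")
    if not wm_mask.any():
        raise ValueError("white-matter mask is empty")
    pd = a / g_receive
    wm_mean = np.nanmean(pd[wm_mask])
    if not np.isfinite(wm_mean) or wm_mean == 0:
        raise ValueError("white-matter mean amplitude is zero or undefined")
    return pd * (WM_PDSTAR_PU / wm_mean)


def fit_all_maps(
    volumes: WeightedVolumeSet,
    protocol: AcquisitionProtocol | None = None,
    fields: FieldMaps | None = None,
    wm_mask: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    n_echoes_used: int | dict | None = None,
    r1_spoiling_correction=None,
    mtsat_b1_correction_c: float | None = None,
) -> ParameterMaps:
    """Run the full map-estimation chain on one weighted volume set.

    ``r1_spoiling_correction`` is a pluggable post-hoc transform of the
    R1 map (identity when None); scanner-specific imperfect-spoiling
    coefficients are out of scope.
    """
    protocol = protocol or volumes.protocol
    fields = fields or volumes.fields
    if mask is None:
        mask = volumes.tissue_mask
    if wm_mask is None:
        wm_mask = volumes.wm_mask

    est = fit_r2star_estatics(volumes, mask=mask)
    avg = average_echoes(volumes, n_echoes_used=n_echoes_used)
    r1, a, valid_r1 = fit_r1_vfa(
        avg["PDw"], avg["T1w"], protocol, fields.f_transmit, mask=est.valid
    )
    if r1_spoiling_correction is not None:
        r1 = r1_spoiling_correction(r1)
    mtsat, valid_mt = compute_mtsat(
        avg["MTw"],
        a,
        r1,
        protocol,
        fields.f_transmit,
        mask=valid_r1,
        b1_correction_c=mtsat_b1_correction_c,
    )
    valid = est.valid & valid_r1 & valid_mt
    pdstar = calibrate_pdstar(a, fields.g_receive, wm_mask & valid)
    nanmask = ~valid
    out = ParameterMaps(
        r1=np.where(nanmask, np.nan, r1),
        r2star=np.where(nanmask, np.nan, est.r2star),
        mtsat=np.where(nanmask, np.nan, mtsat),
        pdstar=np.where(nanmask, np.nan, pdstar),
        a=np.where(nanmask, np.nan, a),
        valid=valid,
        affine=volumes.affine,
    )
    return out
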