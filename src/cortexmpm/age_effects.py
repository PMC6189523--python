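"""Vertex-wise age-effect mapping: covariate residualisation, jackknifed
Fisher-z Pearson correlation with age, per-hemisphere FDR thresholding,
overlap ROI extraction and ROI-level age slopes.

Statistics are always computed on unsmoothed maps; surface smoothing
(:func:`cortexmpm.surface_sample.surface_smooth`) is for display export
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

__all__ = [
    "JackknifeMap",
    "OverlapROI",
    "residualize",
    "jackknife_correlation",
    "fdr_threshold",
    "overlap_rois",
    "roi_age_slope",
]

_R_CLIP = 1.0 - 1e-12


@dataclass
class JackknifeMap:
    """Per-vertex jackknifed age-correlation statistics."""

    r_full: np.ndarray  # full-cohort Pearson r
    z_full: np.ndarray  # T: Fisher z of r_full
    z_partial_mean: np.ndarray  # Tm: mean of leave-one-out z estimates
    z_jack: np.ndarray  # N*T - (N-1)*Tm
    r_jack: np.ndarray  # tanh(z_jack)
    p: np.ndarray
    n: int
    valid: np.ndarray
    q: np.ndarray | None = None
    significant: np.ndarray | None = None
    hemi: np.ndarray | None = None


@dataclass
class OverlapROI:
    """Connected set of vertices significant for both parameters."""

    vertices: np.ndarray  # global vertex indices
    hemisphere: int

    @property
    def size(self) -> int:
        return self.vertices.size


def _as_covariate_matrix(covariates, n_subjects: int, n_vertices: int):
    """Split covariates into subject-constant columns (N,) and per-vertex
    columns (N, V)."""
    common, vertexwise, names_c, names_v = [], [], [], []
    for name, cov in covariates.items():
        arr = np.asarray(cov, dtype=float)
        if arr.ndim == 1 and arr.shape[0] == n_subjects:
            common.append(arr)
            names_c.append(name)
        elif arr.shape == (n_subjects, n_vertices):
            vertexwise.append(arr)
            names_v.append(name)
        else:
            raise ValueError(
                f"covariate {name!r} must have shape ({n_subjects},) or "
                f"({n_subjects}, {n_vertices}), got {arr.shape}"
            )
    return common, vertexwise, names_c, names_v


def _drop_degenerate(x: np.ndarray, names: list) -> np.ndarray:
    """Greedily drop columns that add no rank (constant or collinear)."""
    keep = [0]  # intercept
    dropped = []
    for j in range(1, x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            dropped.append(names[j - 1])
    if dropped:
        warnings.warn(
            f"dropping degenerate covariate columns: {dropped}", stacklevel=3
        )
    return x[:, keep]


def residualize(
    values: np.ndarray,
    covariates: dict,
    add_mean: bool = False,
) -> np.ndarray:
    """Regress covariates out of per-vertex, per-subject values.

    ``values`` is (n_subjects, V); each covariate is (n_subjects,) —
    e.g. a cohort indicator — or (n_subjects, V) — e.g. per-subject
    thickness or curvature.  Per vertex, an OLS fit on
    ``[1, covariates...]`` across subjects is removed; rank-deficient
    designs lose their degenerate columns with a warning.  Residuals are
    mean-zero unless ``add_mean``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("values must be (n_subjects, n_vertices)")
    n, nv = v.shape
    common, vertexwise, names_c, names_v = _as_covariate_matrix(covariates, n, nv)
    if n < len(common) + len(vertexwise) + 2:
        raise ValueError("need at least p + 2 subjects to residualise p covariates")

    mean = v.mean(axis=0)
    if not vertexwise:
        x = np.column_stack([np.ones(n)] + common)
        x = _drop_degenerate(x, names_c)
        beta, *_ = np.linalg.lstsq(x, v, rcond=None)
        resid = v - x @ beta
    else:
        resid = np.empty_like(v)
        base = [np.ones(n)] + common
        for j in range(nv):
            # lstsq yields projection residuals even for rank-deficient
            # designs, so vertex-wise degeneracy needs no column dropping
            x = np.column_stack(base + [c[:, j] for c in vertexwise])
            beta, *_ = np.linalg.lstsq(x, v[:, j], rcond=None)
            resid[:, j] = v[:, j] - x @ beta
    return resid + mean if add_mean else resid


def _pearson_from_sums(n, sx, sy, sxx, syy, sxy):
    cov = sxy - sx * sy / n
    vx = sxx - sx**2 / n
    vy = syy - sy**2 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    return r


def jackknife_correlation(
    values: np.ndarray,
    ages: np.ndarray,
    p_method: str = "t",
) -> JackknifeMap:
    """Leave-one-out jackknife of the Fisher-z age correlation.

    Per vertex: full-cohort Pearson r -> z = atanh(r) = T; for each
    subject i the correlation without i -> z -> mean Tm; the jackknife
    estimate is ``z_J = N*T - (N-1)*Tm`` and is reported back-transformed
    as ``r_J = tanh(z_J)``.

    p-values (two-sided) come from the t transform of r_J on N-2 degrees
    of freedom (``p_method="t"``, the default assumption) or from a
    normal approximation using the jackknife variance of z
    (``p_method="z"``).
    """
    v = np.asarray(values, dtype=float)
    x = np.asarray(ages, dtype=float)
    if v.ndim != 2 or x.shape[0] != v.shape[0]:
        raise ValueError("values must be (n_subjects, V) aligned with ages")
    n = x.shape[0]
    if n < 4:
        raise ValueError("jackknife needs at least 4 subjects")
    if np.ptp(x) == 0:
        raise ValueError("ages are constant; correlation undefined")

    valid = np.all(np.isfinite(v), axis=0)
    sx, sxx = x.sum(), (x**2).sum()
    sy = np.nansum(v, axis=0)
    syy = np.nansum(v**2, axis=0)
    sxy = np.nansum(v * x[:, None], axis=0)

    r_full = _pearson_from_sums(n, sx, sy, sxx, syy, sxy)
    # leave-one-out sufficient statistics, shape (N, V)
    m = n - 1
    sx_i = sx - x
    sxx_i = sxx - x**2
    loo_var_x = sxx_i - sx_i**2 / m
    bad_loo = loo_var_x <= 0
    if np.any(bad_loo):
        # a leave-one-out subsample with zero age variance invalidates all
        valid = valid & False
    sy_i = sy[None, :] - v
    syy_i = syy[None, :] - v**2
    sxy_i = sxy[None, :] - v * x[:, None]
    r_i = _pearson_from_sums(
        m, sx_i[:, None], sy_i, sxx_i[:, None], syy_i, sxy_i
    )

    z_full = np.arctanh(np.clip(r_full, -_R_CLIP, _R_CLIP))
    z_i = np.arctanh(np.clip(r_i, -_R_CLIP, _R_CLIP))
    z_mean = z_i.mean(axis=0)
    z_jack = n * z_full - (n - 1) * z_mean
    r_jack = np.tanh(z_jack)

    if p_method == "t":
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r_jack * np.sqrt((n - 2) / (1.0 - r_jack**2))
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    elif p_method == "z":
        var_jack = (n - 1) / n * np.sum((z_i - z_mean[None, :]) ** 2, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            zstat = z_jack / np.sqrt(var_jack)
        p = 2.0 * sps.norm.sf(np.abs(zstat))
    else:
        raise ValueError(f"unknown p_method {p_method!r}")

    valid &= np.isfinite(r_full) & np.isfinite(r_jack) & np.isfinite(p)
    nanfill = lambda a: np.where(valid, a, np.nan)
    return JackknifeMap(
        r_full=nanfill(r_full),
        z_full=nanfill(z_full),
        z_partial_mean=nanfill(z_mean),
        z_jack=nanfill(z_jack),
        r_jack=nanfill(r_jack),
        p=nanfill(p),
        n=n,
        valid=valid,
    )


def fdr_threshold(
    p_values: np.ndarray,
    q_level: float = 0.05,
    groups: np.ndarray | None = None,
):
    """Benjamini-Hochberg step-up control at level ``q_level``.

    Applied separately within each group (per hemisphere when ``groups``
    is the hemisphere tag array).  NaN p-values are never rejected and
    get NaN adjusted q.

    Returns ``(mask, q_adjusted)``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) & np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    mask = np.zeros(p.shape, dtype=bool)
    qadj = np.full(p.shape, np.nan)
    group_ids = np.zeros(p.shape, dtype=int) if groups is None else np.asarray(groups)
    for g in np.unique(group_ids):
        sel = (group_ids == g) & np.isfinite(p)
        if not sel.any():
            continue
        rej, q, _, _ = multipletests(p[sel], alpha=q_level, method="fdr_bh")
        mask[sel] = rej
        qadj[sel] = q
    return mask, qadj


def overlap_rois(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    adjacency: sp.spmatrix,
    hemi: np.ndarray | None = None,
    min_size: int = 1,
) -> list:
    """Connected components of the intersection of two significance masks.

    Masks must come from unsmoothed statistics.  Components are found
    under mesh adjacency, separately per hemisphere; components smaller
    than ``min_size`` (default 1: keep everything) are dropped.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks are not congruent")
    inter = a & b
    if not inter.any():
        return []
    hemi = np.zeros(a.shape, dtype=int) if hemi is None else np.asarray(hemi)
    adj = sp.csr_matrix(adjacency)
    rois = []
    for h in np.unique(hemi):
        idx = np.where(inter & (hemi == h))[0]
        if idx.size == 0:
            continue
        sub = adj[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            verts = idx[labels == c]
            if verts.size >= min_size:
                rois.append(OverlapROI(vertices=verts, hemisphere=int(h)))
    return rois


def roi_age_slope(
    roi: OverlapROI | np.ndarray,
    values: np.ndarray,
    ages: np.ndarray,
):
    """OLS age slope of the subject-wise ROI mean parameter value.

    ``values`` is (n_subjects, V) sampled at mid-cortical depth (0.5).
    Returns a dict with intercept, slope (native units per year), its
    standard error and 95% CI, and the slope as percent of the cohort
    mean per year.
    """
    verts = roi.vertices if isinstance(roi, OverlapROI) else np.asarray(roi)
    x = np.asarray(ages, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(x) == 0:
        raise ValueError("ages are constant; slope undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        roi_mean = np.nanmean(np.asarray(values, dtype=float)[:, verts], axis=1)
    ok = np.isfinite(roi_mean)
    res = sps.linregress(x[ok], roi_mean[ok])
    dof = ok.sum() - 2
    tcrit = sps.t.ppf(0.975, dof)
    grand = float(np.mean(roi_mean[ok]))
    return {
        "intercept": float(res.intercept),
        "slope_per_year": float(res.slope),
        "slope_se": float(res.stderr),
        "ci95": (
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        "slope_percent_per_year": float(100.0 * res.slope / grand) if grand else np.nan,
        "n_subjects": int(ok.sum()),
        "n_vertices": int(verts.size),
    }
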