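"""Hierarchical models of parameter value versus cortical depth.

Three-level structure: depth fractions nested within ROIs, ROIs nested
within subjects.  Fixed effects: scanner cohort, gender, ROI, centred
depth polynomial (order 1-3), optionally age and its interactions with
depth and ROI.  Random effects: subject intercept, ROI-within-subject
intercept, and a linear random depth slope within each subject x ROI.

All fits are maximum likelihood (not REML) so that likelihood-ratio
tests on fixed effects are valid.  Convergence criterion: statsmodels'
optimiser with a relative log-likelihood tolerance of 1e-8; a simpler
two-level fallback (random slope dropped) is recorded when the full
structure fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "AgeTerms",
    "MultiLevelFit",
    "LrtResult",
    "fit_multilevel_depth",
    "lrt_compare",
    "select_depth_order",
    "simulate_roi_profiles",
]


@dataclass(frozen=True)
class AgeTerms:
    """Which age fixed-effect terms to include."""

    age: bool = False
    age_depth: bool = False
    age_roi: bool = False
    age_depth_roi: bool = False

    def any(self) -> bool:
        return self.age or self.age_depth or self.age_roi or self.age_depth_roi


@dataclass
class MultiLevelFit:
    params: pd.Series  # fixed-effect estimates
    bse: pd.Series  # their standard errors
    variance_components: dict  # name -> variance estimate
    llf: float  # maximised ML log-likelihood
    n_obs: int
    k_fixed: int
    k_total: int  # fixed + variance parameters (incl. residual)
    converged: bool
    depth_order: int
    age_terms: AgeTerms
    fallback_used: bool = False
    formula: str = ""
    result: object = None  # underlying statsmodels result (not serialised)

    def fixed_term_names(self) -> frozenset:
        return frozenset(self.params.index)


@dataclass
class LrtResult:
    statistic: float  # 2 * (llf_large - llf_small)
    df: int
    p_value: float
    preferred: str  # "small" | "large"
    alpha: float = 0.05


_REQUIRED_COLS = {"subject", "roi", "depth", "value"}


def _formula(depth_order: int, age_terms: AgeTerms, df: pd.DataFrame) -> str:
    terms = []
    if df["cohort"].nunique() > 1:
        terms.append("C(cohort)")
    if df["gender"].nunique() > 1:
        terms.append("C(gender)")
    if df["roi"].nunique() > 1:
        terms.append("C(roi)")
    terms += [f"I(dc**{k})" if k > 1 else "dc" for k in range(1, depth_order + 1)]
    if age_terms.age or age_terms.any():
        terms.append("age_c")
    if age_terms.age_depth:
        terms.append("age_c:dc")
    if age_terms.age_roi and df["roi"].nunique() > 1:
        terms.append("age_c:C(roi)")
    if age_terms.age_depth_roi and df["roi"].nunique() > 1:
        terms.append("age_c:dc:C(roi)")
    # small cohorts can make the nuisance indicators collinear; drop the
    # degenerate ones rather than letting the solver hit a singular matrix
    import patsy

    kept: list[str] = []
    rank = 1  # intercept
    for t in terms:
        x = np.asarray(
            patsy.dmatrix(" + ".join(kept + [t]), df, return_type="matrix")
        )
        r = np.linalg.matrix_rank(x)
        if r <= rank:
            warnings.warn(f"dropping collinear fixed-effect term {t}", stacklevel=3)
            continue
        kept.append(t)
        rank = r
    return "value ~ " + " + ".join(kept)


def fit_multilevel_depth(
    profile_data: pd.DataFrame,
    depth_order: int = 1,
    age_terms: AgeTerms | None = None,
    allow_fallback: bool = True,
) -> MultiLevelFit:
    """ML fit of the three-level depth-profile model.

    ``profile_data`` is a tidy frame with columns subject, roi, depth,
    value and optionally cohort, gender, age (missing covariates are
    treated as constants).  Depth is centred before polynomial expansion.
    """
    if depth_order not in (1, 2, 3):
        raise ValueError("depth_order must be 1, 2 or 3")
    age_terms = age_terms or AgeTerms()
    df = profile_data.copy()
    missing = _REQUIRED_COLS - set(df.columns)
    if missing:
        raise ValueError(f"profile data lacks columns: {sorted(missing)}")
    for col, default in (("cohort", 1), ("gender", "F"), ("age", 0.0)):
        if col not in df.columns:
            df[col] = default
    if df["subject"].nunique() < 2 or df["roi"].nunique() < 1:
        raise ValueError("need >= 2 subjects")
    n_depth = df["depth"].nunique()
    if n_depth < depth_order + 2:
        raise ValueError(
            f"need at least {depth_order + 2} distinct depth points for order "
            f"{depth_order}"
        )
    df["dc"] = df["depth"] - df["depth"].mean()
    df["age_c"] = df["age"] - df["age"].mean()

    formula = _formula(depth_order, age_terms, df)
    multi_roi = df["roi"].nunique() > 1
    vc = {"roi": "0 + C(roi)", "roi_slope": "0 + C(roi):dc"} if multi_roi else None
    re_formula = "1" if multi_roi else "1 + dc"

    def _try(vcf, ref):
        model = smf.mixedlm(
            formula, df, groups=df["subject"], re_formula=ref, vc_formula=vcf
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                res = model.fit(reml=False, method="lbfgs", maxiter=500, disp=False)
            except np.linalg.LinAlgError:
                res = None
            if res is None or not res.converged:
                res = model.fit(reml=False, method="powell", maxiter=1000, disp=False)
        return res

    fallback_used = False
    res = _try(vc, re_formula)
    if not res.converged and allow_fallback and vc is not None:
        res = _try({"roi": "0 + C(roi)"}, "1")
        fallback_used = True

    k_fixed = len(res.fe_params)
    n_vc = len(res.vcomp) if res.vcomp is not None else 0
    n_re = res.cov_re.shape[0] * (res.cov_re.shape[0] + 1) // 2
    k_total = k_fixed + n_re + n_vc + 1  # + residual variance
    vcomp = {}
    if res.vcomp is not None and n_vc:
        names = res.model.exog_vc.names if hasattr(res.model, "exog_vc") else None
        for i, v in enumerate(np.atleast_1d(res.vcomp)):
            vcomp[names[i] if names else f"vc{i}"] = float(v)
    vcomp["subject"] = float(np.atleast_2d(res.cov_re)[0, 0]) if n_re else 0.0
    vcomp["residual"] = float(res.scale)

    return MultiLevelFit(
        params=res.fe_params,
        bse=res.bse_fe,
        variance_components=vcomp,
        llf=float(res.llf),
        n_obs=int(res.nobs),
        k_fixed=k_fixed,
        k_total=k_total,
        converged=bool(res.converged),
        depth_order=depth_order,
        age_terms=age_terms,
        fallback_used=fallback_used,
        formula=formula,
        result=res,
    )


def lrt_compare(fit_small: MultiLevelFit, fit_large: MultiLevelFit) -> LrtResult:
    """Likelihood-ratio test of nested ML fits on identical data."""
    if fit_small.n_obs != fit_large.n_obs:
        raise ValueError("fits are not on identical data (n_obs differs)")
    small_terms = fit_small.fixed_term_names()
    large_terms = fit_large.fixed_term_names()
    if not small_terms <= large_terms:
        raise ValueError(
            "models are not nested: the smaller model's fixed-effect terms must "
            "be a subset of the larger model's"
        )
    df = fit_large.k_total - fit_small.k_total
    stat = 2.0 * (fit_large.llf - fit_small.llf)
    if df < 0:
        raise ValueError("larger model must estimate at least as many parameters")
    if df == 0:
        # identical models: zero statistic up to optimizer tolerance
        p = 1.0
    else:
        p = float(sps.chi2.sf(max(stat, 0.0), df))
    return LrtResult(
        statistic=float(stat),
        df=df,
        p_value=p,
        preferred="large" if p < 0.05 else "small",
    )


def select_depth_order(
    profile_data: pd.DataFrame,
    max_order: int = 3,
    alpha: float = 0.05,
    age_terms: AgeTerms | None = None,
):
    """Forward LRT sequence (linear vs quadratic, quadratic vs cubic, ...).

    A higher order is accepted iff the LRT p-value is below ``alpha``;
    the sequence stops at the first non-significant step.

    Returns ``(chosen_order, chain)`` where ``chain`` is the list of
    ``LrtResult`` objects in test order.
    """
    current = fit_multilevel_depth(profile_data, depth_order=1, age_terms=age_terms)
    chain: list[LrtResult] = []
    order = 1
    for o in range(2, max_order + 1):
        candidate = fit_multilevel_depth(
            profile_data, depth_order=o, age_terms=age_terms
        )
        res = lrt_compare(current, candidate)
        res.alpha = alpha
        chain.append(res)
        if res.p_value < alpha:
            order = o
            current = candidate
        else:
            break
    return order, chain


def simulate_roi_profiles(
    n_subjects: int = 93,
    n_rois: int = 17,
    depths=None,
    depth_coefs=(0.8, -0.2, 0.0, 0.0),
    roi_offset_sd: float = 0.04,
    cohort_effect: float = 0.04,
    gender_effect: float = 0.0,
    age_slope: float = 0.0,
    age_depth_slope: float = 0.0,
    subject_sd: float = 0.02,
    roi_sd: float = 0.01,
    slope_sd: float = 0.015,
    resid_sd: float = 0.01,
    age_range=(18, 39),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ROI x depth mean profiles from the hierarchical model.

    ``depth_coefs`` are the fixed polynomial coefficients (intercept,
    linear, quadratic, cubic) in *centred* depth.  Used by the recovery
    and order-selection calibration tests; the generator is the model the
    estimator assumes, which is exactly the point.
    """
    rng = np.random.default_rng(seed)
    depths = np.asarray(
        depths if depths is not None else np.round(np.arange(0.1, 0.95, 0.1), 10)
    )
    dc = depths - depths.mean()
    ages = rng.integers(age_range[0], age_range[1] + 1, size=n_subjects)
    age_c = ages - ages.mean()
    genders = np.where(rng.random(n_subjects) < 0.5, "F", "M")
    cohorts = np.where(rng.random(n_subjects) < 0.5, 2, 1)
    roi_off = rng.normal(0.0, roi_offset_sd, size=n_rois)

    b0, b1, b2, b3 = depth_coefs
    fixed_depth = b0 + b1 * dc + b2 * dc**2 + b3 * dc**3  # (D,)

    rows = []
    for s in range(n_subjects):
        u_s = rng.normal(0.0, subject_sd)
        u_roi = rng.normal(0.0, roi_sd, size=n_rois)
        u_slope = rng.normal(0.0, slope_sd, size=n_rois)
        for r in range(n_rois):
            mu = (
                fixed_depth
                + roi_off[r]
                + cohort_effect * (cohorts[s] == 2)
                + gender_effect * (genders[s] == "M")
                + age_slope * age_c[s]
                + age_depth_slope * age_c[s] * dc
                + u_s
                + u_roi[r]
                + u_slope[r] * dc
            )
            y = mu + rng.normal(0.0, resid_sd, size=depths.size)
            rows.append(
                pd.DataFrame(
                    {
                        "subject": s,
                        "roi": r,
                        "depth": depths,
                        "value": y,
                        "age": ages[s],
                        "gender": genders[s],
                        "cohort": cohorts[s],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
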