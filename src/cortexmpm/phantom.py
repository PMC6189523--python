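"""Synthetic cortical phantom: ground-truth tissue parameters, subject
cohorts, field inhomogeneities and forward FLASH signal simulation.

Tissue label codes used in all volumes: 0 background, 1 white matter,
2 cortical grey matter, 3 CSF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import CSF_HEIGHT_MM, WM_DEPTH_MM, CorticalModel
from .protocols import WEIGHTINGS, AcquisitionProtocol

__all__ = [
    "BG",
    "WM",
    "GM",
    "CSF",
    "PARAMETERS",
    "EffectSpec",
    "SubjectSpec",
    "TissueGroundTruth",
    "FieldMaps",
    "WeightedVolumeSet",
    "make_cohort",
    "build_ground_truth",
    "make_field_maps",
    "flash_signal",
    "simulate_weighted_volumes",
]

BG, WM, GM, CSF = 0, 1, 2, 3

#: quantitative parameters handled by the pipeline (internal names)
PARAMETERS = ("r1", "mtsat", "r2star", "pdstar")

# physiological plausibility bounds enforced on generated ground truth
_BOUNDS = {"r1": (0.2, 2.5), "delta": (0.0, 0.1), "r2star": (0.5, 60.0), "a": (200.0, 1500.0)}


def _monotone_cubic(d: np.ndarray, steepness: float = 4.0) -> np.ndarray:
    """Monotone increasing cubic on [0,1], 0 at d=0 and 1 at d=1.

    Steeper near both ends than in the middle (derivative is
    ``1 + 3*steepness*(d-1/2)^2`` before normalisation), mimicking the
    sharper laminar transitions next to the white and pial boundaries.
    """
    g = d + steepness * (d - 0.5) ** 3 + steepness / 8.0
    return g / (1.0 + steepness / 4.0)


@dataclass
class EffectSpec:
    """Generative recipe for ground-truth tissue parameters.

    Depth profiles are monotone by construction: R1, MT-saturation (delta)
    and R2* decline from the white toward the pial surface while the
    amplitude A (proton-density proxy) rises.  ``delta`` is the
    dimensionless MT saturation fraction (percent units = 100 * delta).
    """

    # GM profile anchors: value at d=0 (white boundary) and drop/rise span
    r1_gm_white: float = 0.92  # s^-1
    r1_gm_span: float = 0.26
    delta_gm_white: float = 0.013  # fraction (1.3 pu)
    delta_gm_span: float = 0.006
    r2star_gm_white: float = 17.5  # s^-1
    r2star_gm_span: float = 4.0
    a_gm_white: float = 810.0  # arbitrary amplitude units
    a_gm_span: float = 50.0
    cubic_steepness: float = 4.0

    # non-GM compartments (constants)
    wm_values: dict = field(
        default_factory=lambda: {"r1": 1.10, "delta": 0.019, "r2star": 21.0, "a": 690.0}
    )
    csf_values: dict = field(
        default_factory=lambda: {"r1": 0.25, "delta": 0.0, "r2star": 1.0, "a": 1000.0}
    )

    # inter-regional structure: fraction of regions treated as "primary"
    # (heavier myelination: higher R1/delta/R2*, lower A)
    primary_region_fraction: float = 0.33
    primary_offsets: dict = field(
        default_factory=lambda: {"r1": 0.05, "delta": 0.0015, "r2star": 1.5, "a": -20.0}
    )

    # scanner-protocol offset applied to cohort-2 subjects
    cohort2_offsets: dict = field(
        default_factory=lambda: {"r1": 0.04, "delta": 0.0004, "r2star": 0.0, "a": 0.0}
    )

    # linear age effects, applied in `age_affected_regions` only
    r1_age_slope: float = 0.003  # s^-1 per year
    delta_age_slope: float = 7.5e-5  # fraction per year (0.0075 pu/yr)
    r2star_age_slope: float = 0.0
    age_affected_regions: tuple = (1, 4)
    age_ref_years: float = 28.5
    #: slope multiplier 1 - attenuation * d (age effect fades toward pial)
    age_depth_attenuation: float = 0.0

    # inter-subject variance components (SDs, in native parameter units)
    subject_sd: dict = field(
        default_factory=lambda: {"r1": 0.010, "delta": 1.5e-4, "r2star": 0.25, "a": 8.0}
    )
    region_sd: dict = field(
        default_factory=lambda: {"r1": 0.005, "delta": 1.0e-4, "r2star": 0.15, "a": 4.0}
    )
    depth_slope_sd: dict = field(
        default_factory=lambda: {"r1": 0.006, "delta": 1.0e-4, "r2star": 0.15, "a": 4.0}
    )

    # acquisition noise (signal units), per weighting; chosen so the
    # simulated raw-signal SNR in WM is ~100, giving map-level SNR of
    # order 50 after echo averaging (reported, not asserted, as matching
    # any particular scanner)
    noise_sd: dict = field(
        default_factory=lambda: {"PDw": 0.4, "T1w": 0.4, "MTw": 0.4}
    )

    def gm_profile(self, param: str, d: np.ndarray) -> np.ndarray:
        """Population-mean GM depth profile; d is the depth fraction."""
        d = np.asarray(d, dtype=float)
        g = _monotone_cubic(d, self.cubic_steepness)
        if param == "r1":
            return self.r1_gm_white - self.r1_gm_span * g
        if param == "delta":
            return self.delta_gm_white - self.delta_gm_span * g
        if param == "r2star":
            # quadratic decline, flattening toward the pial surface
            return self.r2star_gm_white - self.r2star_gm_span * d * (2.0 - d)
        if param == "a":
            return self.a_gm_white + self.a_gm_span * g
        raise KeyError(param)

    def primary_regions(self, n_regions: int) -> np.ndarray:
        n_primary = max(1, int(round(self.primary_region_fraction * n_regions)))
        return np.arange(n_primary)

    def region_offsets(self, param: str, n_regions: int) -> np.ndarray:
        off = np.zeros(n_regions)
        off[self.primary_regions(n_regions)] = self.primary_offsets[param]
        return off

    def age_slope(self, param: str) -> float:
        return {
            "r1": self.r1_age_slope,
            "delta": self.delta_age_slope,
            "r2star": self.r2star_age_slope,
            "a": 0.0,
        }[param]

    def validate(self, n_regions: int = 17, age_range: tuple = (18, 39)) -> None:
        """Reject specs that can push parameters out of physiological bounds."""
        for sd_set in (self.subject_sd, self.region_sd, self.depth_slope_sd):
            for k, v in sd_set.items():
                if v < 0:
                    raise ValueError(f"variance component {k!r} must be >= 0, got {v}")
        for w, v in self.noise_sd.items():
            if v < 0:
                raise ValueError(f"noise_sd[{w!r}] must be >= 0")
        d = np.linspace(0.0, 1.0, 21)
        for param in ("r1", "delta", "r2star", "a"):
            lo, hi = _BOUNDS[param]
            prof = self.gm_profile(param, d)
            # worst-case deterministic excursion over regions, cohorts, ages
            # plus a 4-sigma allowance for the random effects
            off = self.region_offsets(param, n_regions)
            age_dev = max(
                abs(age_range[0] - self.age_ref_years),
                abs(age_range[1] - self.age_ref_years),
            )
            spread = (
                np.abs(off).max()
                + abs(self.cohort2_offsets.get(param, 0.0))
                + abs(self.age_slope(param)) * age_dev
                + 4.0
                * (
                    self.subject_sd[param]
                    + self.region_sd[param]
                    + self.depth_slope_sd[param]
                )
            )
            if prof.min() - spread < lo or prof.max() + spread > hi:
                raise ValueError(
                    f"effect spec produces non-physical {param} values "
                    f"(range [{prof.min() - spread:.4g}, {prof.max() + spread:.4g}] "
                    f"outside [{lo}, {hi}])"
                )


@dataclass(frozen=True)
class SubjectSpec:
    """One synthetic participant."""

    subject_id: int
    age: int  # whole years
    gender: str  # "F" / "M"
    cohort_id: int  # 1 or 2
    seed: int  # per-subject RNG seed for random effects and noise


@dataclass
class TissueGroundTruth:
    """Voxelwise ground-truth tissue parameters for one subject."""

    r1: np.ndarray  # s^-1
    r2star: np.ndarray  # s^-1
    delta: np.ndarray  # MT saturation fraction (not pu)
    a: np.ndarray  # amplitude, arbitrary units
    label: np.ndarray  # int tissue codes (BG/WM/GM/CSF)
    region: np.ndarray  # int, -1 outside GM
    depth: np.ndarray  # float depth fraction, NaN outside GM
    affine: np.ndarray
    subject: SubjectSpec | None = None

    @property
    def wm_mask(self) -> np.ndarray:
        return self.label == WM

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.label != BG


@dataclass
class FieldMaps:
    """Relative transmit efficiency and receive sensitivity."""

    f_transmit: np.ndarray  # actual flip = f_transmit * nominal
    g_receive: np.ndarray
    affine: np.ndarray

    def validate(self) -> None:
        if np.any(self.f_transmit <= 0) or np.any(self.g_receive <= 0):
            raise ValueError("field maps must be strictly positive")


@dataclass
class WeightedVolumeSet:
    """Simulated (or loaded) multi-echo signals for the three weightings."""

    signals: dict  # weighting -> (X, Y, Z, n_echoes) float array
    protocol: AcquisitionProtocol
    fields: FieldMaps
    label: np.ndarray  # tissue label volume
    affine: np.ndarray
    noise_sd: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def wm_mask(self) -> np.ndarray:
        return self.label == WM

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.label != BG

    @property
    def shape(self) -> tuple:
        return self.label.shape


def make_cohort(
    n_subjects: int,
    age_range: tuple[int, int] = (18, 39),
    effect_spec: EffectSpec | None = None,
    seed: int = 0,
    cohort2_fraction: float = 0.5,
    n_regions: int = 17,
) -> list[SubjectSpec]:
    """Draw a synthetic cohort: ages uniform over ``age_range`` (whole
    years, inclusive), genders balanced at random, scanner cohort assigned
    by ``cohort2_fraction``.  Per-subject seeds are derived from ``seed``
    so the full generative recipe is reproducible."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    spec = effect_spec if effect_spec is not None else EffectSpec()
    spec.validate(n_regions=n_regions, age_range=age_range)
    rng = np.random.default_rng(seed)
    ages = rng.integers(age_range[0], age_range[1] + 1, size=n_subjects)
    genders = np.where(rng.random(n_subjects) < 0.5, "F", "M")
    cohorts = np.where(rng.random(n_subjects) < cohort2_fraction, 2, 1)
    seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    return [
        SubjectSpec(
            subject_id=i,
            age=int(ages[i]),
            gender=str(genders[i]),
            cohort_id=int(cohorts[i]),
            seed=int(seeds[i]),
        )
        for i in range(n_subjects)
    ]


def _voxel_grids(model: CorticalModel):
    nx, ny, nz = model.vol_shape
    vs = model.voxel_size
    origin = model.affine[:3, 3]
    x = origin[0] + np.arange(nx) * vs
    y = origin[1] + np.arange(ny) * vs
    z = origin[2] + np.arange(nz) * vs
    return x, y, z


def build_ground_truth(
    model: CorticalModel,
    subject: SubjectSpec,
    effect_spec: EffectSpec | None = None,
) -> TissueGroundTruth:
    """Rasterise one subject's ground-truth parameter fields onto the
    model's voxel grid.

    GM value = population depth profile + regional offset + cohort offset
    + age slope (in age-affected regions, optionally attenuated with
    depth) + subject random effects (intercept, region-within-subject
    intercept, region-wise linear depth slope).
    """
    spec = effect_spec if effect_spec is not None else EffectSpec()
    shape = model.vol_shape
    label = np.zeros(shape, dtype=np.int16)
    region = np.full(shape, -1, dtype=np.int32)
    depth = np.full(shape, np.nan)
    fields = {p: np.zeros(shape) for p in ("r1", "delta", "r2star", "a")}

    rng = np.random.default_rng(subject.seed)
    n_reg = model.n_regions
    subj_int = {p: rng.normal(0.0, spec.subject_sd[p]) for p in fields}
    reg_int = {p: rng.normal(0.0, spec.region_sd[p], size=n_reg) for p in fields}
    reg_slope = {p: rng.normal(0.0, spec.depth_slope_sd[p], size=n_reg) for p in fields}

    age_dev = subject.age - spec.age_ref_years
    affected = np.zeros(n_reg, dtype=bool)
    aff_idx = [r for r in spec.age_affected_regions if r < n_reg]
    affected[aff_idx] = True

    xg, yg, zg = _voxel_grids(model)
    Z = zg[None, :]  # broadcast over (columns, z)
    for h, geom in model.geometry.items():
        in_x = (xg >= geom.x0) & (xg <= geom.x0 + geom.extent_x)
        in_y = (yg >= geom.y0) & (yg <= geom.y0 + geom.extent_y)
        xi = np.where(in_x)[0]
        yi = np.where(in_y)[0]
        if xi.size == 0 or yi.size == 0:
            continue
        xcol = xg[xi]
        hcol = geom.height(xcol)[:, None]  # (nxcol, 1)
        tcol = geom.thickness(xcol)[:, None]
        rcol = geom.region_of(xcol, n_reg)  # (nxcol,)

        d = (Z - hcol) / tcol  # (nxcol, nz) depth fraction along the column
        lbl = np.zeros(d.shape, dtype=np.int16)
        lbl[(Z >= hcol - WM_DEPTH_MM) & (d < 0)] = WM
        gm = (d >= 0) & (d <= 1)
        lbl[gm] = GM
        csf = (d > 1) & (Z <= hcol + tcol + CSF_HEIGHT_MM)
        lbl[csf] = CSF

        vals = {}
        for p in fields:
            v = np.zeros(d.shape)
            v[lbl == WM] = spec.wm_values[p]
            v[lbl == CSF] = spec.csf_values[p]
            dg = np.where(gm, d, 0.5)
            prof = spec.gm_profile(p, dg)
            roff = spec.region_offsets(p, n_reg)[rcol][:, None]
            coh = spec.cohort2_offsets.get(p, 0.0) if subject.cohort_id == 2 else 0.0
            slope = spec.age_slope(p)
            atten = 1.0 - spec.age_depth_attenuation * dg
            age_term = slope * age_dev * affected[rcol][:, None] * atten
            re = (
                subj_int[p]
                + reg_int[p][rcol][:, None]
                + reg_slope[p][rcol][:, None] * (dg - 0.5)
            )
            v[gm] = (prof + roff + coh + age_term + re)[gm]
            vals[p] = v

        ix = np.ix_(xi, yi, np.arange(len(zg)))
        lbl3 = np.broadcast_to(lbl[:, None, :], (xi.size, yi.size, len(zg)))
        label[ix] = lbl3
        d3 = np.broadcast_to(d[:, None, :], lbl3.shape)
        depth[ix] = np.where(lbl3 == GM, d3, np.nan)
        reg3 = np.broadcast_to(rcol[:, None, None], lbl3.shape)
        region[ix] = np.where(lbl3 == GM, reg3, -1)
        for p in fields:
            v3 = np.broadcast_to(vals[p][:, None, :], lbl3.shape)
            fields[p][ix] = np.where(lbl3 != BG, v3, 0.0)

    tissue = label != BG
    for p, (lo, hi) in _BOUNDS.items():
        v = fields[p][tissue]
        if p != "delta" and (np.any(v < lo) or np.any(v > hi)):
            raise ValueError(f"generated {p} outside physiological bounds [{lo}, {hi}]")
        if p == "delta" and (np.any(v < 0.0) or np.any(v >= 0.1)):
            raise ValueError("generated MT saturation outside [0, 0.1)")

    return TissueGroundTruth(
        r1=fields["r1"],
        r2star=fields["r2star"],
        delta=fields["delta"],
        a=fields["a"],
        label=label,
        region=region,
        depth=depth,
        affine=model.affine.copy(),
        subject=subject,
    )


def make_field_maps(
    model: CorticalModel,
    seed: int = 0,
    transmit_amplitude: float = 0.08,
    receive_amplitude: float = 0.12,
) -> FieldMaps:
    """Smooth half-period sinusoidal B1+ and receive-sensitivity fields."""
    if not 0 <= transmit_amplitude < 1 or not 0 <= receive_amplitude < 1:
        raise ValueError("field amplitudes must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    xg, yg, zg = _voxel_grids(model)
    spans = [max(g[-1] - g[0], 1e-9) for g in (xg, yg, zg)]
    coords = [
        (g - g[0])[sl] / s
        for g, s, sl in zip(
            (xg, yg, zg),
            spans,
            (np.s_[:, None, None], np.s_[None, :, None], np.s_[None, None, :]),
        )
    ]

    def smooth_field(amp: float) -> np.ndarray:
        ph = rng.uniform(0, 2 * np.pi, size=3)
        f = (
            np.sin(np.pi * coords[0] + ph[0])
            * np.cos(np.pi * coords[1] + ph[1])
            * np.cos(0.5 * np.pi * coords[2] + ph[2])
        )
        return 1.0 + amp * f

    fm = FieldMaps(
        f_transmit=smooth_field(transmit_amplitude),
        g_receive=smooth_field(receive_amplitude),
        affine=model.affine.copy(),
    )
    fm.validate()
    return fm


def flash_signal(
    a,
    r1,
    r2star,
    delta,
    alpha_true_rad,
    tr_ms,
    te_ms,
    model: str = "ernst",
):
    """Steady-state spoiled multi-echo FLASH signal amplitude.

    ``ernst``: S = A sin(a) (1-E1) / (1 - cos(a)(1-delta) E1) * (1-delta)
    * exp(-TE R2*), with E1 = exp(-TR R1); the MT pre-pulse enters as a
    per-TR fractional saturation (1-delta) of longitudinal magnetisation.

    ``small_angle``: S = A a (TR R1) / (a^2/2 + TR R1 + delta)
    * exp(-TE R2*) — the rational approximation whose algebraic inverses
    are implemented in :mod:`cortexmpm.mpm_fit`.

    TR and TE are in milliseconds, R1 and R2* in s^-1; the conversion to
    consistent units happens here and nowhere else.
    """
    a = np.asarray(a, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    if np.any(a <= 0) or np.any(r1 <= 0):
        raise ValueError("amplitude A and R1 must be strictly positive")
    r2star = np.asarray(r2star, dtype=float)
    delta = np.asarray(delta, dtype=float)
    alpha = np.asarray(alpha_true_rad, dtype=float)
    tr_s = np.asarray(tr_ms, dtype=float) / 1000.0
    te_s = np.asarray(te_ms, dtype=float) / 1000.0
    decay = np.exp(-te_s * r2star)
    if model == "ernst":
        e1 = np.exp(-tr_s * r1)
        s = (
            a
            * np.sin(alpha)
            * (1.0 - e1)
            / (1.0 - np.cos(alpha) * (1.0 - delta) * e1)
            * (1.0 - delta)
        )
    elif model == "small_angle":
        tr_r1 = tr_s * r1
        s = a * alpha * tr_r1 / (alpha**2 / 2.0 + tr_r1 + delta)
    else:
        raise ValueError(f"unknown signal model {model!r}")
    return s * decay


def simulate_weighted_volumes(
    ground_truth: TissueGroundTruth,
    fields: FieldMaps,
    protocol: AcquisitionProtocol,
    noise_sd=None,
    seed: int = 0,
    noise_model: str = "gaussian",
    signal_model: str = "ernst",
) -> WeightedVolumeSet:
    """Forward-simulate the three weighted multi-echo volume sets.

    Voxel signal = g_receive * flash_signal(A, R1, R2*, delta_if_MT,
    f_transmit * alpha_nominal, TR, TE) plus Gaussian noise of standard
    deviation ``noise_sd`` (scalar or per-weighting dict); ``rician``
    applies the noise on quadrature channels and takes the magnitude.
    Noise is independent across echoes and weightings.
    """
    if ground_truth.label.shape != fields.f_transmit.shape:
        raise ValueError("ground truth and field maps are not congruent")
    if noise_model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    if noise_sd is None:
        noise_sd = {w: 0.0 for w in WEIGHTINGS}
    if np.isscalar(noise_sd):
        noise_sd = {w: float(noise_sd) for w in WEIGHTINGS}

    rng = np.random.default_rng(seed)
    tissue = ground_truth.tissue_mask
    a = ground_truth.a[tissue]
    r1 = ground_truth.r1[tissue]
    r2s = ground_truth.r2star[tissue]
    ft = fields.f_transmit[tissue]
    gr = fields.g_receive[tissue]

    signals = {}
    for w in WEIGHTINGS:
        wp = protocol[w]
        delta = ground_truth.delta[tissue] if wp.mt_pulse else 0.0
        alpha = ft * wp.flip_angle_rad
        vol = np.zeros(ground_truth.label.shape + (wp.n_echoes,))
        for i, te in enumerate(wp.te_ms):
            s = gr * flash_signal(
                a, r1, r2s, delta, alpha, wp.tr_ms, te, model=signal_model
            )
            plane = np.zeros(ground_truth.label.shape)
            plane[tissue] = s
            sd = noise_sd[w]
            if sd > 0:
                if noise_model == "gaussian":
                    plane = plane + rng.normal(0.0, sd, size=plane.shape)
                else:
                    plane = np.hypot(
                        plane + rng.normal(0.0, sd, size=plane.shape),
                        rng.normal(0.0, sd, size=plane.shape),
                    )
            vol[..., i] = plane
        signals[w] = vol

    return WeightedVolumeSet(
        signals=signals,
        protocol=protocol,
        fields=fields,
        label=ground_truth.label.copy(),
        affine=ground_truth.affine.copy(),
        noise_sd=dict(noise_sd),
        seed=seed,
    )
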