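"""Depth sampling of volumetric maps onto the cortical model, ROI x depth
aggregation, and iterative surface smoothing."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import map_coordinates

from .mesh import CorticalModel

__all__ = [
    "DEFAULT_FRACTIONS",
    "DepthSampledData",
    "sample_depth",
    "roi_depth_means",
    "surface_smooth",
]

#: default cortical depth fractions, 0.1 above the white boundary to 0.9
#: beneath the pial boundary in increments of 0.1
DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))


def _check_fractions(fractions) -> np.ndarray:
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValueError("fractions must be a non-empty 1-D sequence")
    if np.any(np.diff(f) <= 0):
        raise ValueError("depth fractions must be strictly increasing")
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("depth fractions must lie strictly inside (0, 1)")
    return f


@dataclass
class DepthSampledData:
    """Per-vertex samples: ``values[parameter]`` is (n_subjects, V, n_depths)."""

    values: dict
    fractions: tuple
    subjects: list  # SubjectSpec-like records, len n_subjects
    model: CorticalModel

    @property
    def parameters(self) -> tuple:
        return tuple(self.values)

    def at_depth(self, parameter: str, fraction: float) -> np.ndarray:
        """(n_subjects, V) slice at one depth fraction."""
        idx = int(np.argmin(np.abs(np.asarray(self.fractions) - fraction)))
        if not np.isclose(self.fractions[idx], fraction):
            raise KeyError(f"depth fraction {fraction} was not sampled")
        return self.values[parameter][:, :, idx]

    def to_table(self) -> pd.DataFrame:
        """Tidy long table: subject, hemi, vertex, depth, parameter, value."""
        frames = []
        hemi = self.model.hemi
        for p, arr in self.values.items():
            n_sub, n_v, n_d = arr.shape
            sub_idx = np.repeat(np.arange(n_sub), n_v * n_d)
            vert = np.tile(np.repeat(np.arange(n_v), n_d), n_sub)
            dep = np.tile(np.asarray(self.fractions), n_sub * n_v)
            frames.append(
                pd.DataFrame(
                    {
                        "subject": sub_idx,
                        "hemisphere": hemi[vert],
                        "vertex": vert,
                        "depth": dep,
                        "parameter": p,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def sample_depth(
    volume: np.ndarray,
    affine: np.ndarray,
    model: CorticalModel,
    fractions=DEFAULT_FRACTIONS,
    interpolation: str = "trilinear",
) -> np.ndarray:
    """Sample a volumetric map at depth fractions along each vertex's
    white->pial segment.

    The sample point for vertex v at fraction d is
    ``white_v + d * (pial_v - white_v)`` (straight-line correspondence).
    Trilinear interpolation by default (``nearest`` available for
    ablation); invalid (NaN) voxels propagate into the interpolant and
    out-of-bounds samples come back as NaN.

    Returns an array of shape (V, n_fractions).
    """
    f = _check_fractions(fractions)
    if volume.ndim != 3:
        raise ValueError("expected a 3-D parameter map")
    order = {"trilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")

    seg = model.pial - model.white  # (V, 3)
    pts = model.white[:, None, :] + f[None, :, None] * seg[:, None, :]  # (V, D, 3)
    inv = np.linalg.inv(affine)
    vox = pts.reshape(-1, 3) @ inv[:3, :3].T + inv[:3, 3]
    out = map_coordinates(
        volume, vox.T, order=order, mode="constant", cval=np.nan, prefilter=False
    )
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} of {out.size} depth samples are missing "
            "(outside the volume or touching invalid voxels)",
            stacklevel=2,
        )
    return out.reshape(model.n_vertices, f.size)


def roi_depth_means(
    data: DepthSampledData, model: CorticalModel | None = None
) -> pd.DataFrame:
    """ROI x depth mean profiles, hemisphere-averaged.

    Vertices are first averaged within (ROI, hemisphere), then the two
    hemisphere means are averaged with equal weight (not pooled across
    vertices).  An ROI that is empty (or all-missing) in one hemisphere
    contributes the other hemisphere only, with a warning.

    Returns a tidy frame: subject, roi, depth, parameter, value,
    n_vertices (total contributing vertices across hemispheres).
    """
    model = model or data.model
    fr = np.asarray(data.fractions)
    rows = []
    for p, arr in data.values.items():  # (n_sub, V, D)
        hemi_means = []
        hemi_counts = []
        for h in (0, 1):
            sel = model.hemi == h
            vals = arr[:, sel, :]
            roi = model.roi[sel]
            for r in range(model.n_regions):
                rsel = roi == r
                sub = vals[:, rsel, :]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    m = np.nanmean(sub, axis=1) if rsel.any() else np.full(
                        (arr.shape[0], fr.size), np.nan
                    )
                cnt = (
                    np.sum(np.isfinite(sub), axis=1)
                    if rsel.any()
                    else np.zeros((arr.shape[0], fr.size), dtype=int)
                )
                hemi_means.append(m)
                hemi_counts.append(cnt)
        hemi_means = np.asarray(hemi_means).reshape(
            2, model.n_regions, arr.shape[0], fr.size
        )
        hemi_counts = np.asarray(hemi_counts).reshape(
            2, model.n_regions, arr.shape[0], fr.size
        )
        present = np.isfinite(hemi_means)
        if np.any(present.sum(axis=0) == 1):
            warnings.warn(
                f"{p}: some ROI/depth cells are present in only one hemisphere; "
                "using the single available hemisphere mean",
                stacklevel=2,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_h = np.nanmean(hemi_means, axis=0)  # (R, n_sub, D)
        count_h = hemi_counts.sum(axis=0)
        for r in range(model.n_regions):
            for si in range(arr.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "subject": si,
                            "roi": r,
                            "depth": fr,
                            "parameter": p,
                            "value": mean_h[r, si],
                            "n_vertices": count_h[r, si],
                        }
                    )
                )
    out = pd.concat(rows, ignore_index=True)
    return out[out["n_vertices"] > 0].reset_index(drop=True)


def surface_smooth(
    values: np.ndarray, adjacency: sp.spmatrix, n_steps: int
) -> np.ndarray:
    """Iterative nearest-neighbour smoothing on the mesh.

    Each step replaces a vertex value by the mean of itself and its
    adjacent vertices; missing (NaN) values are excluded from every
    neighbourhood.  ``n_steps = 0`` is the identity.  Ten steps
    approximate the surface Gaussian kernel used for map display;
    smoothing is for export only and is never applied before statistics.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    v = np.asarray(values, dtype=float)
    squeeze = v.ndim == 1
    if squeeze:
        v = v[:, None]
    a = sp.csr_matrix(adjacency, dtype=float)
    a = a + sp.eye(a.shape[0], format="csr")
    for _ in range(n_steps):
        finite = np.isfinite(v)
        filled = np.where(finite, v, 0.0)
        num = a @ filled
        den = a @ finite.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(den > 0, num / den, np.nan)
    return v[:, 0] if squeeze else v
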