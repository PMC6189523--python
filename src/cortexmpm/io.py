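"""Readers/writers for volumes (NIfTI-1), the cortical model (plain-text
tables), tidy statistics tables, run configuration and the run manifest.

Volume dialects: a weighting is stored either as one 4-D NIfTI with echo
as the 4th dimension (``"4d"``) or as one 3-D file per echo
(``"per_echo"``); the sidecar JSON declares which, and both read back to
the same in-memory representation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .mesh import CorticalModel, HemisphereGeometry, _adjacency_from_triangles
from .mpm_fit import ParameterMaps
from .phantom import FieldMaps, WeightedVolumeSet
from .protocols import WEIGHTINGS, AcquisitionProtocol

__all__ = [
    "read_volume",
    "write_volume",
    "write_weighted_set",
    "read_weighted_set",
    "write_parameter_maps",
    "read_parameter_maps",
    "save_cortical_model",
    "load_cortical_model",
    "write_subject_table",
    "read_subject_table",
    "RunConfig",
    "load_config",
    "sha256_file",
    "write_manifest",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json") if path.suffix == ".nii" else Path(
        str(path) + ".json"
    )


def write_volume(
    path, data: np.ndarray, affine: np.ndarray, meta: dict | None = None
) -> Path:
    """Write one NIfTI-1 volume plus a JSON sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine))
    if meta and "description" in meta:
        img.header["descrip"] = meta["description"][:79].encode()
    nib.save(img, path)
    side = _sidecar(path)
    side.write_text(json.dumps(meta or {}, indent=1, sort_keys=True))
    return path


def read_volume(path):
    """Read a NIfTI-1 volume; returns ``(data, affine, meta)``.

    For the ``per_echo`` dialect the path is the sidecar-bearing stem of
    the first echo or the sidecar itself; echo files listed in the
    sidecar are stacked along a new trailing axis.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = path if path.suffix == ".json" else _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    try:
        if meta.get("dialect") == "per_echo":
            vols = []
            affine = None
            for fname in meta["echo_files"]:
                img = nib.load(path.parent / fname)
                vols.append(np.asanyarray(img.dataobj, dtype=np.float64))
                affine = img.affine
            data = np.stack(vols, axis=-1)
        else:
            img = nib.load(path)
            data = np.asanyarray(img.dataobj, dtype=np.float64)
            affine = img.affine
    except Exception as exc:  # noqa: BLE001 - surface a clean diagnostic
        raise OSError(f"failed to read NIfTI volume {path}: {exc}") from exc
    return data, affine, meta


def write_weighted_set(
    volumes: WeightedVolumeSet, outdir, dialect: str = "4d"
) -> Path:
    """Write the three weighted echo sets, field maps and tissue labels."""
    if dialect not in ("4d", "per_echo"):
        raise ValueError(f"unknown volume dialect {dialect!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for w in WEIGHTINGS:
        sig = volumes.signals[w]
        meta = {
            "weighting": w,
            "dialect": dialect,
            "echo_times_ms": list(volumes.protocol[w].te_ms),
            "units": "arbitrary signal",
        }
        if dialect == "4d":
            write_volume(outdir / f"{w}.nii", sig, volumes.affine, meta)
        else:
            files = []
            for i in range(sig.shape[-1]):
                f = f"{w}_echo-{i + 1:02d}.nii"
                img = nib.Nifti1Image(sig[..., i], volumes.affine)
                nib.save(img, outdir / f)
                files.append(f)
            meta["echo_files"] = files
            (outdir / f"{w}.json").write_text(
                json.dumps(meta, indent=1, sort_keys=True)
            )
    write_volume(
        outdir / "label.nii", volumes.label.astype(np.float64), volumes.affine,
        {"units": "tissue code 0=bg 1=wm 2=gm 3=csf"},
    )
    write_volume(
        outdir / "f_transmit.nii", volumes.fields.f_transmit, volumes.affine,
        {"units": "relative transmit efficiency"},
    )
    write_volume(
        outdir / "g_receive.nii", volumes.fields.g_receive, volumes.affine,
        {"units": "relative receive sensitivity"},
    )
    (outdir / "protocol.json").write_text(
        json.dumps(volumes.protocol.to_dict(), indent=1, sort_keys=True)
    )
    (outdir / "simulation.json").write_text(
        json.dumps(
            {"noise_sd": volumes.noise_sd, "seed": volumes.seed}, indent=1,
            sort_keys=True,
        )
    )
    return outdir


def read_weighted_set(indir) -> WeightedVolumeSet:
    indir = Path(indir)
    protocol = AcquisitionProtocol.from_dict(
        json.loads((indir / "protocol.json").read_text())
    )
    signals = {}
    affine = None
    for w in WEIGHTINGS:
        nii = indir / f"{w}.nii"
        src = nii if nii.exists() else indir / f"{w}.json"
        data, affine, _ = read_volume(src)
        signals[w] = data
    label, _, _ = read_volume(indir / "label.nii")
    ft, _, _ = read_volume(indir / "f_transmit.nii")
    gr, _, _ = read_volume(indir / "g_receive.nii")
    sim = json.loads((indir / "simulation.json").read_text())
    return WeightedVolumeSet(
        signals=signals,
        protocol=protocol,
        fields=FieldMaps(f_transmit=ft, g_receive=gr, affine=affine),
        label=label.astype(np.int16),
        affine=affine,
        noise_sd=sim.get("noise_sd", {}),
        seed=sim.get("seed"),
    )


_MAP_UNITS = {
    "r1": "s^-1",
    "r2star": "s^-1",
    "mtsat": "percent units",
    "pdstar": "percent units (WM mean = 69)",
    "a": "arbitrary amplitude",
}


def write_parameter_maps(maps: ParameterMaps, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = maps.affine if maps.affine is not None else np.eye(4)
    for name in ("r1", "r2star", "mtsat", "pdstar", "a"):
        write_volume(
            outdir / f"{name}.nii",
            getattr(maps, name),
            affine,
            {"units": _MAP_UNITS[name], "description": f"{name} [{_MAP_UNITS[name]}]"},
        )
    write_volume(
        outdir / "valid.nii", maps.valid.astype(np.float64), affine,
        {"units": "1 = fit valid"},
    )
    return outdir


def read_parameter_maps(indir) -> ParameterMaps:
    indir = Path(indir)
    vols = {}
    affine = None
    for name in ("r1", "r2star", "mtsat", "pdstar", "a", "valid"):
        data, affine, _ = read_volume(indir / f"{name}.nii")
        vols[name] = data
    return ParameterMaps(
        r1=vols["r1"],
        r2star=vols["r2star"],
        mtsat=vols["mtsat"],
        pdstar=vols["pdstar"],
        a=vols["a"],
        valid=vols["valid"] > 0.5,
        affine=affine,
    )


def save_cortical_model(model: CorticalModel, outdir) -> Path:
    """Plain-text model format: vertex table, triangle table, JSON meta."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vert = pd.DataFrame(
        {
            "white_x": model.white[:, 0],
            "white_y": model.white[:, 1],
            "white_z": model.white[:, 2],
            "pial_x": model.pial[:, 0],
            "pial_y": model.pial[:, 1],
            "pial_z": model.pial[:, 2],
            "normal_x": model.normals[:, 0],
            "normal_y": model.normals[:, 1],
            "normal_z": model.normals[:, 2],
            "thickness": model.thickness,
            "curvature": model.curvature,
            "roi": model.roi,
            "hemi": model.hemi,
        }
    )
    vert.to_csv(outdir / "vertices.tsv", sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(model.triangles, columns=["v0", "v1", "v2"]).to_csv(
        outdir / "triangles.tsv", sep="\t", index=False
    )
    meta = {
        "n_regions": model.n_regions,
        "voxel_size": model.voxel_size,
        "vol_shape": list(model.vol_shape),
        "affine": model.affine.tolist(),
        "grid_shape": list(model.grid_shape),
        "seed": model.seed,
        "geometry": {
            str(h): dataclasses.asdict(g) for h, g in model.geometry.items()
        },
    }
    (outdir / "model.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return outdir


def load_cortical_model(indir) -> CorticalModel:
    indir = Path(indir)
    vert = pd.read_csv(indir / "vertices.tsv", sep="\t")
    tri = pd.read_csv(indir / "triangles.tsv", sep="\t").to_numpy(dtype=np.int64)
    meta = json.loads((indir / "model.json").read_text())
    n_vertices = len(vert)
    return CorticalModel(
        white=vert[["white_x", "white_y", "white_z"]].to_numpy(),
        pial=vert[["pial_x", "pial_y", "pial_z"]].to_numpy(),
        normals=vert[["normal_x", "normal_y", "normal_z"]].to_numpy(),
        thickness=vert["thickness"].to_numpy(),
        curvature=vert["curvature"].to_numpy(),
        roi=vert["roi"].to_numpy(dtype=np.int64),
        hemi=vert["hemi"].to_numpy(dtype=np.int64),
        triangles=tri,
        adjacency=_adjacency_from_triangles(tri, n_vertices),
        n_regions=int(meta["n_regions"]),
        voxel_size=float(meta["voxel_size"]),
        vol_shape=tuple(meta["vol_shape"]),
        affine=np.asarray(meta["affine"]),
        geometry={
            int(h): HemisphereGeometry(**g) for h, g in meta["geometry"].items()
        },
        grid_shape=tuple(meta["grid_shape"]),
        seed=meta.get("seed"),
    )


def write_subject_table(subjects, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "gender": s.gender,
                "cohort_id": s.cohort_id,
                "seed": s.seed,
            }
            for s in subjects
        ]
    ).to_csv(path, sep="\t", index=False)
    return path


def read_subject_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclasses.dataclass
class RunConfig:
    """Configuration of a pipeline run (all stages seeded from ``seed``)."""

    out: str = "run"
    seed: int = 0
    stages: tuple = ("simulate", "fit-mpm", "sample", "depth-stats", "age-map")
    # phantom
    n_subjects: int = 4
    n_vertices_per_hemisphere: int = 400
    folding_amplitude: float = 2.0
    voxel_size: float = 1.0
    n_regions: int = 8
    age_range: tuple = (18, 39)
    cohort2_fraction: float = 0.5
    volume_dialect: str = "4d"
    noise_model: str = "gaussian"
    # sampling
    fractions: tuple = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))
    # stats
    max_depth_order: int = 3
    lrt_alpha: float = 0.05
    stats_parameter: str = "r1"
    # age mapping
    q_level: float = 0.05
    age_depth: float = 0.5
    smooth_steps: int = 10

    def validate(self) -> None:
        known = ("simulate", "fit-mpm", "sample", "depth-stats", "age-map")
        bad = [s for s in self.stages if s not in known]
        if bad:
            raise ValueError(f"unknown stages {bad}; known: {known}")
        order = [known.index(s) for s in self.stages]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ValueError("stages must be a contiguous ordered subset")
        if any(b - a != 1 for a, b in zip(order, order[1:])):
            raise ValueError("stages must be contiguous")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("stages", "fractions", "age_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return path
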