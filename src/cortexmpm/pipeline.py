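"""Pipeline orchestration: simulate -> fit-mpm -> sample -> depth-stats ->
age-map, with a run manifest tying every output to the config and seed.

Each stage reads its inputs from the run directory, so any contiguous
subset of stages can be re-run on precomputed outputs.  All randomness
derives from the config seed via a seed sequence; no global RNG state is
used anywhere.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .age_effects import (
    fdr_threshold,
    jackknife_correlation,
    overlap_rois,
    residualize,
    roi_age_slope,
)
from .depth_stats import select_depth_order
from .mesh import make_cortical_model
from .mpm_fit import fit_all_maps
from .phantom import (
    EffectSpec,
    build_ground_truth,
    make_cohort,
    make_field_maps,
    simulate_weighted_volumes,
)
from .protocols import get_protocol
from .surface_sample import DepthSampledData, roi_depth_means, sample_depth, surface_smooth

log = logging.getLogger("cortexmpm")

__all__ = ["run_pipeline", "stage_simulate", "stage_fit", "stage_sample",
           "stage_depth_stats", "stage_age_map"]

_MAP_PARAMS = ("r1", "mtsat", "r2star", "pdstar")


def _seeds(config: cio.RunConfig) -> dict:
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(4)
    return {
        "model": int(children[0].generate_state(1)[0] % (2**31)),
        "cohort": int(children[1].generate_state(1)[0] % (2**31)),
        "fields": int(children[2].generate_state(1)[0] % (2**31)),
        "noise": int(children[3].generate_state(1)[0] % (2**31)),
    }


def stage_simulate(config: cio.RunConfig, out: Path, effect_spec=None) -> list:
    seeds = _seeds(config)
    spec = effect_spec or EffectSpec()
    model = make_cortical_model(
        config.n_vertices_per_hemisphere,
        config.folding_amplitude,
        config.voxel_size,
        config.n_regions,
        seed=seeds["model"],
    )
    cio.save_cortical_model(model, out / "model")
    subjects = make_cohort(
        config.n_subjects,
        age_range=tuple(config.age_range),
        effect_spec=spec,
        seed=seeds["cohort"],
        cohort2_fraction=config.cohort2_fraction,
        n_regions=config.n_regions,
    )
    cio.write_subject_table(subjects, out / "subjects.tsv")
    fields = make_field_maps(model, seed=seeds["fields"])
    written = [out / "model", out / "subjects.tsv"]
    for s in subjects:
        gt = build_ground_truth(model, s, spec)
        vols = simulate_weighted_volumes(
            gt,
            fields,
            get_protocol(s.cohort_id),
            noise_sd=spec.noise_sd,
            seed=(seeds["noise"] + s.subject_id) % (2**31),
            noise_model=config.noise_model,
        )
        d = out / "volumes" / f"sub-{s.subject_id:03d}"
        cio.write_weighted_set(vols, d, dialect=config.volume_dialect)
        written.append(d)
        log.info("simulated subject %d (age %d, cohort %d)", s.subject_id, s.age,
                 s.cohort_id)
    return written


def stage_fit(config: cio.RunConfig, out: Path) -> list:
    written = []
    for d in sorted((out / "volumes").glob("sub-*")):
        vols = cio.read_weighted_set(d)
        maps = fit_all_maps(vols)
        md = out / "maps" / d.name
        cio.write_parameter_maps(maps, md)
        written.append(md)
        log.info("fitted maps for %s", d.name)
    return written


def stage_sample(config: cio.RunConfig, out: Path) -> list:
    model = cio.load_cortical_model(out / "model")
    subjects = cio.read_subject_table(out / "subjects.tsv")
    values = {p: [] for p in _MAP_PARAMS}
    for sid in subjects["subject_id"]:
        md = out / "maps" / f"sub-{sid:03d}"
        maps = cio.read_parameter_maps(md)
        for p in _MAP_PARAMS:
            values[p].append(
                sample_depth(getattr(maps, p), maps.affine, model, config.fractions)
            )
    data = DepthSampledData(
        values={p: np.asarray(v) for p, v in values.items()},
        fractions=tuple(config.fractions),
        subjects=subjects.to_dict("records"),
        model=model,
    )
    sd = out / "sampled"
    sd.mkdir(parents=True, exist_ok=True)
    written = []
    for p in _MAP_PARAMS:
        arr = data.values[p]
        np.savetxt(
            sd / f"{p}.tsv",  # plain text, one row per subject x vertex
            arr.reshape(arr.shape[0] * arr.shape[1], arr.shape[2]),
            delimiter="\t",
        )
        written.append(sd / f"{p}.tsv")
    written.append(sd / "sampled.json")
    (sd / "sampled.json").write_text(
        json.dumps(
            {
                "parameters": list(_MAP_PARAMS),
                "fractions": list(config.fractions),
                "n_subjects": int(len(subjects)),
                "n_vertices": int(model.n_vertices),
            },
            indent=1,
        )
    )
    profiles = roi_depth_means(data)
    profiles = profiles.merge(
        subjects.rename(columns={"subject_id": "subject"}), on="subject"
    )
    profiles.to_csv(out / "roi_profiles.tsv", sep="\t", index=False)
    written.append(out / "roi_profiles.tsv")
    return written


def _load_sampled(out: Path):
    model = cio.load_cortical_model(out / "model")
    meta = json.loads((out / "sampled" / "sampled.json").read_text())
    values = {}
    for p in meta["parameters"]:
        flat = np.loadtxt(out / "sampled" / f"{p}.tsv", delimiter="\t", ndmin=2)
        values[p] = flat.reshape(
            meta["n_subjects"], meta["n_vertices"], len(meta["fractions"])
        )
    subjects = cio.read_subject_table(out / "subjects.tsv")
    return (
        DepthSampledData(
            values=values,
            fractions=tuple(meta["fractions"]),
            subjects=subjects.to_dict("records"),
            model=model,
        ),
        subjects,
        model,
    )


def stage_depth_stats(config: cio.RunConfig, out: Path) -> list:
    profiles = pd.read_csv(out / "roi_profiles.tsv", sep="\t")
    results = {}
    for p in _MAP_PARAMS:
        sub = profiles[profiles["parameter"] == p].rename(
            columns={"cohort_id": "cohort"}
        )
        order, chain = select_depth_order(
            sub, max_order=config.max_depth_order, alpha=config.lrt_alpha
        )
        results[p] = {
            "chosen_order": order,
            "lrt_chain": [
                {
                    "statistic": c.statistic,
                    "df": c.df,
                    "p_value": c.p_value,
                    "preferred": c.preferred,
                }
                for c in chain
            ],
        }
        log.info("depth-stats %s: order %d", p, order)
    path = out / "depth_stats.json"
    path.write_text(json.dumps(results, indent=1, sort_keys=True))
    return [path]


def stage_age_map(config: cio.RunConfig, out: Path) -> list:
    data, subjects, model = _load_sampled(out)
    ages = subjects["age"].to_numpy(dtype=float)
    cohort = (subjects["cohort_id"].to_numpy() == 2).astype(float)
    covariates = {
        "curvature": np.tile(model.curvature, (len(subjects), 1)),
        "thickness": np.tile(model.thickness, (len(subjects), 1)),
        "cohort": cohort,
    }
    written = []
    masks = {}
    stats_frames = []
    ad = out / "age"
    ad.mkdir(parents=True, exist_ok=True)
    for p in _MAP_PARAMS:
        vals = data.at_depth(p, config.age_depth)
        resid = residualize(vals, covariates)
        jk = jackknife_correlation(resid, ages)
        mask, q = fdr_threshold(jk.p, q_level=config.q_level, groups=model.hemi)
        jk.q, jk.significant, jk.hemi = q, mask, model.hemi
        masks[p] = mask
        smoothed = surface_smooth(jk.r_jack, model.adjacency, config.smooth_steps)
        stats_frames.append(
            pd.DataFrame(
                {
                    "parameter": p,
                    "vertex": np.arange(model.n_vertices),
                    "hemisphere": model.hemi,
                    "r_full": jk.r_full,
                    "z_full": jk.z_full,
                    "z_partial_mean": jk.z_partial_mean,
                    "z_jackknife": jk.z_jack,
                    "r_jackknife": jk.r_jack,
                    "p": jk.p,
                    "q": q,
                    "significant": mask.astype(int),
                    "r_jackknife_smoothed_display": smoothed,
                }
            )
        )
    stats = pd.concat(stats_frames, ignore_index=True)
    stats.to_csv(ad / "vertex_stats.tsv", sep="\t", index=False)
    written.append(ad / "vertex_stats.tsv")

    rois = overlap_rois(masks["r1"], masks["mtsat"], model.adjacency, hemi=model.hemi)
    roi_rows = []
    for i, roi in enumerate(rois):
        for p in ("r1", "mtsat"):
            fit = roi_age_slope(roi, data.at_depth(p, config.age_depth), ages)
            roi_rows.append(
                {
                    "roi_id": i,
                    "hemisphere": roi.hemisphere,
                    "parameter": p,
                    "n_vertices": roi.size,
                    **{
                        k: v
                        for k, v in fit.items()
                        if k not in ("ci95", "n_vertices")
                    },
                    "ci95_lo": fit["ci95"][0],
                    "ci95_hi": fit["ci95"][1],
                }
            )
    pd.DataFrame(roi_rows).to_csv(ad / "overlap_roi_slopes.tsv", sep="\t", index=False)
    written.append(ad / "overlap_roi_slopes.tsv")
    return written


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit-mpm": stage_fit,
    "sample": stage_sample,
    "depth-stats": stage_depth_stats,
    "age-map": stage_age_map,
}


def run_pipeline(config: cio.RunConfig, effect_spec=None) -> dict:
    """Execute the configured stages and write the run manifest.

    Returns the manifest dict (also written to ``<out>/manifest.json``).
    """
    config.validate()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "version": _package_version(),
        "stages": {},
        "warnings": [],
    }
    import warnings as _warnings

    for stage in config.stages:
        func = _STAGE_FUNCS[stage]
        log.info("running stage %s", stage)
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            try:
                if stage == "simulate":
                    outputs = func(config, out, effect_spec)
                else:
                    outputs = func(config, out)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["warnings"].extend(f"{stage}: {w.message}" for w in caught)
        checks = {}
        for o in outputs:
            o = Path(o)
            files = sorted(p for p in ([o] if o.is_file() else o.rglob("*")) if p.is_file())
            for f in files:
                checks[str(f.relative_to(out))] = cio.sha256_file(f)
        manifest["stages"][stage] = {"outputs": checks}
    cio.write_manifest(manifest, out / "manifest.json")
    return manifest


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("cortexmpm")
    except Exception:
        return "unknown"
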