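"""Readers and writers: NIfTI-1 volumes, SPM-dialect motion text files,
covariate TSVs, and the YAML ground-truth sidecar of the simulator."""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .stats import SubjectRecord
from .synthetic import (
    Cohort,
    CohortSpec,
    CommunitySpec,
    EffectSpec,
    generate_subject,
    ground_truth,
    iter_subject_plan,
    make_masks,
)
from .types import (
    BoldSeries,
    InputError,
    MotionTrace,
    VolumeGeometry,
    VolumeMap,
)

COVARIATE_COLUMNS = ["subject_id", "group", "age", "gender", "joa", "duration_months"]


def read_volume(path, expect_geometry: VolumeGeometry | None = None, ndim: int | None = None):
    """Load a NIfTI-1 volume; returns (data, VolumeGeometry).

    ``ndim`` (3 or 4) enforces dimensionality; ``expect_geometry`` enforces a
    bit-exact grid match against a reference.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # malformed file
        raise InputError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if ndim is not None and data.ndim != ndim:
        raise InputError(f"{path} is {data.ndim}D, expected {ndim}D")
    geom = VolumeGeometry(data.shape[:3], img.affine)
    if expect_geometry is not None:
        expect_geometry.require_match(geom, str(path))
    return np.asarray(data, dtype=np.float64), geom


def write_volume(data, affine, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int32)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine, dtype=float)), str(path))
    return path


def write_map(vmap: VolumeMap, path):
    return write_volume(vmap.data, vmap.affine, path)


def read_motion(path) -> MotionTrace:
    """SPM rp-text dialect: 6 whitespace-separated columns, 3 translations in
    mm then 3 rotations in radians."""
    try:
        arr = np.loadtxt(path, ndmin=2)
    except Exception as exc:
        raise InputError(f"cannot read motion file {path}: {exc}") from exc
    if arr.shape[1] != 6:
        raise InputError(f"motion file {path} has {arr.shape[1]} columns, expected 6")
    return MotionTrace(arr)


def write_motion(motion: MotionTrace, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, motion.params, fmt="%.10e")
    return path


def read_covariates(path) -> list:
    """Validated Table-1-shaped TSV -> SubjectRecord list.

    Patients must carry JOA and illness duration; a control carrying either
    raises a validation warning (the value is ignored downstream).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such covariate table: {path}")
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"covariate table {path} is empty") from exc
    missing = [c for c in COVARIATE_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"covariate table {path} lacks columns: {missing}")
    if len(table) == 0:
        raise InputError(f"covariate table {path} has no rows")
    records = []
    for i, row in table.iterrows():
        try:
            age = float(row["age"])
        except (TypeError, ValueError) as exc:
            raise InputError(f"{path} row {i}: non-numeric age {row['age']!r}") from exc
        group = str(row["group"])
        joa = row["joa"]
        dur = row["duration_months"]
        if group == "patient":
            if pd.isna(joa) or pd.isna(dur):
                raise InputError(f"{path} row {i}: patient lacks JOA or duration")
        else:
            if not (pd.isna(joa) and pd.isna(dur)):
                warnings.warn(
                    f"{path} row {i}: control carries clinical scores; ignored",
                    UserWarning,
                    stacklevel=2,
                )
                joa, dur = np.nan, np.nan
        try:
            records.append(
                SubjectRecord(
                    id=str(row["subject_id"]),
                    group=group,
                    age=age,
                    gender=str(row["gender"]),
                    joa=None if pd.isna(joa) else float(joa),
                    duration_months=None if pd.isna(dur) else float(dur),
                )
            )
        except InputError as exc:
            raise InputError(f"{path} row {i}: {exc}") from exc
    return records


def write_covariates(table: pd.DataFrame, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def _spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "n_per_group": spec.n_per_group,
        "grid_shape": list(spec.grid_shape),
        "voxel_size_mm": spec.voxel_size_mm,
        "n_volumes": spec.n_volumes,
        "tr_s": spec.tr_s,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "max_spikes": spec.max_spikes,
        "communities": [
            {"member_voxels": c.member_voxels.tolist(), "loading_c": c.loading_c}
            for c in spec.communities
        ],
        "effects": [
            {
                "region": e.region.tolist(),
                "modality": e.modality,
                "direction": e.direction,
                "magnitude": e.magnitude,
                "loading": e.loading,
            }
            for e in spec.effects
        ],
    }


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    comms = tuple(
        CommunitySpec(np.asarray(c["member_voxels"]), float(c["loading_c"]))
        for c in d.pop("communities", [])
    )
    effs = tuple(
        EffectSpec(
            np.asarray(e["region"]),
            e["modality"],
            e["direction"],
            float(e["magnitude"]),
            float(e.get("loading", 0.7)),
        )
        for e in d.pop("effects", [])
    )
    if "grid_shape" in d:
        d["grid_shape"] = tuple(int(x) for x in d["grid_shape"])
    return CohortSpec(communities=comms, effects=effs, **d)


def write_ground_truth(spec: CohortSpec, path, r_threshold: float = 0.6):
    truth = ground_truth(spec, r_threshold)
    doc = {
        "spec": _spec_to_dict(spec),
        "r_threshold": r_threshold,
        "expected_gfcd": {
            f"community_{i}": {"size": c.size, "expected_degree": int(c.size - 1)}
            for i, c in enumerate(spec.communities)
            if c.loading_c > r_threshold
        },
        "effect_signs": {
            mod: {"positive": np.argwhere(m > 0).tolist(),
                  "negative": np.argwhere(m < 0).tolist()}
            for mod, m in truth.effect_sign_maps.items()
        },
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def read_ground_truth(path):
    """Load the YAML sidecar; returns (CohortSpec, GroundTruth)."""
    doc = yaml.safe_load(Path(path).read_text())
    spec = cohort_spec_from_dict(doc["spec"])
    return spec, ground_truth(spec, float(doc.get("r_threshold", 0.6)))


def write_cohort(spec: CohortSpec, outdir) -> Path:
    """Materialize a cohort on disk, one subject at a time (bounded memory):
    4D BOLD + 3D GMV NIfTI and an rp-dialect motion file per subject, the
    tissue masks, the covariate TSV, and the ground-truth YAML sidecar."""
    from .synthetic import generate_covariates  # local to avoid cycle confusion

    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, wm, csf = make_masks(spec.grid_shape)
    aff = spec.affine
    write_volume(gm, aff, outdir / "mask_gm.nii.gz")
    write_volume(wm, aff, outdir / "mask_wm.nii.gz")
    write_volume(csf, aff, outdir / "mask_csf.nii.gz")
    write_covariates(generate_covariates(spec), outdir / "covariates.tsv")
    write_ground_truth(spec, outdir / "ground_truth.yaml")
    for plan in iter_subject_plan(spec):
        subj = generate_subject(spec, *plan)
        sdir = outdir / subj.subject_id
        write_volume(subj.bold.data.astype(np.float32), aff, sdir / "bold.nii.gz")
        write_volume(subj.gmv.data.astype(np.float32), aff, sdir / "gmv.nii.gz")
        write_motion(subj.motion, sdir / f"rp_{subj.subject_id}.txt")
    return outdir


def read_cohort(datadir, tr_s: float | None = None) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    datadir = Path(datadir)
    spec, truth = read_ground_truth(datadir / "ground_truth.yaml")
    if tr_s is not None:
        spec.tr_s = tr_s
    gm, geom = read_volume(datadir / "mask_gm.nii.gz", ndim=3)
    wm, _ = read_volume(datadir / "mask_wm.nii.gz", expect_geometry=geom, ndim=3)
    csf, _ = read_volume(datadir / "mask_csf.nii.gz", expect_geometry=geom, ndim=3)
    table = pd.read_csv(datadir / "covariates.tsv", sep="\t")
    records = read_covariates(datadir / "covariates.tsv")
    from .synthetic import SubjectData  # deferred import, plain dataclass

    subjects = []
    for i, row in table.iterrows():
        sid = str(row["subject_id"])
        sdir = datadir / sid
        bold_data, bgeom = read_volume(sdir / "bold.nii.gz", ndim=4)
        geom.require_match(VolumeGeometry(bgeom.shape, bgeom.affine), sid)
        gmv_data, _ = read_volume(sdir / "gmv.nii.gz", expect_geometry=geom, ndim=3)
        motion = read_motion(sdir / f"rp_{sid}.txt")
        subjects.append(
            SubjectData(
                subject_id=sid,
                subject_index=i % spec.n_per_group,
                group=str(row["group"]),
                bold=BoldSeries(bold_data, geom.affine, spec.tr_s),
                motion=motion,
                gmv=VolumeMap(gmv_data, geom.affine),
                n_spikes=-1,  # unknown once on disk; FD recomputes it
            )
        )
    return Cohort(
        spec=spec,
        subjects=subjects,
        covariates=table,
        records=records,
        gm_mask=gm.astype(bool),
        wm_mask=wm.astype(bool),
        csf_mask=csf.astype(bool),
        truth=truth,
    )
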