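"""Synthetic resting-state cohorts with planted, analytically known structure.

The generator emulates the study design this package analyzes: two matched
groups (default 35 patients vs 35 controls), 4D BOLD series on a common
3 mm grid (default 180 volumes, TR 2 s), per-volume rigid-motion parameter
traces, 3D gray-matter-volume (GMV) maps, and a Table-1-shaped covariate
sheet (age, gender, JOA score and illness duration for patients).

Connectivity structure is planted as voxel *communities* sharing a latent
signal: a member's series is sqrt(c) * latent + sqrt(1-c) * private noise,
so the expected pairwise correlation of two members is exactly the loading
c, and the expected gFCD of a member of an m-voxel community with c above
the correlation threshold is m - 1 (background voxels: 0). Group effects on
gFCD are planted by group-dependent community membership (correlation, hence
gFCD, is amplitude-invariant, so scaling amplitudes would do nothing);
"increase" plants the community in patients only, "decrease" in controls
only. GMV effects shift the regional mean of the patient group by
magnitude * between-subject SD, i.e. magnitude is a Cohen's d.

All randomness derives from per-(stream, subject, group) seed sequences, so
regenerating any array is bit-identical and adding subjects never perturbs
earlier subjects' data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .stats import SubjectRecord
from .types import (
    BoldSeries,
    ConfigurationError,
    GMVMap,
    MotionTrace,
    make_affine,
)

# RNG stream tags (first entry after the master seed in each SeedSequence)
_STREAM_BOLD, _STREAM_MOTION, _STREAM_GMV, _STREAM_COV, _STREAM_BASE = 1, 2, 3, 4, 5
_GROUP_CODE = {"patient": 1, "control": 0}


def _as_index_array(voxels) -> np.ndarray:
    arr = np.asarray(list(voxels) if not isinstance(voxels, np.ndarray) else voxels,
                     dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ConfigurationError(f"voxel index set must be (m, 3), got {arr.shape}")
    return arr


@dataclasses.dataclass(frozen=True)
class CommunitySpec:
    """A set of voxels sharing a latent signal with loading c in (0, 1):
    the expected pairwise correlation of any two members."""

    member_voxels: np.ndarray
    loading_c: float

    def __post_init__(self):
        arr = _as_index_array(self.member_voxels)
        if len(np.unique(arr, axis=0)) != len(arr):
            raise ConfigurationError("community members must be distinct voxels")
        object.__setattr__(self, "member_voxels", arr)
        if not (0.0 < self.loading_c < 1.0):
            raise ConfigurationError(
                f"loading_c must be in (0, 1), got {self.loading_c}"
            )

    @property
    def size(self) -> int:
        return len(self.member_voxels)


@dataclasses.dataclass(frozen=True)
class EffectSpec:
    """A planted group difference in one modality over a voxel region.

    For ``gmv``, ``magnitude`` is the Cohen's d of the patient-group shift of
    the regional mean. For ``gfcd`` the effect is membership-based and
    ``loading`` sets the planted community's correlation; ``magnitude`` is
    kept for reporting symmetry and must still be positive.
    """

    region: np.ndarray
    modality: str
    direction: str
    magnitude: float
    loading: float = 0.7

    def __post_init__(self):
        object.__setattr__(self, "region", _as_index_array(self.region))
        if len(self.region) == 0:
            raise ConfigurationError("effect region is empty")
        if self.modality not in ("gfcd", "gmv"):
            raise ConfigurationError(f"modality must be gfcd|gmv, got {self.modality!r}")
        if self.direction not in ("increase", "decrease"):
            raise ConfigurationError(
                f"direction must be increase|decrease, got {self.direction!r}"
            )
        if self.magnitude <= 0:
            raise ConfigurationError("magnitude must be positive")
        if self.modality == "gfcd" and not (0.0 < self.loading < 1.0):
            raise ConfigurationError("gfcd effect loading must be in (0, 1)")

    @property
    def sign(self) -> int:
        return 1 if self.direction == "increase" else -1


@dataclasses.dataclass
class CohortSpec:
    """Cohort parameters; defaults mirror the emulated acquisition (3 mm
    cubic voxels, 180 volumes, TR 2 s) and study size (35 per group)."""

    n_per_group: int = 35
    grid_shape: tuple = (20, 20, 20)
    voxel_size_mm: float = 3.0
    n_volumes: int = 180
    tr_s: float = 2.0
    communities: tuple = ()
    effects: tuple = ()
    noise_sd: float = 1.0
    seed: int = 0
    max_spikes: int = 2
    # GMV model: baseline level, between-subject SD of the whole-map offset
    # (the scale of Cohen's d effects), and iid voxel noise SD
    gmv_baseline: float = 0.6
    gmv_between_sd: float = 0.05
    gmv_voxel_sd: float = 0.02
    age_mean: float = 54.0
    age_sd: float = 6.7

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.communities = tuple(self.communities)
        self.effects = tuple(self.effects)

    @property
    def affine(self) -> np.ndarray:
        return make_affine(self.grid_shape, self.voxel_size_mm)

    def validate(self):
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ConfigurationError(f"bad grid_shape {self.grid_shape}")
        if self.n_volumes < 12:
            raise ConfigurationError("n_volumes too small (must exceed the discard period)")
        if self.tr_s <= 0 or self.voxel_size_mm <= 0 or self.noise_sd <= 0:
            raise ConfigurationError("tr_s, voxel_size_mm and noise_sd must be positive")
        gm, _, _ = make_masks(self.grid_shape)
        taken = np.zeros(self.grid_shape, dtype=bool)
        for what, vox in [("community", c.member_voxels) for c in self.communities] + [
            (f"{e.modality} effect", e.region) for e in self.effects if e.modality == "gfcd"
        ]:
            if np.any(vox < 0) or np.any(vox >= np.asarray(self.grid_shape)):
                raise ConfigurationError(f"{what} region lies outside the grid")
            if not gm[tuple(vox.T)].all():
                raise ConfigurationError(
                    f"{what} region lies outside the gray-matter mask"
                )
            if taken[tuple(vox.T)].any():
                raise ConfigurationError(
                    "communities/gfcd-effect regions must be disjoint"
                )
            taken[tuple(vox.T)] = True
        for e in self.effects:
            if e.modality == "gmv":
                if np.any(e.region < 0) or np.any(e.region >= np.asarray(self.grid_shape)):
                    raise ConfigurationError("gmv effect region lies outside the grid")
                if not gm[tuple(e.region.T)].all():
                    raise ConfigurationError(
                        "gmv effect region lies outside the gray-matter mask"
                    )
        return self


def make_masks(grid_shape):
    """Synthetic tissue masks on the grid: gray matter is an inscribed
    ellipsoid (semi-axes 0.45 of each dimension); white matter and CSF are
    two small interior blocks carved out of it."""
    shape = np.asarray(grid_shape, dtype=float)
    center = (shape - 1.0) / 2.0
    semi = np.maximum(shape * 0.45, 1.0)
    idx = np.indices(grid_shape).astype(float)
    dist2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    blob = dist2 <= 1.0

    def _block(frac_lo, frac_hi):
        m = np.zeros(grid_shape, dtype=bool)
        lo = np.maximum(0, np.floor(shape * np.asarray(frac_lo))).astype(int)
        hi = np.minimum(shape, np.ceil(shape * np.asarray(frac_hi))).astype(int)
        m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return m & blob

    wm = _block((0.40, 0.40, 0.40), (0.55, 0.55, 0.50))
    csf = _block((0.40, 0.40, 0.55), (0.50, 0.50, 0.65))
    if not wm.any() or not csf.any():  # tiny grids: fall back to single voxels
        ci = tuple(np.asarray(np.round(center), dtype=int))
        wm = np.zeros(grid_shape, dtype=bool)
        wm[ci] = True
        csf = np.zeros(grid_shape, dtype=bool)
        cj = (ci[0], ci[1], max(ci[2] - 1, 0))
        csf[cj] = blob[cj] or True
        csf &= ~wm
        if not csf.any():
            csf[ci[0], ci[1], min(ci[2] + 1, grid_shape[2] - 1)] = True
    gm = blob & ~wm & ~csf
    return gm, wm, csf


def cube_region(center, half_width: int, grid_shape) -> np.ndarray:
    """Voxel indices of an axis-aligned cube clipped to the grid."""
    c = np.asarray(center, dtype=int)
    lo = np.maximum(c - half_width, 0)
    hi = np.minimum(c + half_width + 1, np.asarray(grid_shape))
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


@dataclasses.dataclass
class GroundTruth:
    """Planted structure in analysis-ready form: the expected gFCD count per
    voxel (shared communities; m - 1 for members of communities whose loading
    exceeds the correlation threshold) and the exact per-modality effect sign
    maps (+1 / 0 / -1), with no leakage outside planted regions."""

    expected_gfcd_map: np.ndarray
    effect_sign_maps: dict


def ground_truth(spec: CohortSpec, r_threshold: float = 0.6) -> GroundTruth:
    expected = np.zeros(spec.grid_shape, dtype=np.int64)
    for c in spec.communities:
        if c.loading_c > r_threshold:
            expected[tuple(c.member_voxels.T)] = c.size - 1
    signs = {
        "gfcd": np.zeros(spec.grid_shape, dtype=np.int8),
        "gmv": np.zeros(spec.grid_shape, dtype=np.int8),
    }
    for e in spec.effects:
        signs[e.modality][tuple(e.region.T)] = e.sign
    return GroundTruth(expected, signs)


def _rng(spec_seed, stream, *key):
    return np.random.default_rng([int(spec_seed), int(stream), *map(int, key)])


def _active_communities(spec: CohortSpec, group: str):
    """Base communities plus group-dependent effect communities."""
    active = [(i, c) for i, c in enumerate(spec.communities)]
    for j, e in enumerate(spec.effects):
        if e.modality != "gfcd":
            continue
        present_in = "patient" if e.direction == "increase" else "control"
        if group == present_in:
            active.append((100 + j, CommunitySpec(e.region, e.loading)))
    return active


def generate_bold(spec: CohortSpec, subject_index: int, group: str,
                  seed: int | None = None) -> BoldSeries:
    """One subject's 4D BOLD grid: independent noise everywhere, overwritten
    at community members by the shared-latent construction."""
    spec.validate()
    if group not in _GROUP_CODE:
        raise ConfigurationError(f"group must be patient|control, got {group!r}")
    seed = spec.seed if seed is None else seed
    gcode = _GROUP_CODE[group]
    T = spec.n_volumes
    rng_bg = _rng(seed, _STREAM_BOLD, subject_index, gcode, 0)
    data = rng_bg.standard_normal((*spec.grid_shape, T)) * spec.noise_sd
    for comm_id, comm in _active_communities(spec, group):
        rng_c = _rng(seed, _STREAM_BOLD, subject_index, gcode, 1 + comm_id)
        latent = rng_c.standard_normal(T)
        private = rng_c.standard_normal((comm.size, T))
        series = (
            np.sqrt(comm.loading_c) * latent[None, :]
            + np.sqrt(1.0 - comm.loading_c) * private
        ) * spec.noise_sd
        data[tuple(comm.member_voxels.T)] = series
    return BoldSeries(data, spec.affine, spec.tr_s)


def generate_motion(spec: CohortSpec, n_spikes: int, seed: int | None = None,
                    subject_index: int = 0, group: str = "control") -> MotionTrace:
    """Smooth low-amplitude 6-parameter trace (well inside the 2 mm / 2 deg
    exclusion limits) with ``n_spikes`` persistent steps large enough to push
    frame-wise displacement above 0.5 mm at exactly those volumes."""
    T = spec.n_volumes
    if n_spikes < 0 or n_spikes >= T:
        raise ConfigurationError("n_spikes must be in [0, n_volumes)")
    first_eligible = 12  # keep spikes clear of the discard period
    eligible = np.arange(first_eligible, T - 1)
    if n_spikes > len(eligible) // 2:
        raise ConfigurationError(f"too many spikes for {T} volumes")
    seed = spec.seed if seed is None else seed
    rng = _rng(seed, _STREAM_MOTION, subject_index, _GROUP_CODE[group])

    t = np.arange(T)
    params = np.empty((T, 6))
    for j in range(6):
        amp = 0.15 if j < 3 else 0.002  # mm / radians
        freq = rng.uniform(0.005, 0.02)  # cycles per volume
        phase = rng.uniform(0, 2 * np.pi)
        jitter_sd = 0.005 if j < 3 else 1e-4
        params[:, j] = amp * np.sin(2 * np.pi * freq * t + phase) + \
            rng.normal(0.0, jitter_sd, T)

    if n_spikes:
        pos = []
        for cand in rng.permutation(eligible):
            if all(abs(cand - p) >= 2 for p in pos):
                pos.append(int(cand))
            if len(pos) == n_spikes:
                break
        offset = np.zeros(T)
        level = 0.0
        for k, i in enumerate(sorted(pos)):
            level = 0.8 if k % 2 == 0 else 0.0  # alternate so |trans| stays small
            offset[i:] = level
        params[:, 0] += offset
    return MotionTrace(params)


def generate_gmv(spec: CohortSpec, subject_index: int, group: str,
                 seed: int | None = None) -> GMVMap:
    """One subject's GMV map: a shared smooth baseline field, a subject-level
    offset (between-subject variation), iid voxel noise, and the planted
    patient-group regional shifts; clamped nonnegative and zero outside the
    gray-matter mask."""
    spec.validate()
    if group not in _GROUP_CODE:
        raise ConfigurationError(f"group must be patient|control, got {group!r}")
    seed = spec.seed if seed is None else seed
    gm, _, _ = make_masks(spec.grid_shape)

    rng_base = _rng(seed, _STREAM_BASE)
    field = ndimage.gaussian_filter(rng_base.standard_normal(spec.grid_shape), 2.0)
    sd = field.std()
    base = spec.gmv_baseline + (0.1 * field / sd if sd > 0 else 0.0)

    rng = _rng(seed, _STREAM_GMV, subject_index, _GROUP_CODE[group])
    subj_offset = rng.normal(0.0, spec.gmv_between_sd)
    noise = rng.normal(0.0, spec.gmv_voxel_sd, spec.grid_shape)
    data = base + subj_offset + noise
    if group == "patient":
        for e in spec.effects:
            if e.modality == "gmv":
                data[tuple(e.region.T)] += e.sign * e.magnitude * spec.gmv_between_sd
    data = np.maximum(data, 0.0)
    return GMVMap(np.where(gm, data, 0.0), spec.affine)


def generate_covariates(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Table-1-shaped covariate sheet: ages drawn from one shared normal for
    both groups (matching), gender balanced within group, JOA (uniform
    integers 6-16) and illness duration (log-normal, median ~30 months) for
    patients only."""
    seed = spec.seed if seed is None else seed
    rng = _rng(seed, _STREAM_COV)
    n = spec.n_per_group
    rows = []
    for g in ("patient", "control"):
        genders = np.array(["F"] * (n // 2) + ["M"] * (n - n // 2))
        rng.shuffle(genders)
        ages = rng.normal(spec.age_mean, spec.age_sd, n)
        joa = rng.integers(6, 17, n)
        dur = np.exp(rng.normal(np.log(30.0), 0.45, n))
        for i in range(n):
            patient = g == "patient"
            rows.append(
                {
                    "subject_id": f"sub-{'p' if patient else 'c'}{i:03d}",
                    "group": g,
                    "age": round(float(ages[i]), 2),
                    "gender": genders[i],
                    "joa": int(joa[i]) if patient else np.nan,
                    "duration_months": round(float(dur[i]), 1) if patient else np.nan,
                }
            )
    return pd.DataFrame(rows)


def covariates_to_records(table: pd.DataFrame):
    recs = []
    for _, row in table.iterrows():
        recs.append(
            SubjectRecord(
                id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                gender=str(row["gender"]),
                joa=None if pd.isna(row.get("joa")) else float(row["joa"]),
                duration_months=(
                    None if pd.isna(row.get("duration_months"))
                    else float(row["duration_months"])
                ),
            )
        )
    return recs


@dataclasses.dataclass
class SubjectData:
    subject_id: str
    subject_index: int
    group: str
    bold: BoldSeries
    motion: MotionTrace
    gmv: GMVMap
    n_spikes: int


@dataclasses.dataclass
class Cohort:
    spec: CohortSpec
    subjects: list
    covariates: pd.DataFrame
    records: list
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    truth: GroundTruth


def iter_subject_plan(spec: CohortSpec):
    """(subject_id, subject_index, group, n_spikes) for every cohort member,
    in covariate-table order."""
    table = generate_covariates(spec)
    for i, row in table.iterrows():
        group = row["group"]
        idx = i % spec.n_per_group
        rng = _rng(spec.seed, 6, idx, _GROUP_CODE[group])
        n_spikes = int(rng.integers(0, spec.max_spikes + 1)) if spec.max_spikes else 0
        yield str(row["subject_id"]), idx, group, n_spikes


def generate_subject(spec: CohortSpec, subject_id: str, subject_index: int,
                     group: str, n_spikes: int) -> SubjectData:
    return SubjectData(
        subject_id=subject_id,
        subject_index=subject_index,
        group=group,
        bold=generate_bold(spec, subject_index, group),
        motion=generate_motion(spec, n_spikes, subject_index=subject_index, group=group),
        gmv=generate_gmv(spec, subject_index, group),
        n_spikes=n_spikes,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """The full in-memory cohort bundle (all subjects' BOLD, motion and GMV,
    covariate table, masks, and the planted ground truth)."""
    spec.validate()
    gm, wm, csf = make_masks(spec.grid_shape)
    table = generate_covariates(spec)
    subjects = [generate_subject(spec, *plan) for plan in iter_subject_plan(spec)]
    return Cohort(
        spec=spec,
        subjects=subjects,
        covariates=table,
        records=covariates_to_records(table),
        gm_mask=gm,
        wm_mask=wm,
        csf_mask=csf,
        truth=ground_truth(spec),
    )


def default_cohort_spec(
    n_per_group: int = 35,
    grid_shape=(20, 20, 20),
    seed: int = 0,
    effect_d: float = 1.5,
    n_volumes: int = 180,
) -> CohortSpec:
    """A study-patterned cohort: two shared hub communities plus three effect
    regions following the reported sign pattern — a sensorimotor-like region
    with decreased connectivity density and decreased GMV (concordant), a
    visual-like region with both increased (concordant), and a cerebellar-
    like region with increased connectivity density but decreased GMV
    (discordant)."""
    gs = tuple(int(s) for s in grid_shape)
    c = np.asarray(gs) // 2

    def _cube(frac, half):
        center = np.clip((np.asarray(gs) * np.asarray(frac)).astype(int), 0,
                         np.asarray(gs) - 1)
        return cube_region(center, half, gs)

    # regions sit well apart inside the gray-matter ellipsoid so that the
    # smoothing halos of same-sign effects cannot bridge into one cluster
    hub1 = _cube((0.50, 0.50, 0.20), 1)
    hub2 = _cube((0.75, 0.65, 0.50), 1)
    region_a = _cube((0.50, 0.50, 0.75), 1)  # gFCD down + GMV down
    region_b = _cube((0.70, 0.25, 0.50), 1)  # gFCD up + GMV up
    region_c = _cube((0.25, 0.70, 0.50), 1)  # gFCD up + GMV down
    return CohortSpec(
        n_per_group=n_per_group,
        grid_shape=gs,
        n_volumes=n_volumes,
        seed=seed,
        communities=(
            CommunitySpec(hub1, 0.7),
            CommunitySpec(hub2, 0.7),
        ),
        effects=(
            EffectSpec(region_a, "gfcd", "decrease", effect_d),
            EffectSpec(region_a, "gmv", "decrease", effect_d),
            EffectSpec(region_b, "gfcd", "increase", effect_d),
            EffectSpec(region_b, "gmv", "increase", effect_d),
            EffectSpec(region_c, "gfcd", "increase", effect_d),
            EffectSpec(region_c, "gmv", "decrease", effect_d),
        ),
    )
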