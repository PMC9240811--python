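import numpy as np
import pytest

from fcdtools import CohortSpec, CommunitySpec, SubjectRecord, make_masks


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_records(n_per_group, rng, gender_mix=True):
    """Covariate records for synthetic GLM inputs."""
    recs = []
    for g in ("patient", "control"):
        for i in range(n_per_group):
            recs.append(
                SubjectRecord(
                    id=f"{g}-{i}",
                    group=g,
                    age=float(rng.normal(54, 6.7)),
                    gender=("M" if (i + (g == "patient")) % 2 else "F")
                    if gender_mix else "M",
                    joa=float(rng.integers(6, 17)) if g == "patient" else None,
                    duration_months=float(rng.uniform(6, 60))
                    if g == "patient" else None,
                )
            )
    return recs


@pytest.fixture
def small_masks():
    return make_masks((8, 8, 8))


def community_spec(grid_shape, m, loading, n_volumes=180, seed=0, **kw):
    """Cohort spec with one m-voxel community spread through gray matter."""
    gm, _, _ = make_masks(grid_shape)
    vox = np.argwhere(gm)
    members = vox[:: max(len(vox) // m, 1)][:m]
    assert len(members) == m
    return CohortSpec(
        n_per_group=2,
        grid_shape=grid_shape,
        n_volumes=n_volumes,
        seed=seed,
        communities=(CommunitySpec(members, loading),),
        **kw,
    ), members
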