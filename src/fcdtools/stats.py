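"""Mass-univariate group statistics, FDR correction, cluster tables, ROI
extraction, correlation tables and the concordance ("dissociation") report.

The voxel-wise comparison is an OLS fit of each voxel's map value on
[intercept, group, age, gender]; the group-coefficient t with df = n - rank
is the two-sample t adjusted for the confounds (with no covariates it
reduces exactly to the textbook pooled two-sample t). Multiple comparisons
are handled with Benjamini-Hochberg FDR within the analysis mask.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .types import GroupStatResult, InputError

GROUP_LABELS = ("patient", "control")

#: SPM-convention cluster connectivity: all 26 neighbours
_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)


@dataclasses.dataclass
class SubjectRecord:
    """One subject's covariate row (Table-1 shape): group, age, gender, and —
    for patients — JOA score and illness duration in months."""

    id: str
    group: str
    age: float
    gender: str
    joa: float | None = None
    duration_months: float | None = None

    def __post_init__(self):
        if self.group not in GROUP_LABELS:
            raise InputError(f"group must be one of {GROUP_LABELS}, got {self.group!r}")
        if self.gender not in ("F", "M"):
            raise InputError(f"gender must be 'F' or 'M', got {self.gender!r}")
        if not np.isfinite(self.age):
            raise InputError(f"age must be finite, got {self.age}")


def _design_from_records(records, covariates=("age", "gender")):
    """[intercept, group(patient=1), covariates...]; any affine gender coding
    yields the same group t, so M is coded 1 and F 0."""
    n = len(records)
    cols = [np.ones(n), np.array([1.0 if r.group == "patient" else 0.0 for r in records])]
    names = ["intercept", "group"]
    for cov in covariates:
        if cov == "age":
            cols.append(np.array([float(r.age) for r in records]))
        elif cov == "gender":
            cols.append(np.array([1.0 if r.gender == "M" else 0.0 for r in records]))
        else:
            raise InputError(f"unknown covariate {cov!r}")
        names.append(cov)
    X = np.column_stack(cols)
    for j, name in enumerate(names[1:], start=1):
        if np.ptp(X[:, j]) == 0:
            raise InputError(f"covariate {name!r} is constant across subjects")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError("singular group design (collinear covariates)")
    return X, names


def _group_contrast_t(X: np.ndarray, Y: np.ndarray):
    """t and p for the group column (index 1) of an OLS fit, vectorized over
    the columns of Y. Degenerate voxels (zero residual and zero effect) get
    t = 0, p = 1."""
    n, k = X.shape
    df = n - k
    if df < 1:
        raise InputError(f"insufficient degrees of freedom (n={n}, rank={k})")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    # voxels fitted exactly (up to roundoff) carry no evidence: t = 0, p = 1
    exact = rss <= 1e-24 * (Y**2).sum(axis=0)
    sigma2 = rss / df
    gvar = np.linalg.inv(X.T @ X)[1, 1]
    se = np.sqrt(sigma2 * gvar)
    ok = (se > 0) & ~exact
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok, beta[1] / np.where(ok, se, 1.0), 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, p, df, beta[1]


def fdr_bh(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: returns (reject mask, q-values).

    q-values follow the standard min-accumulation over the sorted p's; the
    rejection set is the step-up set (q <= alpha).
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise InputError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, q


def glm_group_contrast(
    maps,
    records,
    covariates=("age", "gender"),
    mask=None,
    alpha: float = 0.05,
) -> GroupStatResult:
    """Voxel-wise group contrast (patient - control) with confound adjustment
    and BH-FDR within the mask."""
    records = list(records)
    if isinstance(maps, np.ndarray):
        stacked = maps
        affine = np.eye(4)
    else:
        maps = list(maps)
        geom = maps[0].geometry
        for m in maps[1:]:
            geom.require_match(m.geometry, "subject map")
        stacked = np.stack([np.asarray(m.data, dtype=float) for m in maps])
        affine = maps[0].affine.copy()
    if stacked.shape[0] != len(records):
        raise InputError(
            f"{stacked.shape[0]} maps but {len(records)} subject records"
        )
    for g in GROUP_LABELS:
        if sum(r.group == g for r in records) < 3:
            raise InputError(f"need at least 3 subjects in group {g!r}")
    grid = stacked.shape[1:]
    mask = np.ones(grid, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise InputError(f"mask grid {mask.shape} != map grid {grid}")
    if not mask.any():
        raise InputError("analysis mask is empty")

    X, _ = _design_from_records(records, covariates)
    Y = stacked.reshape(len(records), -1)[:, mask.ravel()]
    t, p, df, effect = _group_contrast_t(X, Y)
    reject, q = fdr_bh(p, alpha=alpha)

    def _embed(v, dtype=float, fill=0.0):
        out = np.full(grid, fill, dtype=dtype).ravel()
        out[mask.ravel()] = v
        return out.reshape(grid)

    return GroupStatResult(
        t_map=_embed(t),
        p_map=_embed(p, fill=1.0),
        q_map=_embed(q, fill=1.0),
        sig_mask=_embed(reject, dtype=bool, fill=False),
        df=df,
        affine=affine,
        mask=mask,
        alpha=alpha,
        effect_map=_embed(effect),
    )


@dataclasses.dataclass
class ClusterRow:
    """One row of the cluster table: peak world coordinate (mm), peak t,
    extent in voxels, and the effect sign."""

    region_label: str
    peak_mni: tuple
    peak_intensity: float
    voxel_size: int
    sign: str


@dataclasses.dataclass
class ClusterTable:
    rows: list
    label_map: np.ndarray  # 0 background; i = rows[i-1]

    def __len__(self):
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "region_label": r.region_label,
                    "mni_x": r.peak_mni[0],
                    "mni_y": r.peak_mni[1],
                    "mni_z": r.peak_mni[2],
                    "peak_intensity": r.peak_intensity,
                    "voxel_size": r.voxel_size,
                    "sign": r.sign,
                }
                for r in self.rows
            ],
            columns=[
                "region_label", "mni_x", "mni_y", "mni_z",
                "peak_intensity", "voxel_size", "sign",
            ],
        )


def extract_clusters(
    sig_mask: np.ndarray,
    t_map: np.ndarray,
    affine: np.ndarray,
    min_extent: int = 10,
) -> ClusterTable:
    """Connected components (26-connectivity) of the significant mask, split
    by t sign; peak = max |t| (ties -> lowest linear index); rows sorted by
    |peak| descending. Components smaller than ``min_extent`` are dropped."""
    sig_mask = np.asarray(sig_mask, dtype=bool)
    t_map = np.asarray(t_map, dtype=float)
    if sig_mask.shape != t_map.shape:
        raise InputError("sig_mask and t_map grids differ")
    affine = np.asarray(affine, dtype=float)
    found = []
    for sign, name in ((1, "increase"), (-1, "decrease")):
        comp = sig_mask & ((t_map > 0) if sign > 0 else (t_map < 0))
        labels, n = ndimage.label(comp, structure=_CONNECTIVITY)
        for lab in range(1, n + 1):
            vox = labels == lab
            extent = int(vox.sum())
            if extent < min_extent:
                continue
            flat_abs = np.where(vox, np.abs(t_map), -np.inf).ravel()
            peak_flat = int(np.argmax(flat_abs))  # first occurrence = lowest index
            ijk = np.unravel_index(peak_flat, t_map.shape)
            world = affine @ np.array([*ijk, 1.0])
            found.append(
                (
                    ClusterRow(
                        region_label="",
                        peak_mni=tuple(world[:3]),
                        peak_intensity=float(t_map[ijk]),
                        voxel_size=extent,
                        sign=name,
                    ),
                    vox,
                )
            )
    found.sort(key=lambda rv: -abs(rv[0].peak_intensity))
    label_map = np.zeros(t_map.shape, dtype=np.int32)
    rows = []
    for i, (row, vox) in enumerate(found, start=1):
        row.region_label = f"cluster_{i:02d}_{row.sign}"
        label_map[vox] = i
        rows.append(row)
    return ClusterTable(rows, label_map)


def roi_means(maps, label_map: np.ndarray, subject_ids=None) -> pd.DataFrame:
    """Per-subject mean over each labelled cluster; subjects x ROIs."""
    maps = list(maps)
    label_map = np.asarray(label_map)
    ids = sorted(int(v) for v in np.unique(label_map) if v != 0)
    if not ids:
        raise InputError("label map contains no ROIs")
    cols = {}
    for roi in ids:
        sel = label_map == roi
        if not sel.any():
            raise InputError(f"ROI {roi} is empty")
        cols[f"roi_{roi:02d}"] = [float(np.asarray(m.data, dtype=float)[sel].mean()) for m in maps]
    index = subject_ids if subject_ids is not None else range(len(maps))
    return pd.DataFrame(cols, index=index)


def roi_group_compare(roi_table: pd.DataFrame, records, covariates=("age", "gender")) -> pd.DataFrame:
    """Per-ROI group contrast with the same confound-adjusted model as the
    voxel-wise analysis, applied to one value per subject."""
    records = list(records)
    if len(records) != len(roi_table):
        raise InputError("roi_table rows must match subject records")
    X, _ = _design_from_records(records, covariates)
    out = []
    for roi in roi_table.columns:
        y = roi_table[roi].to_numpy(dtype=float)[:, None]
        t, p, df, _ = _group_contrast_t(X, y)
        out.append({"roi": roi, "t": float(t[0]), "p": float(p[0]), "df": df})
    return pd.DataFrame(out).set_index("roi")


def correlation_table(
    roi_gfcd: pd.DataFrame,
    roi_gmv: pd.DataFrame,
    records,
    clinical=("joa", "duration_months"),
) -> pd.DataFrame:
    """Pearson correlations per ROI (Table-3 shape): gFCD-GMV within each
    group, and gFCD/GMV vs clinical scores within patients. Reports raw and
    BH-adjusted p side by side (the family is the whole table). Zero-variance
    cells are flagged as undefined (NaN), never raised."""
    records = list(records)
    if len(records) != len(roi_gfcd) or len(records) != len(roi_gmv):
        raise InputError("ROI tables must match subject records")
    if list(roi_gfcd.columns) != list(roi_gmv.columns):
        raise InputError("gFCD and GMV ROI tables must share columns")
    groups = np.array([r.group for r in records])
    rows = []

    def _corr(roi, pair, group_name, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3:
            raise InputError(f"fewer than 3 complete pairs for {roi}/{pair}")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r_val, p_val = np.nan, np.nan
        else:
            r_val, p_val = sps.pearsonr(x, y)
        rows.append(
            {"roi": roi, "pair": pair, "group": group_name,
             "r_value": float(r_val) if np.isfinite(r_val) else np.nan,
             "p_raw": float(p_val) if np.isfinite(p_val) else np.nan}
        )

    for roi in roi_gfcd.columns:
        for g in GROUP_LABELS:
            sel = groups == g
            _corr(roi, "gFCD-GMV", g, roi_gfcd.loc[sel.tolist(), roi], roi_gmv.loc[sel.tolist(), roi])
        pat = (groups == "patient").tolist()
        for clin in clinical:
            cv = np.array(
                [getattr(r, "joa" if clin == "joa" else "duration_months")
                 for r in records if r.group == "patient"],
                dtype=float,
            )
            _corr(roi, f"gFCD-{clin}", "patient", roi_gfcd.loc[pat, roi], cv)
            _corr(roi, f"GMV-{clin}", "patient", roi_gmv.loc[pat, roi], cv)

    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.nan
    finite = table["p_raw"].notna()
    if finite.any():
        _, q = fdr_bh(table.loc[finite, "p_raw"].to_numpy())
        table.loc[finite, "p_adjusted"] = q
    return table


@dataclasses.dataclass
class DissociationReport:
    """Per-region sign pattern of the two modalities and concordance flags."""

    table: pd.DataFrame
    n_concordant: int
    n_discordant: int
    message: str = ""


def dissociation_report(
    gfcd_result: GroupStatResult,
    gmv_result: GroupStatResult,
    min_extent: int = 10,
) -> DissociationReport:
    """Compare effect signs of the two modalities region by region.

    Regions are the FDR-significant gFCD clusters (mirroring the ROI logic of
    the group analysis). Within each, the gFCD sign is the cluster sign and
    the GMV sign is read over the cluster *core*: the voxels at or above
    half the cluster's peak |gFCD effect| (the adjusted group mean
    difference, which decays with distance from the true effect locus the
    way the smoothing kernel does — unlike t, which stays high throughout
    the halo because halo noise shrinks along with the halo signal). The
    reported sign is that of the mean GMV effect over the core. A flag
    records whether any cluster voxel survives the GMV FDR threshold.
    """
    if gfcd_result.t_map.shape != gmv_result.t_map.shape:
        raise InputError("gFCD and GMV results must share one grid")
    clusters = extract_clusters(
        gfcd_result.sig_mask, gfcd_result.t_map, gfcd_result.affine, min_extent
    )
    cols = ["region_label", "mni_x", "mni_y", "mni_z", "voxel_size",
            "gfcd_sign", "gmv_sign", "gmv_fdr_significant", "concordant"]
    if not clusters.rows:
        return DissociationReport(
            pd.DataFrame(columns=cols), 0, 0,
            message="no FDR-significant gFCD clusters at the requested extent",
        )
    rows = []
    for i, row in enumerate(clusters.rows, start=1):
        vox = clusters.label_map == i
        gfcd_sign = 1 if row.sign == "increase" else -1
        loc = gfcd_result.effect_map if gfcd_result.effect_map is not None \
            else gfcd_result.t_map
        gmv_val = gmv_result.effect_map if gmv_result.effect_map is not None \
            else gmv_result.t_map
        abs_eff = np.abs(np.where(vox, loc, 0.0))
        core = vox & (abs_eff >= 0.5 * abs_eff.max())
        gmv_mean = float(gmv_val[core].mean())
        gmv_sign = int(np.sign(gmv_mean)) if gmv_mean != 0 else 0
        rows.append(
            {
                "region_label": row.region_label,
                "mni_x": row.peak_mni[0],
                "mni_y": row.peak_mni[1],
                "mni_z": row.peak_mni[2],
                "voxel_size": row.voxel_size,
                "gfcd_sign": gfcd_sign,
                "gmv_sign": gmv_sign,
                "gmv_fdr_significant": bool(gmv_result.sig_mask[vox].any()),
                "concordant": gfcd_sign == gmv_sign,
            }
        )
    table = pd.DataFrame(rows, columns=cols)
    n_con = int(table["concordant"].sum())
    return DissociationReport(table, n_con, len(table) - n_con)


class GroupContrastGLM(BaseEstimator):
    """Estimator facade for the voxel-wise group contrast.

    ``fit(maps, records)`` runs the confound-adjusted contrast and exposes
    ``t_map_``, ``p_map_``, ``q_map_``, ``sig_mask_``, ``df_`` and
    ``clusters_`` (the extracted cluster table).
    """

    def __init__(self, covariates=("age", "gender"), mask=None,
                 alpha: float = 0.05, min_extent: int = 10):
        self.covariates = covariates
        self.mask = mask
        self.alpha = alpha
        self.min_extent = min_extent

    def fit(self, X, y):
        """X: per-subject 3D maps; y: matching SubjectRecord list."""
        res = glm_group_contrast(
            X, y, covariates=self.covariates, mask=self.mask, alpha=self.alpha
        )
        self.result_ = res
        self.t_map_ = res.t_map
        self.p_map_ = res.p_map
        self.q_map_ = res.q_map
        self.sig_mask_ = res.sig_mask
        self.df_ = res.df
        self.clusters_ = extract_clusters(
            res.sig_mask, res.t_map, res.affine, self.min_extent
        )
        return self
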