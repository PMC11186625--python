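"""Quantitative evaluation statistics for segmentation-derived volumetry.

Implements the statistics used to validate photograph-derived segmentations
and volumes: per-label 2D Dice on selected slices, label volumes, general
linear model (GLM) correction of volumes for age and sex, AUROC + Wilcoxon
rank-sum group comparison, Pearson correlation against reference volumetry,
and Steiger's test for comparing two dependent correlations that share a
common sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from . import errors

#: regions whose segmentations are unreliable due to poor photographic
#: contrast; excluded from group statistics by default
DEFAULT_EXCLUDED_REGIONS = ("accumbens", "ventral_dc")


@dataclass
class LabelImage2D:
    """Integer label raster with physical pixel size and a label dictionary."""

    labels: np.ndarray
    pixel_size: float
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or not np.issubdtype(self.labels.dtype,
                                                      np.integer):
            raise ValueError("labels must be a 2D integer raster")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")


def dice2d(a: LabelImage2D | np.ndarray, b: LabelImage2D | np.ndarray,
           labels: list[int]) -> dict[int, float]:
    """Per-label 2D Dice overlap.

    A label absent from both rasters is reported as NaN (undefined), not 0.
    """
    la = a.labels if isinstance(a, LabelImage2D) else np.asarray(a)
    lb = b.labels if isinstance(b, LabelImage2D) else np.asarray(b)
    if la.shape != lb.shape:
        raise errors.ShapeMismatch(f"{la.shape} vs {lb.shape}")
    out = {}
    for lab in labels:
        sa = la == lab
        sb = lb == lab
        denom = sa.sum() + sb.sum()
        if denom == 0:
            out[lab] = float("nan")
        else:
            out[lab] = float(2.0 * np.sum(sa & sb) / denom)
    return out


def label_volumes(segmentation: np.ndarray,
                  voxel_dims) -> dict[int, float]:
    """Volume in mm^3 of every nonzero label (count * voxel volume)."""
    voxel_dims = np.atleast_1d(np.asarray(voxel_dims, dtype=float))
    if np.any(voxel_dims <= 0):
        raise ValueError("voxel dimensions must be positive")
    vv = float(np.prod(voxel_dims)) if voxel_dims.size > 1 \
        else float(voxel_dims[0]) ** 3
    seg = np.asarray(segmentation)
    labs, counts = np.unique(seg, return_counts=True)
    return {int(l): float(c * vv) for l, c in zip(labs, counts) if l != 0}


# ---------------------------------------------------------------------------
# group statistics on a volume table
# ---------------------------------------------------------------------------

@dataclass
class VolumeTable:
    """Case x region volume table with group flag and covariates.

    ``data`` must contain columns ``group`` (0 = control, 1 = case), ``age``
    (years), ``sex`` (0/1); every other numeric column is treated as a region
    volume (mm^3 or mL).
    """

    data: pd.DataFrame

    def __post_init__(self):
        for col in ("group", "age", "sex"):
            if col not in self.data.columns:
                raise ValueError(f"missing required column {col!r}")
        if self.data["group"].isna().any():
            raise ValueError("missing group labels")

    @property
    def region_columns(self) -> list[str]:
        skip = {"group", "age", "sex", "case_id", "hemispheres"}
        return [c for c in self.data.columns
                if c not in skip and pd.api.types.is_numeric_dtype(self.data[c])]


def contralateral_average(table: VolumeTable,
                          prefix_left: str = "left_",
                          prefix_right: str = "right_") -> VolumeTable:
    """Average left/right volumes into one column per region when both exist.

    Columns named ``left_<region>`` / ``right_<region>`` are merged into
    ``<region>``; single-hemisphere columns are renamed without averaging.
    """
    df = table.data.copy()
    lefts = {c[len(prefix_left):]: c for c in df.columns
             if c.startswith(prefix_left)}
    rights = {c[len(prefix_right):]: c for c in df.columns
              if c.startswith(prefix_right)}
    for region in sorted(set(lefts) | set(rights)):
        cols = [c for c in (lefts.get(region), rights.get(region))
                if c is not None]
        df[region] = df[cols].mean(axis=1)
        df = df.drop(columns=cols)
    return VolumeTable(df)


def residualize(table: VolumeTable,
                covariates: tuple[str, ...] = ("age", "sex")) -> VolumeTable:
    """Replace each volume column by its OLS residual on [1, covariates].

    Residuals are orthogonal to the covariates; raises
    :class:`~photorecon.errors.RankDeficientDesign` when the design matrix is
    rank deficient or there are fewer than 3 cases.
    """
    df = table.data.copy()
    if len(df) < 3:
        raise errors.RankDeficientDesign("need at least 3 cases")
    X = sm.add_constant(df[list(covariates)].astype(float).to_numpy(),
                        has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise errors.RankDeficientDesign("covariate design matrix is rank "
                                         "deficient")
    for col in table.region_columns:
        fit = sm.OLS(df[col].astype(float).to_numpy(), X).fit()
        df[col] = fit.resid
    return VolumeTable(df)


def auroc(x, y) -> float:
    """Area under the ROC curve separating case values ``y`` from controls
    ``x``: (#{pairs y > x} + 0.5 #{ties}) / (|x| |y|).

    0.5 is chance, 1.0 perfect separation; the nonparametric analogue of the
    effect size (the normalized Mann-Whitney U statistic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise errors.EmptyGroup("both groups must be nonempty")
    ranks = scipy.stats.rankdata(np.concatenate([x, y]))
    ry = ranks[len(x):].sum()
    u = ry - len(y) * (len(y) + 1) / 2.0
    return float(u / (len(x) * len(y)))


def _ranksum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p of the Mann-Whitney U (mid-ranks)."""
    nx, ny = len(x), len(y)
    ranks = scipy.stats.rankdata(np.concatenate([x, y]))
    mu = nx * ny / 2.0
    u_obs = ranks[nx:].sum() - ny * (ny + 1) / 2.0
    idx = range(nx + ny)
    count = 0
    total = 0
    for comb in itertools.combinations(idx, ny):
        u = ranks[list(comb)].sum() - ny * (ny + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def ranksum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact permutation enumeration for small samples (min group size <= 8 and
    combined n <= 16); normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise errors.EmptyGroup("both groups must be nonempty")
    if min(len(x), len(y)) <= 8 and len(x) + len(y) <= 16:
        return float(_ranksum_exact_p(x, y))
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic")
    return float(res.pvalue)


def pearson_r(u, v) -> float:
    """Sample Pearson correlation coefficient."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size < 3 or v.size != u.size:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(u) == 0 or np.std(v) == 0:
        raise errors.ZeroVariance("constant input vector")
    return float(scipy.stats.pearsonr(u, v).statistic)


def steiger_test(r_jk: float, r_jh: float, r_kh: float,
                 n: int) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing variable j.

    Compares corr(j,k) with corr(j,h) given corr(k,h) and the common sample
    size n, using Fisher z-transforms and the dependent-correlation
    covariance term.  Returns (z statistic, two-sided p).
    """
    for r in (r_jk, r_jh, r_kh):
        if not -1.0 < r < 1.0:
            raise errors.InvalidCorrelation(f"|r| must be < 1, got {r}")
    if n < 4:
        raise errors.InvalidCorrelation("need n >= 4")
    z1 = np.arctanh(r_jk)
    z2 = np.arctanh(r_jh)
    rbar = (r_jk + r_jh) / 2.0
    psi = (r_kh * (1.0 - 2.0 * rbar ** 2)
           - 0.5 * rbar ** 2 * (1.0 - 2.0 * rbar ** 2 - r_kh ** 2))
    cov = psi / (1.0 - rbar ** 2) ** 2
    if cov >= 1.0:
        raise errors.InvalidCorrelation(
            "correlation triple is not jointly feasible")
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * cov))
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(z), float(p)


def group_stats(table: VolumeTable,
                regions: list[str] | None = None,
                exclude: tuple[str, ...] = DEFAULT_EXCLUDED_REGIONS,
                correct_covariates: bool = True,
                bonferroni: bool = False) -> pd.DataFrame:
    """AUROC and rank-sum p per region comparing cases vs controls.

    Volumes are first residualized on age and sex (GLM, pooled fit) unless
    ``correct_covariates=False``.  Regions whose name contains an excluded
    substring are dropped.  Raw p-values are reported by default; a
    Bonferroni-corrected column is added when ``bonferroni=True``.
    """
    if regions is None:
        regions = table.region_columns
    regions = [r for r in regions
               if not any(e in r.lower() for e in exclude)]
    work = residualize(table) if correct_covariates else table
    grp = work.data["group"].to_numpy().astype(int)
    rows = []
    for r in regions:
        vals = work.data[r].to_numpy(dtype=float)
        x = vals[grp == 0]
        y = vals[grp == 1]
        rows.append({"region": r, "auroc": auroc(x, y),
                     "p_value": ranksum_p(x, y)})
    out = pd.DataFrame(rows)
    if bonferroni:
        out["p_bonferroni"] = np.minimum(out["p_value"] * len(out), 1.0)
    return out
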