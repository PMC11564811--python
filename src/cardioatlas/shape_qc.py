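"""Shape-based quality control: four scores and the 5x-IQR exclusion rule.

Scores per subject: (1) contour fit error, the mean distance from each
contour point to the nearest model point; (2) the first 10 PC z-scores,
fenced per component; (3) Mahalanobis distance, the root sum of squares of
those 10 z-scores; (4) projection residual, the RMS per-point distance
between the aligned shape and its reconstruction from the first 10 modes.
A subject is excluded when any score lies more than 5 interquartile ranges
above the lower quartile or below the upper quartile of that score's
cohort distribution (a fence slightly tighter than Tukey's; the classical
Tukey variant is available via ``fence='tukey'``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atlas import reconstruct_shape, rigid_align_pair, score_shapes, scores_matrix
from .types import ContourSet, ShapeAtlas, SurfaceMesh

QC_N_MODES = 10
IQR_MULTIPLIER = 5.0


def contour_fit_error(mesh: SurfaceMesh, contours: ContourSet) -> float:
    """Mean distance (mm) from contour points to the nearest model point.

    Nearest-vertex approximation: the model is treated as its point cloud
    (dense meshes make the vertex and the true surface foot point nearly
    coincide).
    """
    if contours.points.shape[0] == 0:
        raise ValueError("empty contour set")
    tree = cKDTree(mesh.points)
    d, _ = tree.query(contours.points)
    return float(np.mean(d))


def mahalanobis_distance(z: np.ndarray, n_components: int = QC_N_MODES) -> float:
    """Root sum of squares of the first ``n_components`` z-scores.

    Because atlas scores are unit-variance and uncorrelated on the training
    set, this is the Mahalanobis distance in score space.
    """
    z = np.asarray(z, dtype=float)
    if z.size < n_components:
        raise ValueError(
            f"need {n_components} z-scores, got {z.size}"
        )
    return float(np.sqrt(np.sum(z[:n_components] ** 2)))


def projection_residual(
    atlas: ShapeAtlas,
    mesh: SurfaceMesh,
    n_modes: int = QC_N_MODES,
    align: bool = True,
) -> float:
    """RMS per-point distance (mm) between a shape and its reconstruction
    from the first ``n_modes`` atlas modes."""
    if n_modes > atlas.n_modes:
        raise ValueError("n_modes exceeds atlas rank")
    if align:
        mesh = rigid_align_pair(mesh, atlas.mean_mesh())
    [s] = score_shapes(atlas, [mesh], align=False, n_modes=n_modes)
    recon = reconstruct_shape(atlas, s.z, modes=list(range(n_modes)))
    return float(np.sqrt(np.mean(np.sum((mesh.points - recon.points) ** 2, axis=1))))


def iqr_outlier_flags(
    scores: np.ndarray,
    multiplier: float = IQR_MULTIPLIER,
    fence: str = "cross",
) -> np.ndarray:
    """Flag quality scores lying outside interquartile-range fences.

    Two conventions are provided. ``fence='cross'`` (default) excludes
    values more than ``multiplier`` IQRs above the lower quartile or below
    the upper quartile, i.e. outside [Q3 - m*IQR, Q1 + m*IQR]; with m > 1
    this band contains the interquartile range and is slightly tighter than
    Tukey's. ``fence='tukey'`` uses the classical [Q1 - m*IQR, Q3 + m*IQR].
    Quartiles use linear interpolation between order statistics (numpy's
    default quantile rule). With IQR == 0 and non-constant data, values
    differing from the median beyond an absolute tolerance are flagged;
    constant data yields no flags.
    """
    if fence not in ("cross", "tukey"):
        raise ValueError("fence must be 'cross' or 'tukey'")
    scores = np.asarray(scores, dtype=float)
    if np.sum(np.isfinite(scores)) < 4:
        raise ValueError("need at least 4 finite values")
    q1, q3 = np.quantile(scores, [0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        med = np.median(scores)
        return np.abs(scores - med) > 1e-8 * max(1.0, abs(med))
    if fence == "cross":
        lo, hi = q3 - multiplier * iqr, q1 + multiplier * iqr
    else:
        lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    return (scores < lo) | (scores > hi)


def qc_report(
    atlas: ShapeAtlas,
    meshes: list[SurfaceMesh],
    contours: list[ContourSet] | None = None,
    n_modes: int = QC_N_MODES,
    multiplier: float = IQR_MULTIPLIER,
    fence: str = "cross",
) -> pd.DataFrame:
    """Compute all four quality scores and per-score fences for a cohort.

    Returns one row per subject with columns: contour_error_mm (NaN when no
    contours given), z1..z10, mahalanobis, residual_mm, flag_* booleans and
    the overall ``excluded`` flag (OR of the per-score flags).
    """
    scores = score_shapes(atlas, meshes, align=True, n_modes=n_modes)
    z = scores_matrix(scores)
    maha = np.sqrt(np.sum(z**2, axis=1))
    resid = np.array([projection_residual(atlas, m, n_modes=n_modes) for m in meshes])
    df = pd.DataFrame({"subject_id": [m.subject_id for m in meshes]})
    if contours is not None:
        if len(contours) != len(meshes):
            raise ValueError("one contour set per mesh required")
        df["contour_error_mm"] = [
            contour_fit_error(m, c) for m, c in zip(meshes, contours)
        ]
    else:
        df["contour_error_mm"] = np.nan
    for k in range(n_modes):
        df[f"z{k + 1}"] = z[:, k]
    df["mahalanobis"] = maha
    df["residual_mm"] = resid

    flags = np.zeros(len(meshes), dtype=bool)
    if contours is not None:
        f = iqr_outlier_flags(df["contour_error_mm"].to_numpy(), multiplier, fence)
        df["flag_contour"] = f
        flags |= f
    else:
        df["flag_contour"] = False
    zflags = np.zeros(len(meshes), dtype=bool)
    for k in range(n_modes):
        zflags |= iqr_outlier_flags(z[:, k], multiplier, fence)
    df["flag_z"] = zflags
    flags |= zflags
    f_m = iqr_outlier_flags(maha, multiplier, fence)
    df["flag_mahalanobis"] = f_m
    flags |= f_m
    f_r = iqr_outlier_flags(resid, multiplier, fence)
    df["flag_residual"] = f_r
    flags |= f_r
    df["excluded"] = flags
    return df
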