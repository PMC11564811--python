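"""Statistical shape atlas: Procrustes alignment, PCA modes, Z-scores.

Alignment is rigid only — translation and rotation; scale is deliberately
not removed, so size differences remain part of the shape signal (overall
heart size is typically the first principal component). PCA of the aligned
3P shape vectors gives the atlas modes; per-subject scores are standardized
by sqrt(eigenvalue) so training-set scores have unit variance and
downstream effect sizes read as "per SD of shape mode".
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import ShapeAtlas, ShapeScores, SurfaceMesh, meshes_to_matrix

GPA_TOL_MM = 1e-9
GPA_MAX_ITER = 100


def rigid_align_pair(mesh: SurfaceMesh, reference: SurfaceMesh) -> SurfaceMesh:
    """Least-squares rigid (rotation+translation) alignment to a reference.

    Kabsch solution: SVD of the cross-covariance with a determinant sign
    correction, so the rotation is always proper (no reflection) and scale
    is never applied.
    """
    if mesh.n_points != reference.n_points:
        raise ValueError("meshes must share the same number of points")
    x = mesh.points
    y = reference.points
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0.0):
        raise ValueError("degenerate mesh: all points coincident")
    yc = y - y.mean(axis=0)
    u, _, vt = np.linalg.svd(xc.T @ yc)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u * np.array([1.0, 1.0, d])) @ vt
    aligned = xc @ rot + y.mean(axis=0)
    return SurfaceMesh(mesh.subject_id, aligned)


def generalized_procrustes(
    meshes: list[SurfaceMesh],
    tol_mm: float = GPA_TOL_MM,
    max_iter: int = GPA_MAX_ITER,
) -> tuple[list[SurfaceMesh], SurfaceMesh, int]:
    """Generalized Procrustes analysis: align all meshes to a consensus.

    Iterates aligning every mesh to the current consensus and re-averaging
    until the RMS consensus change falls below ``tol_mm``. The first mesh
    serves as the initial reference; the consensus is centered at the
    origin. Returns (aligned meshes, consensus, iterations used).
    """
    if len(meshes) < 2:
        raise ValueError("GPA needs at least 2 meshes")
    consensus = meshes[0].points - meshes[0].points.mean(axis=0)
    ref = SurfaceMesh("consensus", consensus)
    aligned = list(meshes)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        aligned = [rigid_align_pair(m, ref) for m in aligned]
        new_consensus = np.mean([m.points for m in aligned], axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        change = np.sqrt(np.mean((new_consensus - ref.points) ** 2))
        ref = SurfaceMesh("consensus", new_consensus)
        if change < tol_mm:
            break
    else:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations; returning best iterate",
            stacklevel=2,
        )
    return aligned, ref, n_iter


def build_atlas(aligned: list[SurfaceMesh]) -> ShapeAtlas:
    """PCA of aligned shape vectors via thin SVD of the centered data.

    Eigenvalues use the n-1 divisor. Each mode's sign is fixed by making
    its largest-magnitude loading positive, so atlases are reproducible
    across runs and platforms.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 shapes to build an atlas")
    x = meshes_to_matrix(aligned)
    n = x.shape[0]
    mean = x.mean(axis=0)
    xc = x - mean
    # thin SVD: stable when 3P >> n
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    modes = vt.T
    # deterministic sign convention
    flip = np.sign(modes[np.argmax(np.abs(modes), axis=0), np.arange(modes.shape[1])])
    flip[flip == 0] = 1.0
    modes = modes * flip
    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return ShapeAtlas(mean, modes, eigvals, fractions, n_train=n)


def score_shapes(
    atlas: ShapeAtlas,
    meshes: list[SurfaceMesh],
    align: bool = True,
    n_modes: int | None = None,
) -> list[ShapeScores]:
    """Project meshes onto atlas modes: z_k = v_k'(x - mu) / sqrt(lambda_k).

    With ``align`` each mesh is first rigid-aligned to the atlas mean. Only
    modes with positive eigenvalue may be requested.
    """
    k = atlas.n_modes if n_modes is None else n_modes
    if k > atlas.n_modes:
        raise ValueError("requested more modes than the atlas holds")
    lam = atlas.eigenvalues[:k]
    # eigenvalues below float round-off of the leading one are rank deficiency
    if np.any(lam <= 1e-12 * max(atlas.eigenvalues[0], 1e-300)):
        raise ValueError("zero eigenvalue among requested modes")
    mean_mesh = atlas.mean_mesh()
    out = []
    v = atlas.modes[:, :k]
    sqrt_lam = np.sqrt(lam)
    for m in meshes:
        mm = rigid_align_pair(m, mean_mesh) if align else m
        z = v.T @ (mm.as_vector() - atlas.mean_shape) / sqrt_lam
        out.append(ShapeScores(m.subject_id, z))
    return out


def scores_matrix(scores: list[ShapeScores]) -> np.ndarray:
    return np.stack([s.z for s in scores])


def select_modes(atlas: ShapeAtlas, threshold: float = 0.01) -> list[int]:
    """Indices (0-based) of modes capturing strictly more than ``threshold``
    of total variance, in order."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    return [k for k, f in enumerate(atlas.variance_fractions) if f > threshold]


def reconstruct_shape(
    atlas: ShapeAtlas,
    z: np.ndarray,
    modes: list[int] | None = None,
    subject_id: str = "reconstruction",
) -> SurfaceMesh:
    """x = mu + sum_k z_k * sqrt(lambda_k) * v_k over the listed modes.

    z = +/-2 on a single mode yields the customary "2 SD from the mean"
    extreme shapes used to visualize what a mode encodes.
    """
    z = np.asarray(z, dtype=float)
    if modes is None:
        modes = list(range(z.size))
    modes = list(modes)
    if len(modes) != z.size:
        raise ValueError("z and modes must have equal length")
    if any(m < 0 or m >= atlas.n_modes for m in modes):
        raise ValueError("mode index out of range")
    v = atlas.modes[:, modes]
    lam = atlas.eigenvalues[modes]
    x = atlas.mean_shape + v @ (z * np.sqrt(lam))
    return SurfaceMesh(subject_id, x.reshape(-1, 3))


def subgroup_variance_explained(
    atlas: ShapeAtlas,
    meshes: list[SurfaceMesh],
    modes: list[int],
    align: bool = True,
) -> float:
    """Percent of a subgroup's shape variance captured by the given modes.

    Subgroup meshes are rigid-aligned to the atlas mean; deviations are
    taken about the subgroup's own mean vector, and the captured share is
    100 * ||projection onto the mode span||^2 / ||deviations||^2 summed
    over subjects. With all nonzero modes and the training set this is
    100% by construction.
    """
    if len(meshes) == 0:
        raise ValueError("empty subgroup")
    if any(m < 0 or m >= atlas.n_modes for m in modes):
        raise ValueError("mode index out of range")
    mean_mesh = atlas.mean_mesh()
    if align:
        meshes = [rigid_align_pair(m, mean_mesh) for m in meshes]
    x = meshes_to_matrix(meshes)
    d = x - x.mean(axis=0)
    v = atlas.modes[:, modes]
    proj = d @ v
    total = float(np.sum(d**2))
    if total == 0:
        return 100.0
    return 100.0 * float(np.sum(proj**2)) / total


def align_atlas_frame(atlas: ShapeAtlas, reference: SurfaceMesh) -> ShapeAtlas:
    """Re-express an atlas in a reference mesh's coordinate frame.

    GPA fixes orientation only up to the arbitrary frame of its consensus;
    to compare modes against displacement fields defined on a template, the
    mean shape is rigid-aligned to the reference and the same rotation is
    applied to every mode (translations do not affect modes). Eigenvalues
    and scores are invariant.
    """
    mean_pts = atlas.mean_shape.reshape(-1, 3)
    x = mean_pts - mean_pts.mean(axis=0)
    y = reference.points - reference.points.mean(axis=0)
    u, _, vt = np.linalg.svd(x.T @ y)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u * np.array([1.0, 1.0, d])) @ vt
    new_mean = x @ rot + reference.points.mean(axis=0)
    new_modes = np.empty_like(atlas.modes)
    for k in range(atlas.n_modes):
        new_modes[:, k] = (atlas.modes[:, k].reshape(-1, 3) @ rot).reshape(-1)
    return ShapeAtlas(
        new_mean.reshape(-1), new_modes, atlas.eigenvalues.copy(),
        atlas.variance_fractions.copy(), atlas.n_train,
    )


def principal_angles_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Principal angles (degrees) between the column spans of u and v."""
    qu, _ = np.linalg.qr(u)
    qv, _ = np.linalg.qr(v)
    s = np.linalg.svd(qu.T @ qv, compute_uv=False)
    return np.degrees(np.arccos(np.clip(s, -1.0, 1.0)))
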