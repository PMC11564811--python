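"""Core data containers shared across the pipeline.

Shapes are stored as corresponded point sets: every subject's mesh has the
same number of points P and point ``i`` refers to the same anatomical
location on every heart. The atlas is a point-distribution model: a mean
shape plus orthonormal modes of variation obtained by PCA of the aligned
shape vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SurfaceMesh:
    """One subject's corresponded 3-D surface points, in mm."""

    subject_id: str
    points: np.ndarray  # (P, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be a (P, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("mesh coordinates must be finite")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def as_vector(self) -> np.ndarray:
        """Flatten to the 3P shape vector (x1, y1, z1, x2, ...)."""
        return self.points.reshape(-1)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class ContourSet:
    """Degraded contour points for one subject (QC input)."""

    subject_id: str
    points: np.ndarray  # (C, 3)
    source_index: np.ndarray | None = None  # mesh point each contour came from

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("contour points must be a (C, 3) array")
        if self.points.shape[0] == 0:
            raise ValueError("contour set is empty")


@dataclass
class ShapeAtlas:
    """Point-distribution model: mean shape, PCA modes, eigenvalues.

    ``modes`` columns are orthonormal 3P-vectors ordered by descending
    eigenvalue; ``variance_fractions`` are eigenvalues over the total
    variance of the training shapes about the mean.
    """

    mean_shape: np.ndarray        # (3P,)
    modes: np.ndarray             # (3P, K)
    eigenvalues: np.ndarray       # (K,) descending, >= 0
    variance_fractions: np.ndarray  # (K,)
    n_train: int

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.variance_fractions = np.asarray(self.variance_fractions, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be in descending order")

    @property
    def n_points(self) -> int:
        return self.mean_shape.size // 3

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def mean_mesh(self, subject_id: str = "mean") -> SurfaceMesh:
        return SurfaceMesh(subject_id, self.mean_shape.reshape(-1, 3))


@dataclass
class ShapeScores:
    """Per-subject PC Z-scores (unit variance on the training set)."""

    subject_id: str
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("scores must be finite")


@dataclass
class GenotypeMatrix:
    """Additive dosages, subjects x variants, in [0, 2]; NaN = missing."""

    dosages: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        valid = np.isnan(self.dosages) | (
            (self.dosages >= 0) & (self.dosages <= 2)
        )
        if not valid.all():
            raise ValueError("dosages must lie in [0, 2] or be NaN")
        if not self.subject_ids:
            self.subject_ids = [f"S{i:06d}" for i in range(self.dosages.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class AssocResult:
    """One variant-phenotype association (BETA per effect-allele copy)."""

    pc: str
    variant_id: str
    beta: float
    se: float
    p: float


@dataclass
class HeritabilityEstimate:
    """SNV heritability (or genetic correlation) with jackknife SE."""

    pc: str
    h2: float
    se: float
    method: str = "haseman-elston"


@dataclass
class MREstimate:
    """One Mendelian-randomization estimate on the effect (log-odds) scale."""

    method: str
    estimate: float
    se: float
    p: float
    n_instruments: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)


def meshes_to_matrix(meshes: list[SurfaceMesh]) -> np.ndarray:
    """Stack meshes into an (n, 3P) matrix, validating common P."""
    ps = {m.n_points for m in meshes}
    if len(ps) != 1:
        raise ValueError("all meshes must share the same number of points")
    return np.stack([m.as_vector() for m in meshes])


def variant_table(
    variant_id, chrom, pos, ea, nea, eaf,
    hwe_p=None, missing_rate=None,
) -> pd.DataFrame:
    """Assemble a variant metadata table with derived MAF."""
    eaf = np.asarray(eaf, dtype=float)
    df = pd.DataFrame(
        {
            "variant_id": variant_id,
            "chr": chrom,
            "pos": np.asarray(pos, dtype=int),
            "EA": ea,
            "NEA": nea,
            "EAF": eaf,
            "maf": np.minimum(eaf, 1.0 - eaf),
        }
    )
    if hwe_p is not None:
        df["hwe_p"] = hwe_p
    if missing_rate is not None:
        df["missing_rate"] = missing_rate
    if (df["pos"] <= 0).any():
        raise ValueError("positions are 1-based and must be positive")
    if (df["EA"] == df["NEA"]).any():
        raise ValueError("effect and non-effect alleles must differ")
    return df
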