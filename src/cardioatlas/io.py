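"""Plain-text I/O: mesh point tables, score tables, summary stats, atlas archive."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, ShapeAtlas, ShapeScores, SurfaceMesh

SUMMARY_STATS_COLUMNS = ["PC", "SNP", "CHR", "POS", "EA", "NEA", "EAF", "BETA", "SE", "P"]


def write_mesh_table(meshes: list[SurfaceMesh], path) -> None:
    """TSV with columns subject_id, point_id, x_mm, y_mm, z_mm."""
    frames = []
    for m in meshes:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": m.subject_id,
                    "point_id": np.arange(m.n_points),
                    "x_mm": m.points[:, 0],
                    "y_mm": m.points[:, 1],
                    "z_mm": m.points[:, 2],
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_mesh_table(path) -> list[SurfaceMesh]:
    df = pd.read_csv(path, sep="\t")
    meshes = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("point_id")
        meshes.append(SurfaceMesh(str(sid), grp[["x_mm", "y_mm", "z_mm"]].to_numpy()))
    return meshes


def write_scores(scores: list[ShapeScores], path) -> None:
    """TSV with subject_id, z1..zK."""
    k = scores[0].z.size
    df = pd.DataFrame([s.z for s in scores], columns=[f"z{i + 1}" for i in range(k)])
    df.insert(0, "subject_id", [s.subject_id for s in scores])
    df.to_csv(path, sep="\t", index=False)


def save_atlas(atlas: ShapeAtlas, path) -> None:
    """Single-archive atlas serialization (numpy .npz)."""
    np.savez_compressed(
        path,
        mean_shape=atlas.mean_shape,
        modes=atlas.modes,
        eigenvalues=atlas.eigenvalues,
        variance_fractions=atlas.variance_fractions,
        n_train=np.array([atlas.n_train]),
    )


def load_atlas(path) -> ShapeAtlas:
    with np.load(path) as z:
        return ShapeAtlas(
            mean_shape=z["mean_shape"],
            modes=z["modes"],
            eigenvalues=z["eigenvalues"],
            variance_fractions=z["variance_fractions"],
            n_train=int(z["n_train"][0]),
        )


def write_summary_stats(results: pd.DataFrame, path) -> None:
    """GWAS summary-stats TSV with the exact canonical header."""
    missing = [c for c in SUMMARY_STATS_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"summary stats missing columns: {missing}")
    results[SUMMARY_STATS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dosages(geno: GenotypeMatrix, variants: pd.DataFrame, path) -> None:
    """Dosage TSV, variants as rows, subjects as columns."""
    df = pd.DataFrame(geno.dosages.T, columns=geno.subject_ids)
    df.insert(0, "variant_id", variants["variant_id"].to_numpy())
    df.to_csv(path, sep="\t", index=False)


def read_dosages(path, variants: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    subject_ids = [c for c in df.columns if c != "variant_id"]
    return GenotypeMatrix(df[subject_ids].to_numpy().T, subject_ids=subject_ids)
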