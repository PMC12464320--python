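"""Plain-text and image I/O for count tables, profiles, manifests, reports.

Count tables travel as TSV with columns ``replicate``, ``concentration``,
``n_total``, ``n_positive`` (one file may hold several replicates);
resistance profiles as TSV (``concentration``, ``f_plus``, ``F_R``, ``sd``);
ground-truth manifests as CSV; images as 16-bit grayscale TIFF or 8-bit
PNG; summaries as JSON or a tables-shaped CSV (statistics x samples).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import IMICSummary
from .profiles import CountTable, ResistanceProfile
from .simulate import GroundTruthManifest

__all__ = [
    "read_count_tables",
    "write_count_tables",
    "read_manifest",
    "write_manifest",
    "write_profile",
    "read_profile",
    "save_images",
    "load_images",
    "summary_to_json",
    "summaries_to_table",
    "records_to_csv",
]

COUNT_COLUMNS = ["replicate", "concentration", "n_total", "n_positive"]


def write_count_tables(tables: list[CountTable], path: str | Path) -> None:
    frames = []
    for t in tables:
        df = t.data.copy()
        df.insert(0, "replicate", t.replicate_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_count_tables(path: str | Path, unit: str = "") -> list[CountTable]:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        CountTable(replicate_id=str(rep), data=g.drop(columns="replicate"), unit=unit)
        for rep, g in df.groupby("replicate", sort=False)
    ]


def write_manifest(manifest: GroundTruthManifest, path: str | Path) -> None:
    manifest.data.to_csv(path, index=False)


def read_manifest(path: str | Path) -> GroundTruthManifest:
    return GroundTruthManifest(data=pd.read_csv(path))


def write_profile(profile: ResistanceProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "concentration": profile.concentration,
            "f_plus": profile.f_plus,
            "F_R": profile.f_r,
            "sd": profile.f_r_sd if profile.f_r_sd is not None else np.nan,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_profile(path: str | Path, unit: str = "", sample: str = "") -> ResistanceProfile:
    df = pd.read_csv(path, sep="\t")
    sd = df["sd"].to_numpy() if "sd" in df and df["sd"].notna().all() else None
    return ResistanceProfile(
        concentration=df["concentration"].to_numpy(),
        f_plus=df["f_plus"].to_numpy(),
        f_r=df["F_R"].to_numpy(),
        f_r_sd=sd,
        unit=unit,
        sample=sample,
    )


def save_images(
    images: list[np.ndarray], directory: str | Path, fmt: str = "tiff"
) -> list[Path]:
    """Write float 0-255 grey-level frames as 16-bit TIFF or 8-bit PNG."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        if fmt == "tiff":
            import tifffile

            arr = np.clip(img / 255.0 * 65535.0, 0, 65535).astype(np.uint16)
            p = directory / f"image_{i:03d}.tiff"
            tifffile.imwrite(p, arr)
        elif fmt == "png":
            import imageio.v3 as iio

            arr = np.clip(img, 0, 255).astype(np.uint8)
            p = directory / f"image_{i:03d}.png"
            iio.imwrite(p, arr)
        else:
            raise ValueError("fmt must be 'tiff' or 'png'")
        paths.append(p)
    return paths


def load_images(directory: str | Path) -> tuple[list[np.ndarray], list[str]]:
    """Load every TIFF/PNG in a directory, sorted by filename."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")
    )
    images, ids = [], []
    for p in paths:
        if p.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            images.append(tifffile.imread(p))
        else:
            import imageio.v3 as iio

            images.append(iio.imread(p))
        ids.append(p.stem)
    return images, ids


def summary_to_json(summary: IMICSummary, path: str | Path | None = None) -> str:
    text = json.dumps(summary.to_dict(), indent=2, default=float)
    if path is not None:
        Path(path).write_text(text)
    return text


_STAT_ROWS = [
    ("imic_mode", "(iMIC)_mode"),
    ("imic_mean", "(iMIC)_mean"),
    ("imic_sd", "SD"),
    ("rmsd", "RMSD"),
    ("cov", "CoV"),
    ("imic_start", "(iMIC)_start"),
    ("imic_total", "(iMIC)_total"),
    ("imic_all", "(iMIC)_all"),
    ("imic_exp", "(iMIC)_exp"),
    ("doh", "DoH"),
    ("imic_kurtosis", "Kurtosis"),
    ("imic_skewness", "Skewness"),
]


def summaries_to_table(
    summaries: dict[str, IMICSummary], path: str | Path | None = None
) -> pd.DataFrame:
    """Statistics x samples table (rows = statistics, columns = samples)."""
    data = {}
    for name, s in summaries.items():
        d = s.to_dict()
        col = {}
        for key, row in _STAT_ROWS:
            v = d[key]
            col[row] = "ND" if v is None and key == "imic_all" else v
        data[name] = col
    df = pd.DataFrame(data)
    df.index.name = "statistic"
    if path is not None:
        df.to_csv(path)
    return df


def records_to_csv(records, path: str | Path) -> None:
    """Per-droplet classification output (images module) as CSV."""
    rows = []
    for r in records:
        dis, hom = r.feature_point if r.feature_point is not None else (np.nan, np.nan)
        rows.append(
            {
                "image": r.image_id,
                "droplet_id": r.droplet_id,
                "cx": r.center[0],
                "cy": r.center[1],
                "r": r.radius,
                "dissimilarity": dis,
                "homogeneity": hom,
                "label": r.label,
                "truth": r.truth,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
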