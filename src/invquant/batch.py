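"""Batch processing: pairing, the full per-spheroid pipeline, outlier
flagging and consolidation of per-spheroid records into one table.

A batch run maps a folder of Day-0/Day-2 image pairs through
binarization (if the input is grayscale), circular field-of-view
masking, boundary extraction, registration, outer-pixel measurement and
directionality analysis, writing one metrics row and one per-pixel CSV
per spheroid. Individual failures are recorded and the batch continues
(fail-soft), since a high-throughput run should not abort on one bad
image.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boundary as bd
from . import directionality as dr
from . import imaging_io as iio_mod
from . import metrics as mt
from .errors import ValidationError

log = logging.getLogger("invquant")

#: filename convention: <id>_<d0|day0|d2|day2>.<tif|tiff|png>
DEFAULT_PAIRING = (
    r"^(?P<id>.+?)[_-](?P<tp>[dD](?:ay)?\s?0|[dD](?:ay)?\s?2)\.(?:tif|tiff|png)$"
)

_METRIC_COLUMNS = [
    "delta_area_mm2",
    "mean_distance_mm",
    "max_distance_mm",
    "radial_moment_mm4",
]

_RECORD_COLUMNS = [
    "spheroid_id",
    "status",
    "error",
    "delta_area_mm2",
    "mean_distance_mm",
    "max_distance_mm",
    "radial_moment_mm4",
    "n_outer_pixels",
    "shrinkage",
    "angle_max_deg",
    "angle_min_deg",
    "I_max_mm4",
    "I_min_mm4",
    "Ix_mm4",
    "Iy_mm4",
    "mean_d_max_mm",
    "mean_d_min_mm",
    "fold_change_moment",
    "fold_change_distance",
    "isotropic",
]


@dataclass
class RunConfig:
    """Configuration for a batch run (mirrors the CLI flags)."""

    input_dir: str = "."
    output_dir: str = "results"
    threshold: float = 0.16
    pixel_size_um: float = 1.0
    pairing_pattern: str = DEFAULT_PAIRING
    input_binarized: bool = True
    subtract_background: bool = False
    enhance_contrast: bool = False
    circular_mask: bool = True
    correction_dir: str | None = None  # holds <id>_mask.<ext> keep-masks
    pca_origin: str = "mean"  # "mean" or "centroid"
    drop_outliers: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValidationError("threshold must be in [0, 1]")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")
        if self.pca_origin not in ("mean", "centroid"):
            raise ValidationError("pca_origin must be 'mean' or 'centroid'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def pair_images(
    input_dir: str | Path, pairing_pattern: str = DEFAULT_PAIRING
) -> tuple[list[tuple[Path, Path, str]], list[Path]]:
    """Match Day-0/Day-2 files of the same spheroid by filename.

    Returns lexicographically sorted ``(day0_path, day2_path, id)``
    triples plus the list of unmatched files. Two files claiming the
    same (id, timepoint) slot is an error.
    """
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise ValidationError(f"not a directory: {input_dir}")
    rx = re.compile(pairing_pattern)
    slots: dict[str, dict[str, Path]] = {}
    unmatched: list[Path] = []
    for path in sorted(input_dir.iterdir()):
        if not path.is_file():
            continue
        m = rx.match(path.name)
        if not m:
            unmatched.append(path)
            continue
        sid = m.group("id")
        tp = "day0" if "0" in m.group("tp") else "day2"
        if tp in slots.setdefault(sid, {}):
            raise ValidationError(
                f"ambiguous pairing: both {slots[sid][tp].name} and "
                f"{path.name} claim ({sid}, {tp})"
            )
        slots[sid][tp] = path
    pairs = []
    for sid in sorted(slots):
        tps = slots[sid]
        if "day0" in tps and "day2" in tps:
            pairs.append((tps["day0"], tps["day2"], sid))
        else:
            unmatched.extend(tps.values())
            log.warning("spheroid %s has no complete Day-0/Day-2 pair", sid)
    if not pairs:
        log.warning("no image pairs found in %s", input_dir)
    return pairs, sorted(unmatched)


def _load_pair(
    day0_path: Path, day2_path: Path, config: RunConfig
) -> tuple[iio_mod.BinaryImage, iio_mod.BinaryImage]:
    out = []
    for path, label in ((day0_path, "Day0"), (day2_path, "Day2")):
        if config.input_binarized:
            img = iio_mod.load_binary(path, config.pixel_size_um, label)
        else:
            gray = iio_mod.load_grayscale(path)
            img = iio_mod.binarize_global(
                gray,
                threshold=config.threshold,
                subtract_background_flag=config.subtract_background,
                enhance_contrast_flag=config.enhance_contrast,
                pixel_size_um=config.pixel_size_um,
                timepoint_label=label,
            )
        out.append(img)
    return out[0], out[1]


def process_images(
    day0: iio_mod.BinaryImage,
    day2: iio_mod.BinaryImage,
    spheroid_id: str = "",
    circular_mask: bool = True,
    pca_origin: str = "mean",
) -> tuple[dict, pd.DataFrame]:
    """Run the quantification pipeline on an in-memory binary pair.

    Returns the flat per-spheroid record plus the per-pixel table
    (x_px, y_px, d_mm, theta_deg, d_centroid_mm) for polar plotting.
    """
    if circular_mask:
        day0 = iio_mod.apply_circular_mask(day0)
        day2 = iio_mod.apply_circular_mask(day2)
    sph = bd.extract_spheroid_mask(day0)
    poly = bd.extract_boundary(sph)
    c2 = bd.day2_centroid(day2)
    registered = bd.register_boundary(poly, c2)
    cloud = mt.build_pixel_cloud(day2, registered)
    inv = mt.summarize_invasion(day0, day2, cloud, spheroid_id)
    record: dict = {"spheroid_id": spheroid_id, "status": "ok", "error": ""}
    record.update(dataclasses.asdict(inv))
    try:
        origin = c2 if pca_origin == "centroid" else None
        dm = dr.analyze_directionality(cloud, spheroid_id, origin=origin)
        record.update({k: v for k, v in dataclasses.asdict(dm).items() if k != "spheroid_id"})
    except Exception as exc:  # < 2 outer pixels, zero minimum direction...
        log.warning("spheroid %s: directionality skipped (%s)", spheroid_id, exc)
        record["status"] = "ok"
        record["error"] = f"directionality: {exc}"
    pixels = pd.DataFrame(
        {
            "x_px": cloud.points[:, 0],
            "y_px": cloud.points[:, 1],
            "d_mm": cloud.distances_mm,
            "theta_deg": cloud.angles_deg,
            "d_centroid_mm": cloud.centroid_distances_mm,
        }
    )
    return record, pixels


def process_pair(
    day0_path: str | Path,
    day2_path: str | Path,
    spheroid_id: str,
    config: RunConfig,
) -> tuple[dict, pd.DataFrame | None]:
    """Load, correct and quantify one image pair; fail-soft on error."""
    try:
        day0, day2 = _load_pair(Path(day0_path), Path(day2_path), config)
        if config.correction_dir:
            for ext in ("png", "tif", "tiff"):
                mask_path = Path(config.correction_dir) / f"{spheroid_id}_mask.{ext}"
                if mask_path.exists():
                    keep = iio_mod.load_correction_mask(mask_path)
                    day0 = iio_mod.apply_correction_mask(day0, keep)
                    day2 = iio_mod.apply_correction_mask(day2, keep)
                    break
        return process_images(
            day0,
            day2,
            spheroid_id,
            circular_mask=config.circular_mask,
            pca_origin=config.pca_origin,
        )
    except Exception as exc:
        log.error("spheroid %s failed: %s", spheroid_id, exc)
        record = {"spheroid_id": spheroid_id, "status": "error", "error": str(exc)}
        return record, None


def mad_outlier_filter(
    values, k: float = 3.0
) -> tuple[np.ndarray, list[int]]:
    """Flag values more than k scaled MADs from the median.

    Scaled MAD = 1.4826 * median(|x - median(x)|), the normal-consistent
    robust spread estimate. When the scaled MAD is zero (over half the
    values identical), anything differing from the median is removed.
    Returns (kept values, removed indices).
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("cannot filter an empty list")
    med = np.median(x)
    smad = 1.4826 * np.median(np.abs(x - med))
    if smad == 0:
        removed = np.flatnonzero(x != med)
    else:
        removed = np.flatnonzero(np.abs(x - med) > k * smad)
    keep = np.setdiff1d(np.arange(x.size), removed)
    return x[keep], removed.tolist()


def consolidate(records: list[dict], mad_k: float = 3.0) -> pd.DataFrame:
    """Compile per-spheroid records into one table with outlier flags.

    Every record is preserved (error rows keep their status); outliers
    are flagged per metric column via the scaled-MAD rule, never
    silently dropped.
    """
    df = pd.DataFrame.from_records(records)
    for col in _RECORD_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[_RECORD_COLUMNS]
    if df["spheroid_id"].duplicated().any():
        dupes = df.loc[df["spheroid_id"].duplicated(), "spheroid_id"].tolist()
        raise ValidationError(f"duplicate spheroid ids: {dupes}")
    ok = df["status"] == "ok"
    any_outlier = np.zeros(len(df), dtype=bool)
    for col in _METRIC_COLUMNS:
        flag = np.zeros(len(df), dtype=bool)
        vals = df.loc[ok, col].to_numpy(dtype=float)
        if len(vals) and np.isfinite(vals).all():
            _, removed = mad_outlier_filter(vals, k=mad_k)
            idx = np.flatnonzero(ok.to_numpy())[removed]
            flag[idx] = True
        df[f"outlier_{col}"] = flag
        any_outlier |= flag
    df["outlier"] = any_outlier
    return df


def run_batch(config: RunConfig) -> pd.DataFrame:
    """Process every pair in ``config.input_dir`` and write all outputs.

    Writes metrics.csv (consolidated table), directionality.csv (the
    directional columns), pixels/<id>.csv and a JSON run manifest under
    ``config.output_dir``; returns the consolidated table.
    """
    import json

    from . import __version__

    out_dir = Path(config.output_dir)
    (out_dir / "pixels").mkdir(parents=True, exist_ok=True)
    pairs, unmatched = pair_images(config.input_dir, config.pairing_pattern)
    records = []
    for day0_path, day2_path, sid in pairs:
        record, pixels = process_pair(day0_path, day2_path, sid, config)
        records.append(record)
        if pixels is not None:
            pixels.to_csv(out_dir / "pixels" / f"{sid}.csv", index=False, float_format="%.6g")
    table = consolidate(records)
    if config.drop_outliers:
        table = table[~table["outlier"]].reset_index(drop=True)
    table.to_csv(out_dir / "metrics.csv", index=False, float_format="%.8g")
    dir_cols = ["spheroid_id", "angle_max_deg", "angle_min_deg", "I_max_mm4",
                "I_min_mm4", "Ix_mm4", "Iy_mm4", "mean_d_max_mm", "mean_d_min_mm",
                "fold_change_moment", "fold_change_distance", "isotropic"]
    table[dir_cols].to_csv(out_dir / "directionality.csv", index=False, float_format="%.8g")
    manifest = {
        "invquant_version": __version__,
        "config": config.to_dict(),
        "n_pairs": len(pairs),
        "unmatched_files": [p.name for p in unmatched],
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return table
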