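"""File formats: TIFF images, trace files, and the pipeline's CSV schemas.

All CSVs are UTF-8, header row, "." decimal separator, floats written with
up to 10 significant digits (``%.10g``) so repeated runs are byte-identical.

Schemas
-------
profile CSV      position_um, intensity, excluded
truth CSV        position_um, amplitude
quant CSV        animal_id, genotype, pn, se, total_pf, total_ipf, avg_ipf,
                 window_start_um, window_end_um, flags   (flags ';'-joined)
puncta CSV       animal_id, peak_position_um, peak_intensity, ratio,
                 extent_start_um, extent_end_um
summary CSV      genotype, metric, n, mean, sd
comparisons CSV  group_a, group_b, metric, t_stat, df, p_value, label
trace JSON       list of [x, y] pixel pairs; trace CSV: two columns x, y
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .profiles import IntensityProfile, Polyline
from .quant import ProfileQuant
from .synthetic import GenotypePreset, SceneTruth

__all__ = [
    "read_image",
    "write_image",
    "read_trace",
    "write_trace",
    "read_profile",
    "write_profile",
    "write_truth",
    "quant_row",
    "write_quants",
    "read_quants",
    "write_puncta",
    "preset_to_dict",
    "preset_from_dict",
    "write_presets",
    "read_presets",
]

FLOAT_FMT = "%.10g"


def _write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_image(path) -> np.ndarray:
    """Read a single-plane grayscale TIFF (8- or 16-bit) as float."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-plane grayscale TIFF, got shape {arr.shape} "
            "(RGB or multi-plane images are not supported)"
        )
    return np.asarray(arr, dtype=float)


def write_image(image: np.ndarray, path) -> None:
    """Write a float image as 16-bit grayscale TIFF (clipped to [0, 65535])."""
    arr = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)


def read_trace(path) -> Polyline:
    """Read a cord trace: JSON list of [x, y] pairs, or a 2-column CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        verts = np.asarray(data, dtype=float)
    else:
        df = pd.read_csv(path)
        if df.shape[1] != 2:
            raise ValueError(f"{path}: trace CSV must have exactly two columns (x, y)")
        verts = df.to_numpy(dtype=float)
    return Polyline(vertices=verts)


def write_trace(trace: Polyline, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps([[float(x), float(y)] for x, y in trace.vertices]))
    else:
        _write_csv(pd.DataFrame(trace.vertices, columns=["x", "y"]), path)


def write_profile(profile: IntensityProfile, path) -> None:
    _write_csv(
        pd.DataFrame(
            {
                "position_um": profile.positions_um,
                "intensity": profile.intensities,
                "excluded": profile.exclude_mask.astype(int),
            }
        ),
        path,
    )


def read_profile(path) -> IntensityProfile:
    """Read a profile CSV, validating monotone uniformly spaced positions."""
    df = pd.read_csv(path)
    required = {"position_um", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: profile CSV needs columns {sorted(required)}")
    pos = df["position_um"].to_numpy(dtype=float)
    if pos.size > 1 and np.any(np.diff(pos) <= 0):
        raise ValueError(f"{path}: positions must be strictly increasing")
    mask = (
        df["excluded"].to_numpy(dtype=bool)
        if "excluded" in df.columns
        else np.zeros(pos.size, dtype=bool)
    )
    spacing = float(np.median(np.diff(pos))) if pos.size > 1 else 1.0
    return IntensityProfile(
        positions_um=pos,
        intensities=df["intensity"].to_numpy(dtype=float),
        pixel_size_um=spacing,
        exclude_mask=mask,
    )


def write_truth(truth: SceneTruth, path) -> None:
    _write_csv(
        pd.DataFrame(
            {
                "position_um": np.asarray(truth.punctum_positions_um, dtype=float),
                "amplitude": np.asarray(truth.punctum_amplitudes, dtype=float),
            }
        ),
        path,
    )


def quant_row(quant: ProfileQuant, animal_id: str, genotype: str = "") -> dict:
    return {
        "animal_id": animal_id,
        "genotype": genotype,
        "pn": quant.pn,
        "se": quant.se,
        "total_pf": quant.total_pf,
        "total_ipf": quant.total_ipf,
        "avg_ipf": quant.avg_ipf,
        "window_start_um": quant.window_um[0],
        "window_end_um": quant.window_um[1],
        "flags": ";".join(sorted(quant.flags)),
    }


def write_quants(rows: list[dict], path) -> None:
    _write_csv(pd.DataFrame(rows), path)


def read_quants(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=["nan", ""])
    return df


def write_puncta(quants: list[tuple[str, ProfileQuant]], path) -> None:
    rows = []
    for animal_id, q in quants:
        for p in q.puncta:
            rows.append(
                {
                    "animal_id": animal_id,
                    "peak_position_um": p.peak_position_um,
                    "peak_intensity": p.peak_intensity,
                    "ratio": p.ratio,
                    "extent_start_um": p.extent_um[0],
                    "extent_end_um": p.extent_um[1],
                }
            )
    cols = [
        "animal_id",
        "peak_position_um",
        "peak_intensity",
        "ratio",
        "extent_start_um",
        "extent_end_um",
    ]
    _write_csv(pd.DataFrame(rows, columns=cols), path)


def preset_to_dict(preset: GenotypePreset) -> dict:
    return {
        "name": preset.name,
        "punctum_density": preset.punctum_density,
        "amplitude_mean": preset.amplitude_mean,
        "amplitude_sd": preset.amplitude_sd,
        "punctum_sigma_um": preset.punctum_sigma_um,
        "diffuse_level": preset.diffuse_level,
        "camera_offset": preset.camera_offset,
        "noise_gain": preset.noise_gain,
        "read_noise_sd": preset.read_noise_sd,
        "soma_fraction": preset.soma_fraction,
        "soma_sigma_um": preset.soma_sigma_um,
    }


def preset_from_dict(d: dict) -> GenotypePreset:
    return GenotypePreset(**d)


def write_presets(presets: list[GenotypePreset], path) -> None:
    Path(path).write_text(yaml.safe_dump([preset_to_dict(p) for p in presets], sort_keys=False))


def read_presets(path) -> list[GenotypePreset]:
    data = yaml.safe_load(Path(path).read_text())
    return [preset_from_dict(d) for d in data]
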