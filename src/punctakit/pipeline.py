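"""End-to-end reproducible runs: simulate → extract → quantify → compare.

A run is described by a :class:`RunConfig`; :func:`run_pipeline` executes
every stage, writes all intermediate artifacts, and records a manifest
(config, per-animal seeds, package version, file list). Re-running from the
manifest reproduces every output byte for byte: all randomness descends
from the run seed through per-animal seed-sequence children.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .profiles import Polyline, extract_profile
from .quant import QuantParams, quantify_animal
from .stats import compare_frame, summarize_frame
from .synthetic import get_preset, make_image, make_profile

logger = logging.getLogger("punctakit")

__all__ = ["RunConfig", "run_pipeline", "load_manifest_config"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run.

    ``mode`` selects 1D simulation (``"profile"``, default — quantification
    operates on line scans either way) or 2D rendering plus profile
    extraction (``"image"``). ``reference`` names the genotype all others
    are compared against.
    """

    presets: tuple[str, ...] = ("wild_type", "diffuse_mutant", "enlarged_puncta", "soma_retention")
    n_animals: int = 20
    length_um: float = 110.0
    pixel_size_um: float = 0.1
    seed: int = 1
    params: QuantParams = field(default_factory=QuantParams)
    mode: str = "profile"
    reference: str = "wild_type"
    metrics: tuple[str, ...] = ("se", "pn")
    image_height_px: int = 40
    half_width_px: int = 2
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {
            "presets": list(self.presets),
            "n_animals": self.n_animals,
            "length_um": self.length_um,
            "pixel_size_um": self.pixel_size_um,
            "seed": self.seed,
            "mode": self.mode,
            "reference": self.reference,
            "metrics": list(self.metrics),
            "image_height_px": self.image_height_px,
            "half_width_px": self.half_width_px,
            "log_level": self.log_level,
            "params": {
                "ratio_threshold": self.params.ratio_threshold,
                "window_length_um": self.params.window_length_um,
                "min_separation_um": self.params.min_separation_um,
                "min_prominence": self.params.min_prominence,
                "extent_rule": self.params.extent_rule,
                "max_iterations": self.params.max_iterations,
                "window_offset_um": self.params.window_offset_um,
                "smooth_window_um": self.params.smooth_window_um,
                "subtract_offset": self.params.subtract_offset,
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        params = QuantParams(**d.pop("params", {}))
        d["presets"] = tuple(d.get("presets", ()))
        d["metrics"] = tuple(d.get("metrics", ("se", "pn")))
        return cls(params=params, **d)


def animal_seed(run_seed: int, preset_index: int, animal_index: int) -> int:
    """Deterministic per-animal seed derived from the run seed."""
    ss = np.random.SeedSequence([run_seed, preset_index, animal_index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _straight_trace(length_um: float, pixel_size_um: float, height_px: int) -> Polyline:
    n_cols = int(round(length_um / pixel_size_um)) + 1
    y = height_px / 2.0
    return Polyline(vertices=np.array([[0.0, y], [n_cols - 1.0, y]]))


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute a full run into ``outdir`` and return the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(outdir)
    (out / "profiles").mkdir(parents=True, exist_ok=True)
    (out / "truths").mkdir(exist_ok=True)
    if config.mode == "image":
        (out / "images").mkdir(exist_ok=True)
    elif config.mode != "profile":
        raise ValueError(f"unknown mode {config.mode!r}")

    quant_rows: list[dict] = []
    puncta_records = []
    animals: list[dict] = []
    for pi, preset_name in enumerate(config.presets):
        preset = get_preset(preset_name)
        logger.info("simulating %d %s animals", config.n_animals, preset_name)
        for ai in range(config.n_animals):
            seed = animal_seed(config.seed, pi, ai)
            animal_id = f"{preset_name}_{ai:03d}"
            try:
                if config.mode == "image":
                    trace = _straight_trace(
                        config.length_um, config.pixel_size_um, config.image_height_px
                    )
                    n_cols = int(round(config.length_um / config.pixel_size_um)) + 1
                    image, truth = make_image(
                        preset,
                        (config.image_height_px, n_cols),
                        trace,
                        config.pixel_size_um,
                        seed,
                    )
                    io.write_image(image, out / "images" / f"{animal_id}.tif")
                    profile = extract_profile(
                        image, trace, config.pixel_size_um, config.half_width_px
                    )
                else:
                    profile, truth = make_profile(
                        preset, config.length_um, config.pixel_size_um, seed
                    )
                io.write_profile(profile, out / "profiles" / f"{animal_id}.csv")
                io.write_truth(truth, out / "truths" / f"{animal_id}.csv")
                quant = quantify_animal(profile, config.params)
            except Exception as exc:  # pragma: no cover - defensive abort
                raise RuntimeError(
                    f"pipeline stage failed for animal {animal_id} (preset {preset_name}): {exc}"
                ) from exc
            quant_rows.append(io.quant_row(quant, animal_id, genotype=preset_name))
            puncta_records.append((animal_id, quant))
            animals.append({"animal_id": animal_id, "preset": preset_name, "seed": seed})

    io.write_quants(quant_rows, out / "quant.csv")
    io.write_puncta(puncta_records, out / "puncta.csv")

    quant_df = pd.DataFrame(quant_rows)
    summaries = pd.concat(
        [summarize_frame(quant_df, m) for m in config.metrics], ignore_index=True
    )
    summaries.to_csv(out / "summary.csv", index=False, float_format=io.FLOAT_FMT)
    comparisons = pd.concat(
        [compare_frame(quant_df, m, config.reference) for m in config.metrics],
        ignore_index=True,
    )
    comparisons.to_csv(out / "comparisons.csv", index=False, float_format=io.FLOAT_FMT)

    files = ["quant.csv", "puncta.csv", "summary.csv", "comparisons.csv"]
    files += [f"profiles/{a['animal_id']}.csv" for a in animals]
    files += [f"truths/{a['animal_id']}.csv" for a in animals]
    if config.mode == "image":
        files += [f"images/{a['animal_id']}.tif" for a in animals]
    manifest = {
        "punctakit_version": __version__,
        "config": config.to_dict(),
        "animals": animals,
        "files": sorted(files),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete: %d animals, outputs in %s", len(animals), out)
    return manifest


def load_manifest_config(path) -> RunConfig:
    """Recover the RunConfig recorded in a manifest for an identical rerun."""
    manifest = json.loads(Path(path).read_text())
    return RunConfig.from_dict(manifest["config"])
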