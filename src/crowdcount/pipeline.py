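"""End-to-end pipeline stages wired to files on disk.

Each stage is a pure function of (config, seed, upstream files): tile the
synthetic island, simulate volunteer classifications, collapse them to
consensus counts, and validate against the expert table. The CLI wraps
these; tests and the acceptance script call them directly. In synthetic
mode the expert table is the ground truth itself — the expert is modeled
as error-free, which is what makes the simulated error budget attributable
entirely to volunteer behavior.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ccio
from .aggregation import aggregate_all
from .synthetic import (
    ColonyConfig,
    VolunteerModel,
    generate_colony,
    marks_to_counts,
    simulate_classifications,
)
from .tiling import (
    MosaicSpec,
    assign_animals_to_tiles,
    filter_blank_tiles,
    tile_mosaic,
)
from .validation import validate

log = logging.getLogger(__name__)

__all__ = ["build_mosaic", "run_tile", "run_simulate", "run_aggregate", "run_validate", "run_all"]

MANIFEST = "manifest.csv"
CLASSIFICATIONS = "classifications.csv"
EXPERT = "expert_counts.csv"
CONSENSUS = "consensus.csv"


def build_mosaic(config: ccio.RunConfig) -> MosaicSpec:
    """Synthetic island: an elliptical content region inside the mosaic.

    The ellipse covers roughly half the frame, so the tiling stage has
    genuine blank (open-water) tiles to filter, as a real island mosaic
    does.
    """
    w, h = config.mosaic_width, config.mosaic_height
    cx, cy = w / 2.0, h / 2.0
    dx2 = (((np.arange(w, dtype=np.float32) - cx) / (0.45 * w)) ** 2)[None, :]
    dy2 = (((np.arange(h, dtype=np.float32) - cy) / (0.42 * h)) ** 2)[:, None]
    mask = dx2 + dy2 <= 1.0
    return MosaicSpec(width=w, height=h, flight_id=config.flight_id, content_mask=mask)


def _require(path: Path, producer: str) -> None:
    if not path.exists():
        raise FileNotFoundError(
            f"missing input {path}; run the '{producer}' stage first to produce it"
        )


def run_tile(config: ccio.RunConfig, out_dir: str | Path) -> Path:
    """Tile the mosaic, flag blank tiles, write the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mosaic = build_mosaic(config)
    tiles = filter_blank_tiles(tile_mosaic(mosaic, config.tile_size), mosaic)
    path = out / MANIFEST
    ccio.write_manifest(tiles, path)
    log.info("wrote %s (%d tiles, %d blank)", path, len(tiles), sum(t.is_blank for t in tiles))
    return path


def run_simulate(config: ccio.RunConfig, out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Generate the colony, simulate volunteer counting, write truth + marks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    mosaic = build_mosaic(config)
    tiles = filter_blank_tiles(tile_mosaic(mosaic, config.tile_size), mosaic)
    ccio.write_manifest(tiles, out / MANIFEST)

    colony = ColonyConfig(seed=seed, **dict(config.colony))
    animals = generate_colony(mosaic, colony)
    active = [t for t in tiles if not t.is_blank]
    truth = assign_animals_to_tiles(animals, tiles)
    active_truth = {t.tile_id: truth[t.tile_id] for t in active}

    model = VolunteerModel(species=config.species, seed=seed + 1, **dict(config.volunteers))
    annotations = simulate_classifications(
        active_truth, model, config.retirement_policy(),
        tiles=tiles, animals=animals, seed=seed + 1,
    )
    ccio.write_classifications(annotations, out / CLASSIFICATIONS)

    expert = [
        ccio.ExpertCount(
            tile_id=t.tile_id,
            species=s,
            count=truth[t.tile_id].get(s, 0),
            flight_id=config.flight_id,
        )
        for t in active
        for s in config.species
    ]
    ccio.write_expert_counts(expert, out / EXPERT)
    log.info(
        "simulated %d animals on %d occupied tiles; %d annotation rows",
        len(animals), sum(bool(v) for v in active_truth.values()), len(annotations),
    )
    return {"manifest": out / MANIFEST, "classifications": out / CLASSIFICATIONS, "expert": out / EXPERT}


def run_aggregate(config: ccio.RunConfig, out_dir: str | Path) -> Path:
    """Collapse the classification export into consensus counts."""
    out = Path(out_dir)
    cls_path = out / CLASSIFICATIONS
    _require(cls_path, "simulate")
    annotations = ccio.read_classifications(cls_path, species=config.species)
    counts = marks_to_counts(annotations, species=config.species, flight_id=config.flight_id)
    consensus = aggregate_all(counts, config.algorithms)
    path = out / CONSENSUS
    consensus.to_csv(path, index=False)
    log.info("wrote %s (%d consensus rows)", path, len(consensus))
    return path


def run_validate(config: ccio.RunConfig, out_dir: str | Path):
    """Compare consensus to expert counts and write the report tables."""
    out = Path(out_dir)
    _require(out / CONSENSUS, "aggregate")
    _require(out / EXPERT, "simulate")
    consensus = pd.read_csv(out / CONSENSUS)
    expert = ccio.expert_frame(ccio.read_expert_counts(out / EXPERT))
    report = validate(consensus, expert)
    ccio.write_report(report, out / "report", config=config)
    return report


def run_all(config: ccio.RunConfig, out_dir: str | Path, seed: int | None = None):
    """simulate -> aggregate -> validate, in one call."""
    run_simulate(config, out_dir, seed=seed)
    run_aggregate(config, out_dir)
    return run_validate(config, out_dir)
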