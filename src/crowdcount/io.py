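"""Tabular interchange formats for the counting pipeline.

Canonical files are plain CSV so they diff, version and round-trip cleanly:

* **classifications** — one row per mark: ``classification_id,
  volunteer_id, tile_id, species, x, y``. A classification that found no
  animals appears as a single sentinel row with ``species="__none__"`` and
  empty coordinates, keeping zero counts explicit. Project-specific export
  dialects (e.g. platforms that nest marks in a JSON column) are handled by
  converting to this canonical schema first; ``read_classifications``
  accepts a ``converter`` hook for that.
* **expert counts** — ``flight_id, tile_id, species, count``.
* **tile manifest** — ``flight_id, tile_id, x0, y0, x1, y1, is_blank``.
* **run config** — YAML (or JSON) validated into :class:`RunConfig`.

Anonymous volunteers are supported: rows with a missing/empty volunteer id
are assigned session-scoped pseudo-identifiers keyed on the classification
id, so repeated marks within one anonymous classification stay grouped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .aggregation import ALGORITHMS
from .synthetic import Annotation, DEFAULT_SPECIES, EMPTY_SENTINEL, RetirementPolicy
from .tiling import DEFAULT_TILE_SIZE, Tile

log = logging.getLogger(__name__)

CLASSIFICATION_COLUMNS = ["classification_id", "volunteer_id", "tile_id", "species", "x", "y"]
EXPERT_COLUMNS = ["flight_id", "tile_id", "species", "count"]

__all__ = [
    "ExpertCount",
    "RunConfig",
    "read_classifications",
    "write_classifications",
    "read_expert_counts",
    "write_expert_counts",
    "read_manifest",
    "write_manifest",
    "load_config",
    "write_report",
]


@dataclass(frozen=True)
class ExpertCount:
    """The expert's count for one (tile, species)."""

    tile_id: str
    species: str
    count: int
    flight_id: str = "flight"

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"expert count must be >= 0, got {self.count} on {self.tile_id}")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; defaults mirror the study design.

    700-px tiles, retirement at 15 classifications or 7 empties, two
    pinniped species, all six consensus algorithms.
    """

    tile_size: int = DEFAULT_TILE_SIZE
    species: tuple[str, ...] = DEFAULT_SPECIES
    full_limit: int = 15
    empty_limit: int = 7
    empty_mode: str = "total"
    algorithms: tuple[str, ...] = ALGORITHMS
    seed: int = 0
    # synthetic-island geometry (demo scale: 70 tiles)
    mosaic_width: int = 7000
    mosaic_height: int = 4900
    flight_id: str = "flight"
    # colony + volunteer-model parameters, passed through to synthetic mode
    colony: Mapping[str, object] = field(default_factory=dict)
    volunteers: Mapping[str, object] = field(default_factory=dict)
    out_dir: str = "results"

    def __post_init__(self) -> None:
        bad = [a for a in self.algorithms if a not in ALGORITHMS]
        if bad:
            raise ValueError(
                f"unknown algorithm names {bad}; valid names: {', '.join(ALGORITHMS)}"
            )
        RetirementPolicy(self.full_limit, self.empty_limit, self.empty_mode)

    def retirement_policy(self) -> RetirementPolicy:
        return RetirementPolicy(self.full_limit, self.empty_limit, self.empty_mode)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML/JSON run configuration; omitted keys take study defaults."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for tup_key in ("species", "algorithms"):
        if tup_key in data:
            data[tup_key] = tuple(data[tup_key])
    return RunConfig(**data)


def write_classifications(annotations: Iterable[Annotation], path: str | Path) -> None:
    rows = [
        (a.classification_id, a.volunteer_id, a.tile_id, a.species,
         "" if np.isnan(a.x) else a.x, "" if np.isnan(a.y) else a.y)
        for a in annotations
    ]
    pd.DataFrame(rows, columns=CLASSIFICATION_COLUMNS).to_csv(path, index=False)


def read_classifications(
    path: str | Path,
    species: Sequence[str] = DEFAULT_SPECIES,
    species_map: Mapping[str, str] | None = None,
    converter: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
) -> list[Annotation]:
    """Read a classification export into mark records.

    Parameters
    ----------
    path : path
        CSV with the canonical columns (see module docstring).
    species : sequence of str
        The configured species set; labels outside it are rejected.
    species_map : mapping, optional
        Renames export labels to configured ones before validation
        (e.g. ``{"elephant seal": "seal"}``).
    converter : callable, optional
        Hook that maps a project-specific export DataFrame onto the
        canonical schema before parsing.
    """
    df = pd.read_csv(path, dtype={"x": float, "y": float})
    if converter is not None:
        df = converter(df)
    missing = [c for c in CLASSIFICATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"classification file missing required columns: {missing}")
    if df.empty:
        log.warning("classification file %s has no rows", path)
        return []

    # session-scoped pseudo-ids for anonymous volunteers
    df["volunteer_id"] = df["volunteer_id"].astype("object")
    anon = df["volunteer_id"].isna() | (df["volunteer_id"].astype(str).str.strip() == "")
    if anon.any():
        pseudo = "anon-" + df.loc[anon, "classification_id"].astype(str)
        df.loc[anon, "volunteer_id"] = pseudo

    if species_map:
        df["species"] = df["species"].replace(dict(species_map))
    valid = set(species) | {EMPTY_SENTINEL}
    unknown = sorted(set(df["species"].dropna()) - valid)
    if unknown:
        raise ValueError(
            f"unknown species labels {unknown}; map them via species_map or extend the species set"
        )

    out: list[Annotation] = []
    skipped = 0
    for row in df.itertuples(index=False):
        sp = row.species
        if sp != EMPTY_SENTINEL and (pd.isna(row.x) or pd.isna(row.y)):
            skipped += 1
            continue
        out.append(
            Annotation(
                volunteer_id=str(row.volunteer_id),
                tile_id=str(row.tile_id),
                species=str(sp),
                x=float(row.x) if not pd.isna(row.x) else float("nan"),
                y=float(row.y) if not pd.isna(row.y) else float("nan"),
                classification_id=str(row.classification_id),
            )
        )
    if skipped:
        log.warning("skipped %d malformed mark rows (missing coordinates)", skipped)
    return out


def write_expert_counts(counts: Iterable[ExpertCount] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(counts, pd.DataFrame):
        df = counts[EXPERT_COLUMNS]
    else:
        df = pd.DataFrame(
            [(c.flight_id, c.tile_id, c.species, c.count) for c in counts],
            columns=EXPERT_COLUMNS,
        )
    df.to_csv(path, index=False)


def read_expert_counts(path: str | Path) -> list[ExpertCount]:
    df = pd.read_csv(path)
    missing = [c for c in EXPERT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expert count file missing required columns: {missing}")
    if (df["count"] < 0).any():
        bad = df.loc[df["count"] < 0, "tile_id"].tolist()
        raise ValueError(f"negative expert counts on tiles {bad}")
    dup = df.duplicated(subset=["flight_id", "tile_id", "species"])
    if dup.any():
        bad = sorted(df.loc[dup, "tile_id"].unique())
        raise ValueError(f"duplicate (tile, species) expert rows for tiles {bad}")
    return [
        ExpertCount(
            tile_id=str(r.tile_id),
            species=str(r.species),
            count=int(r.count),
            flight_id=str(r.flight_id),
        )
        for r in df.itertuples(index=False)
    ]


def expert_frame(counts: Iterable[ExpertCount]) -> pd.DataFrame:
    """Expert records as the tabular frame the validation module consumes."""
    return pd.DataFrame(
        [(c.flight_id, c.tile_id, c.species, c.count) for c in counts],
        columns=EXPERT_COLUMNS,
    )


def write_manifest(tiles: Sequence[Tile], path: str | Path) -> None:
    from .tiling import manifest_frame

    manifest_frame(tiles).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[Tile]:
    df = pd.read_csv(path)
    return [
        Tile(
            tile_id=str(r.tile_id),
            x0=int(r.x0),
            y0=int(r.y0),
            x1=int(r.x1),
            y1=int(r.y1),
            flight_id=str(r.flight_id),
            is_blank=bool(r.is_blank),
        )
        for r in df.itertuples(index=False)
    ]


def write_report(report, out_dir: str | Path, config: RunConfig | None = None) -> dict[str, Path]:
    """Write a validation report as one CSV per table plus a JSON summary.

    Returns the mapping of table name -> written path. The summary embeds
    the config hash and seed when a config is supplied, so every output is
    traceable to the run that produced it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, frame in report.tables().items():
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        written[name] = p
    summary = report.summary()
    if config is not None:
        summary["config_hash"] = config.config_hash()
        summary["seed"] = config.seed
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2, default=float))
    written["summary"] = p
    return written
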