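"""Synthetic colonies and simulated volunteer counting behavior.

This module generates everything the downstream pipeline consumes, with the
statistical structure a pinniped haul-out census actually shows:

* **Per-tile true counts are overdispersed and low-median.** Most occupied
  tiles hold a handful of animals while a few dense haul-outs hold dozens
  (observed per-tile structure: seals median 2, mean 6, SD 12; sea lions
  median 5, mean 12, SD 19). The generator reaches this either spatially
  (clustered point process) or directly (negative-binomial tile counts).
* **Volunteers undercount.** Each volunteer detects each animal
  independently with probability ``p_detect`` < 1.
* **Species get confused.** A detected animal's label is drawn from a
  row-stochastic confusion matrix (seals mislabeled as sea lions being the
  empirically dominant confusion).
* **Sparse false positives.** Rocks and shadows attract an expected
  ``fp_rate`` spurious marks per classification.
* **Heavy-tailed volunteer activity.** A log-normal effort distribution
  makes a few volunteers do most of the counting, as crowd-sourced projects
  always show.
* **Retirement rules.** A tile stops being served after ``full_limit``
  classifications (default 15) or once ``empty_limit`` of them (default 7)
  reported no animals.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tiling import AnimalInstance, MosaicSpec, Tile, animals_by_tile

DEFAULT_SPECIES: tuple[str, ...] = ("seal", "sea_lion")
EMPTY_SENTINEL = "__none__"

__all__ = [
    "DEFAULT_SPECIES",
    "EMPTY_SENTINEL",
    "ColonyConfig",
    "VolunteerModel",
    "RetirementPolicy",
    "Annotation",
    "generate_colony",
    "sample_tile_counts",
    "simulate_classifications",
    "simulate_count_matrix",
    "marks_to_counts",
]


@dataclass(frozen=True)
class ColonyConfig:
    """How many animals of each species to place, and where.

    ``species_abundance`` gives the expected total per species over the
    whole mosaic; realized totals are Poisson around it. ``clustered``
    placement draws log-normal cluster weights so per-tile counts come out
    overdispersed (variance well above the mean), matching real haul-outs.
    ``occupancy_fraction`` restricts placement to a random subset of
    non-blank tiles, controlling how many tiles hold any animals at all.
    """

    species_abundance: Mapping[str, float] = field(
        default_factory=lambda: {"seal": 6.0 * 35, "sea_lion": 12.0 * 35}
    )
    spatial_model: str = "clustered"
    cluster_count: int = 12
    cluster_spread: float = 350.0
    occupancy_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.species_abundance.values()):
            raise ValueError("species abundances must be >= 0")
        if not 0.0 <= self.occupancy_fraction <= 1.0:
            raise ValueError("occupancy_fraction must lie in [0, 1]")
        if self.spatial_model not in ("uniform", "clustered"):
            raise ValueError("spatial_model must be 'uniform' or 'clustered'")
        if self.cluster_count < 1:
            raise ValueError("cluster_count must be >= 1")


@dataclass(frozen=True)
class VolunteerModel:
    """Stochastic model of one volunteer classification.

    Parameters
    ----------
    p_detect : float or mapping species -> float
        Per-animal detection probability.
    confusion : mapping species -> mapping species -> float, optional
        Row-stochastic mislabel matrix; identity if omitted.
    fp_rate : float
        Expected spurious marks per classification (Poisson).
    fp_species_probs : mapping, optional
        Species distribution of false-positive marks; uniform if omitted.
    count_jitter : float
        SD of extra integer noise added to each per-species mark count
        (0 disables it).
    activity_sigma : float
        Log-sigma of the log-normal effort weights across the volunteer
        pool; ~1.5 reproduces the observed pattern where a handful of
        volunteers contribute a large share of all classifications.
    mark_jitter_px : float
        Gaussian SD of mark placement around the true head pixel.
    """

    p_detect: float | Mapping[str, float] = 0.85
    confusion: Mapping[str, Mapping[str, float]] | None = None
    fp_rate: float = 0.05
    fp_species_probs: Mapping[str, float] | None = None
    count_jitter: float = 0.0
    activity_sigma: float = 1.5
    n_volunteers: int = 200
    mark_jitter_px: float = 5.0
    species: tuple[str, ...] = DEFAULT_SPECIES
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.species:
            p = self.detect_prob(s)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_detect for {s!r} must be in [0, 1], got {p}")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")
        if self.n_volunteers < 1:
            raise ValueError("volunteer pool must be non-empty")
        for row in self.confusion_matrix():
            if abs(row.sum() - 1.0) > 1e-9:
                raise ValueError("each confusion row must sum to 1")

    def detect_prob(self, species: str) -> float:
        if isinstance(self.p_detect, Mapping):
            return float(self.p_detect[species])
        return float(self.p_detect)

    def confusion_matrix(self) -> np.ndarray:
        k = len(self.species)
        mat = np.eye(k)
        if self.confusion is not None:
            for i, s in enumerate(self.species):
                if s in self.confusion:
                    mat[i] = [self.confusion[s].get(t, 0.0) for t in self.species]
        return mat

    def fp_probs(self) -> np.ndarray:
        if self.fp_species_probs is None:
            return np.full(len(self.species), 1.0 / len(self.species))
        p = np.array([self.fp_species_probs.get(s, 0.0) for s in self.species])
        return p / p.sum()


@dataclass(frozen=True)
class RetirementPolicy:
    """When a tile stops being shown to volunteers.

    A tile retires after ``full_limit`` classifications, or earlier once
    ``empty_limit`` classifications reported no animals. ``empty_mode``
    counts empties in total (default) or consecutively. Empty
    classifications count toward the full limit.
    """

    full_limit: int = 15
    empty_limit: int = 7
    empty_mode: str = "total"

    def __post_init__(self) -> None:
        if not 1 <= self.empty_limit <= self.full_limit:
            raise ValueError("require 1 <= empty_limit <= full_limit")
        if self.empty_mode not in ("total", "consecutive"):
            raise ValueError("empty_mode must be 'total' or 'consecutive'")


@dataclass(frozen=True)
class Annotation:
    """One volunteer mark on one tile (or the empty-classification sentinel).

    ``x, y`` are pixel coordinates *within* the tile. A classification that
    found no animals is represented by a single sentinel record with
    ``species == EMPTY_SENTINEL`` and NaN coordinates, so that zero counts
    stay explicit through every serialization.
    """

    volunteer_id: str
    tile_id: str
    species: str
    x: float
    y: float
    classification_id: str


def generate_colony(mosaic: MosaicSpec, config: ColonyConfig) -> list[AnimalInstance]:
    """Place animals on the mosaic according to the colony configuration.

    Realized totals are Poisson around ``species_abundance``. Placement is
    restricted to an ``occupancy_fraction`` subset of 700-px grid cells that
    intersect the content mask (the whole mosaic if no mask is set); within
    that habitat, positions are uniform or clustered around log-normally
    weighted cluster centers.
    """
    rng = np.random.default_rng(config.seed)
    habitat = _habitat_cells(mosaic, config, rng)
    animals: list[AnimalInstance] = []
    counter = itertools.count()
    for species in sorted(config.species_abundance):
        expected = config.species_abundance[species]
        n = int(rng.poisson(expected)) if expected > 0 else 0
        if n == 0:
            continue
        if config.spatial_model == "uniform":
            xs, ys = _uniform_in_cells(habitat, n, rng)
        else:
            xs, ys = _clustered_in_cells(habitat, n, config, rng)
        xs = np.clip(xs, 0, mosaic.width - 1)
        ys = np.clip(ys, 0, mosaic.height - 1)
        for x, y in zip(xs, ys):
            animals.append(
                AnimalInstance(
                    animal_id=f"a{next(counter):06d}",
                    species=species,
                    head_x=float(x),
                    head_y=float(y),
                    flight_id=mosaic.flight_id,
                )
            )
    return animals


def _habitat_cells(
    mosaic: MosaicSpec, config: ColonyConfig, rng: np.random.Generator
) -> np.ndarray:
    """Pick the (x0, y0, x1, y1) grid cells animals may occupy."""
    from .tiling import tile_mosaic

    cells = []
    for t in tile_mosaic(mosaic):
        if mosaic.content_mask is not None:
            if not mosaic.content_mask[t.y0 : t.y1, t.x0 : t.x1].any():
                continue
        cells.append((t.x0, t.y0, t.x1, t.y1))
    cells = np.array(cells, dtype=float)
    n_keep = max(1, int(round(config.occupancy_fraction * len(cells))))
    keep = rng.choice(len(cells), size=min(n_keep, len(cells)), replace=False)
    return cells[np.sort(keep)]


def _uniform_in_cells(cells: np.ndarray, n: int, rng: np.random.Generator):
    areas = (cells[:, 2] - cells[:, 0]) * (cells[:, 3] - cells[:, 1])
    which = rng.choice(len(cells), size=n, p=areas / areas.sum())
    u, v = rng.random(n), rng.random(n)
    c = cells[which]
    return c[:, 0] + u * (c[:, 2] - c[:, 0]), c[:, 1] + v * (c[:, 3] - c[:, 1])


def _clustered_in_cells(
    cells: np.ndarray, n: int, config: ColonyConfig, rng: np.random.Generator
):
    # log-normal cluster weights -> a few dense haul-outs, many sparse ones
    k = config.cluster_count
    which_cell = rng.choice(len(cells), size=k)
    c = cells[which_cell]
    cx = c[:, 0] + rng.random(k) * (c[:, 2] - c[:, 0])
    cy = c[:, 1] + rng.random(k) * (c[:, 3] - c[:, 1])
    weights = rng.lognormal(mean=0.0, sigma=1.2, size=k)
    assign = rng.choice(k, size=n, p=weights / weights.sum())
    xs = cx[assign] + rng.normal(0.0, config.cluster_spread, size=n)
    ys = cy[assign] + rng.normal(0.0, config.cluster_spread, size=n)
    return xs, ys


def sample_tile_counts(
    n_tiles: int,
    mean: float,
    sd: float,
    rng: np.random.Generator | int | None = None,
    zero_truncated: bool = True,
) -> np.ndarray:
    """Draw overdispersed per-tile true counts with given moments.

    Uses a negative binomial parameterized by mean and SD (requires
    ``sd**2 > mean``); with ``zero_truncated`` the draws are conditioned on
    being >= 1, modeling *occupied* tiles. This is the direct route to the
    observed per-tile count structure when no spatial layout is needed.
    """
    if sd**2 <= mean:
        raise ValueError("need sd^2 > mean for an overdispersed negative binomial")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = mean**2 / (sd**2 - mean)  # NB shape; variance = mean + mean^2/k
    p = k / (k + mean)
    out = rng.negative_binomial(k, p, size=n_tiles)
    if zero_truncated:
        while True:
            zero = out == 0
            if not zero.any():
                break
            out[zero] = rng.negative_binomial(k, p, size=int(zero.sum()))
    return out


def sample_correlated_tile_counts(
    n_tiles: int,
    moments: Mapping[str, tuple[float, float]],
    rho: float = 0.7,
    rng: np.random.Generator | int | None = None,
    zero_truncated: bool = True,
) -> pd.DataFrame:
    """Overdispersed per-tile counts for several species, coupled across species.

    Real haul-out tiles differ mainly in overall animal density: a crowded
    ledge holds many animals of both species, a sparse one few of either.
    A Gaussian copula with correlation ``rho`` couples the species'
    negative-binomial marginals (each parameterized by ``(mean, sd)``)
    through a shared tile-density factor; ``rho=0`` recovers independent
    draws. Zero truncation conditions every species on >= 1 per tile.
    """
    from scipy import stats as _st

    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    shared = rng.standard_normal(n_tiles)
    out = {}
    for sp, (mean, sd) in moments.items():
        if sd**2 <= mean:
            raise ValueError(f"need sd^2 > mean for species {sp!r}")
        k = mean**2 / (sd**2 - mean)
        p = k / (k + mean)
        z = rho * shared + np.sqrt(1 - rho**2) * rng.standard_normal(n_tiles)
        u = _st.norm.cdf(z)
        if zero_truncated:
            p0 = _st.nbinom.pmf(0, k, p)
            u = p0 + u * (1 - p0)
        out[sp] = _st.nbinom.ppf(np.clip(u, 0, 1 - 1e-12), k, p).astype(int)
    return pd.DataFrame(out)


def _volunteer_weights(model: VolunteerModel, rng: np.random.Generator) -> np.ndarray:
    w = rng.lognormal(mean=0.0, sigma=model.activity_sigma, size=model.n_volunteers)
    return w / w.sum()


def _classification_counts(
    truth_vec: np.ndarray,
    model: VolunteerModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one classification's per-species mark counts (no positions)."""
    k = len(model.species)
    conf = model.confusion_matrix()
    out = np.zeros(k, dtype=int)
    for i in range(k):
        detected = rng.binomial(int(truth_vec[i]), model.detect_prob(model.species[i]))
        if detected:
            out += rng.multinomial(detected, conf[i])
    if model.fp_rate > 0:
        n_fp = rng.poisson(model.fp_rate)
        if n_fp:
            out += rng.multinomial(n_fp, model.fp_probs())
    if model.count_jitter > 0:
        jit = np.rint(rng.normal(0.0, model.count_jitter, size=k)).astype(int)
        out = np.maximum(out + jit, 0)
    return out


def simulate_classifications(
    truth: Mapping[str, Mapping[str, int]],
    volunteers: VolunteerModel,
    policy: RetirementPolicy = RetirementPolicy(),
    tiles: Sequence[Tile] | None = None,
    animals: Iterable[AnimalInstance] | None = None,
    seed: int | None = None,
    n_counters: Mapping[str, int] | None = None,
) -> list[Annotation]:
    """Simulate volunteer classifications, mark by mark, until retirement.

    Parameters
    ----------
    truth : mapping tile_id -> {species: true count}
        Ground truth per non-blank tile (zero counts may be implicit).
    volunteers, policy :
        Behavior model and retirement rules.
    tiles, animals : optional
        When both are given, detected marks are jittered around the true
        head positions (converted to tile-local coordinates); otherwise
        marks are placed uniformly inside a default-size tile.
    seed : int, optional
        Overrides ``volunteers.seed``.
    n_counters : mapping tile_id -> int, optional
        Per-tile cap on classifications, modeling a data export taken
        before every tile reached retirement. Retirement rules still apply
        below the cap.

    Returns
    -------
    list of Annotation
        One record per mark, plus one ``EMPTY_SENTINEL`` record per
        classification that found nothing.
    """
    rng = np.random.default_rng(volunteers.seed if seed is None else seed)
    weights = _volunteer_weights(volunteers, rng)
    tile_lookup = {t.tile_id: t for t in tiles} if tiles is not None else {}
    positions = (
        animals_by_tile(animals, tiles) if (animals is not None and tiles is not None) else {}
    )
    species = volunteers.species
    sp_index = {s: i for i, s in enumerate(species)}
    annotations: list[Annotation] = []
    cls_counter = itertools.count()

    for tile_id in sorted(truth):
        per = truth[tile_id]
        truth_vec = np.array([per.get(s, 0) for s in species], dtype=int)
        tile = tile_lookup.get(tile_id)
        tw = tile.width if tile is not None else 700
        th = tile.height if tile is not None else 700
        tile_animals = positions.get(tile_id, [])
        cap = policy.full_limit
        if n_counters is not None:
            cap = min(cap, max(1, int(n_counters[tile_id])))
        order = rng.choice(
            volunteers.n_volunteers,
            size=min(policy.full_limit, volunteers.n_volunteers),
            replace=False,
            p=weights,
        )
        empties = 0
        n_done = 0
        for vol in order:
            if n_done >= cap:
                break
            cid = f"c{next(cls_counter):07d}"
            vid = f"v{vol:04d}"
            origin = (tile.x0, tile.y0) if tile is not None else (0, 0)
            marks = _simulate_marks(
                truth_vec, tile_animals, volunteers, rng, tw, th, sp_index, origin
            )
            n_done += 1
            if not marks:
                empties += 1
                annotations.append(
                    Annotation(vid, tile_id, EMPTY_SENTINEL, float("nan"), float("nan"), cid)
                )
            else:
                if policy.empty_mode == "consecutive":
                    empties = 0
                for sp, x, y in marks:
                    annotations.append(Annotation(vid, tile_id, sp, x, y, cid))
            if empties >= policy.empty_limit:
                break
    return annotations


def _simulate_marks(
    truth_vec: np.ndarray,
    tile_animals: Sequence[AnimalInstance],
    model: VolunteerModel,
    rng: np.random.Generator,
    tw: int,
    th: int,
    sp_index: Mapping[str, int],
    origin: tuple[int, int] = (0, 0),
) -> list[tuple[str, float, float]]:
    """One volunteer's marks on one tile: (label, local x, local y) triples."""
    conf = model.confusion_matrix()
    marks: list[tuple[str, float, float]] = []
    if tile_animals:
        ox, oy = origin
        for a in tile_animals:
            i = sp_index[a.species]
            if rng.random() < model.detect_prob(a.species):
                label = model.species[rng.choice(len(model.species), p=conf[i])]
                # jitter around the true head (tile-local), clipped into the tile
                x = float(np.clip(a.head_x - ox + rng.normal(0.0, model.mark_jitter_px), 0, tw - 1e-6))
                y = float(np.clip(a.head_y - oy + rng.normal(0.0, model.mark_jitter_px), 0, th - 1e-6))
                marks.append((label, x, y))
    else:
        for i, sp in enumerate(model.species):
            detected = rng.binomial(int(truth_vec[i]), model.detect_prob(sp))
            for _ in range(detected):
                label = model.species[rng.choice(len(model.species), p=conf[i])]
                marks.append((label, rng.random() * tw, rng.random() * th))
    if model.fp_rate > 0:
        for _ in range(rng.poisson(model.fp_rate)):
            sp = model.species[rng.choice(len(model.species), p=model.fp_probs())]
            marks.append((sp, rng.random() * tw, rng.random() * th))
    if model.count_jitter > 0:
        by_sp: dict[str, list[int]] = {}
        for j, (sp, _, _) in enumerate(marks):
            by_sp.setdefault(sp, []).append(j)
        drop: set[int] = set()
        extra: list[tuple[str, float, float]] = []
        for sp in model.species:
            jit = int(np.rint(rng.normal(0.0, model.count_jitter)))
            idx = by_sp.get(sp, [])
            if jit < 0 and idx:
                drop.update(rng.choice(idx, size=min(-jit, len(idx)), replace=False))
            elif jit > 0:
                extra.extend((sp, rng.random() * tw, rng.random() * th) for _ in range(jit))
        marks = [m for j, m in enumerate(marks) if j not in drop] + extra
    return marks


def simulate_count_matrix(
    truth: pd.DataFrame | Mapping[str, Mapping[str, int]],
    volunteers: VolunteerModel,
    policy: RetirementPolicy = RetirementPolicy(),
    seed: int | None = None,
    n_counters: np.ndarray | Mapping[str, int] | None = None,
    flight_id: str = "flight",
) -> pd.DataFrame:
    """Simulate repeated counts directly, skipping mark positions.

    Distributionally identical to running :func:`simulate_classifications`
    followed by :func:`marks_to_counts` (same detection, confusion,
    false-positive and retirement model), but vectorized across tiles and
    volunteers — the workhorse for replicate-heavy validation experiments.
    Returns the long count-matrix frame with columns ``flight_id, tile_id,
    species, volunteer_id, count``.
    """
    rng = np.random.default_rng(volunteers.seed if seed is None else seed)
    if isinstance(truth, pd.DataFrame):
        truth_map: dict[str, dict[str, int]] = {}
        for row in truth.itertuples(index=False):
            truth_map.setdefault(row.tile_id, {})[row.species] = int(row.count)
        truth = truth_map
    species = volunteers.species
    k = len(species)
    tile_ids = sorted(truth)
    T = len(tile_ids)
    if T == 0:
        return pd.DataFrame(
            columns=["flight_id", "tile_id", "species", "volunteer_id", "count"]
        )
    truth_mat = np.array(
        [[truth[t].get(s, 0) for s in species] for t in tile_ids], dtype=int
    )
    L = min(policy.full_limit, volunteers.n_volunteers)
    caps = np.full(T, policy.full_limit, dtype=int)
    if n_counters is not None:
        if isinstance(n_counters, Mapping):
            caps = np.array([n_counters[t] for t in tile_ids], dtype=int)
        else:
            caps = np.asarray(n_counters, dtype=int)
        caps = np.clip(caps, 1, policy.full_limit)

    # weighted order of volunteers per tile (Gumbel top-L keeps it vectorized)
    weights = _volunteer_weights(volunteers, rng)
    keys = np.log(weights)[None, :] + rng.gumbel(size=(T, volunteers.n_volunteers))
    order = np.argsort(-keys, axis=1)[:, :L]  # (T, L) volunteer indices

    conf = volunteers.confusion_matrix()
    counts = np.zeros((T, L, k), dtype=int)
    for i in range(k):
        detected = rng.binomial(truth_mat[:, i][:, None], volunteers.detect_prob(species[i]), size=(T, L))
        counts += _multinomial_split(detected, conf[i], rng)
    if volunteers.fp_rate > 0:
        n_fp = rng.poisson(volunteers.fp_rate, size=(T, L))
        counts += _multinomial_split(n_fp, volunteers.fp_probs(), rng)
    if volunteers.count_jitter > 0:
        jit = np.rint(rng.normal(0.0, volunteers.count_jitter, size=(T, L, k))).astype(int)
        counts = np.maximum(counts + jit, 0)

    # sequential retirement, replayed column by column over the drawn counts
    empty = counts.sum(axis=2) == 0
    served = np.zeros((T, L), dtype=bool)
    alive = np.ones(T, dtype=bool)
    n_empty = np.zeros(T, dtype=int)
    for j in range(L):
        s = alive & (j < caps)
        served[:, j] = s
        if policy.empty_mode == "total":
            n_empty += s & empty[:, j]
        else:
            n_empty = np.where(s, np.where(empty[:, j], n_empty + 1, 0), n_empty)
        alive &= n_empty < policy.empty_limit

    t_idx, l_idx = np.nonzero(served)
    vol_names = np.array([f"v{v:04d}" for v in range(volunteers.n_volunteers)])
    tile_arr = np.array(tile_ids, dtype=object)
    return pd.DataFrame(
        {
            "flight_id": flight_id,
            "tile_id": np.repeat(tile_arr[t_idx], k),
            "species": np.tile(np.array(species, dtype=object), t_idx.size),
            "volunteer_id": np.repeat(vol_names[order[t_idx, l_idx]], k),
            "count": counts[t_idx, l_idx, :].ravel(),
        }
    )


def _multinomial_split(
    totals: np.ndarray, probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Split integer totals across categories, vectorized over ``totals``."""
    out = np.zeros(totals.shape + (len(probs),), dtype=int)
    remaining = totals
    remaining_p = 1.0
    for j, pj in enumerate(probs):
        if remaining_p <= 1e-12:
            break
        take = rng.binomial(remaining, min(pj / remaining_p, 1.0))
        out[..., j] = take
        remaining = remaining - take
        remaining_p -= pj
    return out


def marks_to_counts(
    annotations: Iterable[Annotation],
    species: Sequence[str] = DEFAULT_SPECIES,
    flight_id: str = "flight",
) -> pd.DataFrame:
    """Collapse marks into the long count matrix, one row per
    (tile, species, volunteer).

    Classifications with zero marks (sentinel records) contribute explicit
    zero counts for every species in the configured set. A volunteer's
    duplicate classifications of the same tile keep the first and are
    logged.
    """
    import logging

    log = logging.getLogger(__name__)
    first_cls: dict[tuple[str, str], str] = {}
    counts: dict[tuple[str, str], dict[str, int]] = {}
    dupes = 0
    for a in annotations:
        key = (a.tile_id, a.volunteer_id)
        if key in first_cls and first_cls[key] != a.classification_id:
            dupes += 1
            continue
        first_cls.setdefault(key, a.classification_id)
        per = counts.setdefault(key, {s: 0 for s in species})
        if a.species != EMPTY_SENTINEL:
            if a.species not in per:
                raise ValueError(
                    f"mark with species {a.species!r} outside configured set {tuple(species)}"
                )
            per[a.species] += 1
    if dupes:
        log.warning("dropped %d marks from duplicate (volunteer, tile) classifications", dupes)
    rows = [
        (flight_id, tile_id, s, vol, per[s])
        for (tile_id, vol), per in counts.items()
        for s in species
    ]
    return pd.DataFrame(
        rows, columns=["flight_id", "tile_id", "species", "volunteer_id", "count"]
    )
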