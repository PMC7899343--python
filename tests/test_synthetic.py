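"""The synthetic colony generator and volunteer behavior model."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from crowdcount import (
    ColonyConfig,
    MosaicSpec,
    RetirementPolicy,
    VolunteerModel,
    assign_animals_to_tiles,
    generate_colony,
    marks_to_counts,
    sample_tile_counts,
    simulate_classifications,
    simulate_count_matrix,
    tile_mosaic,
)
from crowdcount.synthetic import Annotation, EMPTY_SENTINEL


def test_zero_abundance_gives_empty_colony(small_mosaic):
    config = ColonyConfig(species_abundance={"seal": 0, "sea_lion": 0}, seed=1)
    assert generate_colony(small_mosaic, config) == []


def test_colony_is_deterministic_given_seed(small_mosaic):
    config = ColonyConfig(
        species_abundance={"seal": 1000}, spatial_model="uniform", seed=42
    )
    a = generate_colony(small_mosaic, config)
    b = generate_colony(small_mosaic, config)
    assert a == b
    assert abs(len(a) - 1000) < 4 * np.sqrt(1000)  # Poisson total around target


def test_clustered_colony_is_overdispersed():
    """Per-tile counts from the clustered layout show variance > mean,
    estimated over a 500-tile mosaic."""
    mosaic = MosaicSpec(700 * 25, 700 * 20, flight_id="big")
    config = ColonyConfig(
        species_abundance={"seal": 6.0 * 250},  # mean ~6 per occupied tile
        spatial_model="clustered",
        cluster_count=40,
        occupancy_fraction=0.5,
        seed=5,
    )
    animals = generate_colony(mosaic, config)
    tiles = tile_mosaic(mosaic, 700)
    counts = assign_animals_to_tiles(animals, tiles)
    per_tile = np.array([per.get("seal", 0) for per in counts.values()])
    assert per_tile.sum() == len(animals)
    assert per_tile.var() > per_tile.mean()


def test_config_validation():
    with pytest.raises(ValueError):
        ColonyConfig(species_abundance={"seal": -1})
    with pytest.raises(ValueError):
        ColonyConfig(occupancy_fraction=1.5)
    with pytest.raises(ValueError):
        VolunteerModel(p_detect=1.2)
    with pytest.raises(ValueError):
        VolunteerModel(confusion={"seal": {"seal": 0.5, "sea_lion": 0.4}})
    with pytest.raises(ValueError):
        RetirementPolicy(full_limit=5, empty_limit=7)


def test_negative_binomial_tile_counts_hit_target_moments(rng):
    counts = sample_tile_counts(20000, mean=12.0, sd=19.0, rng=rng, zero_truncated=False)
    assert counts.mean() == pytest.approx(12.0, rel=0.05)
    assert counts.std() == pytest.approx(19.0, rel=0.05)
    truncated = sample_tile_counts(5000, mean=12.0, sd=19.0, rng=rng)
    assert truncated.min() >= 1


def test_noise_free_volunteers_reproduce_truth_exactly(noise_free_model):
    truth = {"t1": {"seal": 3, "sea_lion": 1}, "t2": {"seal": 0, "sea_lion": 5}}
    annotations = simulate_classifications(truth, noise_free_model, RetirementPolicy())
    counts = marks_to_counts(annotations)
    merged = counts.pivot_table(index=["tile_id", "species"], values="count", aggfunc=["min", "max"])
    for (tile, sp), row in merged.iterrows():
        assert row["min"].item() == row["max"].item() == truth[tile].get(sp, 0)


def test_retirement_empty_tiles_get_exactly_seven(noise_free_model):
    """With no false positives, a truly empty tile retires after the
    empty-classification limit; occupied tiles run to the full limit."""
    truth = {f"empty{i}": {"seal": 0, "sea_lion": 0} for i in range(10)}
    truth["occupied"] = {"seal": 4, "sea_lion": 0}
    annotations = simulate_classifications(truth, noise_free_model, RetirementPolicy())
    counts = marks_to_counts(annotations)
    per_tile = counts.groupby("tile_id")["volunteer_id"].nunique()
    for i in range(10):
        assert per_tile[f"empty{i}"] == 7
    assert per_tile["occupied"] == 15


def test_no_tile_exceeds_full_limit():
    model = VolunteerModel(p_detect=0.6, fp_rate=0.3, seed=11)
    truth = {f"t{i}": {"seal": i % 5, "sea_lion": (i * 3) % 7} for i in range(30)}
    matrix = simulate_count_matrix(truth, model, RetirementPolicy())
    per_tile = matrix.groupby("tile_id")["volunteer_id"].nunique()
    assert (per_tile <= 15).all()


def test_undercount_mean_matches_binomial_thinning():
    """Mean volunteer count over ~10,000 classifications of a 10-animal tile
    with p_detect = 0.8 lands on the binomial mean 8.0 within 3 SE."""
    model = VolunteerModel(p_detect=0.8, fp_rate=0.0, seed=3)
    truth = {f"t{i}": {"seal": 10, "sea_lion": 0} for i in range(667)}
    matrix = simulate_count_matrix(truth, model, RetirementPolicy())
    seal = matrix[matrix.species == "seal"]["count"]
    n = len(seal)
    assert n >= 10000
    se = np.sqrt(10 * 0.8 * 0.2 / n)
    assert abs(seal.mean() - 8.0) < 3 * se


def test_detection_probability_recoverable_from_count_ratio(rng):
    """fp_rate = 0, identity confusion: mean(count)/truth converges to p_detect."""
    p = 0.7
    model = VolunteerModel(p_detect=p, fp_rate=0.0, seed=9)
    tile_truth = sample_tile_counts(700, mean=6.0, sd=12.0, rng=rng)
    truth = {f"t{i:04d}": {"seal": int(c), "sea_lion": 0} for i, c in enumerate(tile_truth)}
    matrix = simulate_count_matrix(truth, model, RetirementPolicy())
    seal = matrix[matrix.species == "seal"]
    truth_per_row = seal["tile_id"].map({k: v["seal"] for k, v in truth.items()})
    ratio = seal["count"].sum() / truth_per_row.sum()
    n_classifications = len(seal)
    se = np.sqrt(p * (1 - p) / truth_per_row.sum())
    assert n_classifications >= 10000
    assert abs(ratio - p) < 3 * se


def test_confusion_conserves_total_marks():
    """With perfect detection and no false positives, mislabeling moves
    marks between species but never changes the per-classification total."""
    model = VolunteerModel(
        p_detect=1.0,
        fp_rate=0.0,
        confusion={"seal": {"seal": 0.5, "sea_lion": 0.5}},
        seed=21,
    )
    truth = {f"t{i}": {"seal": 5, "sea_lion": 3} for i in range(40)}
    matrix = simulate_count_matrix(truth, model, RetirementPolicy())
    totals = matrix.groupby(["tile_id", "volunteer_id"])["count"].sum()
    assert (totals == 8).all()


def test_identical_seeds_give_identical_tables():
    model = VolunteerModel(p_detect=0.8, fp_rate=0.1, seed=5)
    truth = {f"t{i}": {"seal": i % 4, "sea_lion": 1} for i in range(20)}
    a = simulate_classifications(truth, model, RetirementPolicy(), seed=99)
    b = simulate_classifications(truth, model, RetirementPolicy(), seed=99)
    # NaN coordinates on sentinel rows defeat plain ==; frame comparison
    # treats them as equal
    pd.testing.assert_frame_equal(
        pd.DataFrame([dataclasses.asdict(x) for x in a]),
        pd.DataFrame([dataclasses.asdict(x) for x in b]),
    )
    ma = simulate_count_matrix(truth, model, RetirementPolicy(), seed=99)
    mb = simulate_count_matrix(truth, model, RetirementPolicy(), seed=99)
    pd.testing.assert_frame_equal(ma, mb)


def test_mark_and_count_level_paths_agree_in_distribution():
    """The fast count-level simulator and the mark-level route share the
    same detection model: their mean counts agree within Monte-Carlo error."""
    model = VolunteerModel(p_detect=0.75, fp_rate=0.0, seed=2)
    truth = {f"t{i}": {"seal": 8, "sea_lion": 0} for i in range(300)}
    marks = marks_to_counts(simulate_classifications(truth, model, RetirementPolicy(), seed=4))
    fast = simulate_count_matrix(truth, model, RetirementPolicy(), seed=8)
    m1 = marks[marks.species == "seal"]["count"].mean()
    m2 = fast[fast.species == "seal"]["count"].mean()
    se = np.sqrt(2 * 8 * 0.75 * 0.25 / (300 * 15))
    assert abs(m1 - m2) < 4 * se


def test_marks_to_counts_examples():
    ann = [
        Annotation("v1", "t1", "seal", 1, 1, "c1"),
        Annotation("v1", "t1", "seal", 2, 2, "c1"),
        Annotation("v1", "t1", "seal", 3, 3, "c1"),
        Annotation("v1", "t1", "sea_lion", 4, 4, "c1"),
        Annotation("v1", "t1", "sea_lion", 5, 5, "c1"),
        Annotation("v2", "t1", EMPTY_SENTINEL, float("nan"), float("nan"), "c2"),
    ]
    counts = marks_to_counts(ann)
    by = counts.set_index(["volunteer_id", "species"])["count"]
    assert by[("v1", "seal")] == 3
    assert by[("v1", "sea_lion")] == 2
    assert by[("v2", "seal")] == 0
    assert by[("v2", "sea_lion")] == 0


def test_duplicate_classifications_keep_first(caplog):
    ann = [
        Annotation("v1", "t1", "seal", 1, 1, "c1"),
        Annotation("v1", "t1", "seal", 2, 2, "c9"),  # second pass, dropped
    ]
    with caplog.at_level("WARNING"):
        counts = marks_to_counts(ann)
    assert counts.set_index("species")["count"]["seal"] == 1
    assert any("duplicate" in r.message for r in caplog.records)
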