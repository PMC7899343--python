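"""Error metrics, confusion, regression, flight totals and the paired test."""

import numpy as np
import pandas as pd
import pytest

from crowdcount import (
    RetirementPolicy,
    VolunteerModel,
    confusion_classify,
    confusion_proportions,
    error_by_n_counters,
    flight_totals,
    paired_wilcoxon,
    per_photo_errors,
    regress_cs_on_expert,
    sample_tile_counts,
    simulate_count_matrix,
    aggregate_all,
    validate,
)


def frames(pairs, algorithm="Median", species="seal", n_counters=15):
    """Build matching consensus/expert frames from (cs, e) pairs."""
    consensus = pd.DataFrame(
        {
            "flight_id": "f1",
            "tile_id": [f"t{i}" for i in range(len(pairs))],
            "species": species,
            "algorithm": algorithm,
            "value": [cs for cs, _ in pairs],
            "n_counters": n_counters,
            "fallback_used": False,
        }
    )
    expert = pd.DataFrame(
        {
            "flight_id": "f1",
            "tile_id": [f"t{i}" for i in range(len(pairs))],
            "species": species,
            "count": [e for _, e in pairs],
        }
    )
    return consensus, expert


def test_relative_error_definition():
    errors = per_photo_errors(*frames([(9, 10), (7, 7), (2, 0)]))
    by_tile = errors.set_index("tile_id")["rel_error"]
    assert by_tile["t0"] == pytest.approx(0.10)
    assert by_tile["t1"] == 0.0
    assert np.isnan(by_tile["t2"])  # undefined, not zero


def test_zero_expert_photo_routes_to_false_positive():
    consensus, expert = frames([(2, 0)])
    classes = confusion_classify(consensus, expert)
    assert classes["category"].item() == "FP"


def test_relative_error_is_scale_invariant():
    base = per_photo_errors(*frames([(9, 10), (3, 4), (8, 5)]))["rel_error"]
    scaled = per_photo_errors(*frames([(27, 30), (9, 12), (24, 15)]))["rel_error"]
    assert np.allclose(base, scaled)


def test_unmatched_consensus_rows_are_excluded(caplog):
    consensus, expert = frames([(5, 5), (4, 4)])
    expert = expert[expert.tile_id != "t1"]
    with caplog.at_level("WARNING"):
        errors = per_photo_errors(consensus, expert)
    assert list(errors["tile_id"]) == ["t0"]
    assert any("no expert count" in r.message for r in caplog.records)


def test_error_by_n_counters_groups_exactly():
    consensus, expert = frames([(1, 2), (1, 2), (9, 10)])
    consensus["n_counters"] = [1, 1, 15]
    table = error_by_n_counters(per_photo_errors(consensus, expert))
    by_n = table.set_index("n_counters")
    assert by_n.loc[1, "mean_rel_error"] == pytest.approx(0.5)
    assert by_n.loc[1, "n_photos"] == 2
    assert by_n.loc[15, "mean_rel_error"] == pytest.approx(0.1)


@pytest.mark.parametrize(
    "cs, e, category",
    [(0, 0, "TN"), (3, 2, "TP"), (0, 4, "FN"), (2, 0, "FP")],
)
def test_confusion_categories(cs, e, category):
    classes = confusion_classify(*frames([(cs, e)]))
    assert classes["category"].item() == category


def test_confusion_proportions_sum_to_one():
    classes = confusion_classify(*frames([(0, 0), (3, 2), (0, 4), (2, 0), (1, 1)]))
    props = confusion_proportions(classes)
    assert props.groupby(["species", "algorithm"])["proportion"].sum().item() == pytest.approx(1.0)


def test_regression_identity_and_exact_scaling():
    ident = regress_cs_on_expert(*frames([(1, 1), (4, 4), (9, 9)]))
    assert ident["slope"].item() == pytest.approx(1.0)
    assert ident["intercept"].item() == pytest.approx(0.0)
    assert ident["r_squared"].item() == pytest.approx(1.0)

    scaled = regress_cs_on_expert(*frames([(0.8, 1), (3.2, 4), (7.2, 9)]))
    assert scaled["slope"].item() == pytest.approx(0.8)
    assert scaled["r_squared"].item() == pytest.approx(1.0)


def test_regression_needs_three_pairs(caplog):
    with caplog.at_level("WARNING"):
        out = regress_cs_on_expert(*frames([(1, 1), (2, 2)]))
    assert out.empty
    assert any("only 2 pairs" in r.message for r in caplog.records)


def test_flight_totals_percent_error():
    consensus, expert = frames([(3, 5), (4, 5)])
    totals = flight_totals(consensus, expert)
    assert totals["total_cs"].item() == 7
    assert totals["total_expert"].item() == 10
    assert totals["percent_error"].item() == pytest.approx(30.0)

    exact = flight_totals(*frames([(5, 5), (2, 2)]))
    assert exact["percent_error"].item() == 0.0

    zero = flight_totals(*frames([(1, 0), (2, 0)]))
    assert np.isnan(zero["percent_error"].item())


def test_wilcoxon_no_difference_reported_as_such():
    out = paired_wilcoxon(*frames([(5, 5), (2, 2), (0, 0)]))
    assert out["no_difference"].item()
    assert np.isnan(out["p_value"].item())


def test_wilcoxon_exact_p_for_six_positive_unit_differences():
    """Six paired differences of +1: the two-sided exact signed-rank p-value
    is 2/2^6 = 0.03125 (only the all-positive and all-negative sign
    patterns reach the extreme rank sum)."""
    out = paired_wilcoxon(*frames([(e + 1, e) for e in [3, 5, 2, 8, 1, 4]]))
    assert out["p_value"].item() == pytest.approx(0.03125)


def test_noise_free_report_is_exact(rng):
    """p_detect = 1, identity confusion, no false positives: every metric
    collapses to its ideal value."""
    truth_counts = sample_tile_counts(80, mean=6.0, sd=12.0, rng=rng)
    truth = {f"t{i:03d}": {"seal": int(c), "sea_lion": 0} for i, c in enumerate(truth_counts)}
    truth["t_empty"] = {"seal": 0, "sea_lion": 0}
    model = VolunteerModel(p_detect=1.0, fp_rate=0.0, seed=2)
    matrix = simulate_count_matrix(truth, model, RetirementPolicy())
    consensus = aggregate_all(matrix)
    expert = pd.DataFrame(
        [("flight", t, s, truth[t].get(s, 0)) for t in truth for s in ("seal", "sea_lion")],
        columns=["flight_id", "tile_id", "species", "count"],
    )
    report = validate(consensus, expert)
    defined = report.photo_errors.dropna(subset=["rel_error"])
    assert (defined["rel_error"] == 0).all()
    seal_reg = report.regression[report.regression.species == "seal"]
    assert np.allclose(seal_reg["slope"], 1.0)
    assert np.allclose(seal_reg["r_squared"], 1.0)
    props = report.confusion_props
    tp_tn = props[props.category.isin(["TP", "TN"])].groupby(["species", "algorithm"])["proportion"].sum()
    assert np.allclose(tp_tn, 1.0)
    assert (report.flight_totals["percent_error"].dropna() == 0).all()
    assert report.wilcoxon["no_difference"].all()


def test_report_figures_are_written(tmp_path, rng):
    from crowdcount.plots import save_report_figures

    pairs = [(int(0.8 * e), e) for e in rng.integers(0, 20, size=12)]
    report = validate(*frames(pairs))
    written = save_report_figures(report, tmp_path)
    assert len(written) == 4
    assert all(p.exists() and p.stat().st_size > 0 for p in written)
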