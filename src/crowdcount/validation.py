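"""Accuracy of consensus counts against expert counts.

The expert count is the reference. For each (tile, species, algorithm) the
relative error is |cs - e| / e, defined only when the expert counted at
least one animal; tiles the expert scored zero instead feed the
presence/absence confusion table (a consensus count there is either a true
negative or a false positive). Errors are summarized two ways, matching
how survey-validation studies report them:

1. per photo — the mean (and median) relative error over photos with e > 0;
2. by number of counters — photos grouped by how many volunteers counted
   them, showing how error falls as repeated counts accumulate.

A least-squares regression of consensus on expert per (algorithm, species)
exposes systematic bias: a slope below 1 means crowded photos are
undercounted. Flight-level totals answer the question managers actually
ask — how far off is the whole-census number. A Wilcoxon signed-rank test
(the paired variant; counts are far from normal) tests whether consensus
and expert counts differ systematically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ValidationReport",
    "per_photo_errors",
    "error_by_n_counters",
    "confusion_classify",
    "confusion_proportions",
    "regress_cs_on_expert",
    "flight_totals",
    "paired_wilcoxon",
    "validate",
]

_KEYS = ["flight_id", "tile_id", "species"]


def _merge(consensus: pd.DataFrame, expert: pd.DataFrame) -> pd.DataFrame:
    """Inner-join consensus and expert on (flight, tile, species).

    Consensus tiles absent from the expert table are logged and excluded;
    expert (tile, species) pairs with no consensus row are treated as
    consensus zero only by callers that ask for it (the pipeline always
    aggregates every counted tile, so a missing row means the tile was
    never served, not that it was counted empty).
    """
    merged = consensus.merge(expert, on=_KEYS, how="left", indicator=True)
    unmatched = merged["_merge"] == "left_only"
    if unmatched.any():
        tiles = sorted(merged.loc[unmatched, "tile_id"].unique())
        log.warning(
            "%d consensus rows on %d tiles have no expert count and were excluded: %s",
            int(unmatched.sum()), len(tiles), tiles[:10],
        )
    merged = merged[~unmatched].drop(columns="_merge")
    merged = merged.rename(columns={"value": "cs", "count": "expert"})
    merged["expert"] = merged["expert"].astype(float)
    return merged


def per_photo_errors(consensus: pd.DataFrame, expert: pd.DataFrame) -> pd.DataFrame:
    """Relative error |cs - e| / e per (tile, species, algorithm).

    ``rel_error`` is NaN (undefined, not zero) where the expert count is
    zero; those photos are classified by :func:`confusion_classify`
    instead of entering error averages.
    """
    merged = _merge(consensus, expert)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(merged["cs"] - merged["expert"]) / merged["expert"]
    merged["rel_error"] = rel.where(merged["expert"] > 0)
    cols = _KEYS + ["algorithm", "cs", "expert", "rel_error", "n_counters"]
    return merged[cols].reset_index(drop=True)


def error_by_n_counters(errors: pd.DataFrame) -> pd.DataFrame:
    """Mean relative error per exact number of counters, species, algorithm.

    Group sizes (``n_photos``: photos with a defined error) are reported
    alongside, since sparse groups carry little information.
    """
    defined = errors.dropna(subset=["rel_error"])
    grouped = (
        defined.groupby(["n_counters", "species", "algorithm"], sort=True)["rel_error"]
        .agg(mean_rel_error="mean", n_photos="size")
        .reset_index()
    )
    return grouped


def confusion_classify(consensus: pd.DataFrame, expert: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence category per (tile, species, algorithm).

    TN: both zero; TP: both nonzero; FN: consensus zero, expert nonzero;
    FP: consensus nonzero, expert zero.
    """
    merged = _merge(consensus, expert)
    cs_pos = merged["cs"] > 0
    e_pos = merged["expert"] > 0
    merged["category"] = np.select(
        [cs_pos & e_pos, ~cs_pos & ~e_pos, ~cs_pos & e_pos],
        ["TP", "TN", "FN"],
        default="FP",
    )
    return merged[_KEYS + ["algorithm", "category"]].reset_index(drop=True)


def confusion_proportions(classes: pd.DataFrame) -> pd.DataFrame:
    """Proportion of photos per category, per (species, algorithm); sums to 1."""
    counts = (
        classes.groupby(["species", "algorithm", "category"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby(["species", "algorithm"])["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals
    return counts


def regress_cs_on_expert(consensus: pd.DataFrame, expert: pd.DataFrame) -> pd.DataFrame:
    """OLS of consensus on expert count per (algorithm, species).

    Slope < 1 flags systematic undercounting that worsens with crowd size.
    Combinations with fewer than 3 matched pairs are omitted with a
    warning.
    """
    merged = _merge(consensus, expert)
    rows = []
    for (alg, sp), grp in merged.groupby(["algorithm", "species"], sort=True):
        if len(grp) < 3:
            log.warning("regression skipped for (%s, %s): only %d pairs", alg, sp, len(grp))
            continue
        if grp["expert"].nunique() == 1:
            log.warning("regression skipped for (%s, %s): expert counts constant", alg, sp)
            continue
        fit = stats.linregress(grp["expert"], grp["cs"])
        rows.append(
            {
                "algorithm": alg,
                "species": sp,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.rvalue**2,
                "n_pairs": len(grp),
            }
        )
    return pd.DataFrame(rows, columns=["algorithm", "species", "slope", "intercept", "r_squared", "n_pairs"])


def flight_totals(consensus: pd.DataFrame, expert: pd.DataFrame) -> pd.DataFrame:
    """Whole-flight summed counts and percent error per (flight, species, algorithm).

    ``percent_error`` is |sum(cs) - sum(e)| / sum(e) expressed in percent;
    NaN when the expert total is zero.
    """
    merged = _merge(consensus, expert)
    grouped = (
        merged.groupby(["flight_id", "species", "algorithm"], sort=True)
        .agg(total_cs=("cs", "sum"), total_expert=("expert", "sum"), n_tiles=("cs", "size"))
        .reset_index()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        pe = 100.0 * np.abs(grouped["total_cs"] - grouped["total_expert"]) / grouped["total_expert"]
    grouped["percent_error"] = pe.where(grouped["total_expert"] > 0)
    return grouped


def paired_wilcoxon(consensus: pd.DataFrame, expert: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon signed-rank test of consensus vs expert per (algorithm, species).

    Zero differences are dropped (the classic procedure); when every
    difference is zero the test is undefined and reported as such with
    ``no_difference=True``.
    """
    merged = _merge(consensus, expert)
    rows = []
    for (alg, sp), grp in merged.groupby(["algorithm", "species"], sort=True):
        d = (grp["cs"] - grp["expert"]).to_numpy(dtype=float)
        nonzero = d[d != 0]
        if nonzero.size == 0:
            rows.append(
                {"algorithm": alg, "species": sp, "statistic": np.nan,
                 "p_value": np.nan, "n_pairs": len(d), "no_difference": True}
            )
            continue
        res = stats.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided")
        rows.append(
            {"algorithm": alg, "species": sp, "statistic": float(res.statistic),
             "p_value": float(res.pvalue), "n_pairs": len(d), "no_difference": False}
        )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """All validation tables for one run, with serialization helpers."""

    photo_errors: pd.DataFrame
    error_by_n: pd.DataFrame
    confusion: pd.DataFrame
    confusion_props: pd.DataFrame
    regression: pd.DataFrame
    flight_totals: pd.DataFrame
    wilcoxon: pd.DataFrame
    extra: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "photo_errors": self.photo_errors,
            "error_by_n": self.error_by_n,
            "confusion": self.confusion,
            "confusion_proportions": self.confusion_props,
            "regression": self.regression,
            "flight_totals": self.flight_totals,
            "wilcoxon": self.wilcoxon,
        }

    def mean_rel_error(self) -> pd.DataFrame:
        """Headline per-photo error: mean (and median) rel_error over photos
        with a nonzero expert count, per (species, algorithm)."""
        defined = self.photo_errors.dropna(subset=["rel_error"])
        return (
            defined.groupby(["species", "algorithm"], sort=True)["rel_error"]
            .agg(mean_rel_error="mean", median_rel_error="median", n_photos="size")
            .reset_index()
        )

    def summary(self) -> dict:
        mre = self.mean_rel_error()
        return {
            "mean_rel_error": mre.to_dict(orient="records"),
            "regression": self.regression.to_dict(orient="records"),
            "flight_totals": self.flight_totals.to_dict(orient="records"),
            "wilcoxon": self.wilcoxon.to_dict(orient="records"),
            **self.extra,
        }


def validate(consensus: pd.DataFrame, expert: pd.DataFrame) -> ValidationReport:
    """Run the full validation battery and bundle the tables."""
    errors = per_photo_errors(consensus, expert)
    classes = confusion_classify(consensus, expert)
    return ValidationReport(
        photo_errors=errors,
        error_by_n=error_by_n_counters(errors),
        confusion=classes,
        confusion_props=confusion_proportions(classes),
        regression=regress_cs_on_expert(consensus, expert),
        flight_totals=flight_totals(consensus, expert),
        wilcoxon=paired_wilcoxon(consensus, expert),
    )
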