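"""qPCR time-course analysis and substrate-preference scoring.

When a strain grows in a mixture of two polysaccharides, the induction of
each substrate's PUL marker gene (a susC-like transporter gene) is followed
over time by qRT-PCR, normalized to 16S rRNA abundance and calibrated to the
glucose-grown culture, i.e. standard 2^-ddCt relative quantification.  Each
marker's time course is then classified:

* **inactive** — mean induction over all time points <= 5: 0 points;
* **active** — induction above 5 at every considered time point (the final
  point may be exempted for rapidly depleted substrates such as starch):
  1 point;
* **delayed** — everything else, i.e. activation was gradual: 0.5 points.

A substrate's preference score is its summed points divided by the number of
mixture assays it took part in, so scores live in [0, 1] and substrates can
be ranked (ties grouped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import QPCRSeries

__all__ = [
    "DynamicCall",
    "PreferenceTable",
    "ddct_relative_expression",
    "classify_dynamic",
    "classify_assay",
    "score_preferences",
    "preference_heatmap",
]

POINTS = {"inactive": 0.0, "delayed": 0.5, "active": 1.0}
DEFAULT_EXEMPT_FINAL = ("starch",)


@dataclass(frozen=True)
class DynamicCall:
    """Classified dynamic of one PUL marker in one mixture assay."""

    assay_id: str
    pul_id: str
    substrate: str
    dynamic: str
    points: float
    final_point_exempted: bool = False

    def __post_init__(self):
        if self.dynamic not in POINTS:
            raise ValueError(f"unknown dynamic {self.dynamic!r}")
        if self.points != POINTS[self.dynamic]:
            raise ValueError("points must follow the 0 / 0.5 / 1 rule")


@dataclass(frozen=True)
class PreferenceTable:
    """Per-substrate preference scores and the derived ranking.

    ``table`` is indexed by substrate with columns total_points, n_assays
    and score; ``ranking`` groups substrates with equal scores, best first.
    """

    table: pd.DataFrame
    ranking: tuple[tuple[str, ...], ...]

    def ranking_str(self) -> str:
        return " > ".join(", ".join(group) for group in self.ranking)


def ddct_relative_expression(
    ct: pd.DataFrame, sample: str, calibrator: str
) -> float:
    """Fold-change by the 2^-ddCt method with a 16S rRNA reference gene.

    ``ct`` is a long table with columns ``sample_id``, ``bio_rep``,
    ``tech_rep``, ``target_ct`` and ``reference_ct`` (the 16S well paired
    with each target well).  Per well, dCt = Ct_target - Ct_16S; technical
    wells are averaged within each biological replicate and then across
    replicates, all on the Ct scale; ddCt is the sample mean minus the
    calibrator mean and the fold-change 2^-ddCt (assay efficiency fixed
    at 2).
    """
    needed = {"sample_id", "bio_rep", "tech_rep", "target_ct", "reference_ct"}
    if not needed.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(needed)}")
    if ct["reference_ct"].isna().any():
        raise ValueError("missing 16S reference Ct values")
    if not np.isfinite(ct[["target_ct", "reference_ct"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")

    def mean_dct(label: str) -> float:
        rows = ct[ct["sample_id"] == label]
        if rows.empty:
            raise ValueError(f"no Ct rows for sample {label!r}")
        dct = rows["target_ct"] - rows["reference_ct"]
        per_bio = dct.groupby(rows["bio_rep"]).mean()
        return float(per_bio.mean())

    ddct = mean_dct(sample) - mean_dct(calibrator)
    return float(2.0 ** (-ddct))


def classify_dynamic(
    series: QPCRSeries,
    inactive_mean_threshold: float = 5.0,
    exempt_final: bool = False,
) -> DynamicCall:
    """Classify a marker time course as inactive, active or delayed.

    Rules are applied in order: (1) inactive when the mean induction over
    *all* time points is at or below the threshold; (2) active when every
    considered time point is strictly above it — the final point is dropped
    from consideration when ``exempt_final`` is set, accommodating
    substrates depleted before the last sample; (3) otherwise the
    activation was gradual: delayed.
    """
    if inactive_mean_threshold <= 0:
        raise ValueError("threshold must be positive")
    vals = series.induction
    if vals.size == 0:
        raise ValueError("empty qPCR series")
    exempted = bool(exempt_final and vals.size > 1)
    considered = vals[:-1] if exempted else vals
    if float(vals.mean()) <= inactive_mean_threshold:
        dyn = "inactive"
    elif np.all(considered > inactive_mean_threshold):
        dyn = "active"
    else:
        dyn = "delayed"
    return DynamicCall(
        assay_id=series.assay_id,
        pul_id=series.pul_id,
        substrate=series.substrate,
        dynamic=dyn,
        points=POINTS[dyn],
        final_point_exempted=exempted and dyn == "active",
    )


def classify_assay(
    series_list: list[QPCRSeries],
    inactive_mean_threshold: float = 5.0,
    exempt_final_substrates: tuple[str, ...] = DEFAULT_EXEMPT_FINAL,
) -> list[DynamicCall]:
    """Classify every series of an experiment, applying the final-point
    exemption to the configured substrates (by default only starch)."""
    return [
        classify_dynamic(
            s,
            inactive_mean_threshold,
            exempt_final=s.substrate in exempt_final_substrates,
        )
        for s in series_list
    ]


def score_preferences(
    calls: list[DynamicCall],
    assay_map: dict[str, set[str]] | None = None,
) -> PreferenceTable:
    """Summed points per substrate divided by its number of assays.

    ``assay_map`` (substrate -> assay ids containing it) defaults to the
    assays observed in ``calls``; substrates with zero assays are excluded
    with a warning.  The score is the arithmetic mean of awarded points, so
    it is bounded by [0, 1]; equal scores form tie groups in the ranking.
    """
    if assay_map is None:
        assay_map = {}
        for c in calls:
            assay_map.setdefault(c.substrate, set()).add(c.assay_id)
    rows = {}
    points: dict[str, float] = {}
    for c in calls:
        if c.substrate not in assay_map:
            raise ValueError(f"call substrate {c.substrate!r} missing from assay map")
        points[c.substrate] = points.get(c.substrate, 0.0) + c.points
    for sub, assays in assay_map.items():
        n = len(assays)
        if n == 0:
            warnings.warn(f"substrate {sub!r} has no assays; excluded from ranking")
            continue
        total = points.get(sub, 0.0)
        rows[sub] = {"total_points": total, "n_assays": n, "score": total / n}
    table = pd.DataFrame.from_dict(rows, orient="index").sort_values(
        "score", ascending=False
    )
    table.index.name = "substrate"
    ranking: list[tuple[str, ...]] = []
    for score in table["score"].unique():
        ranking.append(tuple(sorted(table.index[table["score"] == score])))
    return PreferenceTable(table=table, ranking=tuple(ranking))


def preference_heatmap(
    calls: list[DynamicCall],
    growth_rates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Composite table per mixture: both markers' dynamics plus growth rate.

    One row per assay with the two substrates, their dynamic codes, the
    mixture growth rate (NaN when unknown), a flag summarizing the pair
    ("both active", "one inactive", "one delayed", ...) and an arrow naming
    the delayed-or-inactive substrate, mirroring the composite heatmap
    figures.
    """
    growth_rates = growth_rates or {}
    by_assay: dict[str, list[DynamicCall]] = {}
    for c in calls:
        by_assay.setdefault(c.assay_id, []).append(c)
    rows = []
    for assay_id, group in by_assay.items():
        group = sorted(group, key=lambda c: c.substrate)
        dyns = [c.dynamic for c in group]
        if all(d == "active" for d in dyns):
            flag = "both active"
        elif all(d == "inactive" for d in dyns):
            flag = "both inactive"
        elif "inactive" in dyns:
            flag = "one inactive"
        elif all(d == "delayed" for d in dyns):
            flag = "both delayed"
        else:
            flag = "one delayed"
        weak = [c.substrate for c in group if c.dynamic != "active"]
        rows.append(
            {
                "assay_id": assay_id,
                "substrate_a": group[0].substrate,
                "substrate_b": group[-1].substrate if len(group) > 1 else "",
                "dynamic_a": group[0].dynamic,
                "dynamic_b": group[-1].dynamic if len(group) > 1 else "",
                "growth_rate": growth_rates.get(assay_id, float("nan")),
                "flag": flag,
                "arrow_to": ", ".join(weak),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "assay_id", "substrate_a", "substrate_b", "dynamic_a", "dynamic_b",
            "growth_rate", "flag", "arrow_to",
        ],
    )
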