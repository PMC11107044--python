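"""File formats, configuration, and annotation summaries.

All tabular interchange is plain UTF-8 TSV/CSV with header rows and "." as
the decimal separator; locus tags are opaque strings (annotation pipelines
mix RG252_*- and SAMN*-style tags freely).  Readers validate their input and
report offending rows by line number; write -> read round-trips are
lossless.  The :class:`Config` object gathers every tunable threshold of the
pipeline with the published cut-offs as defaults and round-trips through
YAML; unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import CountMatrix, InductionProfile, PULAnnotation, PULCall, PUL_ROLES
from .growth import GrowthCurve
from .preference import DynamicCall, PreferenceTable
from .synthetic import QPCRSeries

__all__ = [
    "Config",
    "AnnotationSummary",
    "cazyme_density",
    "format_cazyme_density",
    "read_counts",
    "write_counts",
    "read_pul_annotation",
    "write_pul_annotation",
    "read_growth_csv",
    "write_growth_csv",
    "read_qpcr_csv",
    "write_qpcr_csv",
    "write_log2fc",
    "write_pul_calls",
    "write_dynamic_calls",
    "write_preference_table",
]


@dataclass
class Config:
    """Pipeline thresholds and settings (defaults are the published cut-offs)."""

    # gene/PUL induction
    log2fc_gate: float = 3.0
    confirm_threshold: float = 3.0
    specificity_margin: float = 1.0
    pseudocount: float = 0.5
    min_cpm: float = 1.0
    min_samples: int = 3
    tmm_logratio_trim: float = 0.30
    tmm_abs_trim: float = 0.05
    # growth phenotyping
    rate_excellent: float = 0.5
    od_excellent: float = 3.0
    od_poor: float = 1.5
    min_points: int = 5
    r2_min: float = 0.995
    od_floor: float = 0.02
    # qPCR preference
    inactive_mean: float = 5.0
    exempt_final_substrates: tuple[str, ...] = ("starch",)
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        positive = (
            "log2fc_gate", "confirm_threshold", "specificity_margin",
            "min_cpm", "rate_excellent", "od_excellent", "od_poor",
            "inactive_mean", "r2_min", "od_floor",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.pseudocount < 0 or self.min_samples < 0 or self.min_points < 2:
            raise ValueError("invalid filtering settings")
        self.exempt_final_substrates = tuple(self.exempt_final_substrates)

    @classmethod
    def load(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        data = asdict(self)
        data["exempt_final_substrates"] = list(self.exempt_final_substrates)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass(frozen=True)
class AnnotationSummary:
    """Genome-level CAZyme content, as tabulated per strain."""

    strain: str
    genome_size_mb: float
    n_cazymes: int

    @property
    def density_per_mb(self) -> float:
        return cazyme_density(self.n_cazymes, self.genome_size_mb)


def cazyme_density(n_cazymes: int, genome_size_mb: float) -> float:
    """CAZymes per Mb of genome, rounded to one decimal as tabulated."""
    if genome_size_mb <= 0:
        raise ValueError("genome size must be positive")
    if n_cazymes < 0:
        raise ValueError("CAZyme count must be non-negative")
    return round(n_cazymes / genome_size_mb, 1)


def format_cazyme_density(n_cazymes: int, genome_size_mb: float) -> str:
    """Density as printed: one decimal, trailing '.0' dropped (58.1, 51)."""
    d = cazyme_density(n_cazymes, genome_size_mb)
    return str(int(d)) if d == int(d) else f"{d:.1f}"


# ---------------------------------------------------------------------------
# counts / metadata / lengths / annotation
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    # engine="python" handles CRLF and LF uniformly
    return pd.read_csv(path, sep=sep, engine="python")


def read_counts(
    counts_tsv: str | Path,
    meta_tsv: str | Path,
    lengths_tsv: str | Path | None = None,
) -> CountMatrix:
    """Read a counts bundle: genes x samples TSV, sample metadata TSV and an
    optional gene-length TSV.  Malformed rows are reported by line number
    (header = line 1)."""
    raw = _read_table(counts_tsv, "\t")
    gene_col = raw.columns[0]
    counts = raw.set_index(gene_col)
    counts.index.name = "gene_id"
    arr = counts.to_numpy()
    bad = np.argwhere(~np.isfinite(arr.astype(float)) | (arr < 0) | (arr != np.floor(arr)))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{counts_tsv}: line {r + 2}, sample {counts.columns[c]!r}: "
            f"count {arr[r, c]!r} is not a non-negative integer"
        )
    meta = _read_table(meta_tsv, "\t")
    for col in ("sample_id", "substrate", "replicate"):
        if col not in meta.columns:
            raise ValueError(f"{meta_tsv}: missing column {col!r}")
    meta = meta.set_index("sample_id")
    lengths = None
    if lengths_tsv is not None:
        lt = _read_table(lengths_tsv, "\t")
        if not {"gene_id", "length_bp"}.issubset(lt.columns):
            raise ValueError(f"{lengths_tsv}: need columns gene_id, length_bp")
        neg = lt.index[lt["length_bp"] <= 0]
        if len(neg):
            raise ValueError(f"{lengths_tsv}: line {neg[0] + 2}: non-positive length")
        lengths = lt.set_index("gene_id")["length_bp"].astype(float)
    return CountMatrix(counts.astype(int), meta, lengths)


def write_counts(cm: CountMatrix, counts_tsv: str | Path, meta_tsv: str | Path,
                 lengths_tsv: str | Path | None = None) -> None:
    cm.counts.to_csv(counts_tsv, sep="\t")
    cm.sample_meta.to_csv(meta_tsv, sep="\t")
    if lengths_tsv is not None and cm.gene_lengths is not None:
        cm.gene_lengths.rename("length_bp").to_csv(lengths_tsv, sep="\t")


def read_pul_annotation(path: str | Path) -> PULAnnotation:
    """PUL annotation TSV: locus_tag, pul_id, role, predicted_substrate,
    cazy_families (semicolon-separated)."""
    t = _read_table(path, "\t")
    needed = {"locus_tag", "pul_id", "role"}
    if not needed.issubset(t.columns):
        raise ValueError(f"{path}: need columns {sorted(needed)}")
    bad_role = t.index[~t["role"].isin(PUL_ROLES)]
    if len(bad_role):
        i = bad_role[0]
        raise ValueError(f"{path}: line {i + 2}: unknown role {t.loc[i, 'role']!r}")
    if "predicted_substrate" not in t.columns:
        t["predicted_substrate"] = ""
    t["predicted_substrate"] = t["predicted_substrate"].fillna("")
    if "cazy_families" in t.columns:
        t["cazy_families"] = [
            [] if (not isinstance(v, str) or not v) else v.split(";")
            for v in t["cazy_families"]
        ]
    else:
        t["cazy_families"] = [[] for _ in range(len(t))]
    return PULAnnotation(t)


def write_pul_annotation(ann: PULAnnotation, path: str | Path) -> None:
    t = ann.table.copy()
    t["cazy_families"] = [";".join(v) for v in t["cazy_families"]]
    t.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# growth curves (long CSV)
# ---------------------------------------------------------------------------

def read_growth_csv(path: str | Path) -> dict[tuple[str, str, int], GrowthCurve]:
    """Long growth CSV (strain, substrate, replicate, time_h, od,
    dilution_factor) -> curves keyed by (strain, substrate, replicate)."""
    t = _read_table(path, ",")
    needed = {"strain", "substrate", "replicate", "time_h", "od", "dilution_factor"}
    if not needed.issubset(t.columns):
        raise ValueError(f"{path}: need columns {sorted(needed)}")
    neg = t.index[t["od"] < 0]
    if len(neg):
        raise ValueError(f"{path}: line {neg[0] + 2}: negative OD")
    curves = {}
    for (strain, sub, rep), grp in t.groupby(["strain", "substrate", "replicate"]):
        grp = grp.sort_values("time_h")
        curves[(strain, sub, int(rep))] = GrowthCurve(
            grp["time_h"].to_numpy(float),
            grp["od"].to_numpy(float),
            grp["dilution_factor"].to_numpy(float),
        )
    return curves


def write_growth_csv(curves: dict[tuple[str, str, int], GrowthCurve],
                     path: str | Path) -> None:
    rows = []
    for (strain, sub, rep), c in curves.items():
        for t, od, f in zip(c.time_h, c.measured_od, c.dilution_factor):
            rows.append({"strain": strain, "substrate": sub, "replicate": rep,
                         "time_h": t, "od": od, "dilution_factor": f})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# qPCR series (long CSV)
# ---------------------------------------------------------------------------

def write_qpcr_csv(series_list: list[QPCRSeries], path: str | Path) -> None:
    """Long qPCR CSV of relative normalized expression (value_type rel_expr);
    one row per assay x PUL x time x replicate well (or per time point when
    only the replicate-mean series is held)."""
    rows = []
    for s in series_list:
        if s.wells is not None:
            for _, w in s.wells.iterrows():
                rows.append({
                    "assay_id": s.assay_id, "pul_id": s.pul_id, "substrate": s.substrate,
                    "time_h": w["time_h"], "bio_rep": int(w["bio_rep"]),
                    "tech_rep": int(w["tech_rep"]), "value": w["value"],
                    "value_type": "rel_expr",
                })
        else:
            for t, v in zip(s.time_points_h, s.induction):
                rows.append({
                    "assay_id": s.assay_id, "pul_id": s.pul_id, "substrate": s.substrate,
                    "time_h": t, "bio_rep": 1, "tech_rep": 1, "value": v,
                    "value_type": "rel_expr",
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_qpcr_csv(path: str | Path) -> list[QPCRSeries]:
    """Read a long qPCR CSV back into replicate-mean induction series.

    Rows tagged ``value_type=rel_expr`` are relative normalized expression;
    technical wells are averaged within biological replicate, then across
    replicates, per time point.  Rows with ``pul_id=reference`` (16S) are
    only meaningful for Ct-valued tables and are ignored here.
    """
    t = _read_table(path, ",")
    needed = {"assay_id", "pul_id", "substrate", "time_h", "bio_rep",
              "tech_rep", "value", "value_type"}
    if not needed.issubset(t.columns):
        raise ValueError(f"{path}: need columns {sorted(needed)}")
    bad = t.index[(t["value_type"] == "rel_expr") & (t["value"] <= 0)]
    if len(bad):
        raise ValueError(f"{path}: line {bad[0] + 2}: non-positive expression value")
    t = t[(t["value_type"] == "rel_expr") & (t["pul_id"] != "reference")]
    out = []
    for (assay, pul, sub), grp in t.groupby(["assay_id", "pul_id", "substrate"]):
        per_bio = grp.groupby(["time_h", "bio_rep"])["value"].mean()
        series = per_bio.groupby("time_h").mean().sort_index()
        out.append(QPCRSeries(
            assay_id=assay, pul_id=pul, substrate=sub,
            time_points_h=series.index.to_numpy(float),
            induction=series.to_numpy(float),
        ))
    return out


# ---------------------------------------------------------------------------
# analysis outputs
# ---------------------------------------------------------------------------

def write_log2fc(profile: InductionProfile, path: str | Path) -> None:
    out = profile.log2fc.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_pul_calls(calls: list[PULCall], path: str | Path) -> None:
    pd.DataFrame([{
        "pul_id": c.pul_id, "substrate": c.substrate,
        "marker_log2fc": c.marker_log2fc, "status": c.status,
        "near_tie": c.near_tie,
    } for c in calls]).to_csv(path, sep="\t", index=False)


def write_dynamic_calls(calls: list[DynamicCall], path: str | Path) -> None:
    pd.DataFrame([{
        "assay_id": c.assay_id, "pul_id": c.pul_id, "substrate": c.substrate,
        "dynamic": c.dynamic, "points": c.points,
        "final_point_exempted": c.final_point_exempted,
    } for c in calls]).to_csv(path, sep="\t", index=False)


def write_preference_table(prefs: PreferenceTable, path: str | Path) -> None:
    prefs.table.to_csv(path, sep="\t")
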