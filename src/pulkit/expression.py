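"""Glucose-referenced induction profiling of polysaccharide utilization loci.

Takes a gene-level RNA-seq count matrix over a glucose reference plus a panel
of polysaccharide growth conditions and turns it into per-gene log2
fold-changes versus glucose, then aggregates them over PUL marker genes
(susC/susD-like transporter pairs) to call, for every PUL, which substrates
induce it.

Normalization is implemented from first principles:

* within-sample: counts per million (CPM) and, when gene lengths are known,
  transcripts per million (TPM);
* between-sample: trimmed mean of M-values (TMM) scaling factors — the
  doubly-trimmed, precision-weighted mean of per-gene log ratios against a
  reference sample, with factors normalized to geometric mean 1.

Induction is estimated as the log2 ratio of mean TMM-normalized CPM on a
substrate versus the glucose reference (with a pseudocount), which is the
quantity the heatmaps and the |log2FC| > 3 gene gate operate on.  No
negative-binomial GLM testing is performed: target calling is deliberately
threshold-based, mirroring how PUL induction is read out in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "InductionProfile",
    "PULAnnotation",
    "PULCall",
    "cpm",
    "tpm",
    "tmm_factors",
    "filter_expressed",
    "log2fc_vs_reference",
    "select_regulated",
    "pul_heatmap_matrix",
    "call_pul_targets",
]

MARKER_ROLES = ("susC", "susD")
PUL_ROLES = ("susC", "susD", "CAZyme", "regulator", "other")
CALL_STATUSES = ("confirmed", "cross_activated", "moderate", "not_induced")


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample condition metadata.

    ``counts``: DataFrame indexed by gene id, one column per sample.
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``substrate`` and ``replicate``.
    ``gene_lengths``: optional Series (bp) indexed by gene id; required
    only for TPM.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self):
        c = self.counts
        vals = c.to_numpy()
        if vals.size and (np.any(vals < 0) or np.any(vals != np.floor(vals))):
            raise ValueError("counts must be non-negative integers")
        missing = [s for s in c.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        for col in ("substrate", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")

    @property
    def substrates(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            sub = self.sample_meta.loc[s, "substrate"]
            if sub not in seen:
                seen.append(sub)
        return seen

    def samples_for(self, substrate: str) -> list[str]:
        return [
            s
            for s in self.counts.columns
            if self.sample_meta.loc[s, "substrate"] == substrate
        ]

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.sample_meta, self.gene_lengths)


@dataclass
class InductionProfile:
    """Per-gene log2 fold-change versus the reference substrate."""

    log2fc: pd.DataFrame  # genes x non-reference substrates
    mean_ref_cpm: pd.Series
    reference: str

    def __post_init__(self):
        if self.reference in self.log2fc.columns:
            raise ValueError("log2FC columns must exclude the reference substrate")
        if not np.all(np.isfinite(self.log2fc.to_numpy())):
            raise ValueError("log2FC values must be finite")


@dataclass
class PULAnnotation:
    """Locus-tag level PUL membership table.

    ``table`` columns: locus_tag, pul_id, role (susC/susD/CAZyme/regulator/
    other), predicted_substrate (may be empty), cazy_families (list).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"locus_tag", "pul_id", "role"}
        if not required.issubset(t.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        if t["locus_tag"].duplicated().any():
            dup = t.loc[t["locus_tag"].duplicated(), "locus_tag"].iloc[0]
            raise ValueError(f"duplicate locus tag: {dup}")
        bad = set(t["role"]) - set(PUL_ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}; expected {PUL_ROLES}")
        no_susc = [
            p
            for p, grp in t.groupby("pul_id")
            if not (grp["role"] == "susC").any()
        ]
        if no_susc:
            raise ValueError(
                f"PULs without a susC-role member (not scoreable): {sorted(no_susc)}"
            )

    @property
    def pul_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["pul_id"]))

    def members(self, pul_id: str) -> pd.DataFrame:
        return self.table[self.table["pul_id"] == pul_id]


@dataclass(frozen=True)
class PULCall:
    """Induction status of one PUL on one substrate."""

    pul_id: str
    substrate: str
    marker_log2fc: float
    status: str
    near_tie: bool = False

    def __post_init__(self):
        if self.status not in CALL_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


# ---------------------------------------------------------------------------
# within- and between-sample normalization
# ---------------------------------------------------------------------------

def cpm(counts: CountMatrix, norm_factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million of each sample's (optionally TMM-scaled) library.

    With ``norm_factors`` the effective library size is
    ``column sum * factor``; plain CPM columns sum to exactly 1e6.
    """
    lib = counts.counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        empty = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples: {empty}")
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(lib.index)
    return counts.counts.div(lib, axis=1) * 1e6


def tpm(counts: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalized within-sample abundance.

    Per sample, ``rate_g = count_g / length_g`` and
    ``TPM_g = rate_g / sum(rates) * 1e6``; columns sum to exactly 1e6.
    """
    if counts.gene_lengths is None:
        raise ValueError("gene lengths are required for TPM")
    lengths = counts.gene_lengths.reindex(counts.counts.index)
    bad = list(lengths.index[lengths.isna() | (lengths <= 0)])
    if bad:
        raise ValueError(f"missing or non-positive gene length for: {bad[:5]}")
    rates = counts.counts.div(lengths, axis=0)
    return rates.div(rates.sum(axis=0), axis=1) * 1e6


def tmm_factors(
    counts: CountMatrix,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    ref_column: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the column whose 75th-percentile count
    proportion is closest to the mean of those percentiles.  For every
    sample, per-gene M (log2 ratio of proportions vs the reference) and A
    (average log2 abundance) are computed on genes observed in both; genes
    in the upper/lower ``logratio_trim`` tails of M and ``abs_trim`` tails
    of A are discarded and the factor is 2 to the precision-weighted mean
    of the remaining M values, the weights being inverse binomial
    asymptotic variances.
    """
    mat = counts.counts.to_numpy(dtype=float)
    samples = list(counts.counts.columns)
    if len(samples) < 2:
        raise ValueError("TMM needs at least two samples")
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    props = mat / lib

    if ref_column is None:
        uq = np.quantile(props, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = samples.index(ref_column)

    factors = np.ones(len(samples))
    for s in range(len(samples)):
        factors[s] = _tmm_pair(
            mat[:, s], mat[:, ref_idx], lib[s], lib[ref_idx],
            logratio_trim, abs_trim, samples[s],
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    abs_trim: float,
    label: str,
) -> float:
    both = (obs > 0) & (ref > 0)
    if not both.any():
        warnings.warn(f"sample {label!r}: no genes expressed in common with "
                      "the TMM reference; factor set to 1")
        return 1.0
    o, r = obs[both], ref[both]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # inverse of the asymptotic variance of M under binomial sampling
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:  # identical proportions: nothing to trim
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or not np.isfinite(v[keep]).all():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def filter_expressed(
    counts: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3
) -> CountMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples."""
    keep = (cpm(counts) >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            f"no genes pass CPM >= {min_cpm} in >= {min_samples} samples; "
            "lower min_cpm or min_samples"
        )
    return counts.subset_genes(counts.counts.index[keep])


# ---------------------------------------------------------------------------
# induction profiling
# ---------------------------------------------------------------------------

def log2fc_vs_reference(
    counts: CountMatrix,
    reference: str = "glucose",
    pseudocount: float = 0.5,
    norm_factors: pd.Series | None = None,
) -> InductionProfile:
    """Per-gene log2 fold-change of each substrate versus the reference.

    Replicate columns are TMM-normalized (factors computed here unless
    supplied), converted to CPM, and averaged per substrate; the profile is
    ``log2((mean_substrate + pseudocount) / (mean_reference + pseudocount))``.
    The pseudocount (CPM units) keeps values finite for genes silent on
    glucose.
    """
    if reference not in counts.substrates:
        raise ValueError(
            f"reference substrate {reference!r} not present; "
            f"have {counts.substrates}"
        )
    if norm_factors is None:
        norm_factors = tmm_factors(counts)
    ncpm = cpm(counts, norm_factors)
    means = {
        sub: ncpm[counts.samples_for(sub)].mean(axis=1)
        for sub in counts.substrates
    }
    ref_mean = means[reference]
    fc = {
        sub: np.log2((means[sub] + pseudocount) / (ref_mean + pseudocount))
        for sub in counts.substrates
        if sub != reference
    }
    return InductionProfile(
        log2fc=pd.DataFrame(fc), mean_ref_cpm=ref_mean, reference=reference
    )


def select_regulated(profile: InductionProfile, threshold: float = 3.0) -> set[str]:
    """Genes with log2FC strictly above ``threshold`` or strictly below
    ``-threshold`` on at least one substrate."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mask = (profile.log2fc > threshold) | (profile.log2fc < -threshold)
    return set(profile.log2fc.index[mask.any(axis=1)])


def pul_heatmap_matrix(
    profile: InductionProfile, annotation: PULAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene heatmap matrix grouped by PUL, plus the marker summary.

    Returns ``(gene_matrix, summary)``: the gene matrix has one row per
    annotated locus tag (ordered by pul_id then locus_tag, indexed by
    (pul_id, locus_tag)); genes filtered out of the profile appear as NaN
    rows, not zeros.  The summary has one row per PUL — the mean log2FC of
    its susC/susD members — which encodes the observation that marker-gene
    induction dominates that of effector genes.
    """
    ann = annotation.table.sort_values(["pul_id", "locus_tag"])
    present = ann["locus_tag"].isin(profile.log2fc.index)
    if not present.any():
        raise ValueError("annotation references no genes present in the profile")
    gene_matrix = profile.log2fc.reindex(ann["locus_tag"])
    gene_matrix.index = pd.MultiIndex.from_arrays(
        [ann["pul_id"], ann["locus_tag"]], names=["pul_id", "locus_tag"]
    )
    rows = {}
    for pul in annotation.pul_ids:
        members = annotation.members(pul)
        markers = members.loc[members["role"].isin(MARKER_ROLES), "locus_tag"]
        rows[pul] = profile.log2fc.reindex(markers).mean(axis=0)
    summary = pd.DataFrame(rows).T
    summary.index.name = "pul_id"
    return gene_matrix, summary


def call_pul_targets(
    summary: pd.DataFrame,
    confirm_threshold: float = 3.0,
    specificity_margin: float = 1.0,
) -> list[PULCall]:
    """Substrate calls per PUL from the marker (susC/susD) summary matrix.

    For every PUL, the substrate with the maximal marker log2FC is
    *confirmed* when it exceeds ``confirm_threshold``; any other substrate
    above the threshold is *cross_activated*; substrates in
    ``(1, confirm_threshold]`` are *moderate* (induced but inconclusive);
    everything else is *not_induced*.  Cross-activated substrates within
    ``specificity_margin`` log2 units of the maximum are flagged
    ``near_tie`` so near-equal inductions are visible in reports.
    """
    if confirm_threshold <= 0 or specificity_margin <= 0:
        raise ValueError("thresholds must be positive")
    calls: list[PULCall] = []
    for pul, row in summary.iterrows():
        vals = row.dropna()
        if vals.empty:
            continue
        best = vals.idxmax()
        for sub, v in vals.items():
            v = float(v)
            if sub == best and v > confirm_threshold:
                status = "confirmed"
            elif v > confirm_threshold:
                status = "cross_activated"
            elif v > 1.0:
                status = "moderate"
            else:
                status = "not_induced"
            calls.append(
                PULCall(
                    pul_id=str(pul),
                    substrate=str(sub),
                    marker_log2fc=v,
                    status=status,
                    near_tie=(
                        status == "cross_activated"
                        and float(vals[best]) - v <= specificity_margin
                    ),
                )
            )
    return calls


def confirmed_puls(calls: list[PULCall]) -> set[str]:
    """PULs with at least one confirmed substrate call."""
    return {c.pul_id for c in calls if c.status == "confirmed"}
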