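"""Time-course expression processing and gene-set derivation.

Covers the RNA-seq side of the analysis: TPM conversion, threshold-based
differential-expression calls between knockout (KO) and wild-type (WT)
conditions at each timepoint, deterministic temporal-profile clustering by
per-interval sign patterns, PCA projection of samples, and the audited set
algebra that derives the "degradation-dependent" and "naive-GRN-like" gene
sets.  Every set operation is recorded in a :class:`GeneSetLedger` so the
derivation chain (operand sizes, operation, result size) is reproducible and
checkable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DegResult",
    "ProfileCluster",
    "GeneSetLedger",
    "compute_tpm",
    "call_degs",
    "mean_by_group",
    "cluster_profiles",
    "degradation_cluster",
    "cnot8_dependent_degradation",
    "derive_grn_like",
    "intersect_naive_like",
    "pca_projection",
    "summarize_ratio",
]

TIMEPOINTS_H = (0, 6, 12, 24, 48)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a sample sheet.

    ``values``: DataFrame indexed by gene, columns are sample ids.
    ``samples``: DataFrame indexed by sample id with columns condition
    (WT/KO), timepoint_h, replicate.  ``gene_lengths``: Series in nt,
    required for TPM conversion.  ``units`` records whether values are raw
    counts or TPM.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: Optional[pd.Series] = None
    units: str = "counts"

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples absent from sample sheet: {sorted(missing)}")

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)],
            self.samples.loc[list(sample_ids)],
            self.gene_lengths,
            self.units,
        )


@dataclass
class DegResult:
    """Thresholded differential-expression call at one timepoint (KO vs WT)."""

    timepoint_h: float
    up_genes: frozenset
    down_genes: frozenset
    fc_threshold: float = 1.5
    expr_threshold_log2_tpm: float = 1.0

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValueError("a gene cannot be both up- and down-regulated")


@dataclass
class ProfileCluster:
    cluster_id: int
    pattern: str  # sign string over successive intervals, e.g. "----"
    member_genes: frozenset
    mean_profile: np.ndarray  # per-timepoint mean log2 expression


class GeneSetLedger:
    """Named gene sets plus a provenance record for every derivation step."""

    def __init__(self) -> None:
        self.sets: dict[str, frozenset] = {}
        self.records: list[dict] = []

    def record(
        self,
        name: str,
        operation: str,
        operands: Mapping[str, int],
        result: Iterable,
        **extra,
    ) -> frozenset:
        result = frozenset(result)
        self.sets[name] = result
        self.records.append(
            {
                "name": name,
                "operation": operation,
                "operands": dict(operands),
                "size": len(result),
                **extra,
            }
        )
        return result

    def size(self, name: str) -> int:
        return len(self.sets[name])

    def to_dict(self) -> dict:
        return {"sets": {k: sorted(v) for k, v in self.sets.items()}, "records": self.records}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# expression-level operations


def compute_tpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to transcripts per million.

    TPM_gi = 1e6 * (count_gi / length_g) / sum_g(count_gi / length_g); every
    sample column of the result sums to 1e6.
    """
    if counts.gene_lengths is None:
        raise ValueError("gene lengths are required for TPM conversion")
    lengths = counts.gene_lengths.reindex(counts.values.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    rate = counts.values.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero column total, cannot normalize: {bad}")
    tpm = rate.div(totals, axis=1) * 1e6
    return ExpressionMatrix(tpm, counts.samples, counts.gene_lengths, units="TPM")


def mean_by_group(em: ExpressionMatrix, condition: str, timepoint_h: float) -> pd.Series:
    """Replicate-mean expression per gene for one (condition, timepoint)."""
    mask = (em.samples["condition"] == condition) & (em.samples["timepoint_h"] == timepoint_h)
    cols = list(em.samples.index[mask])
    if not cols:
        raise KeyError(f"no samples for condition={condition}, t={timepoint_h} h")
    return em.values[cols].mean(axis=1)


def call_degs(
    tpm_ko: pd.Series,
    tpm_wt: pd.Series,
    fc: float = 1.5,
    expr_log2: float = 1.0,
    pseudocount: float = 0.1,
    timepoint_h: float = float("nan"),
) -> DegResult:
    """Threshold-based DEG call: KO vs WT at one timepoint.

    A gene is called up when (TPM_KO + eps)/(TPM_WT + eps) > fc and
    log2(max(TPM_KO, TPM_WT)) > expr_log2; down symmetrically.  The
    expression floor keeps fold changes on barely-expressed genes from being
    called; the pseudocount eps guards division by zero while leaving the
    ratio essentially the TPM ratio for expressed genes.
    """
    tpm_ko, tpm_wt = tpm_ko.align(tpm_wt, join="inner")
    ratio = (tpm_ko + pseudocount) / (tpm_wt + pseudocount)
    with np.errstate(divide="ignore"):
        expressed = np.log2(np.maximum(tpm_ko, tpm_wt)) > expr_log2
    up = frozenset(tpm_ko.index[(ratio > fc) & expressed])
    down = frozenset(tpm_ko.index[(ratio < 1.0 / fc) & expressed])
    return DegResult(timepoint_h, up, down, fc, expr_log2)


def cluster_profiles(
    log2_timecourse: pd.DataFrame,
    n_top: int = 8,
    step_threshold: float = 0.5,
) -> tuple[list[ProfileCluster], float]:
    """Cluster genes by the sign pattern of their temporal profile.

    ``log2_timecourse`` is genes x ordered timepoints of log-scale
    expression (with pseudocount already applied).  Each successive interval
    is discretized to '+', '-' or '0' by comparing the log2 change against
    ``step_threshold``; genes sharing a pattern form a cluster.  Returns the
    ``n_top`` most populous clusters (ties broken by pattern string) and the
    fraction of the gene universe they cover.
    """
    if log2_timecourse.shape[1] < 3:
        raise ValueError("need at least 3 timepoints to cluster temporal profiles")
    values = log2_timecourse.to_numpy(dtype=float)
    diffs = np.diff(values, axis=1)
    symbols = np.where(diffs > step_threshold, "+", np.where(diffs < -step_threshold, "-", "0"))
    patterns = ["".join(row) for row in symbols]
    by_pattern: dict[str, list] = {}
    for gene, pattern in zip(log2_timecourse.index, patterns):
        by_pattern.setdefault(pattern, []).append(gene)
    ordered = sorted(by_pattern.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:n_top]
    clusters = [
        ProfileCluster(
            cluster_id=i + 1,
            pattern=pattern,
            member_genes=frozenset(genes),
            mean_profile=log2_timecourse.loc[genes].mean(axis=0).to_numpy(),
        )
        for i, (pattern, genes) in enumerate(ordered)
    ]
    covered = sum(len(c.member_genes) for c in clusters) / len(log2_timecourse)
    return clusters, covered


def degradation_cluster(clusters: Sequence[ProfileCluster]) -> frozenset:
    """Members of the continuous-downregulation (all '-') cluster."""
    for cluster in clusters:
        if set(cluster.pattern) == {"-"}:
            return cluster.member_genes
    warnings.warn("no continuous-downregulation cluster found", stacklevel=2)
    return frozenset()


# ---------------------------------------------------------------------------
# gene-set algebra


def cnot8_dependent_degradation(
    deg_up_union: Iterable,
    degradation_set: Iterable,
    ledger: GeneSetLedger,
    name: str = "cnot8_dependent_degradation",
) -> frozenset:
    """Genes both KO-upregulated and in the degradation cluster.

    The intersection of the union of KO-up DEGs (all timepoints) with the
    continuous-downregulation cluster; the ledger records both operand sizes
    and the resulting fraction of the degradation set.
    """
    deg_up_union = frozenset(deg_up_union)
    degradation_set = frozenset(degradation_set)
    result = deg_up_union & degradation_set
    fraction = (
        summarize_ratio(len(result), len(degradation_set)) if degradation_set else 0.0
    )
    return ledger.record(
        name,
        "intersection",
        {"ko_upregulated_union": len(deg_up_union), "degradation_cluster": len(degradation_set)},
        result,
        fraction_of_degradation_set_pct=fraction,
    )


def derive_grn_like(
    up_by_timepoint: Mapping[float, Iterable],
    esc_up: Iterable,
    ledger: GeneSetLedger,
    name: str = "naive_grn_like",
) -> frozenset:
    """Derive the naive-GRN-like set from per-timepoint KO-up sets.

    From the KO-up sets at 6, 12, 24 and 48 h, four disjoint categories are
    formed: continuous (up at all four), shared-24&48 (up at 24 and 48 h but
    not all four), 24-only (up at 24 h but not 48 h) and 48-only (up at 48 h
    but not 24 h).  Their union, minus genes already up in undifferentiated
    (0 h) cells, is the result; every intermediate size is recorded.
    """
    required = (6, 12, 24, 48)
    ups = {}
    for t in required:
        match = [k for k in up_by_timepoint if float(k) == float(t)]
        if not match:
            raise KeyError(f"missing KO-up set for timepoint {t} h")
        ups[t] = frozenset(up_by_timepoint[match[0]])
    esc_up = frozenset(esc_up)

    continuous = ups[6] & ups[12] & ups[24] & ups[48]
    shared_24_48 = (ups[24] & ups[48]) - continuous
    only_24 = ups[24] - ups[48]
    only_48 = ups[48] - ups[24]

    categories = [continuous, shared_24_48, only_24, only_48]
    union: frozenset = frozenset().union(*categories)
    if sum(len(c) for c in categories) != len(union):
        raise RuntimeError("internal error: GRN categories are not disjoint")

    final = union - esc_up
    return ledger.record(
        name,
        "union_minus_esc_up",
        {
            "continuous_6_48": len(continuous),
            "shared_24_48": len(shared_24_48),
            "only_24": len(only_24),
            "only_48": len(only_48),
            "union": len(union),
            "esc_up": len(esc_up),
            "excluded": len(union & esc_up),
        },
        final,
    )


def intersect_naive_like(
    cnot8_dep_set: Iterable,
    naive_like_reference: Iterable,
    ledger: GeneSetLedger,
    name: str = "naive_like_cnot8_dependent",
) -> frozenset:
    """Intersect the Cnot8-dependent set with an external naive-like gene list."""
    cnot8_dep_set = frozenset(cnot8_dep_set)
    naive_like_reference = frozenset(naive_like_reference)
    if not naive_like_reference:
        warnings.warn("naive-like reference list is empty", stacklevel=2)
    return ledger.record(
        name,
        "intersection",
        {
            "cnot8_dependent": len(cnot8_dep_set),
            "naive_like_reference": len(naive_like_reference),
        },
        cnot8_dep_set & naive_like_reference,
    )


# ---------------------------------------------------------------------------
# projection and reporting helpers


def pca_projection(em: ExpressionMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the top two principal axes of gene-standardized
    expression.

    Genes are centred and scaled to unit variance across samples; genes with
    zero variance carry no information and are dropped.  Returns per-sample
    PC1/PC2 coordinates and the explained-variance fractions.
    """
    if em.values.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = em.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("degenerate input: every gene is constant across samples")
    if (~keep).any():
        logger.info("pca: dropping %d zero-variance genes", int((~keep).sum()))
    Z = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    n_comp = min(2, em.values.shape[1] - 1) or 1
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(Z.T)
    if coords.shape[1] < 2:  # two samples only: PC2 is degenerate
        coords = np.hstack([coords, np.zeros((coords.shape[0], 1))])
    frame = pd.DataFrame(coords[:, :2], index=em.values.columns, columns=["PC1", "PC2"])
    return frame, pca.explained_variance_ratio_


def summarize_ratio(numerator: int, denominator: int) -> float:
    """Percentage numerator/denominator rounded to one decimal place."""
    if denominator == 0:
        raise ZeroDivisionError("denominator must be positive")
    return round(100.0 * numerator / denominator, 1)
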