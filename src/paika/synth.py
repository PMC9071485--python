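"""Synthetic inputs with known truth for every pipeline stage.

Three generators, all seed-deterministic and all paired with a truth table
sufficient to score the downstream stage:

- :func:`simulate_tailed_reads` emits aligned long-read records whose 3'
  soft clips encode sampled poly(A) tails.  Within-gene tail lengths are
  lognormal (integer nt, >= 1), matching the roughly lognormal shape of real
  per-gene tail-length distributions; substitution errors are applied to
  tail bases only, so alignment stays trivial and the tail-calling logic is
  isolated.  A configurable fraction of reads is stored reverse-strand
  (reverse complement with a leading soft clip) to exercise the strand path.
- :func:`simulate_decay_series` draws exponential-decay time courses with
  multiplicative lognormal noise.
- :func:`simulate_expression_timecourse` plants monotone-down / flat /
  monotone-up temporal templates over a 5-point time course in two
  conditions, with an optional KO "stabilization" effect (the decline of a
  designated gene subset halts after 12 h) so threshold DEG calling has a
  planted signal at 24/48 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .decay import DecaySeries, normalize_series
from .dynamics import ExpressionMatrix
from .tailcall import AlignedRead, GeneAnnotation, GeneInterval, reverse_complement

__all__ = [
    "TailSimConfig",
    "simulate_tailed_reads",
    "simulate_decay_series",
    "simulate_expression_timecourse",
    "DEFAULT_TEMPLATES",
]

_BASES = np.array(list("ACGT"))


@dataclass
class TailSimConfig:
    """Study conditions for the tailed-read generator.

    ``geom_mean_nt`` is the condition-level geometric-mean tail length;
    per-gene geometric means scatter around it lognormally with
    ``gene_log_sigma`` and within-gene lengths scatter with ``log_sigma``.
    """

    n_genes: int = 500
    reads_per_gene: int = 200
    geom_mean_nt: float = 100.0
    log_sigma: float = 0.25  # within-gene spread of ln(tail length)
    gene_log_sigma: float = 0.3  # gene-to-gene spread of ln(geometric mean)
    base_error_rate: float = 0.01
    frac_reverse: float = 0.2  # fraction of genes on '-', i.e. reverse-strand records
    frac_no_tail: float = 0.0
    pass_mean: float = 12.0  # passes ~ 1 + Poisson(pass_mean - 1)
    gene_body_len: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_error_rate", "frac_reverse", "frac_no_tail"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.geom_mean_nt <= 0:
            raise ValueError("geom_mean_nt must be positive")


def default_annotation(
    n_genes: int,
    gene_body_len: int = 100,
    gap: int = 100,
    frac_minus: float = 0.0,
    seed: int = 0,
) -> GeneAnnotation:
    """One interval per gene along chr1; a ``frac_minus`` fraction on '-'.

    Transcripts of minus-strand genes are emitted as reverse-strand
    alignments (reverse complement stored, leading soft clip), so the strand
    mix of the annotation sets the strand mix of the simulated reads.
    """
    rng = np.random.default_rng(seed)
    ann = GeneAnnotation()
    for i in range(n_genes):
        start = i * (gene_body_len + gap)
        strand = "-" if rng.random() < frac_minus else "+"
        ann.add(GeneInterval(f"G{i:04d}", "chr1", start, start + gene_body_len, strand))
    return ann


def _gene_body(rng: np.random.Generator, length: int) -> str:
    """Random gene-body sequence whose final base is non-A.

    A non-A terminal base keeps the sampled tail length exactly recoverable:
    A-tract extension at the alignment boundary never moves template bases
    into the tail.
    """
    body = rng.choice(_BASES, size=length)
    body[-1] = rng.choice(np.array(list("CGT")))
    return "".join(body)


def simulate_tailed_reads(
    config: TailSimConfig,
    annotation: Optional[GeneAnnotation] = None,
) -> tuple[list[AlignedRead], dict[str, pd.DataFrame]]:
    """Generate aligned reads with known poly(A) tails.

    Returns the reads plus a truth dict with ``reads`` (read_id, gene_id,
    true_tail_len, is_reverse, passes) and ``genes`` (gene_id,
    planted_geom_mean, realized_geom_mean).  Identical config (including
    seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    if annotation is None:
        annotation = default_annotation(
            config.n_genes, config.gene_body_len, frac_minus=config.frac_reverse,
            seed=config.seed,
        )
    intervals = annotation.intervals[: config.n_genes]
    if len(intervals) < config.n_genes:
        raise ValueError("annotation supplies fewer intervals than n_genes")

    gene_gms = config.geom_mean_nt * np.exp(
        rng.normal(0.0, config.gene_log_sigma, size=config.n_genes)
    )

    reads: list[AlignedRead] = []
    read_rows = []
    gene_rows = []
    for gi, (iv, gm) in enumerate(zip(intervals, gene_gms)):
        body = _gene_body(rng, iv.end - iv.start)  # transcript sense, ends non-A
        m = len(body)
        is_reverse = iv.strand == "-"
        lengths = np.maximum(
            1, np.rint(np.exp(rng.normal(np.log(gm), config.log_sigma, config.reads_per_gene)))
        ).astype(int)
        no_tail = rng.random(config.reads_per_gene) < config.frac_no_tail
        passes = 1 + rng.poisson(max(config.pass_mean - 1.0, 0.0), config.reads_per_gene)
        for ri in range(config.reads_per_gene):
            read_id = f"read_{gi:04d}_{ri:04d}"
            if no_tail[ri]:
                tail = ""
                true_len = 0
            else:
                true_len = int(lengths[ri])
                tail_arr = np.full(true_len, "A")
                errs = rng.random(true_len) < config.base_error_rate
                if errs.any():
                    tail_arr[errs] = rng.choice(np.array(list("CGT")), size=int(errs.sum()))
                tail = "".join(tail_arr)
            transcript = body + tail
            if is_reverse:
                # minus-strand gene: stored sequence is the reverse complement
                # of the transcript, with the tail as a leading soft clip
                seq = reverse_complement(transcript)
                cigar = (f"{len(tail)}S" if tail else "") + f"{m}M"
            else:
                seq = transcript
                cigar = f"{m}M" + (f"{len(tail)}S" if tail else "")
            reads.append(
                AlignedRead(
                    read_id=read_id,
                    seq=seq,
                    cigar=cigar,
                    is_reverse=is_reverse,
                    ref_name=iv.ref_name,
                    ref_start=iv.start,
                    passes=int(passes[ri]),
                )
            )
            read_rows.append(
                {
                    "read_id": read_id,
                    "gene_id": iv.gene_id,
                    "true_tail_len": true_len,
                    "is_reverse": is_reverse,
                    "passes": int(passes[ri]),
                }
            )
        with_tail = lengths[~no_tail]
        gene_rows.append(
            {
                "gene_id": iv.gene_id,
                "planted_geom_mean": float(gm),
                "realized_geom_mean": float(np.exp(np.mean(np.log(with_tail))))
                if with_tail.size
                else float("nan"),
            }
        )
    truth = {"reads": pd.DataFrame(read_rows), "genes": pd.DataFrame(gene_rows)}
    return reads, truth


def simulate_decay_series(
    k_true: Sequence[float],
    timepoints: Sequence[float] = (0.0, 2.0, 4.0),
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> tuple[list[DecaySeries], pd.DataFrame]:
    """Exponential decay C(t) = exp(-k t) with multiplicative lognormal noise.

    Noise is applied to every measurement including t = 0, after which the
    series is renormalized so the t = 0 value is 1 — exactly what a
    relative-quantification time course does.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints, dtype=float)
    k_true = np.asarray(k_true, dtype=float)
    if (k_true < 0).any():
        raise ValueError("decay rates must be non-negative")
    series = []
    rows = []
    for i, k in enumerate(k_true):
        gene_id = f"G{i:04d}"
        raw = np.exp(-k * t) * np.exp(rng.normal(0.0, noise_sigma, size=t.size))
        series.append(normalize_series(raw, t, gene_id=gene_id))
        rows.append({"gene_id": gene_id, "true_k": float(k)})
    return series, pd.DataFrame(rows)


#: log2-TPM templates over the 5 timepoints (0, 6, 12, 24, 48 h).  The down
#: and up templates step 1.5 log2 units per interval — a strong, roughly
#: 64-fold total change over the course, in line with the clearance of naive
#: transcription-factor mRNAs during the naive-to-formative transition.
DEFAULT_TEMPLATES: dict[str, np.ndarray] = {
    "down": np.array([7.0, 5.5, 4.0, 2.5, 1.0]),
    "flat": np.array([4.0, 4.0, 4.0, 4.0, 4.0]),
    "up": np.array([1.0, 2.5, 4.0, 5.5, 7.0]),
}


def simulate_expression_timecourse(
    cluster_spec: Mapping[str, float] = None,
    n_genes: int = 1000,
    noise_sigma: float = 0.2,
    conditions: Sequence[str] = ("WT", "KO"),
    n_replicates: int = 2,
    timepoints: Sequence[float] = (0, 6, 12, 24, 48),
    n_ko_stabilized: int = 100,
    templates: Mapping[str, np.ndarray] = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Plant clustered expression trajectories in two conditions.

    ``cluster_spec`` maps template names to gene fractions (must sum to 1;
    default 40% down / 30% flat / 30% up).  Values are emitted directly in
    TPM-like units as 2**(template + Normal(0, noise_sigma)) per (gene,
    sample).  In the KO condition the first ``n_ko_stabilized`` planted-down
    genes are stabilized: their trajectory holds at the 12 h level from 24 h
    on, emulating loss of deadenylation-driven decay.  Truth columns:
    gene_id, cluster (template name), ko_stabilized.
    """
    if cluster_spec is None:
        cluster_spec = {"down": 0.4, "flat": 0.3, "up": 0.3}
    if templates is None:
        templates = DEFAULT_TEMPLATES
    total = sum(cluster_spec.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"cluster fractions must sum to 1, got {total}")
    unknown = set(cluster_spec) - set(templates)
    if unknown:
        raise ValueError(f"no template for cluster(s): {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints, dtype=float)

    # deterministic assignment of genes to templates, by spec order
    labels: list[str] = []
    names = list(cluster_spec)
    for name in names[:-1]:
        labels.extend([name] * int(round(cluster_spec[name] * n_genes)))
    labels.extend([names[-1]] * (n_genes - len(labels)))
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]

    down_genes = [g for g, lab in zip(gene_ids, labels) if lab == "down"]
    stabilized = set(down_genes[:n_ko_stabilized])

    sample_rows = []
    columns = {}
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            for tp in t:
                sid = f"{cond}_t{int(tp)}_r{rep}"
                sample_rows.append(
                    {"sample": sid, "condition": cond, "timepoint_h": tp, "replicate": rep}
                )
                col = np.empty(n_genes)
                ti = int(np.where(t == tp)[0][0])
                for gi, (gene, lab) in enumerate(zip(gene_ids, labels)):
                    profile = templates[lab]
                    level = profile[ti]
                    if cond == "KO" and gene in stabilized and tp >= 24:
                        level = profile[2]  # hold at the 12 h value
                    col[gi] = level
                columns[sid] = 2.0 ** (col + rng.normal(0.0, noise_sigma, size=n_genes))
    values = pd.DataFrame(columns, index=gene_ids)
    samples = pd.DataFrame(sample_rows).set_index("sample")
    em = ExpressionMatrix(
        values,
        samples,
        gene_lengths=pd.Series(1000.0, index=gene_ids),
        units="TPM",
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "cluster": labels,
            "ko_stabilized": [g in stabilized for g in gene_ids],
        }
    )
    return em, truth
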