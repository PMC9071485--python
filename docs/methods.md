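# Methods

This note documents the models and processing rules the package implements,
the parameters that matter, what the synthetic-data generators do and do not
emulate, and the design choices made where the procedure was genuinely open.

## Poly(A) tail calling

A long-read (CCS) alignment of a polyadenylated transcript leaves the tail
as a soft clip at the transcript's 3' end: the trailing clip of a
forward-strand alignment, or the leading clip of a reverse-strand alignment
read back as its reverse complement. The per-read procedure is:

1. **Extraction.** Take the 3' soft clip as the candidate tail, in
   transcript orientation. A hard clip at the 3' end means the tail bases
   were not stored; such reads are counted as unusable, not silently
   dropped. Reads with no 3' soft clip carry no tail evidence and are
   discarded (`REJECTED_NO_CLIP`).
2. **A-tract extension.** Aligners absorb leading tail bases into the
   alignment whenever the reference continues in A. The maximal run of
   consecutive A's at the 3' end of the *aligned query* is therefore moved
   onto the front of the tail. Extension is unconditional (the alternative —
   gating it on a misalignment heuristic — is underdetermined; the
   unconditional rule is deterministic and idempotent, and on A-free
   alignment boundaries it is a no-op). N never counts as A.
3. **Quality filter.** A high-quality tail must have at least 4 A's among
   its first min(8, len) bases; fewer rejects the read (`REJECTED_LOW_A`).
   Applied literally without padding, so tails shorter than 4 nt always
   fail, and an accepted tail is always ≥ 4 nt. Exactly 4 A's passes.
4. **Pass filter.** Reads with a known consensus pass count below
   `min_passes` (default 7, inclusive — "no less than seven") are filtered.
   The filter is applied uniformly to all reads entering summaries and
   distributions (stricter and simpler than gating it on gene assignment);
   it can be disabled, and reads without a pass tag are never filtered.

Reads are assigned to the single best overlapping gene on the matching
strand (largest overlap, then lexicographically smallest gene id — the tie
rule has to be *some* deterministic choice, and this one is auditable).
Secondary, supplementary and duplicate-flagged records are excluded at I/O,
which is the de-duplication step. Internally all intervals are 0-based
half-open; BED6 enters unchanged and GFF3 (1-based closed) is converted at
the boundary.

Per gene, only genes with at least `min_transcripts` (default 10) accepted
tails are summarized, by the **geometric mean** of tail lengths — the
natural location statistic for a lognormal-like within-gene distribution.
Condition comparisons report (a) the median of per-gene geometric means over
genes summarized in both conditions (the per-gene route, rather than pooling
transcripts, keeps deeply covered genes from dominating), (b) per-condition
fractions of accepted transcripts in user-supplied length bins (default
5–90 / 90–200 nt), and (c) the symmetric `trim_quantile` = 0.02 central
support of the transcript-level length distribution.

Every run emits an audit report in which each input read lands in exactly
one outcome count (hard-clipped / no-clip / low-A / low-pass / accepted);
the pipeline refuses to return if the counts do not conserve reads.

## Decay kinetics

First-order decay after transcription shutoff: dC/dt = −K·C, hence
ln(C/C₀) = −K·t and t½ = ln 2 / K. Series are normalized so C(0) = 1;
replicates are averaged per timepoint before fitting (per-replicate fits are
available). The regression of −ln(C/C₀) on t is **through the origin**,
because the model has no intercept and the normalization pins the t = 0
point; a free-intercept variant exists for diagnostics. No weighting —
plain least squares. r² is computed against the through-origin model
(uncentred), and is undefined for a perfectly constant series. K ≤ 0 is a
valid outcome (an apparently stabilized transcript) reported with t½ = +∞,
never an error. Units are hours and 1/hour throughout; the fit is exactly
equivariant under time-unit changes.

Relative qPCR quantification is 2^−ΔΔCt with ΔCt = Ct(target) −
Ct(internal control).

## Expression dynamics

TPM: counts are divided by gene length, then each sample column is scaled
to sum to 10⁶.

DEG calls are pure thresholds, not significance tests: up at a timepoint
when (TPM_KO + ε)/(TPM_WT + ε) > 1.5 **and** log₂ max(TPM_KO, TPM_WT) > 1;
down symmetrically (so swapping the conditions exactly swaps the sets). The
expression floor is applied to the larger of the two condition means —
whichever side is expressed makes the comparison meaningful — and the
pseudocount ε = 0.1 guards division by zero while leaving the ratio
essentially the TPM ratio for expressed genes. Replicates are averaged per
(condition, timepoint) first.

Temporal clustering is deliberately simple and deterministic: each gene's
replicate-mean log₂ profile over the ordered timepoints (0, 6, 12, 24, 48 h)
is discretized per interval into {−, 0, +} using `step_threshold` = 0.5 on
the log₂ change, and genes sharing the resulting sign pattern form a
cluster; the top 8 most populous clusters are reported together with the
fraction of the gene universe they cover. This reproduces the intended
semantics — the all-"−" pattern *is* "continuous downregulation" — while
being auditable, which a generic HMM fit with unstated parameters would not
be. The threshold 0.5 log₂ ≈ 1.4-fold per interval separates real steps
from replicate noise at the noise levels typical of bulk RNA-seq means.

Set derivations, all recorded in a ledger with operand sizes:

- **Degradation set** — members of the all-"−" cluster.
- **Cnot8-dependent degradation** — (union of KO-up sets over all
  post-0 h timepoints) ∩ degradation set, with the result's fraction of the
  degradation set.
- **Naive-GRN-like** — four *disjoint* categories from the KO-up sets:
  continuous (up at 6, 12, 24 and 48 h), shared-24&48 (up at 24 and 48 h but
  not all four), 24-only (up at 24 h but not 48 h), 48-only (up at 48 h but
  not 24 h). Their union (size = sum of the category sizes, verified at run
  time) minus the 0 h up set. "Continually increased" is interpreted as
  membership in the up set at all four post-0 h timepoints.
- **Naive-like ∩ Cnot8-dependent** — plain intersection with a
  user-supplied external reference list.

PCA standardizes genes (centre, unit variance; zero-variance genes dropped)
and projects samples onto the top two axes, reporting explained-variance
fractions.

## Synthetic data

The generators define the package's verification conditions; all are
seed-deterministic and emit truth tables.

**Tailed reads.** Within-gene tail lengths are round(exp(N(ln gm_g, σ)))
truncated at ≥ 1 nt with σ = 0.25; per-gene geometric means gm_g scatter
lognormally (σ_gene = 0.3) around the condition-level geometric mean — both
spreads chosen once as realistic for per-gene tail-length distributions.
Substitution errors (default 1% per base) are applied to tail bases only,
and the reference-matching gene body is emitted to match the alignment, so
the tail-calling logic is isolated from alignment artifacts; gene bodies end
in a non-A base so the planted tail length is exactly recoverable when the
error rate is 0. A fraction of genes (default 20%) sits on the minus
strand, and their transcripts are stored as reverse-complement records with
leading soft clips, exercising the strand path end to end. Pass counts are
1 + Poisson(mean − 1) with mean 12, so a small tail of reads falls below
the 7-pass threshold. Not emulated: homopolymer-aware or quality-dependent
error models, alignment errors outside the tail, partial gene coverage, and
non-A tail composition — so passing recovery tests demonstrates the
correctness of the calling rules, not robustness to aligner pathologies.

**Decay series.** C(t) = exp(−k·t) × exp(N(0, σ)) at every timepoint
(default t = 0, 2, 4 h, σ = 0.05), renormalized so C(0) = 1 — exactly what
relative quantification does, including the fact that noise at t = 0
propagates into all points.

**Expression time course.** Genes are assigned to templates (default 40%
down, 30% flat, 30% up) over log₂-TPM trajectories stepping ±1.5 log₂ per
interval (~64-fold total change over 48 h, the scale of naive-TF clearance);
values are 2^(template + N(0, σ)) with σ = 0.2, emitted directly in TPM-like
units with two replicates per condition/timepoint. In the KO condition a
designated subset of down genes (default 100) is *stabilized*: the
trajectory holds at its 12 h level from 24 h on, so these genes surface in
the 24/48 h up-regulated DEG sets. Not emulated: library-size
compositionality (columns are not renormalized, so planted per-gene patterns
stay interpretable), count noise at low expression, and batch effects.

## Numerical and scale choices

- Geometric means via `scipy.stats.gmean`; through-origin fits via
  statsmodels OLS without a constant; the closed-form slope Σ(t·y)/Σt² is
  kept as an independent oracle in the tests.
- Recovery checks run at 500 genes × 200 reads per condition for tails,
  1,000 series for decay, and 1,000 genes for clustering — sizes at which
  the estimator errors are an order of magnitude inside the stated
  tolerances (per-gene geometric-mean error ≈ σ/√200 ≈ 1.8% against a 5%
  band; mean recovered k error ≈ 0.3% against 2%). The per-gene 5% recovery
  criterion is assessed as the mean absolute relative error across genes:
  with 500 genes at ≈1.8% SE, individual genes exceed 5% by chance alone,
  so the per-gene maximum is not the meaningful statistic at this scale.
- Ratios are reported as percentages rounded to one decimal.
- Ledger invariants (recorded size = actual cardinality; disjoint category
  sizes summing to the union) are enforced at run time, not assumed.

## Known limitations

- The sign-pattern clustering is a deterministic stand-in for an HMM-style
  profile clustering; profiles that change within an interval but return to
  baseline at the sampled timepoints are invisible to it.
- Gene assignment picks a single best gene; reads genuinely spanning two
  genes contribute to only one.
- The SAM reader handles the text dialect (headerless accepted via a
  fallback parser); BAM input should be converted with `samtools view`
  first.
- DEG calling is threshold-only by design; no variance model, no multiple
  testing.
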