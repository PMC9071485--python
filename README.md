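# paika

Poly(A) tail calling from aligned long reads, mRNA decay kinetics, and
time-course expression analysis — a tested, reusable implementation of the
computations behind a deadenylation study of the naive-to-formative
pluripotency transition (Cnot8-dependent mRNA clearance in mouse embryonic
stem cells).

It is aimed at people analysing PAIso-seq-style long-read data, actinomycin-D
transcription-shutoff time courses, or WT/KO expression time courses, who
want the processing rules to be explicit, auditable, and verifiable against
synthetic data with known truth.

## What it computes

**Tail calling** (`paika.tailcall`). The untemplated poly(A) tail of a
long-read transcript appears as a soft-clipped segment at the transcript's
3' end of its alignment. Per read: extract the 3' soft clip (strand-aware;
for reverse-strand alignments the reverse complement of the leading clip),
extend it with any run of A's that the aligner absorbed into the 3' end of
the aligned query, then classify — no clip ⇒ discarded; fewer than 4 A's in
the first 8 bases ⇒ rejected; CCS pass count < 7 ⇒ filtered; otherwise
accepted, with tail length = length of the extended clip. Per gene: genes
with ≥ 10 accepted transcripts are summarized by the **geometric mean** tail
length (within-gene lengths are roughly lognormal). Conditions are compared
by the median of per-gene geometric means over shared genes, binned
transcript-level length fractions, and 2%-quantile-trimmed supports.

**Decay kinetics** (`paika.decay`). After transcription shutoff,
dC/dt = −K·C, so ln(C/C₀) = −K·t. `fit_decay` estimates K as the
through-origin least-squares slope of −ln(C/C₀) on t and reports the
half-life t½ = ln 2 / K (infinite when K ≤ 0, i.e. an apparently stabilized
transcript). qPCR relative quantification uses 2^−ΔΔCt against an internal
control.

**Expression dynamics** (`paika.dynamics`). TPM conversion
(TPM_g = 10⁶·(c_g/ℓ_g)/Σ(c/ℓ)); threshold DEG calls (fold change > 1.5 and
log₂ max TPM > 1); deterministic temporal clustering by the sign pattern of
per-interval log₂ changes (the all-"−" cluster is the *degradation* set);
PCA of gene-standardized samples; and the audited set algebra that derives
the *Cnot8-dependent degradation* set (KO-up ∩ degradation cluster) and the
*naive-GRN-like* set (union of four disjoint late-upregulation categories,
minus genes already up at 0 h). Every operation is recorded in a
`GeneSetLedger` (operands, sizes, provenance) written as JSON.

**Synthetic data** (`paika.synth`). Seed-deterministic generators with truth
tables for all three stages: tailed alignments (lognormal tails, tail-only
substitution errors, strand mix, pass counts), noisy exponential decay
series, and planted down/flat/up expression trajectories with an optional KO
stabilization effect.

## Worked example

Simulate two conditions whose planted condition-level geometric-mean tail
lengths are 92 nt (control) and 121 nt (knockout), call tails, and compare:

```
paika synth reads --n-genes 50 --reads-per-gene 40 --geom-mean 92  --seed 7 --out wt
paika synth reads --n-genes 50 --reads-per-gene 40 --geom-mean 121 --seed 8 --out ko
paika tailcall --alignments wt/reads.sam --annotation wt/genes.bed --out wt_tails
paika tailcall --alignments ko/reads.sam --annotation ko/genes.bed --out ko_tails
paika compare --a wt_tails --b ko_tails --bins 5,90,200
```

The tail-calling report for the control condition prints

```
{
  "n_records": 2000,
  "n_hard_clipped": 0,
  "n_no_clip": 0,
  "n_low_a": 0,
  "n_low_pass": 79,
  "n_accepted": 1921,
  "n_genes_summarized": 50
}
```

— an audit of the filter cascade: of 2,000 reads, 79 fell below the 7-pass
threshold and the rest were accepted (the simulation planted no missing or
low-quality tails), and all 50 genes cleared the 10-transcript floor. The
comparison prints

```
{
  "n_shared_genes": 50,
  "median_a": 84.81,
  "median_b": 116.54,
  "bin_fractions": {
    "a": {"5-90": 0.564, "90-200": 0.436},
    "b": {"5-90": 0.310, "90-200": 0.690}
  },
  "support_a": [40.0, 176.2],
  "support_b": [50.0, 263.0]
}
```

— the knockout's median per-gene geometric mean is ~32 nt longer and its
90–200 nt bin fraction is larger at the expense of the 5–90 nt bin, the
signature of lost deadenylation. (With only 50 genes, the gene-level spread
of the generator moves the medians several percent off the planted 92/121.)

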