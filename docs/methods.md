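# Methods

This note records the models, defaults and numerical choices behind
`ribosig`, and what the synthetic benchmarks do and do not demonstrate.

## Differential workflow

The quantification container is a proteins × samples table of log2
intensities with a control/treatment label per sample and `NaN` for
missing cells; a flag records whether the log2 transform has been
applied, and testing refuses raw intensities. The workflow is the one
used by mainstream quantitative-proteomics suites:

1. **Log transform.** `log2(x)` per present cell; non-positive raw
   values are a data error naming the offending protein and sample.
2. **Valid-value filter** (default 70%). A protein is kept when the
   fraction of present values is at least `min_valid_frac`, computed
   over all samples by default. The threshold's scope is genuinely
   ambiguous in common practice, so a `per_group` option applies the
   rule within each condition instead. Filtering is idempotent and
   preserves row order.
3. **Down-shifted normal imputation** (width 0.3, shift 1.8). Each
   missing cell in column *c* is drawn independently from
   `Normal(mu_c - shift*sd_c, (width*sd_c)^2)`, where `mu_c` and `sd_c`
   are the mean and ddof-1 SD of the observed values of that column.
   Width and shift are expressed in units of the column SD — the
   convention of the quantification software this mirrors. Observed
   cells are never modified; columns with fewer than two observed
   values are an error. This models left-censoring: low-abundance
   proteins fall below the detection limit, so plausible replacements
   sit ~1.8 SDs below the column mean.
4. **Moderated t and permutation q.** The statistic is the pooled-
   variance two-sample t with an additive constant `s0` in the
   denominator (default 0 = plain t). Raw p comes from the t reference
   distribution with n1+n2-2 df. For q-values, condition labels are
   rearranged over balanced relabelings — all of them when at most
   `n_permutations` exist (deduplicated up to a group swap for balanced
   designs, and excluding the identity partition, which would
   contribute a ratio of exactly 1 for every protein; a 3-vs-3 design
   therefore uses 9 informative relabelings), otherwise a random
   subset. The null |t| values are pooled over proteins, and each
   protein's q is the median over relabelings of (null exceedances) /
   (observed exceedances), clipped to [0, 1] and made monotone
   non-increasing in |t| with ties broken by protein id.
5. **Classification.** Positive/negative responder by sign of log2FC
   and raw p below `alpha` (default 0.05; a strict mode uses 0.01), the
   convention of the study design this pipeline reproduces; the q
   column is carried alongside so a q ≤ `fdr_target` selection can be
   reported too. Relabeling bait-vs-control pull-down data turns the
   same computation into an enrichment volcano (log2 enrichment,
   −log10 p); no separate code path exists.

**On `s0`.** With three replicates per condition the plain t statistic
has 4 df: proteins whose replicate noise is accidentally tiny produce
enormous null t values, and a q ≤ 0.05 selection must climb far into
the tail, costing sensitivity (≈0.4 at planted |log2FC| = 1.5, noise SD
0.3). The SAM-style `s0 = 0.1` stabilises the denominator and is what
the package's own recovery benchmark uses (sensitivity ≈0.96 at
empirical FDR ≈0.05). The default stays 0 because raw p-values are then
exactly calibrated; with `s0 > 0` raw p is conservative and only the
permutation q should be interpreted.

**Calibration benchmarks** run on complete matrices (no missingness) so
they measure the test itself, not its interaction with imputation.
Imputation of MNAR holes is condition-symmetric under the null but
mixes a narrow down-shifted component into the replicate distribution,
so type-I error on imputed data is approximately, not exactly, nominal.

## Transcript features

Coordinates: −1 is the last 5'UTR base, +1 the first CDS base; there is
no position 0. CDS windows +1..k include the start codon, which
depresses CDS GC identically in all groups at small k — a property of
the window definition, not a biological signal.

* Sequences are case-folded and U→T on construction; any other
  character makes the affected window (or logo fragment) ineligible
  rather than being counted as non-GC.
* Foreground groups take one transcript per responder gene (longest
  5'UTR, ties by transcript id). The background takes one uniformly
  random transcript per non-responder gene, over a canonical sorted
  ordering so the choice is independent of input order given the seed.
* A global ≥20 nt 5'UTR filter precedes profiling (short UTRs would
  otherwise bias small-k means); windows a transcript is too short for
  are then dropped per k, so each k uses the maximal eligible sample.
* Logo matrices cover −20..−1 and +1..+20 and exclude (never pad)
  transcripts too short on either side; each contributing column sums
  to 1.

## Enrichment statistics

* **GC windows.** Default mode is a per-window two-tailed Welch t-test
  on per-transcript window GC values, Bonferroni-corrected across the
  windows tested on that side (5'UTR and CDS corrected separately). A
  `paired_positions` mode implements the literal paired reading —
  pairing the two groups' per-position mean GC across the k positions
  of each window — for groups of unequal size there is no natural
  per-transcript pairing, so both readings are provided rather than
  silently choosing. Windows with n < 2 in either group are reported
  untestable (NaN) and excluded from the Bonferroni family.
* **Lengths.** One-tailed Mann–Whitney U (foreground shorter), midrank
  ties. The exact no-ties null distribution is used when n1·n2 ≤ 400
  and the pooled sample is tie-free; otherwise the normal approximation
  with tie and continuity correction. (Integer length data almost
  always contain ties, so the exact path mostly serves small continuous
  benchmarks; full arrangement enumeration at, say, 20 vs 20 would be
  ~1.4e11 arrangements and is not attempted.) Fully tied input yields
  p = 0.5 with a degeneracy warning. The background is a single draw of
  1000 transcripts by default, sampled without replacement.
* **Hexamers.** Overlapping windows, single strand, no reverse
  complement or canonical collapsing (5'UTRs are single-stranded mRNA
  contexts); windows containing non-ACGT are skipped and do not count
  toward the token total. Background frequencies are smoothed with a +1
  pseudocount over the 4^6 alphabet so p0 is never 0; the binomial
  upper tail P(X ≥ k_h) is thresholded at 1e-5 raw, with no further
  multiplicity correction. Results are sorted by p, ties
  lexicographically.

## Synthetic-data generator

The generator encodes the study conditions the benchmarks assume.

Quantification (`SimQuantParams` defaults): 2000 proteins, 3 replicates
per condition, 8% positive and 11% negative responders (the proportions
of the experiment this emulates), planted |log2FC| 1.0, replicate noise
SD 0.3 log2 units, baselines N(25, 2²) log2 — the scale of typical
MS intensity tables. Missingness is MNAR:
`P(missing | x) = sigmoid(logit(base) - slope*z(x))` with z the
within-column standard score, base 0.15 and slope 1.0; under these
defaults roughly 70% of proteins survive the 70% filter, matching the
quantified/identified attrition the workflow is built for. The true
mechanism of missingness in real data is unknown; this choice is an
assumption consistent with the down-shifted imputation model, not a
claim about any particular dataset.

Transcriptome (`SimTranscriptomeParams` defaults): responder 5'UTRs GC
0.75, background 0.60; 5'UTR lengths log-normal with mean 60 nt (SD 30)
for responders vs 120 (SD 60) for background, truncated at ≥1 nt —
right-skewed like real UTR lengths, and keeping the 20-nt filter
meaningful. Bases are i.i.d. at the group GC fraction with
P(G)=P(C)=g/2 and P(A)=P(T)=(1−g)/2 — the simplest model matching a
GC-only characterisation. CDSs start with ATG, lengths are multiples of
3 around a 900-nt mean; codon usage is deliberately not modelled. An
optional hexamer is planted into foreground 5'UTRs by replacing a
random 6-mer window (lengths unchanged), with the number of insertions
binomial at `multiplier` times the hexamer's composition rate per
window, on top of chance occurrences — so its total rate is roughly
(1 + multiplier)× background. Sequences are DNA ({A,C,G,T}) throughout
even where the biology is mRNA.

What passing synthetic benchmarks shows: the statistics are implemented
correctly (calibration, recovery, exactness against enumeration
oracles) and the qualitative contrasts the pipeline is designed to
detect are detected. What it does not show: performance on real
proteomes, where effects are heterogeneous, noise is protein-dependent,
missingness is only approximately MNAR, and UTR composition is not
i.i.d.; the generator's homogeneous groups make the benchmarks easier
than reality in those respects.

## Orchestration and reproducibility

`run_pipeline` executes classify → group building → features →
enrichment from a single config. Every stage's seed is derived
deterministically from one global seed via `SeedSequence([seed,
stage_index])`; no stage reads entropy elsewhere, so a fixed config
yields byte-identical output tables (verified by SHA-256 checksums in
the run manifest). All tables are TSV (header row, UTF-8, '.' decimal,
empty cell = missing); sequences are FASTA with U→T normalisation and
duplicate-id detection. Group sizes before and after the 20-nt filter,
and proteins in/out of the valid-value filter, are logged at INFO so
the pipeline's sample-size bookkeeping is always visible.

Benchmark problem sizes (20 null simulations of 2000 proteins, 5
recovery simulations, 1e5 imputed draws, 1200-gene transcriptomes, 100
null hexamer subsamples) were chosen so the full suite and the
acceptance script each complete in well under a minute on one CPU while
keeping Monte-Carlo error far inside the asserted tolerances.

## Known limitations

* The permutation null at 3 vs 3 rests on 9 relabelings; q-values are
  coarse and the median ratio is a biased-upward FDR estimate when
  planted effects leak into permuted statistics.
* No normalisation across runs, peptide-level aggregation or
  contaminant filtering — inputs are assumed to be search-engine output
  already processed to protein level.
* One-sample (ratio-based) designs are not implemented; the two-sample
  path covers per-channel intensity comparisons.
* Hexamer enrichment is not GC-corrected beyond the background
  frequency model: in GC-shifted foregrounds, GC-rich hexamers are
  expected to flag as a family, and the planted-motif benchmark
  therefore uses composition-matched groups.
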