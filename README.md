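# ribosig

Tools for asking two linked questions about ribosome-composition-sensitive
translation:

1. **Which proteins respond when a ribosomal protein (e.g. RPS26) is
   depleted?** Starting from a replicated two-condition protein
   quantification table (SILAC or label-free log2 intensities, missing
   values allowed), `ribosig` applies the standard quantitative-proteomics
   workflow — log2 transform, minimum-valid-value filter, down-shifted
   normal imputation, moderated t-test with a permutation-based FDR — and
   classifies each protein as a positive responder, negative responder or
   non-responder.
2. **What distinguishes the mRNAs encoding the responders?** Given 5'UTR
   and CDS sequences and a gene↔transcript map, it profiles GC content in
   extending windows anchored at the start codon, compares 5'UTR lengths
   with a one-tailed Mann–Whitney U test against a sampled background,
   builds positional base-frequency (sequence-logo) matrices, and scores
   hexamer over-representation under a binomial null.

A synthetic-data generator produces quantification matrices with planted
effects and missing-not-at-random holes, and transcriptomes with
group-dependent 5'UTR GC content, length distributions and optionally
planted hexamer motifs, so the whole pipeline is testable end to end
without any external download.

## The statistics at the core

**Differential response.** For protein *i* with condition means
$\bar{x}_T, \bar{x}_C$ and pooled standard deviation $s_i$,

$$t_i = \frac{\bar{x}_{T,i} - \bar{x}_{C,i}}{s_i\sqrt{1/n_1 + 1/n_2} + s_0},$$

with raw p from the $t_{n_1+n_2-2}$ reference distribution and an optional
SAM-style moderation constant $s_0$ (default 0). q-values come from
balanced relabelings of the condition labels: pooling the null statistics
over proteins,

$$q_i = \operatorname{median}_{\pi} \frac{\#\{|t^{\pi}| \ge |t_i|\}}{\#\{|t^{obs}| \ge |t_i|\}},$$

clipped to [0, 1] and made monotone non-increasing in $|t|$. Missing
values are imputed per column from
$\mathcal{N}(\mu_c - 1.8\,\sigma_c,\ (0.3\,\sigma_c)^2)$, modelling
left-censoring of low-abundance proteins.

**Sequence features.** Position −1 is the last 5'UTR base, +1 the first
CDS base (no position 0). The 5'UTR window of size *k* is −*k*..−1 and is
summarised by its GC fraction; foreground and background windows are
compared per *k* with a Welch t-test, Bonferroni-corrected across
windows. Hexamer *h* observed $k_h$ times among *n* overlapping
foreground tokens gets $p = P(X \ge k_h)$, $X \sim \mathrm{Bin}(n, p_0(h))$
with $p_0$ the pseudocount-smoothed background frequency.

## Worked example

```python
import ribosig as r

matrix, truth = r.generate_quant_matrix(r.SimQuantParams(
    n_proteins=2000, effect_log2=1.0, noise_sd_log2=0.3, seed=1))
matrix = r.filter_valid(matrix, r.FilterParams(min_valid_frac=0.70))
matrix = r.impute_downshifted_normal(matrix, r.ImputeParams(seed=2))
result = r.classify_responders(
    r.differential_test(matrix, r.TestParams(seed=3)), r.TestParams())
print(result.class_counts)
```

Running `python examples/classify_responders.py` prints:

```
simulated 2000 proteins, 18.8% missing cells
1362 proteins pass the 70% valid-value filter
responders at p<0.05: 100 positive, 96 negative, 1166 unchanged
recovered 153 of 260 planted responders that survived filtering
```

Of 2000 simulated proteins, 1362 are quantified well enough to test
(70% valid values); at raw p < 0.05 the workflow calls 100 positive and
96 negative responders, most of them planted. The other scripts under
`examples/` walk through the sequence side — e.g.
`examples/gc_window_profiles.py`:

```
220 foreground and 2404 background transcripts with 5'UTR >= 20 nt
window -6..-1: foreground GC 0.766 vs background 0.603, Bonferroni-adjusted p = 2.68e-28
25 of 25 windows significant at adjusted p < 0.01
```

and `examples/hexamer_enrichment.py`, where the planted GCCGCC hexamer
ranks first (47 observed vs 10.4 expected, p ≈ 9e-17).

A thin CLI mirrors the library (`ribosig simulate-quant`, `classify`,
`features`, `enrich`, `run-all`); `run-all` executes the whole chain
from a YAML config with every stage seeded from one global seed and
writes a manifest of SHA-256 checksums.

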