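"""GC-content profiles in extending windows anchored at the start codon.

Simulates a transcriptome where responder 5'UTRs are GC-richer (0.75)
than background (0.60), profiles the mean GC of windows -k..-1 for
k = 6..30, and tests each window with a two-tailed Welch t-test,
Bonferroni-corrected across the 25 windows.
"""

import ribosig as r
from ribosig.transcripts import UTR5

records, truth = r.generate_transcriptome(r.SimTranscriptomeParams(n_genes=1500, seed=5))
group = dict(zip(truth.transcripts["transcript_id"], truth.transcripts["group"]))
fg = r.filter_min_utr5([t for t in records if group[t.transcript_id] == "positive"])
bg = r.filter_min_utr5([t for t in records if group[t.transcript_id] == "background"])
print(f"{len(fg)} foreground and {len(bg)} background transcripts "
      f"with 5'UTR >= 20 nt")

spec = r.WindowSpec(UTR5, 6, 30)
tests = r.compare_gc_profiles(fg, bg, spec, mode="two_sample", level=0.01)
n_sig = int(tests["significant"].sum())
row = tests.set_index("k").loc[6]
print(f"window -6..-1: foreground GC {row['fg_mean']:.3f} vs background "
      f"{row['bg_mean']:.3f}, Bonferroni-adjusted p = {row['adj_p']:.2e}")
print(f"{n_sig} of {len(tests)} windows significant at adjusted p < 0.01")
print("a flat run of significant windows across k mirrors a genuinely "
      "GC-shifted 5'UTR, not a positional motif")
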