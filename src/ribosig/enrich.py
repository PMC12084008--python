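"""Foreground-vs-background enrichment statistics.

Three families of comparison:

* per-window GC tests (Welch two-sample on per-transcript window GC, or
  a literal paired-across-positions reading), Bonferroni-corrected
  across the window sizes tested on one side;
* a one-tailed Mann-Whitney U test of 5'UTR lengths against a sampled
  background;
* hexamer over-representation under a binomial null whose per-hexamer
  success probability is the pseudocount-smoothed background frequency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .transcripts import TranscriptRecord, WindowSpec, window_gc

logger = logging.getLogger(__name__)

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# GC window tests


def _per_position_gc_means(group: list[TranscriptRecord], side: str, k_max: int) -> np.ndarray:
    """Mean G/C indicator at positions 1..k_max from the start codon.

    Position j on the 5'UTR side is -j; on the CDS side it is +j.  Each
    position uses every transcript long enough to have that position.
    """
    sums = np.zeros(k_max)
    counts = np.zeros(k_max)
    for t in group:
        seq = t.sequence(side)
        span = min(len(seq), k_max)
        for j in range(span):
            base = seq[-(j + 1)] if side == "utr5" else seq[j]
            if base in "GC":
                sums[j] += 1
                counts[j] += 1
            elif base in "AT":
                counts[j] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def compare_gc_profiles(
    fg: list[TranscriptRecord],
    bg: list[TranscriptRecord],
    spec: WindowSpec | None = None,
    mode: str = "two_sample",
    level: float = 0.01,
) -> pd.DataFrame:
    """Per window size k: group means, raw and Bonferroni-adjusted p.

    ``two_sample`` runs a two-tailed Welch t-test on the per-transcript
    window GC values of the two groups.  ``paired_positions`` pairs the
    two groups' per-position mean GC across the k positions of the
    window and runs a paired two-tailed t-test.  The Bonferroni family
    is the set of testable windows of this spec (one side).
    """
    if mode not in ("two_sample", "paired_positions"):
        raise ValueError("mode must be 'two_sample' or 'paired_positions'")
    spec = spec or WindowSpec()
    rows = []
    if mode == "paired_positions":
        fg_pos = _per_position_gc_means(fg, spec.side, spec.k_max)
        bg_pos = _per_position_gc_means(bg, spec.side, spec.k_max)
    for k in spec.ks:
        if mode == "two_sample":
            a = np.array([v for t in fg if (v := window_gc(t, spec.side, k)) is not None])
            b = np.array([v for t in bg if (v := window_gc(t, spec.side, k)) is not None])
            fg_mean = a.mean() if a.size else np.nan
            bg_mean = b.mean() if b.size else np.nan
            if a.size < 2 or b.size < 2:
                raw_p = np.nan  # untestable k-slice
            elif a.std() == 0 and b.std() == 0:
                raw_p = 1.0 if fg_mean == bg_mean else 0.0
            else:
                raw_p = stats.ttest_ind(a, b, equal_var=False).pvalue
            n_fg, n_bg = a.size, b.size
        else:
            fa, ba = fg_pos[:k], bg_pos[:k]
            ok = ~(np.isnan(fa) | np.isnan(ba))
            fg_mean = np.nanmean(fa) if ok.any() else np.nan
            bg_mean = np.nanmean(ba) if ok.any() else np.nan
            d = fa[ok] - ba[ok]
            if d.size < 2:
                raw_p = np.nan
            elif np.allclose(d.std(ddof=1), 0):
                raw_p = 1.0 if np.allclose(d, 0) else 0.0
            else:
                raw_p = stats.ttest_rel(fa[ok], ba[ok]).pvalue
            n_fg = n_bg = int(ok.sum())
        rows.append({"side": spec.side, "k": k, "fg_mean": fg_mean, "bg_mean": bg_mean,
                     "n_fg": n_fg, "n_bg": n_bg, "raw_p": raw_p})
    out = pd.DataFrame(rows)
    m = int(out["raw_p"].notna().sum())
    out["adj_p"] = np.minimum(out["raw_p"] * m, 1.0)
    out["significant"] = out["adj_p"] < level
    return out


# ---------------------------------------------------------------------------
# Length test


@dataclass
class LengthTestResult:
    U: float
    p: float
    n_fg: int
    n_bg: int
    method: str


def mann_whitney_one_tailed(
    fg_lengths: list[float], bg_lengths: list[float], alternative: str = "fg_less"
) -> LengthTestResult:
    """One-tailed Mann-Whitney U test (midrank ties).

    ``U`` is the statistic of the foreground sample.  The exact no-ties
    null distribution is used when n1*n2 <= 400 and the pooled values
    are tie-free; otherwise the normal approximation with tie and
    continuity correction.  Fully tied data yield p = 0.5 with a
    degeneracy warning.
    """
    if alternative not in ("fg_less", "fg_greater"):
        raise ValueError("alternative must be 'fg_less' or 'fg_greater'")
    x = np.asarray(fg_lengths, dtype=float)
    y = np.asarray(bg_lengths, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_fg = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied across both groups; test is degenerate")
        return LengthTestResult(u_fg, 0.5, x.size, y.size, "degenerate")
    scipy_alt = "less" if alternative == "fg_less" else "greater"
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size * y.size <= 400 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative=scipy_alt, method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative=scipy_alt, method="asymptotic", use_continuity=True
        )
        method = "asymptotic"
    return LengthTestResult(float(u_fg), float(res.pvalue), x.size, y.size, method)


def sample_background(
    bg: list[TranscriptRecord], n: int = 1000, seed: int = 0
) -> list[TranscriptRecord]:
    """Uniform sample of n transcripts without replacement, seed-deterministic."""
    if len(bg) < n:
        warnings.warn(f"background has only {len(bg)} < {n} transcripts; using all")
        return list(bg)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(bg), size=n, replace=False)
    return [bg[i] for i in idx]


# ---------------------------------------------------------------------------
# k-mer enrichment


@dataclass
class KmerCounts:
    """Overlapping k-mer counts over a sequence set, single strand."""

    counts: dict[str, int]
    total: int
    k: int


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.size, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        codes[arr == ord(b)] = i
    return codes


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def count_kmers(seqs: list[str] | list[TranscriptRecord], k: int = 6) -> KmerCounts:
    """Count overlapping k-mers on the given strand.

    Windows containing a non-ACGT character are skipped and do not count
    toward the token total.  TranscriptRecords contribute their 5'UTR.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    acc = np.zeros(4**k, dtype=np.int64)
    total = 0
    for s in seqs:
        seq = s.utr5 if isinstance(s, TranscriptRecord) else s
        if len(seq) < k:
            continue
        codes = _encode(seq)
        wins = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (wins >= 0).all(axis=1)
        if not valid.any():
            continue
        ids = (wins[valid] * weights).sum(axis=1)
        acc += np.bincount(ids, minlength=4**k)
        total += int(valid.sum())
    nz = np.nonzero(acc)[0]
    return KmerCounts({_decode(int(c), k): int(acc[c]) for c in nz}, total, k)


def kmer_binomial_enrichment(
    fg: KmerCounts,
    bg: KmerCounts,
    threshold: float = 1e-5,
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """Binomial upper-tail over-representation of foreground k-mers.

    For hexamer h with foreground count k_h out of n tokens, the p-value
    is P(X >= k_h) with X ~ Binomial(n, p0(h)) and
    p0(h) = (bg_count(h) + pseudo) / (bg_total + pseudo * 4^k).
    Results cover the k-mers observed in the foreground, sorted by
    ascending p then lexicographically.
    """
    if fg.k != bg.k:
        raise ValueError("foreground and background k differ")
    if bg.total <= 0:
        raise ValueError("background has no countable tokens")
    if fg.total == 0:
        return pd.DataFrame(
            columns=["kmer", "fg_count", "fg_total", "bg_freq", "p_value", "flagged"]
        )
    kmers = sorted(fg.counts)
    k_h = np.array([fg.counts[h] for h in kmers], dtype=np.int64)
    p0 = np.array(
        [(bg.counts.get(h, 0) + pseudo) / (bg.total + pseudo * 4**bg.k) for h in kmers]
    )
    pvals = stats.binom.sf(k_h - 1, fg.total, p0)
    out = pd.DataFrame(
        {"kmer": kmers, "fg_count": k_h, "fg_total": fg.total,
         "bg_freq": p0, "p_value": pvals, "flagged": pvals < threshold}
    )
    out = out.sort_values(["p_value", "kmer"], kind="mergesort").reset_index(drop=True)
    return out
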