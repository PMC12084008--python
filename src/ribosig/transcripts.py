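"""Transcript records and start-codon-proximal sequence features.

Coordinate convention (fixed throughout the package): position -1 is the
last base of the 5'UTR, i.e. the base immediately 5' of the coding
sequence; position +1 is the first base of the CDS (the first base of
the start codon).  There is no position 0.  A 5'UTR window of size k
spans -k..-1; a CDS window spans +1..+k and therefore contains the start
codon for k >= 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UTR5 = "utr5"
CDS = "cds"
_VALID = frozenset("ACGT")


def normalize_seq(seq: str) -> str:
    """Case-fold and convert RNA U to DNA T; other characters pass through."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: gene id, transcript id, 5'UTR and CDS sequence.

    Sequences are normalized on construction.  A CDS that does not begin
    with ATG is tolerated (annotation may be imperfect) but logged.
    """

    gene_id: str
    transcript_id: str
    utr5: str
    cds: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "utr5", normalize_seq(self.utr5))
        object.__setattr__(self, "cds", normalize_seq(self.cds))
        if len(self.cds) < 3:
            raise ValueError(f"{self.transcript_id}: CDS shorter than 3 nt")
        if not self.cds.startswith("ATG"):
            logger.debug("%s: CDS does not start with ATG", self.transcript_id)

    def sequence(self, side: str) -> str:
        if side == UTR5:
            return self.utr5
        if side == CDS:
            return self.cds
        raise ValueError(f"unknown side {side!r}")


@dataclass
class GroupedTranscripts:
    """Foreground responder sets and the per-gene background set."""

    positive: list[TranscriptRecord] = field(default_factory=list)
    negative: list[TranscriptRecord] = field(default_factory=list)
    background: list[TranscriptRecord] = field(default_factory=list)

    def items(self):
        return (("positive", self.positive), ("negative", self.negative),
                ("background", self.background))


@dataclass
class WindowSpec:
    """Extending windows anchored at the start codon."""

    side: str = UTR5
    k_min: int = 6
    k_max: int = 30

    def __post_init__(self) -> None:
        if self.side not in (UTR5, CDS):
            raise ValueError("side must be 'utr5' or 'cds'")
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("need 1 <= k_min <= k_max")

    @property
    def ks(self) -> range:
        return range(self.k_min, self.k_max + 1)


def select_background(
    all_transcripts: list[TranscriptRecord],
    exclude_genes: set[str],
    seed: int = 0,
) -> list[TranscriptRecord]:
    """One uniformly chosen transcript per gene, excluding responder genes.

    Internally transcripts are put in canonical (gene id, transcript id)
    order, so the selection is invariant to input ordering for a fixed
    seed.
    """
    if not all_transcripts:
        raise ValueError("empty transcript list")
    pool = sorted(
        (t for t in all_transcripts if t.gene_id not in exclude_genes),
        key=lambda t: (t.gene_id, t.transcript_id),
    )
    rng = np.random.default_rng(seed)
    out: list[TranscriptRecord] = []
    i = 0
    while i < len(pool):
        j = i
        while j < len(pool) and pool[j].gene_id == pool[i].gene_id:
            j += 1
        out.append(pool[i + rng.integers(j - i)])
        i = j
    return out


def foreground_transcripts(
    all_transcripts: list[TranscriptRecord], gene_ids: set[str]
) -> list[TranscriptRecord]:
    """One transcript per foreground gene: the longest 5'UTR, ties by id."""
    best: dict[str, TranscriptRecord] = {}
    for t in sorted(all_transcripts, key=lambda t: t.transcript_id):
        if t.gene_id not in gene_ids:
            continue
        cur = best.get(t.gene_id)
        if cur is None or len(t.utr5) > len(cur.utr5):
            best[t.gene_id] = t
    return [best[g] for g in sorted(best)]


def filter_min_utr5(
    transcripts: list[TranscriptRecord], min_len: int = 20
) -> list[TranscriptRecord]:
    """Drop transcripts whose 5'UTR is shorter than ``min_len`` nucleotides."""
    kept = [t for t in transcripts if len(t.utr5) >= min_len]
    if len(kept) < len(transcripts):
        logger.info("filter_min_utr5(%d): %d -> %d transcripts",
                    min_len, len(transcripts), len(kept))
    return kept


def gc_content(seq: str) -> float:
    """(#G + #C) / length of a non-empty sequence."""
    seq = normalize_seq(seq)
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def window_gc(t: TranscriptRecord, side: str, k: int) -> float | None:
    """GC fraction of the k-window anchored at the start codon.

    Returns ``None`` when the sequence is shorter than k or the window
    contains a non-ACGT character (the transcript is skipped for that k).
    """
    seq = t.sequence(side)
    if len(seq) < k:
        return None
    window = seq[-k:] if side == UTR5 else seq[:k]
    if not _VALID.issuperset(window):
        return None
    return (window.count("G") + window.count("C")) / k


def gc_profile(group: list[TranscriptRecord], spec: WindowSpec) -> pd.DataFrame:
    """Per-window-size mean GC, SEM and eligible-transcript count.

    Windows a transcript is too short for are dropped for that k only,
    so each k uses the maximal eligible sample.
    """
    rows = []
    for k in spec.ks:
        vals = np.array([v for t in group if (v := window_gc(t, spec.side, k)) is not None])
        n = len(vals)
        mean = vals.mean() if n else np.nan
        sem = vals.std(ddof=1) / np.sqrt(n) if n > 1 else (0.0 if n == 1 else np.nan)
        rows.append({"side": spec.side, "k": k, "mean_gc": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows)


def utr5_lengths(group: list[TranscriptRecord]) -> list[int]:
    """5'UTR lengths in nucleotides, preserving group order."""
    return [len(t.utr5) for t in group]


def build_logo_matrix(
    group: list[TranscriptRecord], up: int = 20, down: int = 20
) -> pd.DataFrame:
    """Positional base-frequency matrix around the start codon.

    Positions run -up..-1 (5'UTR) and +1..+down (CDS).  Only transcripts
    long enough on both sides, with unambiguous bases across the whole
    fragment, contribute; the contributing count is recorded per
    position.  At every contributing position the four frequencies sum
    to 1.
    """
    if not group:
        raise ValueError("empty group")
    frags = []
    for t in group:
        if len(t.utr5) >= up and len(t.cds) >= down:
            frag = t.utr5[-up:] + t.cds[:down]
            if _VALID.issuperset(frag):
                frags.append(frag)
    positions = list(range(-up, 0)) + list(range(1, down + 1))
    n = len(frags)
    counts = np.zeros((up + down, 4), dtype=int)
    base_index = {b: i for i, b in enumerate("ACGT")}
    for frag in frags:
        for j, b in enumerate(frag):
            counts[j, base_index[b]] += 1
    freqs = counts / n if n else np.full_like(counts, np.nan, dtype=float)
    out = pd.DataFrame(freqs, columns=list("ACGT"))
    out.insert(0, "position", positions)
    out["n"] = n
    return out
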