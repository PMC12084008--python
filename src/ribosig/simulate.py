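"""Synthetic quantification matrices and transcript sets.

The generator emulates the statistical structure the downstream stages
assume, so the whole pipeline can be exercised without any deposited
data:

* a replicated two-condition log2 intensity matrix with planted
  positive/negative effects and abundance-dependent (missing-not-at-
  random) missingness, P(missing | x) = sigmoid(logit(base) - slope * z(x))
  with z the within-column standard score;
* a transcriptome of genes with one or more transcripts each, where the
  responder groups have their own 5'UTR GC content and (log-normal)
  length distribution, CDSs start with ATG and have length a multiple
  of 3, and an optional hexamer can be planted into foreground 5'UTRs
  at a multiple of its composition rate.

Default parameter values are the study conditions of the analysis this
package reproduces: 2000 proteins in a 3-vs-3 design with ~8% positive
and ~11% negative responders, and responder 5'UTRs that are shorter
(mean 60 vs 120 nt) and GC-richer (0.75 vs 0.60) than background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import QuantMatrix
from .transcripts import TranscriptRecord

GROUPS = ("positive", "negative", "background")


class ParameterError(ValueError):
    pass


@dataclass
class GroundTruth:
    """Planted truth: per-protein class/effect and/or per-transcript group."""

    proteins: pd.DataFrame | None = None     # protein_id, true_class, true_log2fc
    transcripts: pd.DataFrame | None = None  # gene_id, transcript_id, group


@dataclass
class SimQuantParams:
    n_proteins: int = 2000
    n_reps_per_condition: int = 3
    frac_positive: float = 0.08
    frac_negative: float = 0.11
    effect_log2: float = 1.0
    noise_sd_log2: float = 0.3
    baseline_mean_log2: float = 25.0
    baseline_sd_log2: float = 2.0
    missing_base_rate: float = 0.15
    missing_abundance_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_positive", "frac_negative", "missing_base_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.frac_positive + self.frac_negative > 1:
            raise ParameterError("frac_positive + frac_negative must be <= 1")
        if self.n_reps_per_condition < 2:
            raise ParameterError("need at least 2 replicates per condition")
        if self.n_proteins < 1:
            raise ParameterError("n_proteins must be >= 1")
        for name in ("effect_log2", "noise_sd_log2", "baseline_sd_log2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


def _per_group(value, name: str) -> dict[str, float]:
    """Accept a scalar (applied to every group) or a full per-group dict."""
    if isinstance(value, dict):
        missing = set(GROUPS) - set(value)
        if missing:
            raise ParameterError(f"{name} missing groups: {sorted(missing)}")
        return {g: float(value[g]) for g in GROUPS}
    return {g: float(value) for g in GROUPS}


@dataclass
class SimTranscriptomeParams:
    n_genes: int = 2000
    transcripts_per_gene: float = 2.0  # mean of 1 + Poisson(mean - 1)
    frac_positive: float = 0.08
    frac_negative: float = 0.11
    utr5_gc: dict | float = field(
        default_factory=lambda: {"positive": 0.75, "negative": 0.75, "background": 0.60}
    )
    cds_gc: dict | float = field(
        default_factory=lambda: {"positive": 0.55, "negative": 0.52, "background": 0.50}
    )
    utr5_len_mean: dict | float = field(
        default_factory=lambda: {"positive": 60.0, "negative": 60.0, "background": 120.0}
    )
    utr5_len_sd: dict | float = field(
        default_factory=lambda: {"positive": 30.0, "negative": 30.0, "background": 60.0}
    )
    cds_len_mean: float = 900.0
    planted_kmer: str | None = None
    planted_kmer_rate_multiplier: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.utr5_gc = _per_group(self.utr5_gc, "utr5_gc")
        self.cds_gc = _per_group(self.cds_gc, "cds_gc")
        self.utr5_len_mean = _per_group(self.utr5_len_mean, "utr5_len_mean")
        self.utr5_len_sd = _per_group(self.utr5_len_sd, "utr5_len_sd")
        for g in GROUPS:
            if not (0 <= self.utr5_gc[g] <= 1) or not (0 <= self.cds_gc[g] <= 1):
                raise ParameterError("GC fractions must be in [0, 1]")
            if self.utr5_len_mean[g] < 0 or self.utr5_len_sd[g] < 0:
                raise ParameterError("lengths must be >= 0")
        if not (0 <= self.frac_positive <= 1 and 0 <= self.frac_negative <= 1):
            raise ParameterError("group fractions must be in [0, 1]")
        if self.frac_positive + self.frac_negative > 1:
            raise ParameterError("frac_positive + frac_negative must be <= 1")
        if self.transcripts_per_gene < 1:
            raise ParameterError("transcripts_per_gene must be >= 1")
        if self.cds_len_mean < 3:
            raise ParameterError("cds_len_mean must be >= 3")
        if self.planted_kmer is not None:
            if len(self.planted_kmer) != 6 or set(self.planted_kmer) - set("ACGT"):
                raise ParameterError("planted_kmer must be a 6-mer over {A,C,G,T}")
        if self.planted_kmer_rate_multiplier <= 0:
            raise ParameterError("planted_kmer_rate_multiplier must be > 0")


def generate_quant_matrix(params: SimQuantParams) -> tuple[QuantMatrix, GroundTruth]:
    """Simulate a log2 intensity matrix with planted effects and MNAR holes.

    Null proteins have identical expected means in both conditions;
    planted proteins are shifted by +/- effect_log2 in the treatment
    condition.  Output is identical for identical parameters and seed.
    """
    rng = np.random.default_rng(params.seed)
    n, r = params.n_proteins, params.n_reps_per_condition
    n_pos = int(round(params.frac_positive * n))
    n_neg = int(round(params.frac_negative * n))
    classes = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_pos]] = "positive"
    classes[order[n_pos:n_pos + n_neg]] = "negative"
    effect = np.where(classes == "positive", params.effect_log2,
                      np.where(classes == "negative", -params.effect_log2, 0.0))

    baseline = rng.normal(params.baseline_mean_log2, params.baseline_sd_log2, n)
    values = baseline[:, None] + rng.normal(0.0, params.noise_sd_log2, (n, 2 * r))
    values[:, r:] += effect[:, None]

    if params.missing_base_rate > 0:
        logit_base = np.log(params.missing_base_rate / (1 - params.missing_base_rate))
        col_mu = values.mean(axis=0)
        col_sd = values.std(axis=0, ddof=1)
        z = (values - col_mu) / np.where(col_sd > 0, col_sd, 1.0)
        p_missing = 1.0 / (1.0 + np.exp(-(logit_base - params.missing_abundance_slope * z)))
        mask = rng.random((n, 2 * r)) < p_missing
        values = np.where(mask, np.nan, values)

    protein_ids = [f"P{i:05d}" for i in range(n)]
    ctrl_cols = [f"ctrl_{j + 1}" for j in range(r)]
    treat_cols = [f"treat_{j + 1}" for j in range(r)]
    frame = pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                         columns=ctrl_cols + treat_cols)
    conditions = pd.Series(
        ["control"] * r + ["treatment"] * r, index=ctrl_cols + treat_cols
    )
    truth = GroundTruth(proteins=pd.DataFrame(
        {"protein_id": protein_ids, "true_class": classes, "true_log2fc": effect}
    ))
    return QuantMatrix(frame, conditions, log2_transformed=True), truth


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _lognormal_lengths(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Right-skewed lengths with the requested arithmetic mean and SD, >= 1 nt."""
    if mean <= 0:
        return np.ones(size, dtype=int)
    if sd == 0:
        return np.full(size, max(1, int(round(mean))), dtype=int)
    sigma2 = np.log(1 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    draws = rng.lognormal(mu, np.sqrt(sigma2), size)
    return np.maximum(1, np.round(draws).astype(int))


def _kmer_composition_prob(kmer: str, gc: float) -> float:
    p = 1.0
    for b in kmer:
        p *= gc / 2 if b in "GC" else (1 - gc) / 2
    return p


def generate_transcriptome(
    params: SimTranscriptomeParams,
    group_assignment: dict[str, str] | None = None,
) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Simulate transcripts with group-dependent 5'UTR composition.

    Bases are i.i.d. at the group GC fraction with G/C (and A/T)
    equiprobable.  Every CDS starts with ATG and has length a multiple
    of 3.  When ``planted_kmer`` is set, foreground (responder) 5'UTRs
    receive extra copies of that hexamer, each replacing a random
    6-mer window, at ``multiplier`` times its composition rate on top of
    the chance occurrences, so its total occurrence rate is roughly
    ``1 + multiplier`` times background.

    ``group_assignment`` optionally fixes each gene's group label (for
    example from planted quantification classes); genes absent from the
    mapping fall back to "background".
    """
    rng = np.random.default_rng(params.seed)
    gene_ids = [f"G{i:05d}" for i in range(params.n_genes)]
    if group_assignment is not None:
        groups = np.array(
            [group_assignment.get(g, "background") for g in gene_ids], dtype=object
        )
        unknown = set(groups) - set(GROUPS)
        if unknown:
            raise ParameterError(f"unknown groups in assignment: {sorted(unknown)}")
    else:
        n_pos = int(round(params.frac_positive * params.n_genes))
        n_neg = int(round(params.frac_negative * params.n_genes))
        groups = np.array(["background"] * params.n_genes, dtype=object)
        order = rng.permutation(params.n_genes)
        groups[order[:n_pos]] = "positive"
        groups[order[n_pos:n_pos + n_neg]] = "negative"

    n_tx = 1 + rng.poisson(params.transcripts_per_gene - 1, params.n_genes)
    records: list[TranscriptRecord] = []
    rows = []
    for gi, gene in enumerate(gene_ids):
        group = groups[gi]
        gc_u = params.utr5_gc[group]
        lens = _lognormal_lengths(
            rng, params.utr5_len_mean[group], params.utr5_len_sd[group], n_tx[gi]
        )
        for ti in range(n_tx[gi]):
            utr5 = _random_seq(rng, int(lens[ti]), gc_u)
            if params.planted_kmer is not None and group != "background":
                p_comp = _kmer_composition_prob(params.planted_kmer, gc_u)
                n_windows = max(0, len(utr5) - 5)
                rate = params.planted_kmer_rate_multiplier * p_comp
                n_ins = rng.binomial(n_windows, min(1.0, rate)) if n_windows else 0
                chars = list(utr5)
                for _ in range(n_ins):
                    start = int(rng.integers(0, n_windows))
                    chars[start:start + 6] = params.planted_kmer
                utr5 = "".join(chars)
            n_codons = max(2, int(round(rng.normal(params.cds_len_mean / 3, params.cds_len_mean / 12))))
            cds = "ATG" + _random_seq(rng, 3 * (n_codons - 1), params.cds_gc[group])
            tid = f"{gene}.T{ti + 1}"
            records.append(TranscriptRecord(gene, tid, utr5, cds))
            rows.append({"gene_id": gene, "transcript_id": tid, "group": group})
    truth = GroundTruth(transcripts=pd.DataFrame(rows))
    return records, truth
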