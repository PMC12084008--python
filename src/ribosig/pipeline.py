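"""End-to-end orchestration: simulate (or load) -> classify -> features -> enrich.

All randomness flows from a single global seed: each stage receives a
seed derived deterministically from it, so re-running an identical
configuration reproduces byte-identical output tables.  A run manifest
records the effective configuration, package version and SHA-256
checksums of every written table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as rio
from .diffexpr import TestParams, classify_responders, differential_test
from .enrich import (compare_gc_profiles, count_kmers, kmer_binomial_enrichment,
                     mann_whitney_one_tailed, sample_background)
from .quant import FilterParams, ImputeParams, filter_valid, impute_downshifted_normal, logarithmize
from .simulate import SimQuantParams, SimTranscriptomeParams, generate_quant_matrix, generate_transcriptome
from .transcripts import (UTR5, CDS, GroupedTranscripts, WindowSpec, build_logo_matrix,
                          filter_min_utr5, foreground_transcripts, gc_profile,
                          select_background, utr5_lengths)

logger = logging.getLogger(__name__)

_STAGES = ("simulate_quant", "simulate_transcriptome", "classify", "features", "enrich")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything one run needs: input paths or simulation blocks, stage
    parameters, output directory and the global seed."""

    out_dir: str = "ribosig_out"
    seed: int = 0
    # inputs: either paths ...
    quant_path: str | None = None
    conditions_path: str | None = None
    quant_is_log2: bool = True
    utr5_fasta: str | None = None
    cds_fasta: str | None = None
    gene_map: str | None = None
    # ... or simulation blocks
    simulate_quant: SimQuantParams | None = None
    simulate_transcriptome: SimTranscriptomeParams | None = None
    # stage parameters
    filter_params: FilterParams = field(default_factory=FilterParams)
    impute_params: ImputeParams = field(default_factory=ImputeParams)
    test_params: TestParams = field(default_factory=TestParams)
    min_utr5_len: int = 20
    window_utr5: WindowSpec = field(default_factory=lambda: WindowSpec(UTR5, 6, 30))
    window_cds: WindowSpec = field(default_factory=lambda: WindowSpec(CDS, 4, 30))
    gc_test_mode: str = "two_sample"
    gc_test_level: float = 0.01
    bg_sample_n: int = 1000
    kmer_k: int = 6
    kmer_threshold: float = 1e-5
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        idx = _STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % 2**31)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        for key, sub in (
            ("simulate_quant", SimQuantParams),
            ("simulate_transcriptome", SimTranscriptomeParams),
            ("filter_params", FilterParams),
            ("impute_params", ImputeParams),
            ("test_params", TestParams),
        ):
            if isinstance(raw.get(key), dict):
                raw[key] = sub(**raw[key])
        for key in ("window_utr5", "window_cds"):
            if isinstance(raw.get(key), dict):
                raw[key] = WindowSpec(**raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def snapshot(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v):
                return dataclasses.asdict(v)
            return v
        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass
class RunManifest:
    config: dict
    version: str
    checksums: dict[str, str]
    timestamp: str

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _validate(config: PipelineConfig) -> None:
    if config.simulate_quant is None and (
        config.quant_path is None or config.conditions_path is None
    ):
        raise ConfigError("need a quant matrix path pair or a simulate_quant block")
    if config.simulate_transcriptome is None and (
        config.utr5_fasta is None or config.cds_fasta is None or config.gene_map is None
    ):
        raise ConfigError(
            "need 5'UTR/CDS FASTA paths and a gene map, or a simulate_transcriptome block"
        )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute classify -> group building -> features -> enrichment.

    Writes every stage's TSV into ``config.out_dir`` and returns the
    manifest.  Raises before any compute when the configuration is
    incomplete.
    """
    _validate(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        rio.write_tsv(frame, path, index=index)
        written.append(path)

    # ---- quantification input -------------------------------------------
    if config.simulate_quant is not None:
        params = dataclasses.replace(
            config.simulate_quant, seed=config.stage_seed("simulate_quant")
        )
        matrix, quant_truth = generate_quant_matrix(params)
        logger.info("simulate_quant: %d proteins, %d samples",
                    matrix.n_proteins, matrix.values.shape[1])
        rio.write_quant_matrix(matrix, out / "quant_matrix.tsv", out / "conditions.tsv")
        written += [out / "quant_matrix.tsv", out / "conditions.tsv"]
        emit(quant_truth.proteins, "quant_ground_truth.tsv")
    else:
        matrix = rio.read_quant_matrix(
            config.quant_path, config.conditions_path, config.quant_is_log2
        )
        quant_truth = None

    # ---- classify --------------------------------------------------------
    if not matrix.log2_transformed:
        matrix = logarithmize(matrix)
    n_before = matrix.n_proteins
    matrix = filter_valid(matrix, config.filter_params)
    logger.info("classify: %d of %d proteins pass the valid-value filter",
                matrix.n_proteins, n_before)
    impute = dataclasses.replace(config.impute_params, seed=config.stage_seed("classify"))
    matrix = impute_downshifted_normal(matrix, impute)
    test = dataclasses.replace(config.test_params, seed=config.stage_seed("classify"))
    result = classify_responders(differential_test(matrix, test), test)
    logger.info("classify: %s", result.class_counts)
    emit(result.table.reset_index(), "diff_result.tsv")

    # ---- transcriptome input --------------------------------------------
    if config.simulate_transcriptome is not None:
        tparams = dataclasses.replace(
            config.simulate_transcriptome, seed=config.stage_seed("simulate_transcriptome")
        )
        assignment = None
        if quant_truth is not None:
            # gene G%05d carries the transcripts of protein P%05d
            assignment = {
                f"G{i:05d}": {"positive": "positive", "negative": "negative"}.get(c, "background")
                for i, c in enumerate(quant_truth.proteins["true_class"])
            }
            tparams = dataclasses.replace(tparams, n_genes=max(tparams.n_genes, len(assignment)))
        transcripts, tx_truth = generate_transcriptome(tparams, group_assignment=assignment)
        rio.write_transcripts(
            transcripts, out / "utr5.fasta", out / "cds.fasta", out / "gene_map.tsv",
            groups=dict(zip(tx_truth.transcripts["transcript_id"], tx_truth.transcripts["group"])),
        )
        written += [out / "utr5.fasta", out / "cds.fasta", out / "gene_map.tsv"]
    else:
        transcripts, _ = rio.read_transcripts(
            config.utr5_fasta, config.cds_fasta, config.gene_map
        )

    # ---- group building --------------------------------------------------
    gene_of_protein = lambda pid: "G" + pid[1:] if pid.startswith("P") else pid
    classes = result.table["class"]
    pos_genes = {gene_of_protein(p) for p in classes.index[classes == "positive"]}
    neg_genes = {gene_of_protein(p) for p in classes.index[classes == "negative"]}
    groups = GroupedTranscripts(
        positive=foreground_transcripts(transcripts, pos_genes),
        negative=foreground_transcripts(transcripts, neg_genes),
        background=select_background(
            transcripts, pos_genes | neg_genes, seed=config.stage_seed("features")
        ),
    )
    for name, members in groups.items():
        kept = filter_min_utr5(members, config.min_utr5_len)
        logger.info("group %s: %d transcripts, %d after %d-nt 5'UTR filter",
                    name, len(members), len(kept), config.min_utr5_len)
        setattr(groups, name, kept)

    # ---- features --------------------------------------------------------
    profiles, logos, lengths = [], [], []
    for name, members in groups.items():
        if not members:
            logger.warning("group %s is empty after filtering", name)
            continue
        for spec in (config.window_utr5, config.window_cds):
            prof = gc_profile(members, spec)
            prof.insert(0, "group", name)
            profiles.append(prof)
        logo = build_logo_matrix(members)
        logo.insert(0, "group", name)
        logos.append(logo)
        lengths.append(pd.DataFrame(
            {"group": name,
             "transcript_id": [t.transcript_id for t in members],
             "utr5_length": utr5_lengths(members)}
        ))
    emit(pd.concat(profiles, ignore_index=True), "gc_profiles.tsv")
    emit(pd.concat(logos, ignore_index=True), "logo_matrix.tsv")
    emit(pd.concat(lengths, ignore_index=True), "utr5_lengths.tsv")

    # ---- enrichment ------------------------------------------------------
    enrich_seed = config.stage_seed("enrich")
    window_rows, length_rows, kmer_frames = [], [], []
    bg_sample = sample_background(groups.background, config.bg_sample_n, seed=enrich_seed)
    bg_kmers = count_kmers(groups.background, config.kmer_k)
    for name in ("positive", "negative"):
        fg = getattr(groups, name)
        if not fg:
            continue
        for spec in (config.window_utr5, config.window_cds):
            res = compare_gc_profiles(fg, groups.background, spec,
                                      mode=config.gc_test_mode, level=config.gc_test_level)
            res.insert(0, "group", name)
            window_rows.append(res)
        lt = mann_whitney_one_tailed(
            utr5_lengths(fg), utr5_lengths(bg_sample), alternative="fg_less"
        )
        length_rows.append({"group": name, "U": lt.U, "p": lt.p, "n_fg": lt.n_fg,
                            "n_bg_sample": lt.n_bg, "seed": enrich_seed})
        km = kmer_binomial_enrichment(
            count_kmers(fg, config.kmer_k), bg_kmers, threshold=config.kmer_threshold
        )
        km.insert(0, "group", name)
        kmer_frames.append(km)
    if window_rows:
        emit(pd.concat(window_rows, ignore_index=True), "window_tests.tsv")
    if length_rows:
        emit(pd.DataFrame(length_rows), "length_tests.tsv")
    if kmer_frames:
        emit(pd.concat(kmer_frames, ignore_index=True), "kmer_enrichment.tsv")

    manifest = RunManifest(
        config=config.snapshot(),
        version=__version__,
        checksums={p.name: _sha256(p) for p in written},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out / "manifest.json")
    return manifest
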