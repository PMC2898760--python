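"""End-to-end pipeline: filter -> map -> quantify -> test, with reporting.

``run_pipeline`` takes a validated PipelineConfig, runs every stage over all
libraries, and writes the full report bundle: a per-library summary table
(raw/clean/mapped counts and percentages), tag-abundance and gene-expression
distributions, saturation curves, pairwise Pearson correlations, pairwise DE
tables with up/down tallies, and a machine-readable run manifest carrying
the config hash so any output can be traced to the exact run that made it.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import call_de
from .expression import (
    DEFAULT_BINS,
    ExpressionTable,
    abundance_distribution,
    library_correlation,
    quantify,
    saturation,
)
from .filtering import RawTagLibrary, filter_tags, read_fastq, read_tag_table
from .reference import build_reference, read_fasta

log = logging.getLogger("tagdge")

_KNOWN_KEYS = {
    "reference_fasta", "libraries", "outdir", "adaptor_seq", "both_strands",
    "variable_region_only", "alpha", "min_abs_log2", "bins",
    "saturation_step", "seed",
}


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage, self.code = stage, code


@dataclass
class PipelineConfig:
    reference_fasta: str
    libraries: dict[str, str]  # sample_id -> FASTQ or 2-column TSV path
    outdir: str
    adaptor_seq: str = ""
    both_strands: bool = False
    variable_region_only: bool = True
    alpha: float = 0.001
    min_abs_log2: float = 1.0
    bins: Sequence = DEFAULT_BINS
    saturation_step: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.libraries:
            raise ConfigError("at least one library is required")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.saturation_step <= 0:
            raise ConfigError("saturation_step must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "bins" in raw:
            raw["bins"] = [tuple(b) for b in raw["bins"]]
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {**asdict(self), "bins": [list(b) for b in self.bins]},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_library(sample_id: str, path: str) -> RawTagLibrary:
    p = Path(path)
    if p.suffix in {".fastq", ".fq"}:
        return read_fastq(p, sample_id)
    return read_tag_table(p, sample_id)


@dataclass
class PipelineResult:
    config: PipelineConfig
    census: dict
    library_summaries: pd.DataFrame
    expression: dict[str, ExpressionTable]
    correlations: dict[tuple[str, str], float]
    de_tables: dict[tuple[str, str], pd.DataFrame]
    de_summaries: dict[tuple[str, str], dict]
    saturation_curves: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_pipeline(
    cfg: PipelineConfig,
    *,
    raw_libraries: Mapping[str, RawTagLibrary] | None = None,
    transcripts=None,
) -> PipelineResult:
    """Run every stage and write the report bundle to cfg.outdir.

    ``raw_libraries``/``transcripts`` allow in-memory inputs (e.g. straight
    from the simulator) to bypass file loading; paths in the config are then
    ignored for those inputs.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "version": __version__}
    t0 = time.time()

    def _stage(name):
        log.info("stage %-12s t=%.1fs", name, time.time() - t0)

    try:
        _stage("reference")
        if transcripts is None:
            transcripts = read_fasta(cfg.reference_fasta)
        ref = build_reference(transcripts, both_strands=cfg.both_strands)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("reference", "build_failed", str(e)) from e

    clean, rows = {}, []
    gene_ids = [t.gene_id for t in ref.transcripts]
    expr: dict[str, ExpressionTable] = {}
    sat: dict[str, pd.DataFrame] = {}
    rng = np.random.default_rng(cfg.seed)
    for sample_id in cfg.libraries:
        try:
            _stage(f"filter:{sample_id}")
            raw = (
                raw_libraries[sample_id]
                if raw_libraries is not None
                else _load_library(sample_id, cfg.libraries[sample_id])
            )
            lib = filter_tags(raw, cfg.adaptor_seq)
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(f"filter:{sample_id}", "filter_failed", str(e)) from e
        try:
            _stage(f"map:{sample_id}")
            table, summary = quantify(lib, ref, gene_ids=gene_ids)
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(f"map:{sample_id}", "map_failed", str(e)) from e
        clean[sample_id] = lib
        expr[sample_id] = table
        rows.append(
            {
                "sample_id": sample_id,
                "n_raw_total": raw.n_raw_total,
                "n_raw_distinct": raw.n_raw_distinct,
                **lib.summary(),
                **summary.as_dict(),
            }
        )
        _stage(f"saturate:{sample_id}")
        sat[sample_id] = saturation(lib, ref, cfg.saturation_step, rng)

    summaries = pd.DataFrame(rows).set_index("sample_id")

    _stage("correlate")
    correlations = {
        (a, b): library_correlation(clean[a], clean[b])
        for a, b in itertools.combinations(cfg.libraries, 2)
    }

    de_tables, de_summaries = {}, {}
    for a, b in itertools.combinations(cfg.libraries, 2):
        _stage(f"de:{a}-vs-{b}")
        try:
            table, summary = call_de(
                expr[a], expr[b], alpha=cfg.alpha, min_abs_log2=cfg.min_abs_log2
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(f"de:{a}-vs-{b}", "test_failed", str(e)) from e
        de_tables[(a, b)] = table
        de_summaries[(a, b)] = summary.as_dict()

    _write_bundle(outdir, stamp, ref, clean, summaries, expr, sat, correlations,
                  de_tables, de_summaries, cfg)
    return PipelineResult(
        config=cfg,
        census=ref.census(),
        library_summaries=summaries,
        expression=expr,
        correlations=correlations,
        de_tables=de_tables,
        de_summaries=de_summaries,
        saturation_curves=sat,
    )


def _write_bundle(outdir, stamp, ref, clean, summaries, expr, sat, correlations,
                  de_tables, de_summaries, cfg) -> None:
    summaries.to_csv(outdir / "library_summary.tsv", sep="\t")
    with open(outdir / "reference_census.json", "w") as fh:
        json.dump({**stamp, **ref.census()}, fh, indent=2)
    expr_frame = pd.concat(
        {s: t.to_frame() for s, t in expr.items()}, axis=1
    )
    expr_frame.to_csv(outdir / "expression.tsv", sep="\t")
    for s, lib in clean.items():
        abundance_distribution(lib.counts, cfg.bins).to_csv(
            outdir / f"tag_distribution.{s}.tsv", sep="\t", index=False
        )
        tpm = expr[s].tpm
        abundance_distribution(tpm[tpm >= 1], cfg.bins).to_csv(
            outdir / f"gene_tpm_distribution.{s}.tsv", sep="\t", index=False
        )
        sat[s].to_csv(outdir / f"saturation.{s}.tsv", sep="\t", index=False)
    with open(outdir / "correlations.json", "w") as fh:
        json.dump({**stamp, **{f"{a}:{b}": r for (a, b), r in correlations.items()}},
                  fh, indent=2)
    for (a, b), table in de_tables.items():
        table.to_csv(outdir / f"de.{a}_vs_{b}.tsv", sep="\t", index=False)
    with open(outdir / "de_summary.json", "w") as fh:
        json.dump({**stamp, **{f"{a}:{b}": s for (a, b), s in de_summaries.items()}},
                  fh, indent=2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({**stamp, "config": {**asdict(cfg), "bins": [list(b) for b in cfg.bins]}},
                  fh, indent=2)


def profile_genes(
    gene_ids: Sequence[str], tables: Mapping[str, ExpressionTable]
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene TPM profile across libraries (stage-profile plots).

    Unknown gene_ids are collected as warnings, not errors; genes absent
    from a library report 0 TPM.
    """
    warnings = []
    known = []
    for g in gene_ids:
        if all(g not in t.tpm.index for t in tables.values()):
            warnings.append(f"unknown gene_id: {g}")
        else:
            known.append(g)
    prof = pd.DataFrame(
        {s: t.tpm.reindex(known, fill_value=0.0) for s, t in tables.items()}
    ).rename_axis("gene_id")
    return prof, warnings
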