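"""End-to-end run: (simulate | load) -> test -> call -> integrate.

A run consumes either a synthetic-experiment configuration or a triple of
input files (annotation, counts, sample table), executes the gene-level and
exon-level two-group tests and the cryptic-transcription caller, and writes
every artifact plus a manifest into one output directory.  The three
significance thresholds in play (gene track 0.01, exon track 0.001, caller
0.05) are all echoed into the manifest so a run is self-describing.
Re-running with the same configuration and seed reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy
import sklearn

from . import __version__
from . import io as cio
from .caller import CallerParams, CrypticCaller, calls_to_frame, evaluate_vs_truth
from .overlap import OverlapQuery, fisher_overlap, membership_table
from .simulate import SimConfig, simulate_experiment
from .stats import ExonDifferentialTest, FilterParams, TestParams, gene_test

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``sim`` or (``annotation``, ``counts``, ``samples``)
    must be provided.
    """

    out_dir: str
    sim: SimConfig | None = None
    annotation: str | None = None
    counts: str | None = None
    samples: str | None = None
    test: TestParams = field(default_factory=TestParams)
    filter: FilterParams = field(default_factory=FilterParams)
    caller: CallerParams = field(default_factory=CallerParams)
    seed: int | None = None
    universe_n: int | None = None

    def validate(self) -> None:
        have_paths = any(x is not None for x in (self.annotation, self.counts, self.samples))
        if self.sim is not None and have_paths:
            raise ValueError("provide either a SimConfig or input paths, not both")
        if self.sim is None:
            missing = [
                n for n in ("annotation", "counts", "samples") if getattr(self, n) is None
            ]
            if missing:
                raise ValueError(f"missing input paths: {missing}")


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write artifacts into ``config.out_dir``.

    Returns the manifest dictionary.  Any stage error aborts the run with
    the stage name attached and removes files written so far.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    written: list[str] = []

    def path(name: str) -> str:
        p = os.path.join(config.out_dir, name)
        written.append(p)
        return p

    stage = "setup"
    try:
        stage = "input"
        truth = None
        if config.sim is not None:
            sim = dataclasses.replace(config.sim)
            if config.seed is not None:
                sim.seed = config.seed
            models, samples, matrix, truth = simulate_experiment(sim)
        else:
            models = cio.read_exon_annotation(config.annotation)
            samples = cio.read_sample_table(config.samples)
            matrix = cio.read_counts(config.counts, models, samples)

        stage = "gene-test"
        gene_results = gene_test(matrix, samples, config.test, config.filter)
        cio._write_tsv(path("gene_tests.tsv"), gene_results)

        stage = "exon-test"
        exon_fit = ExonDifferentialTest(
            min_count=config.filter.min_count,
            min_samples=config.filter.min_samples,
            pseudocount=config.test.pseudocount,
            dispersion_floor=config.test.dispersion_floor,
            dispersion_cap=config.test.dispersion_cap,
            prior_df=config.test.prior_df,
            mode=config.test.mode,
        ).fit(matrix, samples)
        exon_results = exon_fit.results_
        cio._write_tsv(path("exon_tests.tsv"), exon_results)

        stage = "call-cryptic"
        caller = CrypticCaller(**_caller_kwargs(config.caller)).fit(
            exon_results, models=models
        )
        calls_frame = calls_to_frame(caller.calls_)
        cio._write_tsv(path("cryptic_calls.tsv"), calls_frame)
        cio.write_cryptic_bed(path("cryptic_tss.bed"), caller.calls_, models)

        stage = "integrate"
        deg = set(gene_results.loc[gene_results["p"] < config.test.deg_alpha, "gene_id"])
        deu_mask = (exon_results["p"] < config.test.deu_alpha) & exon_results["expressed"]
        deu = set(exon_results.loc[deu_mask, "gene_id"])
        ct = set(caller.passing_genes_)
        universe = config.universe_n or len(models)
        overlap_rows = []
        for (la, sa), (lb, sb) in [(("DEG", deg), ("CT", ct)), (("DEU", deu), ("CT", ct)), (("DEG", deg), ("DEU", deu))]:
            res = fisher_overlap(
                OverlapQuery(sa, sb, universe, label_a=la, label_b=lb)
            )
            overlap_rows.append(dataclasses.asdict(res))
        cio._write_tsv(path("overlaps.tsv"), pd.DataFrame(overlap_rows))
        members = membership_table({"DEG": deg, "DEU": deu, "CT": ct})
        cio._write_tsv(path("membership.tsv"), members.reset_index())

        metrics = None
        if truth is not None:
            stage = "evaluate"
            metrics = evaluate_vs_truth(caller.calls_, truth.genes)
            confusion = metrics.pop("confusion")
            cio._write_tsv(path("reason_confusion.tsv"), confusion.reset_index())
            cio._write_tsv(
                path("metrics.tsv"),
                pd.DataFrame([metrics]),
            )

        stage = "manifest"
        manifest = {
            "crypticseq_version": __version__,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
                "sklearn": sklearn.__version__,
            },
            "seed": config.seed if config.seed is not None else (
                config.sim.seed if config.sim is not None else None
            ),
            "config": {
                "sim": dataclasses.asdict(config.sim) if config.sim else None,
                "inputs": {
                    "annotation": config.annotation,
                    "counts": config.counts,
                    "samples": config.samples,
                },
                "test": dataclasses.asdict(config.test),
                "filter": dataclasses.asdict(config.filter),
                "caller": dataclasses.asdict(config.caller),
                "universe_n": universe,
            },
            "row_counts": {
                "genes_tested": int(len(gene_results)),
                "exons_tested": int(len(exon_results)),
                "genes_called": int(len(calls_frame)),
                "cryptic_pass": int((calls_frame["decision"] == "PASS").sum()),
                "deg": len(deg),
                "deu_genes": len(deu),
            },
            "metrics": metrics,
        }
        with open(path("manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")
        return manifest
    except Exception as exc:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def _caller_kwargs(params: CallerParams) -> dict:
    return dataclasses.asdict(params)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
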