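"""Synthetic exon-count experiments with per-gene ground truth.

The generator emulates the statistical design the analysis assumes: two
groups (five control vs six treatment replicates), negative-binomial exon
counts over multi-exon gene models, per-sample library-size factors, and a
mix of gene classes the caller must separate:

* NULL            — no treatment effect;
* DE_UP / DE_DOWN — all exons scaled by f (or 1/f): full-length regulation;
* CRYPTIC         — exons from an internal TSS j onward scaled by f, with
                    j in the first half of the gene (internal initiation
                    adds reads to every downstream bin);
* DECOY_PARTIAL   — only a fraction of the bins from j onward elevated, so
                    the downstream-fraction rule must reject it;
* DECOY_LATE      — full downstream elevation but j in the second half, so
                    the first-half rule must reject it.

Counts are NB(mean = mu_{g,e} * t_j * effect, variance = mu + alpha mu^2).
Per-exon baseline means are log-normal around a log-normal gene level, with
a small probability of a nearly silent exon (baseline times 0.01).  The
generation is fully deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .models import ExonBin, GeneModel, make_sample_table
from . import io as cio

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimTruth", "simulate_experiment", "write_fixture"]

CLASSES = ("NULL", "DE_UP", "DE_DOWN", "CRYPTIC", "DECOY_PARTIAL", "DECOY_LATE")
EFFECT_CLASSES = ("CRYPTIC", "DECOY_PARTIAL", "DECOY_LATE")

EXON_LENGTH = 100
EXON_GAP = 100
GENE_GAP = 1000


def _default_proportions() -> dict[str, float]:
    return {
        "NULL": 0.80,
        "DE_UP": 0.05,
        "DE_DOWN": 0.05,
        "CRYPTIC": 0.05,
        "DECOY_PARTIAL": 0.025,
        "DECOY_LATE": 0.025,
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment (defaults are the study design)."""

    n_genes: int = 2000
    exon_count_range: tuple[int, int] = (2, 25)
    n_control: int = 5
    n_treatment: int = 6
    class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    fold_range: tuple[float, float] = (2.0, 4.0)
    dispersion: float = 0.1
    gene_mean_logmean: float = 4.0
    gene_mean_logsd: float = 1.0
    exon_weight_logsd: float = 0.5
    library_factor_range: tuple[float, float] = (0.7, 1.3)
    low_expression_prob: float = 0.05
    low_expression_factor: float = 0.01
    partial_coverage: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if set(self.class_proportions) - set(CLASSES):
            raise ValueError(
                f"unknown class labels {set(self.class_proportions) - set(CLASSES)}"
            )
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        for name in ("exon_count_range", "fold_range", "library_factor_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        if self.n_control < 2 or self.n_treatment < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.partial_coverage <= 1:
            raise ValueError("partial_coverage must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    genes: per-gene table (class_label, ctss_index, fold, affected_exons,
    n_exons) indexed by gene_id; exon_means: baseline per-exon means
    indexed by (gene_id, bin_index); library_factors: per-sample factors.
    """

    genes: pd.DataFrame
    exon_means: pd.Series
    library_factors: pd.Series


def simulate_experiment(
    config: SimConfig | None = None,
) -> tuple[dict[str, GeneModel], pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (gene models, sample table, exon count matrix, truth)."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    sample_ids = [f"ctl{i + 1}" for i in range(config.n_control)] + [
        f"trt{i + 1}" for i in range(config.n_treatment)
    ]
    conditions = ["control"] * config.n_control + ["treatment"] * config.n_treatment
    samples = make_sample_table(sample_ids, conditions)
    lib_lo, lib_hi = config.library_factor_range
    lib = pd.Series(
        rng.uniform(lib_lo, lib_hi, size=len(sample_ids)), index=sample_ids,
        name="library_factor",
    )

    n = config.n_genes
    width = max(4, len(str(max(n, 1))))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n)]
    labels = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in labels], dtype=float)
    classes = rng.choice(labels, size=n, p=probs) if n else np.array([], dtype=object)

    lo, hi = config.exon_count_range
    effect_lo = max(lo, 4)  # internal-TSS classes need E >= 4 for a valid j
    if any(c in EFFECT_CLASSES for c in classes) and hi < 4:
        raise ValueError("exon_count_range max must be >= 4 to place internal TSSs")

    models: dict[str, GeneModel] = {}
    truth_rows = []
    mean_index = []
    mean_values = []
    mu_rows = []       # per-exon baseline means in transcriptional order
    effect_rows = []   # per-exon treatment multiplier
    cursor = 0
    for gi, gene_id in enumerate(gene_ids):
        label = classes[gi]
        elo = effect_lo if label in EFFECT_CLASSES else lo
        E = int(rng.integers(elo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        # tile exon bins on one synthetic chromosome
        genomic = [
            (cursor + k * (EXON_LENGTH + EXON_GAP), cursor + k * (EXON_LENGTH + EXON_GAP) + EXON_LENGTH)
            for k in range(E)
        ]
        cursor = genomic[-1][1] + GENE_GAP
        order = range(E) if strand == "+" else range(E - 1, -1, -1)
        bins = tuple(
            ExonBin(gene_id, b + 1, "chrS", genomic[k][0], genomic[k][1], strand)
            for b, k in enumerate(order)
        )
        models[gene_id] = GeneModel(gene_id, bins)

        gene_mu = math.exp(rng.normal(config.gene_mean_logmean, config.gene_mean_logsd))
        weights = np.exp(rng.normal(0.0, config.exon_weight_logsd, size=E))
        mu = gene_mu * weights
        low = rng.random(E) < config.low_expression_prob
        mu = np.where(low, mu * config.low_expression_factor, mu)

        fold = float(rng.uniform(*config.fold_range))
        half = math.ceil(E / 2)
        j: int | None = None
        affected: list[int] = []
        effect = np.ones(E)
        if label == "DE_UP":
            affected = list(range(1, E + 1))
            effect[:] = fold
        elif label == "DE_DOWN":
            affected = list(range(1, E + 1))
            effect[:] = 1.0 / fold
        elif label == "CRYPTIC":
            j = int(rng.integers(2, half + 1))
            affected = list(range(j, E + 1))
            effect[j - 1 :] = fold
        elif label == "DECOY_LATE":
            j = int(rng.integers(half + 1, E + 1))
            affected = list(range(j, E + 1))
            effect[j - 1 :] = fold
        elif label == "DECOY_PARTIAL":
            j = int(rng.integers(2, half + 1))
            tail = list(range(j, E + 1))
            size = max(1, int(round(config.partial_coverage * len(tail))))
            # the decoy's internal TSS is always affected so the first
            # significant exon sits at j and the downstream fraction,
            # not the first-half rule, is what rejects it
            extra = rng.choice(tail[1:], size=size - 1, replace=False) if size > 1 else []
            affected = sorted([j, *map(int, extra)])
            effect[[a - 1 for a in affected]] = fold
        if label == "NULL":
            fold = 1.0

        truth_rows.append(
            {
                "gene_id": gene_id,
                "class_label": label,
                "ctss_index": j,
                "fold": fold if label != "NULL" else 1.0,
                "affected_exons": ",".join(map(str, affected)),
                "n_exons": E,
            }
        )
        for b in range(E):
            mean_index.append((gene_id, b + 1))
            mean_values.append(mu[b])
        mu_rows.append(mu)
        effect_rows.append(effect)

    index = pd.MultiIndex.from_tuples(
        mean_index or [], names=["gene_id", "bin_index"]
    )
    if n:
        mu_flat = np.concatenate(mu_rows)
        eff_flat = np.concatenate(effect_rows)
        is_treatment = np.array([c == "treatment" for c in conditions])
        mean_matrix = (
            mu_flat[:, None]
            * np.where(is_treatment[None, :], eff_flat[:, None], 1.0)
            * lib.to_numpy()[None, :]
        )
        counts = _nb_draw(rng, mean_matrix, config.dispersion)
    else:
        counts = np.zeros((0, len(sample_ids)), dtype=np.int64)
    matrix = pd.DataFrame(counts, index=index, columns=sample_ids)

    truth = SimTruth(
        genes=pd.DataFrame(
            truth_rows,
            columns=["gene_id", "class_label", "ctss_index", "fold", "affected_exons", "n_exons"],
        ).set_index("gene_id"),
        exon_means=pd.Series(mean_values, index=index, name="baseline_mean", dtype=float),
        library_factors=lib,
    )
    return models, samples, matrix, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, variance = mu + alpha mu^2) sample; Poisson when alpha = 0."""
    if dispersion == 0:
        return rng.poisson(mean).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.int64)


def write_fixture(
    out_dir: str,
    models: dict[str, GeneModel],
    samples: pd.DataFrame,
    matrix: pd.DataFrame,
    truth: SimTruth,
    force: bool = False,
) -> dict[str, str]:
    """Write annotation/counts/samples/truth files readable by the IO layer."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "annotation": os.path.join(out_dir, "annotation.gff"),
        "counts": os.path.join(out_dir, "counts.tsv"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "exon_means": os.path.join(out_dir, "truth_exon_means.tsv"),
        "library_factors": os.path.join(out_dir, "truth_library_factors.tsv"),
    }
    existing = [p for p in paths.values() if os.path.exists(p)]
    if existing and not force:
        raise FileExistsError(
            f"refusing to overwrite {existing[0]} (pass force=True to allow)"
        )
    cio.write_exon_annotation(paths["annotation"], models)
    cio.write_counts(paths["counts"], matrix)
    cio.write_sample_table(paths["samples"], samples)
    cio._write_tsv(paths["truth"], truth.genes.reset_index())
    means = truth.exon_means.reset_index()
    cio._write_tsv(paths["exon_means"], means)
    cio._write_tsv(
        paths["library_factors"],
        truth.library_factors.rename_axis("sample_id").reset_index(),
    )
    return paths
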