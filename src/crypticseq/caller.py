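"""Cryptic-transcription calling from per-exon two-group statistics.

A gene shows evidence of cryptic (intragenic) transcription when an internal
run of exon bins is significantly elevated in the treatment group while the
annotated 5' end is not — the signature of transcription initiating inside
the gene body after loss of H3K36me3-mediated suppression.  The decision
cascade, applied to exon bins in transcriptional order:

0. genes with fewer than ``min_exons`` bins, or no expressed bin, are not
   callable (TOO_FEW_EXONS / NOT_EXPRESSED);
1. at least one exon bin must be significantly elevated (else NO_UP);
2. if the first annotated *and expressed* exon is itself significantly
   elevated the gene is treated as an up-regulated full-length mRNA and
   discarded (FULL_LENGTH_UP);
3. the cryptic TSS is the first (5'-most) significantly elevated exon;
4. genes where fewer than ``min_downstream_frac`` (default 60%) of the
   exons from the cryptic TSS onward are significantly elevated are
   filtered out (DOWNSTREAM_FRAC);
5. the cryptic TSS must lie within the first half of the gene's exons,
   c <= ceil(E/2) (LATE_TSS otherwise).

"Significantly elevated" means p < ``sig_alpha`` with direction up;
``sig_alpha`` defaults to 0.05, independent of the stricter exon-level
reporting threshold.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "CallerParams",
    "CrypticCall",
    "call_cryptic",
    "call_all",
    "calls_to_frame",
    "evaluate_vs_truth",
    "CrypticCaller",
]

REASONS = (
    "PASS",
    "NO_UP",
    "FULL_LENGTH_UP",
    "DOWNSTREAM_FRAC",
    "LATE_TSS",
    "NOT_EXPRESSED",
    "TOO_FEW_EXONS",
)


@dataclass
class CallerParams:
    """Tunables of the calling cascade.

    include_tss_in_downstream: whether the cryptic-TSS exon itself counts in
    the downstream-fraction denominator (it is elevated under internal
    initiation, and excluding it makes two-exon tails degenerate).
    require_expressed_denominator: restrict the denominator to expressed
    exons.  first_half_boundary: 'ceil' reads "among the first half"
    inclusively for odd exon counts (c <= ceil(E/2)); 'floor' is stricter.
    """

    sig_alpha: float = 0.05
    min_downstream_frac: float = 0.60
    first_half_rule: bool = True
    include_tss_in_downstream: bool = True
    require_expressed_denominator: bool = False
    min_exons: int = 1
    first_half_boundary: str = "ceil"

    def __post_init__(self) -> None:
        if not 0 < self.sig_alpha < 1:
            raise ValueError("sig_alpha must be in (0, 1)")
        if not 0 < self.min_downstream_frac <= 1:
            raise ValueError("min_downstream_frac must be in (0, 1]")
        if self.first_half_boundary not in ("ceil", "floor"):
            raise ValueError("first_half_boundary must be 'ceil' or 'floor'")


@dataclass(frozen=True)
class CrypticCall:
    """Per-gene decision with the inferred cryptic TSS and reason code."""

    gene_id: str
    decision: str
    reason: str
    ctss_index: int | None
    downstream_frac: float | None
    n_exons: int


def call_cryptic(
    gene_results: pd.DataFrame,
    params: CallerParams | None = None,
    n_exons: int | None = None,
) -> CrypticCall:
    """Apply the calling cascade to one gene's ordered exon results.

    ``gene_results`` must cover bins 1..E for a single gene with columns
    ``bin_index``, ``p``, ``direction`` and ``expressed``.
    """
    params = params or CallerParams()
    gene_ids = gene_results["gene_id"].unique()
    if len(gene_ids) != 1:
        raise ValueError(f"call_cryptic expects one gene, got {gene_ids.tolist()}")
    gene_id = gene_ids[0]
    df = gene_results.sort_values("bin_index")
    bins = df["bin_index"].to_numpy()
    E = len(bins)
    if not np.array_equal(bins, np.arange(1, E + 1)):
        raise ValueError(
            f"{gene_id}: exon results must cover bins 1..E contiguously, got {bins.tolist()}"
        )
    if n_exons is not None and n_exons != E:
        raise ValueError(
            f"{gene_id}: gene model has {n_exons} exons but results cover {E}"
        )
    expressed = df["expressed"].to_numpy(dtype=bool)
    sig_up = (df["p"].to_numpy() < params.sig_alpha) & (
        df["direction"].to_numpy() == "up"
    )

    def fail(reason: str, c=None, frac=None) -> CrypticCall:
        return CrypticCall(gene_id, "FAIL", reason, c, frac, E)

    # step 0: callability
    if E < params.min_exons:
        return fail("TOO_FEW_EXONS")
    if not expressed.any():
        return fail("NOT_EXPRESSED")
    # step 1: at least one significantly elevated exon
    if not sig_up.any():
        return fail("NO_UP")
    # step 2: discard upregulated full-length mRNAs
    first_expressed = int(np.flatnonzero(expressed)[0])
    if sig_up[first_expressed]:
        return fail("FULL_LENGTH_UP")
    # step 3: cryptic TSS = first significantly elevated exon
    c = int(np.flatnonzero(sig_up)[0]) + 1  # 1-based
    # step 4: downstream fraction
    lo = c if params.include_tss_in_downstream else c + 1
    denom_mask = bins >= lo
    if params.require_expressed_denominator:
        denom_mask &= expressed
    n_denom = int(denom_mask.sum())
    frac = float((sig_up & denom_mask).sum()) / n_denom if n_denom else 0.0
    if frac < params.min_downstream_frac:
        return fail("DOWNSTREAM_FRAC", c, frac)
    # step 5: cryptic TSS within the first half of all exons
    if params.first_half_rule:
        half = math.ceil(E / 2) if params.first_half_boundary == "ceil" else E // 2
        if c > half:
            return fail("LATE_TSS", c, frac)
    return CrypticCall(gene_id, "PASS", "PASS", c, frac, E)


def call_all(
    results: pd.DataFrame,
    models: Mapping | None = None,
    params: CallerParams | None = None,
) -> tuple[list[CrypticCall], Counter]:
    """Run the cascade over every gene with any tested exon.

    Returns calls in deterministic gene_id order plus summary counts per
    reason code (summing to the number of genes called).
    """
    params = params or CallerParams()
    calls: list[CrypticCall] = []
    for gene_id, gdf in results.groupby("gene_id", sort=True):
        n_exons = models[gene_id].n_exons if models is not None else None
        try:
            calls.append(call_cryptic(gdf, params, n_exons=n_exons))
        except ValueError as exc:
            raise ValueError(f"gene {gene_id}: {exc}") from exc
    summary = Counter(c.reason for c in calls)
    return calls, summary


def calls_to_frame(calls: Iterable[CrypticCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "decision": c.decision,
                "reason": c.reason,
                "ctss_index": c.ctss_index,
                "downstream_frac": c.downstream_frac,
                "n_exons": c.n_exons,
            }
            for c in calls
        ],
        columns=[
            "gene_id",
            "decision",
            "reason",
            "ctss_index",
            "downstream_frac",
            "n_exons",
        ],
    )


def evaluate_vs_truth(
    calls: Iterable[CrypticCall],
    truth: pd.DataFrame,
    min_baseline_mean: float | None = None,
    baseline_means: pd.Series | None = None,
) -> dict:
    """Score calls against simulated ground truth.

    ``truth`` is the per-gene truth table (class_label, ctss_index) from the
    synthetic generator.  Sensitivity is the PASS rate over CRYPTIC genes
    (optionally restricted to genes whose mean baseline exon mean is at
    least ``min_baseline_mean``); the false-call rate is the PASS rate over
    NULL genes; FDR is the fraction of PASS calls whose true class is not
    CRYPTIC; ctss_exact_rate is the fraction of true-positive calls whose
    cryptic TSS equals the true internal TSS.  A gene-class by reason-code
    confusion table covers the decoys' rejection paths.
    """
    frame = calls_to_frame(list(calls)).set_index("gene_id")
    call_genes = set(frame.index)
    truth_genes = set(truth.index)
    if call_genes - truth_genes:
        raise ValueError(
            f"calls reference genes absent from truth: {sorted(call_genes - truth_genes)[:5]}"
        )
    joined = frame.join(truth[["class_label", "ctss_index"]], rsuffix="_true")
    is_pass = joined["decision"] == "PASS"

    cryptic = joined["class_label"] == "CRYPTIC"
    sens_mask = cryptic.copy()
    if min_baseline_mean is not None:
        if baseline_means is None:
            raise ValueError("min_baseline_mean requires baseline_means")
        eligible = baseline_means.reindex(joined.index) >= min_baseline_mean
        sens_mask &= eligible.fillna(False)
    null = joined["class_label"] == "NULL"
    tp = (is_pass & cryptic).sum()
    fp = (is_pass & ~cryptic).sum()
    exact = (
        is_pass
        & cryptic
        & (joined["ctss_index"] == joined["ctss_index_true"])
    ).sum()
    confusion = pd.crosstab(joined["class_label"], joined["reason"])
    return {
        "sensitivity": float(is_pass[sens_mask].mean()) if sens_mask.any() else float("nan"),
        "specificity": float((~is_pass[null]).mean()) if null.any() else float("nan"),
        "null_pass_rate": float(is_pass[null].mean()) if null.any() else float("nan"),
        "fdr": float(fp / (tp + fp)) if (tp + fp) else 0.0,
        "ctss_exact_rate": float(exact / tp) if tp else float("nan"),
        "n_pass": int(is_pass.sum()),
        "confusion": confusion,
    }


class CrypticCaller(BaseEstimator):
    """Rule-based gene classifier over per-exon test results.

    scikit-learn style front-end for the calling cascade: ``fit`` consumes
    an exon-results table (native or imported) and exposes ``calls_``,
    ``summary_`` and ``passing_genes_``; ``predict`` returns the PASS/FAIL
    decision per gene of a results table.
    """

    def __init__(
        self,
        sig_alpha: float = 0.05,
        min_downstream_frac: float = 0.60,
        first_half_rule: bool = True,
        include_tss_in_downstream: bool = True,
        require_expressed_denominator: bool = False,
        min_exons: int = 1,
        first_half_boundary: str = "ceil",
    ):
        self.sig_alpha = sig_alpha
        self.min_downstream_frac = min_downstream_frac
        self.first_half_rule = first_half_rule
        self.include_tss_in_downstream = include_tss_in_downstream
        self.require_expressed_denominator = require_expressed_denominator
        self.min_exons = min_exons
        self.first_half_boundary = first_half_boundary

    def _caller_params(self) -> CallerParams:
        return CallerParams(
            sig_alpha=self.sig_alpha,
            min_downstream_frac=self.min_downstream_frac,
            first_half_rule=self.first_half_rule,
            include_tss_in_downstream=self.include_tss_in_downstream,
            require_expressed_denominator=self.require_expressed_denominator,
            min_exons=self.min_exons,
            first_half_boundary=self.first_half_boundary,
        )

    def fit(self, X: pd.DataFrame, y=None, models: Mapping | None = None):
        self.calls_, self.summary_ = call_all(X, models, self._caller_params())
        self.passing_genes_ = [c.gene_id for c in self.calls_ if c.decision == "PASS"]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        calls, _ = call_all(X, None, self._caller_params())
        return np.array([c.decision for c in calls])
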