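"""Two-group negative-binomial count statistics on exon bins and genes.

The model: counts K_ij for feature i in sample j are negative binomial with
mean mu_ij = s_j * q_ij and variance mu + alpha * mu^2, where s_j is a
median-of-ratios size factor and alpha the per-feature overdispersion.  The
two-group comparison is a Wald test on the log ratio of group means of
normalized counts, with the delta-method variance

    Var(log mean_g) ~= (1 / n_g) * (1 / (m_g + eps) + alpha_i)

so z = log(m_t + eps) - log(m_c + eps) over its standard error and
p = 2 * (1 - Phi(|z|)).  Dispersions are per-feature method-of-moments
estimates, optionally moderated toward the across-feature mean in the
empirical-Bayes style of limma/edgeR; with only a handful of replicates the
raw per-feature estimate is noisy enough to visibly inflate type-I error,
and the moderation restores calibration while keeping the estimator
per-feature.

Raw p-values are compared against thresholds downstream (a
Benjamini-Hochberg column is emitted for reference but not used for
calling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .models import validate_sample_table

logger = logging.getLogger(__name__)

__all__ = [
    "FilterParams",
    "TestParams",
    "prefilter",
    "size_factors",
    "estimate_dispersion",
    "moderate_dispersion",
    "wald_nb_test",
    "exon_test",
    "gene_test",
    "sum_to_genes",
    "ExonDifferentialTest",
    "GeneDifferentialTest",
]

RESULT_COLUMNS = [
    "gene_id",
    "bin_index",
    "mean_control",
    "mean_treatment",
    "log2fc",
    "p",
    "p_bh",
    "direction",
    "expressed",
    "source",
]


@dataclass
class FilterParams:
    """Low-expression prefilter: keep a feature iff strictly more than
    ``min_count`` counts in at least ``min_samples`` samples."""

    min_count: int = 10
    min_samples: int = 2

    def __post_init__(self) -> None:
        if self.min_count < 1 or self.min_samples < 1:
            raise ValueError("min_count and min_samples must be >= 1")


@dataclass
class TestParams:
    """Thresholds and numerical guards for the two-group NB Wald test.

    deg_alpha / deu_alpha are the reporting thresholds for the gene-level
    and exon-level tracks.  ``mode='relative'`` replaces the global size
    factor with a per-gene factor (the gene total in each sample over the
    geometric mean of gene totals) so the exon statistic measures relative
    exon usage within the gene rather than absolute abundance.
    """

    __test__ = False  # not a pytest class despite the name

    deg_alpha: float = 0.01
    deu_alpha: float = 0.001
    pseudocount: float = 0.5
    dispersion_floor: float = 1e-8
    dispersion_cap: float = 10.0
    prior_df: float = 20.0
    mode: str = "absolute"

    def __post_init__(self) -> None:
        for a in (self.deg_alpha, self.deu_alpha):
            if not 0 < a < 1:
                raise ValueError("alpha thresholds must be in (0, 1)")
        if not self.dispersion_floor < self.dispersion_cap:
            raise ValueError("dispersion_floor must be < dispersion_cap")
        if self.mode not in ("absolute", "relative"):
            raise ValueError("mode must be 'absolute' or 'relative'")


def prefilter(
    matrix: pd.DataFrame, params: FilterParams | None = None
) -> tuple[pd.DataFrame, list]:
    """Drop features without > min_count counts in >= min_samples samples.

    Returns the filtered matrix and the list of removed row keys.  The
    inequality is strict (a count of exactly min_count does not qualify).
    """
    params = params or FilterParams()
    keep = (matrix > params.min_count).sum(axis=1) >= params.min_samples
    removed = matrix.index[~keep].tolist()
    return matrix.loc[keep], removed


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The pseudo-reference for feature i is the geometric mean of its counts
    across samples, computed over features with all counts > 0; the factor
    for sample j is the median over those features of K_ij / reference_i.
    """
    values = matrix.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "pool counts to gene level before computing size factors"
        )
    logs = np.log(values[all_positive])
    log_ref = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_ref[:, None], axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def _group_masks(matrix: pd.DataFrame, samples: pd.DataFrame):
    validate_sample_table(samples, require_two_per_group=True)
    cond = samples.loc[matrix.columns, "condition"].to_numpy()
    return cond == "control", cond == "treatment"


def estimate_dispersion(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    floor: float = 1e-8,
    cap: float = 10.0,
) -> pd.Series:
    """Per-feature method-of-moments NB dispersion from normalized counts.

    With group means m_{i,g} and pooled residual variance
    v_i = sum_g sum_{j in g} (q_ij - m_{i,g})^2 / (n_total - 2), the
    estimate is clamp((v_i - m_i) / m_i^2, floor, cap) where m_i is the
    overall mean; features with m_i = 0 get the floor.
    """
    ctrl, trt = _group_masks(normalized, samples)
    n_total = normalized.shape[1]
    if n_total <= 2:
        raise ValueError("dispersion estimation needs more than 2 samples")
    q = normalized.to_numpy(dtype=float)
    mc = q[:, ctrl].mean(axis=1)
    mt = q[:, trt].mean(axis=1)
    rss = ((q[:, ctrl] - mc[:, None]) ** 2).sum(axis=1)
    rss += ((q[:, trt] - mt[:, None]) ** 2).sum(axis=1)
    v = rss / (n_total - 2)
    m = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / np.square(m)
    alpha = np.where(m > 0, alpha, floor)
    alpha = np.clip(alpha, floor, cap)
    return pd.Series(alpha, index=normalized.index, name="dispersion")


def moderate_dispersion(
    alpha_hat: pd.Series, residual_df: int, prior_df: float = 20.0
) -> pd.Series:
    """Shrink per-feature dispersions toward their across-feature mean.

    Weighted combination (residual_df * alpha_i + prior_df * mean(alpha)) /
    (residual_df + prior_df).  prior_df = 0 disables moderation.
    """
    if prior_df <= 0 or len(alpha_hat) == 0:
        return alpha_hat
    center = float(alpha_hat.mean())
    return (residual_df * alpha_hat + prior_df * center) / (residual_df + prior_df)


def wald_nb_test(mc, mt, n_c: int, n_t: int, alpha, eps: float = 0.5):
    """Delta-method Wald test on the log ratio of NB group means.

    Returns (log2fc, z, p) as arrays; vectorized over features.
    """
    mc = np.asarray(mc, dtype=float)
    mt = np.asarray(mt, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    log_ratio = np.log(mt + eps) - np.log(mc + eps)
    var = (1.0 / n_c) * (1.0 / (mc + eps) + alpha) + (1.0 / n_t) * (
        1.0 / (mt + eps) + alpha
    )
    z = log_ratio / np.sqrt(var)
    p = 2.0 * norm.sf(np.abs(z))
    return log_ratio / np.log(2.0), z, p


def _gene_relative_factors(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Per-gene per-sample usage factors g_j = gene total / geomean of totals.

    Genes with a zero total in any sample cannot be scaled and are skipped
    (returned in the second element).
    """
    totals = matrix.groupby(level="gene_id", sort=False).sum()
    positive = (totals > 0).all(axis=1)
    skipped = totals.index[~positive].tolist()
    totals = totals.loc[positive]
    logt = np.log(totals.to_numpy(dtype=float))
    factors = pd.DataFrame(
        np.exp(logt - logt.mean(axis=1, keepdims=True)),
        index=totals.index, columns=totals.columns,
    )
    per_row = factors.reindex(matrix.index.get_level_values("gene_id"))
    per_row.index = matrix.index
    return per_row, skipped


def exon_test(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    factors: pd.Series,
    dispersions: pd.Series,
    params: TestParams | None = None,
    filter_params: FilterParams | None = None,
) -> pd.DataFrame:
    """Two-group Wald test per exon bin.

    ``matrix`` holds raw counts (rows (gene_id, bin_index)); ``factors``
    are global size factors, ignored when ``params.mode == 'relative'`` in
    favour of per-gene usage factors.  The ``expressed`` flag applies the
    prefilter rule to each exon's raw counts; unexpressed exons are still
    tested so gene results stay contiguous for the caller.
    """
    params = params or TestParams()
    filter_params = filter_params or FilterParams()
    ctrl, trt = _group_masks(matrix, samples)
    raw = matrix.to_numpy(dtype=float)
    if params.mode == "relative":
        per_row, skipped = _gene_relative_factors(matrix)
        if skipped:
            logger.warning(
                "relative mode: skipping %d genes with a zero total in some sample",
                len(skipped),
            )
        keep = ~matrix.index.get_level_values("gene_id").isin(skipped)
        matrix = matrix.loc[keep]
        raw = matrix.to_numpy(dtype=float)
        q = raw / per_row.loc[matrix.index].to_numpy(dtype=float)
        dispersions = dispersions.reindex(matrix.index)
    else:
        q = raw / factors.loc[matrix.columns].to_numpy(dtype=float)[None, :]
    n_c, n_t = int(ctrl.sum()), int(trt.sum())
    mc = q[:, ctrl].mean(axis=1)
    mt = q[:, trt].mean(axis=1)
    alpha = dispersions.loc[matrix.index].to_numpy(dtype=float)
    log2fc, _, p = wald_nb_test(mc, mt, n_c, n_t, alpha, params.pseudocount)
    expressed = (
        (matrix > filter_params.min_count).sum(axis=1) >= filter_params.min_samples
    ).to_numpy()
    p_bh = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    out = pd.DataFrame(
        {
            "gene_id": matrix.index.get_level_values("gene_id"),
            "bin_index": matrix.index.get_level_values("bin_index"),
            "mean_control": mc,
            "mean_treatment": mt,
            "log2fc": log2fc,
            "p": p,
            "p_bh": p_bh,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
            "expressed": expressed,
            "source": "native",
        }
    ).reset_index(drop=True)
    return out


def sum_to_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse an exon-bin count matrix to per-gene totals."""
    return matrix.groupby(level="gene_id", sort=True).sum()


def gene_test(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    params: TestParams | None = None,
    filter_params: FilterParams | None = None,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group Wald test on per-gene summed counts.

    Prefilters low-expressed genes (they are absent from the result),
    normalizes by median-of-ratios size factors, estimates moderated
    gene-level dispersions, and applies the same Wald machinery as
    :func:`exon_test`.
    """
    params = params or TestParams()
    filter_params = filter_params or FilterParams()
    if isinstance(matrix.index, pd.MultiIndex):
        matrix = sum_to_genes(matrix)
    kept, _ = prefilter(matrix, filter_params)
    if factors is None:
        factors = size_factors(kept)
    ctrl, trt = _group_masks(kept, samples)
    q = kept.to_numpy(dtype=float) / factors.loc[kept.columns].to_numpy(dtype=float)[None, :]
    normalized = pd.DataFrame(q, index=kept.index, columns=kept.columns)
    disp = estimate_dispersion(
        normalized, samples, params.dispersion_floor, params.dispersion_cap
    )
    disp = moderate_dispersion(disp, kept.shape[1] - 2, params.prior_df)
    n_c, n_t = int(ctrl.sum()), int(trt.sum())
    mc = q[:, ctrl].mean(axis=1)
    mt = q[:, trt].mean(axis=1)
    log2fc, _, p = wald_nb_test(
        mc, mt, n_c, n_t, disp.to_numpy(), params.pseudocount
    )
    p_bh = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    return pd.DataFrame(
        {
            "gene_id": kept.index,
            "mean_control": mc,
            "mean_treatment": mt,
            "log2fc": log2fc,
            "p": p,
            "p_bh": p_bh,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# estimator front-ends


class _BaseDifferentialTest(BaseEstimator):
    """Shared fit machinery for the exon- and gene-level two-group tests."""

    def __init__(
        self,
        min_count: int = 10,
        min_samples: int = 2,
        pseudocount: float = 0.5,
        dispersion_floor: float = 1e-8,
        dispersion_cap: float = 10.0,
        prior_df: float = 20.0,
        mode: str = "absolute",
    ):
        self.min_count = min_count
        self.min_samples = min_samples
        self.pseudocount = pseudocount
        self.dispersion_floor = dispersion_floor
        self.dispersion_cap = dispersion_cap
        self.prior_df = prior_df
        self.mode = mode

    def _params(self) -> tuple[TestParams, FilterParams]:
        return (
            TestParams(
                pseudocount=self.pseudocount,
                dispersion_floor=self.dispersion_floor,
                dispersion_cap=self.dispersion_cap,
                prior_df=self.prior_df,
                mode=self.mode,
            ),
            FilterParams(self.min_count, self.min_samples),
        )

    @staticmethod
    def _sample_table(X: pd.DataFrame, y) -> pd.DataFrame:
        from .models import make_sample_table

        if isinstance(y, pd.DataFrame):
            return y
        return make_sample_table(X.columns, list(y))


class ExonDifferentialTest(_BaseDifferentialTest):
    """Two-group NB Wald test per exon bin, scikit-learn style.

    ``fit(X, y)`` takes an exon-by-sample count matrix (rows indexed by
    (gene_id, bin_index)) and either a sample table or a sequence of
    condition labels aligned to the columns.  Fitted attributes:
    ``size_factors_``, ``dispersions_`` (moderated), ``results_``.
    """

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            raise ValueError("y (condition labels or sample table) is required")
        samples = self._sample_table(X, y)
        params, fparams = self._params()
        gene_totals = sum_to_genes(X)
        self.size_factors_ = size_factors(gene_totals)
        q = X / self.size_factors_.loc[X.columns]
        raw_disp = estimate_dispersion(
            q, samples, params.dispersion_floor, params.dispersion_cap
        )
        self.dispersions_ = moderate_dispersion(
            raw_disp, X.shape[1] - 2, params.prior_df
        )
        self.results_ = exon_test(
            X, samples, self.size_factors_, self.dispersions_, params, fparams
        )
        return self


class GeneDifferentialTest(_BaseDifferentialTest):
    """Two-group NB Wald test on per-gene summed counts, scikit-learn style."""

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            raise ValueError("y (condition labels or sample table) is required")
        samples = self._sample_table(X, y)
        params, fparams = self._params()
        totals = sum_to_genes(X) if isinstance(X.index, pd.MultiIndex) else X
        kept, self.removed_ = prefilter(totals, fparams)
        self.size_factors_ = size_factors(kept)
        self.results_ = gene_test(
            totals, samples, params, fparams, factors=self.size_factors_
        )
        return self
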