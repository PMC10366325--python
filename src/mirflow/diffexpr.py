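"""Negative-binomial differential expression for miRNA count matrices.

The workflow mirrors the standard bulk RNA-seq treatment: median-of-ratios
size factors, an abundance filter (normalized count > 50 in at least two
samples of one cell type), and a per-miRNA negative-binomial Wald test with
a mean–dispersion trend and Benjamini–Hochberg correction per contrast.

The test is deliberately a single, fully specified NB Wald test — not a
re-implementation of any particular external tool's numerics:

* group means are size-factor-weighted means of raw counts,
  ``mu_g = sum_j K_ij / sum_j s_j``;
* per-miRNA dispersion is a method-of-moments estimate pooled across the two
  groups, floored at 1e-8, shrunk 50/50 toward the least-squares trend
  ``alpha(mu) = a0/mu + a1``;
* ``log2fc = log2((mu_b + 0.5) / (mu_a + 0.5))`` with a delta-method SE and a
  two-sided normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
LOG2FC_EPS = 0.5
DEFAULT_DESIGN = ("hESC", "NSC", "DiffNSC")

DE_COLUMNS = ["mirna_id", "baseMean_a", "baseMean_b", "log2fc", "se", "pvalue", "padj", "contrast"]


@dataclass
class CountMatrix:
    """miRNA × sample integer counts with per-sample metadata.

    ``counts`` is indexed by mirna_id with sample_id columns; ``sample_meta``
    is indexed by sample_id with columns cell_type, replicate.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if not set(self.counts.columns) <= set(self.sample_meta.index):
            missing = set(self.counts.columns) - set(self.sample_meta.index)
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)]
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("negative counts")
        self.counts.index.name = "mirna_id"
        self.sample_meta.index.name = "sample_id"

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def cell_types(self) -> list[str]:
        seen: list[str] = []
        for ct in self.sample_meta["cell_type"]:
            if ct not in seen:
                seen.append(ct)
        return seen

    def samples_of(self, cell_type: str) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["cell_type"] == cell_type])

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="mirna_id")
        self.sample_meta.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="mirna_id")
        meta = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        return cls(counts=counts, sample_meta=meta)


@dataclass
class NormalizedMatrix:
    """Counts divided by per-sample size factors (geometric mean 1)."""

    raw: CountMatrix
    size_factors: pd.Series
    normalized: pd.DataFrame = field(init=False)

    def __post_init__(self):
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        self.normalized = self.raw.counts / self.size_factors

    @property
    def sample_meta(self) -> pd.DataFrame:
        return self.raw.sample_meta

    def subset(self, mirna_ids: Sequence[str]) -> "NormalizedMatrix":
        sub = CountMatrix(self.raw.counts.loc[list(mirna_ids)], self.raw.sample_meta)
        return NormalizedMatrix(raw=sub, size_factors=self.size_factors)

    def type_means(self) -> pd.DataFrame:
        """Mean normalized count per cell type (columns = cell types)."""
        cols = {}
        for ct in self.raw.cell_types():
            cols[ct] = self.normalized[self.raw.samples_of(ct)].mean(axis=1)
        return pd.DataFrame(cols)


def size_factors(counts: CountMatrix) -> NormalizedMatrix:
    """Median-of-ratios normalization.

    For each sample j, ``s_j = median_i count_ij / geomean_i`` over miRNAs with
    a finite positive geometric mean across all samples; size factors are then
    rescaled so their geometric mean is exactly 1.
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("size-factor estimation needs at least 2 samples")
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no miRNA has positive counts in every sample; size factors are "
            "undefined (consider a pseudo-reference fallback)"
        )
    ref = mat[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    log_sf = np.median(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean of s_j == 1
    sf = pd.Series(np.exp(log_sf), index=counts.counts.columns, name="size_factor")
    return NormalizedMatrix(raw=counts, size_factors=sf)


def abundance_filter(
    norm: NormalizedMatrix, threshold: float = 50.0, min_samples: int = 2
) -> list[str]:
    """Keep a miRNA iff some cell type has > ``threshold`` normalized counts
    (strict) in at least ``min_samples`` of its samples."""
    import warnings

    keep = pd.Series(False, index=norm.normalized.index)
    for ct in norm.raw.cell_types():
        samples = norm.raw.samples_of(ct)
        if len(samples) < min_samples:
            warnings.warn(
                f"cell type {ct} has fewer than {min_samples} samples and cannot "
                "qualify miRNAs for retention"
            )
            continue
        n_over = (norm.normalized[samples] > threshold).sum(axis=1)
        keep |= n_over >= min_samples
    return list(norm.normalized.index[keep])


def _dispersion_mom(z: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Pooled within-group method-of-moments dispersion on normalized counts.

    Solves  pooled residual variance = mean + alpha * mean^2  per miRNA, where
    variance and squared mean are pooled over the two groups with (n_g - 1)
    weights.
    """
    num = np.zeros(z.shape[0])
    den = np.zeros(z.shape[0])
    for idx in groups:
        zg = z[:, idx]
        n = zg.shape[1]
        if n < 2:
            continue
        m = zg.mean(axis=1)
        v = zg.var(axis=1, ddof=1)
        num += (n - 1) * (v - m)
        den += (n - 1) * m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return alpha


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a0/mu + a1 over miRNAs with mu > 0."""
    ok = mu > 0
    if ok.sum() < 2:
        return 0.0, float(np.mean(alpha[ok])) if ok.any() else 0.0
    x = 1.0 / mu[ok]
    X = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(X, alpha[ok], rcond=None)
    return float(coef[0]), float(coef[1])


def nb_test(
    norm: NormalizedMatrix,
    group_a: str,
    group_b: str,
    contrast_label: str | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test; positive log2fc means higher in ``group_b``.

    Returns a frame with columns mirna_id, baseMean_a, baseMean_b, log2fc,
    se, pvalue, padj (BH within this contrast), contrast.
    """
    samples_a = norm.raw.samples_of(group_a)
    samples_b = norm.raw.samples_of(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both groups need at least 2 samples")
    label = contrast_label or f"{group_b}_vs_{group_a}"

    K = norm.raw.counts[samples_a + samples_b].to_numpy(dtype=float)
    sf = norm.size_factors[samples_a + samples_b].to_numpy()
    z = K / sf
    na, nb = len(samples_a), len(samples_b)
    idx_a = np.arange(na)
    idx_b = np.arange(na, na + nb)

    sum_sa, sum_sb = sf[idx_a].sum(), sf[idx_b].sum()
    mu_a = K[:, idx_a].sum(axis=1) / sum_sa
    mu_b = K[:, idx_b].sum(axis=1) / sum_sb
    mu_all = K.sum(axis=1) / sf.sum()

    alpha_raw = np.maximum(_dispersion_mom(z, [idx_a, idx_b]), DISPERSION_FLOOR)
    a0, a1 = _fit_dispersion_trend(mu_all, alpha_raw)
    with np.errstate(divide="ignore"):
        alpha_trend = np.where(mu_all > 0, a0 / np.maximum(mu_all, 1e-300) + a1, a1)
    alpha_trend = np.maximum(alpha_trend, DISPERSION_FLOOR)
    # 50/50 shrink toward the trend, floored at the trend: the per-gene moment
    # estimate has ~4 df at these group sizes and letting it pull the shrunk
    # value below the trend makes the normal-reference Wald test anticonservative
    alpha = np.maximum(0.5 * alpha_raw + 0.5 * alpha_trend, alpha_trend)

    log2fc = np.log2((mu_b + LOG2FC_EPS) / (mu_a + LOG2FC_EPS))

    def _var_log2_mu(mu: np.ndarray, idx: np.ndarray, sum_s: float) -> np.ndarray:
        var_mu = ((sf[idx] * mu[:, None]) + alpha[:, None] * (sf[idx] ** 2) * mu[:, None] ** 2).sum(
            axis=1
        ) / sum_s**2
        return var_mu / ((mu + LOG2FC_EPS) ** 2 * np.log(2) ** 2)

    var = _var_log2_mu(mu_a, idx_a, sum_sa) + _var_log2_mu(mu_b, idx_b, sum_sb)
    se = np.sqrt(var)

    both_zero = (mu_a == 0) & (mu_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / np.maximum(se, 1e-300), 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))
    log2fc = np.where(both_zero, 0.0, log2fc)
    pvalue = np.where(both_zero, 1.0, pvalue)
    se = np.where(se > 0, se, np.inf)
    pvalue = np.minimum(pvalue, 1.0)

    padj = benjamini_hochberg(pvalue)
    return pd.DataFrame(
        {
            "mirna_id": list(norm.raw.counts.index),
            "baseMean_a": mu_a,
            "baseMean_b": mu_b,
            "log2fc": log2fc,
            "se": se,
            "pvalue": pvalue,
            "padj": padj,
            "contrast": label,
        }
    )


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


def run_contrasts(
    norm: NormalizedMatrix, design: Sequence[str] = DEFAULT_DESIGN
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The study's two transitions: (2nd vs 1st cell type, 3rd vs 2nd).

    Positive log2fc in contrast 1 means higher in the second state (NSC over
    hESC with the default design).
    """
    if len(design) != 3:
        raise ValueError("design must list exactly three cell types in order")
    present = set(norm.raw.sample_meta["cell_type"])
    missing = [ct for ct in design if ct not in present]
    if missing:
        raise ValueError(f"cell types missing from sample sheet: {missing}")
    de1 = nb_test(norm, design[0], design[1], f"{design[1]}_vs_{design[0]}")
    de2 = nb_test(norm, design[1], design[2], f"{design[2]}_vs_{design[1]}")
    return de1, de2


class DifferentialExpressionModel:
    """Three-state miRNA differential-expression model.

    Wraps normalization, abundance filtering and the two-transition NB Wald
    tests behind a fit() -> results interface.

    Parameters
    ----------
    counts : CountMatrix
    design : ordered cell types (reference → intermediate → terminal)
    filter_threshold, min_samples : abundance-filter settings (normalized
        count strictly greater than the threshold in at least ``min_samples``
        samples of one cell type).
    """

    def __init__(
        self,
        counts: CountMatrix,
        design: Sequence[str] = DEFAULT_DESIGN,
        filter_threshold: float = 50.0,
        min_samples: int = 2,
    ):
        self.counts = counts
        self.design = tuple(design)
        self.filter_threshold = filter_threshold
        self.min_samples = min_samples

    @classmethod
    def from_tsv(cls, counts_path, samples_path, **kwargs) -> "DifferentialExpressionModel":
        return cls(CountMatrix.from_tsv(counts_path, samples_path), **kwargs)

    def fit(self) -> "DifferentialExpressionResults":
        norm = size_factors(self.counts)
        retained = abundance_filter(norm, self.filter_threshold, self.min_samples)
        norm_retained = norm.subset(retained)
        de1, de2 = run_contrasts(norm_retained, self.design)
        return DifferentialExpressionResults(self, norm, norm_retained, retained, de1, de2)


class DifferentialExpressionResults:
    """Fitted results: size factors, retained universe and the two DE tables."""

    def __init__(self, model, norm, norm_retained, retained, de1, de2):
        self.model = model
        self.normalized = norm
        self.normalized_retained = norm_retained
        self.retained = retained
        self.de1 = de1
        self.de2 = de2

    def classify(self, p_thresh: float = 0.05, fc_thresh: float = 0.6, mapping=None) -> pd.DataFrame:
        from .trajectory import classify

        return classify(self.de1, self.de2, p_thresh=p_thresh, fc_thresh=fc_thresh, mapping=mapping)

    def n_significant(self, which: int = 1, p_thresh: float = 0.05) -> int:
        de = self.de1 if which == 1 else self.de2
        return int((de["padj"] < p_thresh).sum())

    def summary(self) -> str:
        lines = [
            "Differential expression summary",
            "================================",
            f"design: {' -> '.join(self.model.design)}",
            f"miRNAs: {len(self.model.counts.mirna_ids)} input, "
            f"{len(self.retained)} retained "
            f"(normalized count > {self.model.filter_threshold} in >= "
            f"{self.model.min_samples} samples of one cell type)",
            "size factors:",
        ]
        for sid, s in self.normalized.size_factors.items():
            lines.append(f"  {sid}: {s:.4f}")
        for i, de in ((1, self.de1), (2, self.de2)):
            sig = (de["padj"] < 0.05).sum()
            lines.append(
                f"contrast {i} ({de['contrast'].iloc[0]}): {sig} miRNAs at padj < 0.05"
            )
        return "\n".join(lines)
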