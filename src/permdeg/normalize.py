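"""Count normalization: log2(count + 1) and trimmed mean of M-values (TMM).

TMM estimates one scaling factor per sample from precision-weighted,
doubly-trimmed log ratios (M-values) of count fractions against a reference
sample, following the canonical published procedure: genes with a zero in
either the sample or the reference are excluded from factor estimation
(never from the expression matrix), M-values are trimmed by 30% on each
side and A-values by 5%, weights are the inverse asymptotic binomial
variance of M, and the resulting factors are rescaled to geometric mean 1.
The reference is the sample whose 75th-percentile count fraction is closest
to the across-sample mean.

Two ways of applying the factors are provided:

* :func:`normalize_counts` — the package's main path: each count is divided
  by its sample's *relative effective size factor* (library size x TMM
  factor, rescaled to geometric mean 1) before the +1 pseudocount, i.e.
  ``log2(count / s_j + 1)``.  This makes samples that are exact scalar
  multiples of each other normalize to identical columns.
* :func:`apply_factors` — a per-column shift of an existing log2(count+1)
  matrix by ``-log2(s_j)``; equivalent to the above for large counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import NormalizationError, ValidationError
from .matrix import CountMatrix, LogExpressionMatrix

__all__ = [
    "NormalizationFactors",
    "log2_plus_one",
    "tmm_factors",
    "effective_size_factors",
    "apply_factors",
    "normalize_counts",
]


@dataclass
class NormalizationFactors:
    """Per-sample TMM factors (geometric mean 1) plus the library sizes
    they were estimated with and the reference sample used."""

    factors: pd.Series
    reference_sample: str
    library_sizes: pd.Series

    def effective(self) -> pd.Series:
        """Relative effective size factors: library size x TMM factor,
        rescaled to geometric mean 1."""
        eff = self.library_sizes * self.factors
        return eff / np.exp(np.log(eff).mean())


def log2_plus_one(counts: CountMatrix) -> LogExpressionMatrix:
    """Convert counts to log2(count + 1)."""
    arr = counts.counts.to_numpy(dtype=float)
    vals = np.log2(arr + 1.0)
    return LogExpressionMatrix(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
        counts.group_labels,
    )


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**f)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / lib_obs) / (ref / lib_ref))
        a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
        # asymptotic binomial variance of M (delta method)
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[finite], a[finite], v[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationFactors:
    """Estimate TMM scaling factors (rescaled to geometric mean 1)."""
    if counts.n_samples < 2:
        raise ValidationError("TMM needs at least two samples")
    X = counts.counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    zero_samples = [s for s, l in zip(counts.sample_ids, lib) if l == 0]
    if zero_samples:
        raise NormalizationError(
            f"cannot normalize all-zero sample(s): {zero_samples}"
        )
    Y = X[X.sum(axis=1) > 0]  # all-zero genes never inform the factors
    if Y.shape[0] == 0:
        raise NormalizationError("no gene with positive counts")
    f75 = np.array([np.quantile(Y[:, j], 0.75) for j in range(Y.shape[1])]) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    raw = np.array(
        [
            _tmm_pair_factor(Y[:, j], Y[:, ref], lib[j], lib[ref], trim_m, trim_a)
            for j in range(Y.shape[1])
        ]
    )
    factors = raw / np.exp(np.log(raw).mean())
    return NormalizationFactors(
        factors=pd.Series(factors, index=counts.sample_ids),
        reference_sample=counts.sample_ids[ref],
        library_sizes=pd.Series(lib, index=counts.sample_ids),
    )


def effective_size_factors(counts: CountMatrix, trim_m: float = 0.30,
                           trim_a: float = 0.05) -> pd.Series:
    """Relative effective size factors (library size x TMM, geomean 1)."""
    return tmm_factors(counts, trim_m=trim_m, trim_a=trim_a).effective()


def apply_factors(
    logmat: LogExpressionMatrix, factors: NormalizationFactors
) -> LogExpressionMatrix:
    """Shift each log2 column by −log2 of its relative effective size factor."""
    if list(logmat.sample_ids) != list(factors.factors.index):
        raise ValidationError(
            "sample ids of the expression matrix and the factors differ "
            f"({logmat.sample_ids} vs {list(factors.factors.index)})"
        )
    eff = factors.effective().to_numpy()
    vals = logmat.values.to_numpy(dtype=float) - np.log2(eff)[None, :]
    return LogExpressionMatrix(
        pd.DataFrame(vals, index=logmat.gene_ids, columns=logmat.sample_ids),
        logmat.group_labels,
    )


def normalize_counts(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> LogExpressionMatrix:
    """TMM-normalized log2 expression: ``log2(count / s_j + 1)``.

    ``s_j`` is sample j's relative effective size factor (library size x
    TMM factor, geometric mean 1 across samples).
    """
    eff = effective_size_factors(counts, trim_m=trim_m, trim_a=trim_a).to_numpy()
    arr = counts.counts.to_numpy(dtype=float)
    vals = np.log2(arr / eff[None, :] + 1.0)
    return LogExpressionMatrix(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
        counts.group_labels,
    )
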