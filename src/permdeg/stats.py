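"""Integrative permutation-null differential expression.

For each gene two statistics are computed on normalized log2 expression:
a pooled-variance Student's t and the log2 fold change (second condition
minus first).  Null distributions for both are built empirically by
recomputing the statistics under every distinct relabelling of the samples
that preserves the group sizes (the identity labelling, and its group-swap
mirror when the design is balanced, excluded) and pooling the permuted
values across all genes.  Each observed statistic gets a two-sided,
add-one-smoothed empirical p-value from its null, the two p-values are
combined with Stouffer's method (equal weights), and a gene is called
differentially expressed when the combined p-value is at most
``alpha_combined`` *and* the absolute log2 fold change is at least
``min_abs_log2fc`` (defaults 0.05 and 0.58, i.e. 1.5-fold).

With two replicates per condition there are C(4,2) = 6 labellings, of which
two non-identity split classes remain after removing group-swap mirrors, so
the pooled null holds ``2 * n_genes`` draws per statistic — the pooling
across genes is what gives usable p-value resolution at this design size.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DesignError, ValidationError
from .matrix import CountMatrix, LogExpressionMatrix
from .normalize import normalize_counts

__all__ = [
    "DEGThresholds",
    "SplitEnumeration",
    "PermutationNull",
    "GeneStatTable",
    "gene_statistics",
    "enumerate_splits",
    "build_null",
    "empirical_p",
    "stouffer_combine",
    "call_degs",
    "integrative_test",
]


@dataclass(frozen=True)
class DEGThresholds:
    """Dual DEG-calling cutoffs; both inequalities are inclusive.

    ``min_abs_log2fc`` = 0.58 corresponds to a 1.5-fold change
    (2**0.58 rounds to 1.5).
    """

    alpha_combined: float = 0.05
    min_abs_log2fc: float = 0.58
    variance_floor: float = 1e-8

    def __post_init__(self):
        if not 0.0 < self.alpha_combined < 1.0:
            raise ValidationError("alpha_combined must lie in (0, 1)")
        if self.min_abs_log2fc < 0:
            raise ValidationError("min_abs_log2fc must be >= 0")
        if not self.variance_floor > 0:
            raise ValidationError("variance_floor must be positive")


# ---------------------------------------------------------------------------
# label permutations

@dataclass
class SplitEnumeration:
    """All group-size-preserving relabellings of the samples.

    ``n_assignments`` counts every C(n, n1) assignment.  ``retained`` holds
    the boolean second-group membership masks actually used for the null:
    the identity assignment is removed, and for balanced designs each
    assignment and its group-swapped mirror collapse to one split class.
    """

    sample_ids: list[str]
    group_sizes: tuple[int, int]
    n_assignments: int
    retained: list[np.ndarray]
    exhaustive: bool = True

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def _canonical(mask: tuple[bool, ...], balanced: bool) -> tuple[bool, ...]:
    # for balanced designs a mask and its complement are the same split
    if balanced and mask[0]:
        return tuple(not b for b in mask)
    return mask


def enumerate_splits(
    labels: Sequence[str] | pd.Series,
    sample_ids: Sequence[str] | None = None,
    max_exhaustive: int = 10_000,
    n_permutations: int = 1_000,
    seed: int | None = None,
) -> SplitEnumeration:
    """Enumerate the label permutations defining the empirical null.

    Enumeration is exhaustive whenever the number of assignments
    C(n1+n2, n1) is at most ``max_exhaustive``; beyond that a seeded
    Monte-Carlo subsample of ``n_permutations`` distinct non-identity
    splits is drawn instead.
    """
    if isinstance(labels, pd.Series):
        if sample_ids is None:
            sample_ids = list(labels.index)
        labels = labels.tolist()
    labels = [str(x) for x in labels]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(labels))]
    order = list(dict.fromkeys(labels))
    if len(order) != 2:
        raise ValidationError(f"two group labels required, got {order!r}")
    observed = tuple(lab == order[1] for lab in labels)
    n = len(labels)
    n2 = sum(observed)
    n1 = n - n2
    if n1 < 2 or n2 < 2:
        raise DesignError(
            f"each group needs >= 2 samples for the t-statistic (got {n1} vs {n2})"
        )
    balanced = n1 == n2
    total = math.comb(n, n2)

    if total <= max_exhaustive:
        seen: set[tuple[bool, ...]] = set()
        retained: list[np.ndarray] = []
        identity = _canonical(observed, balanced)
        for combo in itertools.combinations(range(n), n2):
            mask = tuple(i in combo for i in range(n))
            canon = _canonical(mask, balanced)
            if canon == identity or canon in seen:
                continue
            seen.add(canon)
            retained.append(np.array(canon, dtype=bool))
        return SplitEnumeration(
            sample_ids=list(sample_ids),
            group_sizes=(n1, n2),
            n_assignments=total,
            retained=retained,
            exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    seen = set()
    retained = []
    identity = _canonical(observed, balanced)
    attempts = 0
    while len(retained) < n_permutations and attempts < 100 * n_permutations:
        attempts += 1
        combo = rng.choice(n, size=n2, replace=False)
        mask = tuple(i in set(combo.tolist()) for i in range(n))
        canon = _canonical(mask, balanced)
        if canon == identity or canon in seen:
            continue
        seen.add(canon)
        retained.append(np.array(canon, dtype=bool))
    return SplitEnumeration(
        sample_ids=list(sample_ids),
        group_sizes=(n1, n2),
        n_assignments=total,
        retained=retained,
        exhaustive=False,
    )


# ---------------------------------------------------------------------------
# per-gene statistics

def _t_and_lfc(
    values: np.ndarray, mask2: np.ndarray, variance_floor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled-variance t and log2FC for one labelling."""
    x1 = values[:, ~mask2]
    x2 = values[:, mask2]
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise DesignError("each group needs >= 2 samples")
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    lfc = m2 - m1
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    sp2 = np.maximum(sp2, variance_floor)
    t = lfc / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return t, lfc


def gene_statistics(
    logmat: LogExpressionMatrix,
    labels: Sequence[str] | pd.Series | None = None,
    variance_floor: float = 1e-8,
) -> pd.DataFrame:
    """Observed pooled-variance t and log2FC per gene.

    ``labels`` defaults to the matrix's own group labelling; fold change is
    mean(second group) − mean(first group) in first-appearance order.
    """
    if labels is None:
        mask2 = logmat.group_mask()
    else:
        lab = [str(x) for x in (labels.tolist() if isinstance(labels, pd.Series) else labels)]
        order = list(dict.fromkeys(lab))
        if len(order) != 2:
            raise ValidationError(f"two group labels required, got {order!r}")
        mask2 = np.array([x == order[1] for x in lab])
    t, lfc = _t_and_lfc(logmat.values.to_numpy(dtype=float), mask2, variance_floor)
    return pd.DataFrame({"gene_id": logmat.gene_ids, "t_stat": t, "log2fc": lfc})


# ---------------------------------------------------------------------------
# empirical null

@dataclass
class PermutationNull:
    """Permuted t and log2FC values, one column per retained split.

    ``null_t`` / ``null_lfc`` expose the pooled (flattened) multisets; the
    2-D arrays are kept so a per-gene null scope can reuse them.
    """

    splits: SplitEnumeration
    t: np.ndarray  # (n_genes, n_splits)
    lfc: np.ndarray  # (n_genes, n_splits)

    @property
    def null_t(self) -> np.ndarray:
        return self.t.ravel()

    @property
    def null_lfc(self) -> np.ndarray:
        return self.lfc.ravel()

    @property
    def size(self) -> int:
        return self.t.size


def build_null(
    logmat: LogExpressionMatrix,
    splits: SplitEnumeration,
    variance_floor: float = 1e-8,
) -> PermutationNull:
    """Recompute both statistics under every retained relabelling."""
    if splits.n_retained == 0:
        raise DesignError(
            "no non-identity label permutation available; the design is too "
            "small to build an empirical null (need more replicates)"
        )
    values = logmat.values.to_numpy(dtype=float)
    t_cols = []
    lfc_cols = []
    for mask in splits.retained:
        t, lfc = _t_and_lfc(values, mask, variance_floor)
        t_cols.append(t)
        lfc_cols.append(lfc)
    return PermutationNull(
        splits=splits,
        t=np.column_stack(t_cols),
        lfc=np.column_stack(lfc_cols),
    )


def empirical_p(observed, null: np.ndarray) -> np.ndarray | float:
    """Two-sided add-one-smoothed empirical p-value(s).

    p = (#{x in null : |x| >= |observed|} + 1) / (|null| + 1), so p lies on
    the grid k/(N+1), k = 1..N+1.
    """
    null = np.asarray(null, dtype=float).ravel()
    if null.size == 0:
        raise ValidationError("empty null distribution")
    sorted_abs = np.sort(np.abs(null))
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    exceed = null.size - np.searchsorted(sorted_abs, np.abs(obs), side="left")
    p = (exceed + 1.0) / (null.size + 1.0)
    return float(p[0]) if np.isscalar(observed) or np.ndim(observed) == 0 else p


def stouffer_combine(p_t, p_lfc, eps: float = 1e-12):
    """Combine two p-values with Stouffer's method (equal weights).

    Inputs are clipped to [eps, 1−eps] before the normal-quantile
    transform; callers pass eps = 1/(null size + 1), the smallest p the
    empirical null can produce.  Returns (p_combined, z_t, z_lfc).
    """
    p1 = np.clip(np.asarray(p_t, dtype=float), eps, 1.0 - eps)
    p2 = np.clip(np.asarray(p_lfc, dtype=float), eps, 1.0 - eps)
    if not (np.isfinite(p1).all() and np.isfinite(p2).all()):
        raise ValidationError("p-values must be finite")
    z1 = norm.isf(p1)
    z2 = norm.isf(p2)
    combined = norm.sf((z1 + z2) / math.sqrt(2.0))
    return combined, z1, z2


# ---------------------------------------------------------------------------
# DEG calling

@dataclass
class GeneStatTable:
    """Per-gene statistics with DEG calls and a null-distribution summary.

    ``table`` columns: gene_id, t_stat, log2fc, p_t, p_lfc, z_t, z_lfc,
    p_combined (+ p_combined_bh when BH was applied), is_deg, direction.
    """

    table: pd.DataFrame
    thresholds: DEGThresholds
    null_summary: dict
    group_order: tuple[str, str]

    @property
    def n_deg(self) -> int:
        return int(self.table["is_deg"].sum())

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())

    @property
    def deg_genes(self) -> list[str]:
        return self.table.loc[self.table["is_deg"], "gene_id"].tolist()

    def summary(self) -> dict:
        return {
            "n_genes": int(len(self.table)),
            "n_deg": self.n_deg,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "group_order": list(self.group_order),
            "thresholds": {
                "alpha_combined": self.thresholds.alpha_combined,
                "min_abs_log2fc": self.thresholds.min_abs_log2fc,
                "variance_floor": self.thresholds.variance_floor,
            },
            "null": self.null_summary,
        }

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["is_deg"] = out["is_deg"].map({True: "true", False: "false"})
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gene_stats(path) -> pd.DataFrame:
    """Read back a per-gene statistics TSV written by GeneStatTable.to_tsv."""
    df = pd.read_csv(path, sep="\t")
    df["is_deg"] = df["is_deg"].map(lambda x: str(x).strip().lower() in {"true", "1"})
    return df


def call_degs(
    stats: pd.DataFrame, thresholds: DEGThresholds | None = None
) -> pd.DataFrame:
    """Apply the dual threshold: combined p <= alpha AND |log2FC| >= cutoff."""
    th = thresholds or DEGThresholds()
    out = stats.copy()
    p_col = "p_combined_bh" if "p_combined_bh" in out.columns else "p_combined"
    is_deg = (out[p_col] <= th.alpha_combined) & (
        out["log2fc"].abs() >= th.min_abs_log2fc
    )
    out["is_deg"] = is_deg
    direction = np.where(out["log2fc"] > 0, "up", "down")
    out["direction"] = np.where(is_deg, direction, "none")
    return out


def integrative_test(
    data: CountMatrix | LogExpressionMatrix,
    thresholds: DEGThresholds | None = None,
    *,
    null_scope: str = "pooled",
    max_exhaustive: int = 10_000,
    n_permutations: int = 1_000,
    seed: int | None = None,
    bh: bool = False,
) -> GeneStatTable:
    """Run the full integrative test on a count or log-expression matrix.

    A :class:`CountMatrix` is first TMM-normalized to log2 expression.
    ``null_scope`` is "pooled" (default: one null across all genes) or
    "per_gene" (each gene ranked only against its own permuted values —
    very coarse p-values at small designs, provided for sensitivity
    analysis).  ``bh`` adds Benjamini–Hochberg adjustment of the combined
    p-values and bases the DEG call on the adjusted values.
    """
    th = thresholds or DEGThresholds()
    if null_scope not in {"pooled", "per_gene"}:
        raise ValidationError(f"unknown null_scope {null_scope!r}")
    logmat = normalize_counts(data) if isinstance(data, CountMatrix) else data

    splits = enumerate_splits(
        logmat.group_labels,
        sample_ids=logmat.sample_ids,
        max_exhaustive=max_exhaustive,
        n_permutations=n_permutations,
        seed=seed,
    )
    values = logmat.values.to_numpy(dtype=float)
    t_obs, lfc_obs = _t_and_lfc(values, logmat.group_mask(), th.variance_floor)
    null = build_null(logmat, splits, variance_floor=th.variance_floor)

    if null_scope == "pooled":
        p_t = empirical_p(t_obs, null.null_t)
        p_lfc = empirical_p(lfc_obs, null.null_lfc)
        null_n = null.size
    else:
        k = null.t.shape[1]
        p_t = ((np.abs(null.t) >= np.abs(t_obs)[:, None]).sum(axis=1) + 1.0) / (k + 1.0)
        p_lfc = ((np.abs(null.lfc) >= np.abs(lfc_obs)[:, None]).sum(axis=1) + 1.0) / (
            k + 1.0
        )
        null_n = k

    eps = 1.0 / (null_n + 1.0)
    p_combined, z_t, z_lfc = stouffer_combine(p_t, p_lfc, eps=eps)

    table = pd.DataFrame(
        {
            "gene_id": logmat.gene_ids,
            "t_stat": t_obs,
            "log2fc": lfc_obs,
            "p_t": np.atleast_1d(p_t),
            "p_lfc": np.atleast_1d(p_lfc),
            "z_t": z_t,
            "z_lfc": z_lfc,
            "p_combined": p_combined,
        }
    )
    if bh:
        from statsmodels.stats.multitest import multipletests

        table["p_combined_bh"] = multipletests(
            table["p_combined"].to_numpy(), method="fdr_bh"
        )[1]
    table = call_degs(table, th)

    null_summary = {
        "scope": null_scope,
        "n_assignments": splits.n_assignments,
        "n_retained_splits": splits.n_retained,
        "exhaustive": splits.exhaustive,
        "null_size": int(null_n),
        "min_attainable_p": eps,
        "bh": bool(bh),
    }
    return GeneStatTable(
        table=table,
        thresholds=th,
        null_summary=null_summary,
        group_order=logmat.group_order,
    )
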