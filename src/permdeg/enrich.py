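"""Hypergeometric gene-set over-representation and category summaries.

A query gene list (typically the up- or downregulated DEGs) is tested
against each named gene set with the upper-tail hypergeometric test
P(X >= overlap), where the population is an explicit gene universe —
by default every gene present in the tested expression matrix, not the
genome.  No multiple-testing correction is applied by default (sets with
raw p < 0.05 are flagged enriched); Benjamini–Hochberg is available as an
option.  Category-proportion summaries split a DEG list across tagged
categories, a gene in k categories contributing 1/k to each so the
proportions (including "other" for unassigned genes) sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ParseError, ValidationError

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_enrich",
    "category_proportions",
    "enrichment_barplot",
]

OTHER_CATEGORY = "other"


@dataclass
class GeneSetCollection:
    """Named gene sets with optional category tags and a gene universe.

    ``restrict_to`` performs the explicit intersection step that makes set
    members a subset of the universe; enrichment requires it (or a
    collection constructed with the universe already set).
    """

    sets: dict[str, frozenset[str]]
    levels: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self):
        if any(name == "" for name in self.sets):
            raise ValidationError("empty gene-set name")
        self.sets = {str(k): frozenset(map(str, v)) for k, v in self.sets.items()}
        if self.universe is not None:
            self.universe = frozenset(map(str, self.universe))

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def restrict_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe`` (drops sets left empty)."""
        uni = frozenset(map(str, universe))
        sets = {}
        levels = {}
        for name, members in self.sets.items():
            inter = members & uni
            if inter:
                sets[name] = inter
                if name in self.levels:
                    levels[name] = self.levels[name]
        return GeneSetCollection(sets=sets, levels=levels, universe=uni)

    def at_level(self, level: str) -> "GeneSetCollection":
        """Subset to the sets carrying the requested category tag."""
        keep = {n for n, l in self.levels.items() if l == level}
        return GeneSetCollection(
            sets={n: s for n, s in self.sets.items() if n in keep},
            levels={n: self.levels[n] for n in keep},
            universe=self.universe,
        )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: set name <tab> description <tab> member genes...

    The description field doubles as the category tag when non-empty and
    not a URL (the common convention for flat GMT exports).
    """
    sets: dict[str, frozenset[str]] = {}
    levels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    "GMT line needs name, description and >= 1 gene",
                    path=path,
                    line=i,
                )
            name, desc = parts[0].strip(), parts[1].strip()
            if not name:
                raise ParseError("empty gene-set name", path=path, line=i)
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            sets[name] = genes
            if desc and not desc.lower().startswith(("http:", "https:")):
                levels[name] = desc
    return GeneSetCollection(sets=sets, levels=levels)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.levels.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def hypergeom_enrich(
    query: Sequence[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    query_direction: str = "all",
    bh: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in every set.

    Returns a DataFrame sorted ascending by p-value with columns set_name,
    overlap, set_size, query_size, universe_size, p_value, neg_log10_p,
    enriched (raw p < alpha; on p_bh instead when ``bh``), query_direction.
    """
    if collection.universe is None:
        raise ValidationError(
            "collection has no universe; call restrict_to(...) first"
        )
    uni = collection.universe
    query_set = frozenset(map(str, query))
    offenders = sorted(query_set - uni)
    if offenders:
        raise ValidationError(
            f"{len(offenders)} query gene(s) absent from the universe: "
            f"{offenders[:10]}"
        )
    M = len(uni)
    N = len(query_set)
    rows = []
    for name, members in collection.sets.items():
        n = len(members)
        k = len(members & query_set)
        # P(X >= k) for X ~ Hypergeom(M, n, N)
        p = float(hypergeom.sf(k - 1, M, n, N))
        p = min(p, 1.0)
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": n,
                "query_size": N,
                "universe_size": M,
                "p_value": p,
                "neg_log10_p": -np.log10(p) if p > 0 else np.inf,
                "query_direction": query_direction,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_name", "overlap", "set_size", "query_size",
            "universe_size", "p_value", "neg_log10_p", "query_direction",
        ],
    )
    if bh and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        out["enriched"] = out["p_bh"] < alpha
    else:
        out["enriched"] = out["p_value"] < alpha
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def category_proportions(
    genes: Sequence[str],
    collection: GeneSetCollection,
    level: str | None = None,
) -> pd.Series:
    """Fraction of genes per category, split weights for multi-membership.

    A gene matched by k categories contributes 1/k to each; genes matching
    none fall under "other".  Proportions sum to 1.  ``genes`` is usually a
    DEG list; an empty input returns an empty Series.
    """
    coll = collection.at_level(level) if level is not None else collection
    gene_list = [str(g) for g in genes]
    if not gene_list:
        import warnings

        warnings.warn("category_proportions: empty gene list", stacklevel=2)
        return pd.Series(dtype=float)
    weights: dict[str, float] = {}
    for g in gene_list:
        hits = [name for name, members in coll.sets.items() if g in members]
        if not hits:
            weights[OTHER_CATEGORY] = weights.get(OTHER_CATEGORY, 0.0) + 1.0
        else:
            w = 1.0 / len(hits)
            for name in hits:
                weights[name] = weights.get(name, 0.0) + w
    ser = pd.Series(weights, dtype=float) / len(gene_list)
    return ser.sort_values(ascending=False)


def enrichment_barplot(results: pd.DataFrame, path, top: int = 15) -> None:
    """Horizontal −log10(p) bar chart of the top enriched sets (SVG/PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.35 * len(df))))
    ax.barh(df["set_name"], df["neg_log10_p"], color="#4477aa")
    ax.axvline(-np.log10(0.05), color="crimson", linestyle="--", linewidth=1)
    ax.set_xlabel(r"$-\log_{10}(P)$")
    ax.set_title("Gene-set over-representation")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
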