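"""Negative-binomial count simulator for two-condition, tiny-replicate designs.

The generator emulates the statistical structure the differential-expression
test assumes: a gene x sample integer count matrix with two conditions and a
small number of replicates per condition (two by default, mirroring a
knockout-versus-wildtype comparison sequenced in duplicate), heavy-tailed
log-normal gene means, negative-binomial sampling noise with a gene-level
dispersion (variance = m + phi * m^2), unequal library sizes, and a spiked
fraction of genes carrying true log2 fold changes whose sign is randomized
gene by gene.  Every run is fully determined by the integer seed, and the
per-gene ground truth (spiked or not, true log2FC) is returned alongside the
counts so sensitivity and false-discovery rates can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import CountMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_counts",
    "write_truth_table",
    "read_truth_table",
]

#: condition labels used for simulated samples, in fold-change order:
#: log2FC is mean("ko") - mean("wt").
GROUP_NAMES = ("wt", "ko")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic count model.

    Defaults describe a realistic small bulk RNA-seq experiment: log-normal
    gene means with median exp(4.0) ~ 55 counts and a heavy tail
    (sdlog 1.5), dispersion 0.1, two replicates per condition with modestly
    unequal sequencing depths, and 10% of genes spiked at |log2FC| = 2.
    """

    n_genes: int
    n_per_group: int = 2
    base_mean_log_mu: float = 4.0
    base_mean_log_sigma: float = 1.5
    dispersion: float = 0.1
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    lib_size_factors: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if not self.dispersion > 0:
            raise ConfigurationError("dispersion must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError("de_fraction must lie in [0, 1]")
        if self.base_mean_log_sigma < 0:
            raise ConfigurationError("base_mean_log_sigma must be >= 0")
        if self.lib_size_factors is not None:
            facs = tuple(float(x) for x in self.lib_size_factors)
            if len(facs) != self.n_samples:
                raise ConfigurationError(
                    f"lib_size_factors needs {self.n_samples} entries, got {len(facs)}"
                )
            if any(f <= 0 for f in facs):
                raise ConfigurationError("lib_size_factors must be positive")
            object.__setattr__(self, "lib_size_factors", facs)

    @property
    def n_samples(self) -> int:
        return 2 * self.n_per_group

    @property
    def n_de(self) -> int:
        # round half up so de_fraction * n_genes maps to the exact count
        return int(np.floor(self.de_fraction * self.n_genes + 0.5))

    def resolved_lib_factors(self) -> np.ndarray:
        """Library-size factors; the default is a deterministic unequal
        ladder (geometric from 0.8 to 1.25, geometric mean 1)."""
        if self.lib_size_factors is not None:
            return np.asarray(self.lib_size_factors, dtype=float)
        return np.geomspace(0.8, 1.25, self.n_samples)


@dataclass
class SyntheticDataset:
    """A simulated count matrix plus its per-gene ground truth."""

    counts: CountMatrix
    truth: pd.DataFrame  # columns: gene_id, is_de, true_log2fc
    config: SimulationConfig

    @property
    def n_de(self) -> int:
        return int(self.truth["is_de"].sum())


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(max(n - 1, 0))))
    return [f"g{i:0{width}d}" for i in range(n)]


def _sample_ids(n_per_group: int) -> list[str]:
    return [f"{g}_{i + 1}" for g in GROUP_NAMES for i in range(n_per_group)]


def simulate_counts(config: SimulationConfig) -> SyntheticDataset:
    """Draw a synthetic dataset from the negative-binomial model.

    Spiked genes have their second-condition mean multiplied by
    ``2**(+/- de_log2fc)`` before library scaling, with signs balanced
    (half up, half down) and assigned at random.  Counts are NB with
    variance ``m + dispersion * m**2``.  Identical configs (including the
    seed) produce byte-identical matrices.
    """
    rng = np.random.default_rng(config.seed)
    G, S = config.n_genes, config.n_samples
    gene_ids = _gene_ids(G)
    sample_ids = _sample_ids(config.n_per_group)
    groups = pd.Series(
        [g for g in GROUP_NAMES for _ in range(config.n_per_group)],
        index=sample_ids,
    )

    base_mean = rng.lognormal(
        mean=config.base_mean_log_mu, sigma=config.base_mean_log_sigma, size=G
    )

    true_lfc = np.zeros(G)
    is_de = np.zeros(G, dtype=bool)
    n_de = config.n_de
    if n_de:
        idx = rng.choice(G, size=n_de, replace=False)
        signs = np.ones(n_de)
        signs[n_de // 2 :] = -1.0
        rng.shuffle(signs)
        true_lfc[idx] = signs * config.de_log2fc
        is_de[idx] = True

    lib = config.resolved_lib_factors()
    in_group2 = (groups == GROUP_NAMES[1]).to_numpy()
    # mean[g, j] = base[g] * 2^true_lfc[g] (second group only) * lib[j]
    mu = base_mean[:, None] * np.where(in_group2[None, :], 2.0 ** true_lfc[:, None], 1.0)
    mu = mu * lib[None, :]

    if G:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(n=r, p=r / (r + mu))
    else:
        counts = np.zeros((0, S), dtype=int)

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), groups
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "is_de": is_de, "true_log2fc": true_lfc}
    )
    return SyntheticDataset(counts=cm, truth=truth, config=config)


def write_truth_table(dataset: SyntheticDataset, path) -> None:
    """Write the ground-truth table as TSV (gene_id, is_de, true_log2fc)."""
    out = dataset.truth.copy()
    out["is_de"] = out["is_de"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_de"] = df["is_de"].map(
        lambda x: str(x).strip().lower() in {"true", "1"}
    )
    df["true_log2fc"] = df["true_log2fc"].astype(float)
    return df
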