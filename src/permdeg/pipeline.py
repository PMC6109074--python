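"""End-to-end orchestration: simulate/load → normalize → test → enrich → network.

A run is a pure function of (inputs, configuration, seed): every stage
writes plain-text artifacts into the output directory and a final
``manifest.json`` records SHA-256 hashes of all inputs and outputs, the
fully-resolved configuration and the library versions, so a rerun with the
same inputs reproduces byte-identical results.  While a run is in flight a
``RUN_INCOMPLETE`` marker flags partial outputs as stale; it is removed on
success.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .enrich import category_proportions, enrichment_barplot, hypergeom_enrich, read_gmt
from .errors import ConfigurationError, PermdegError, PipelineError
from .matrix import read_counts_tsv, write_design_tsv
from .network import group_nodes, induce_subnetwork, merge_edge_lists, write_graphml, write_node_attributes, write_sif
from .normalize import normalize_counts, tmm_factors
from .phenotype import FAT_DENSITY_G_PER_CM3, add_lean_body_mass
from .simulate import SimulationConfig, simulate_counts, write_truth_table
from .stats import DEGThresholds, integrative_test

__all__ = ["RunConfig", "run_pipeline", "parse_config_file"]

logger = logging.getLogger("permdeg")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    In simulate mode (``simulate`` set) the count matrix and design are
    generated; otherwise ``counts`` and ``design`` must point to existing
    files.  ``gmt`` enables enrichment, ``edges`` enables network assembly,
    ``phenotypes`` enables the lean-body-mass table.
    """

    outdir: Path
    counts: Path | None = None
    design: Path | None = None
    gmt: Path | None = None
    edges: tuple[Path, ...] = ()
    phenotypes: Path | None = None
    simulate: SimulationConfig | None = None
    thresholds: DEGThresholds = field(default_factory=DEGThresholds)
    seed: int = 0
    bh: bool = False
    null_scope: str = "pooled"
    max_exhaustive: int = 10_000
    n_permutations: int = 1_000
    fat_density: float = FAT_DENSITY_G_PER_CM3
    make_plots: bool = False

    def validate(self) -> None:
        """Fail fast, before any compute."""
        if self.simulate is None:
            if self.counts is None or self.design is None:
                raise ConfigurationError(
                    "non-simulate mode needs --counts and --design"
                )
            for p in (self.counts, self.design):
                if not Path(p).is_file():
                    raise ConfigurationError(f"input not found: {p}")
        for p in (self.gmt, self.phenotypes, *self.edges):
            if p is not None and not Path(p).is_file():
                raise ConfigurationError(f"input not found: {p}")
        if self.null_scope not in {"pooled", "per_gene"}:
            raise ConfigurationError(f"unknown null_scope {self.null_scope!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (tuple, list)):
        return [_jsonable(x) for x in obj]
    return obj


def parse_config_file(path) -> dict:
    """Parse the plain-text run configuration: ``dotted.key = value`` lines.

    '#' starts a comment; values keep their string form (the CLI applies
    type conversion).  Nesting comes from dots: ``simulate.n_genes = 2000``.
    """
    flat: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            if "=" not in stripped:
                raise ConfigurationError(
                    f"{path}:{i}: expected 'key = value', got {stripped!r}"
                )
            key, value = (s.strip() for s in stripped.split("=", 1))
            flat[key] = value
    return flat


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except PermdegError as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns the manifest dictionary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stale = outdir / "RUN_INCOMPLETE"
    stale.write_text("run in progress; outputs may be partial\n")

    outputs: dict[str, Path] = {}
    inputs: dict[str, Path] = {}

    # -- stage: counts -----------------------------------------------------
    @_stage("counts")
    def _counts():
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            ds = simulate_counts(sim)
            cpath, dpath, tpath = (
                outdir / "counts.tsv",
                outdir / "design.tsv",
                outdir / "truth.tsv",
            )
            ds.counts.to_tsv(cpath)
            write_design_tsv(ds.counts, dpath)
            write_truth_table(ds, tpath)
            outputs.update(counts=cpath, design=dpath, truth=tpath)
            logger.info(
                "simulated %d genes x %d samples (%d spiked)",
                ds.counts.n_genes, ds.counts.n_samples, ds.n_de,
            )
            return ds.counts
        inputs["counts"] = Path(config.counts)
        inputs["design"] = Path(config.design)
        return read_counts_tsv(config.counts, config.design)

    cm = _counts()

    # -- stage: normalize --------------------------------------------------
    @_stage("normalize")
    def _normalize():
        facs = tmm_factors(cm)
        logmat = normalize_counts(cm)
        fpath = outdir / "tmm_factors.tsv"
        pd.DataFrame(
            {
                "sample_id": facs.factors.index,
                "library_size": facs.library_sizes.to_numpy(),
                "tmm_factor": facs.factors.to_numpy(),
                "effective_size_factor": facs.effective().to_numpy(),
            }
        ).to_csv(fpath, sep="\t", index=False, float_format="%.6g")
        epath = outdir / "log_expression.tsv"
        logmat.to_tsv(epath)
        outputs.update(tmm_factors=fpath, log_expression=epath)
        logger.info("TMM reference sample: %s", facs.reference_sample)
        return logmat

    logmat = _normalize()

    # -- stage: test -------------------------------------------------------
    @_stage("test")
    def _test():
        res = integrative_test(
            logmat,
            config.thresholds,
            null_scope=config.null_scope,
            max_exhaustive=config.max_exhaustive,
            n_permutations=config.n_permutations,
            seed=config.seed,
            bh=config.bh,
        )
        tpath = outdir / "gene_stats.tsv"
        res.to_tsv(tpath)
        spath = outdir / "run_summary.json"
        spath.write_text(json.dumps(res.summary(), indent=2) + "\n")
        outputs.update(gene_stats=tpath, run_summary=spath)
        logger.info(
            "%d DEGs (%d up, %d down) of %d genes",
            res.n_deg, res.n_up, res.n_down, len(res.table),
        )
        return res

    res = _test()

    # -- stage: enrich -----------------------------------------------------
    if config.gmt is not None:
        @_stage("enrich")
        def _enrich():
            inputs["gmt"] = Path(config.gmt)
            coll = read_gmt(config.gmt).restrict_to(res.table["gene_id"])
            for direction in ("all", "up", "down"):
                if direction == "all":
                    query = res.deg_genes
                else:
                    query = res.table.loc[
                        res.table["direction"] == direction, "gene_id"
                    ].tolist()
                query = [g for g in query if g in (coll.universe or set())]
                enr = hypergeom_enrich(
                    query, coll, query_direction=direction, bh=config.bh
                )
                path = outdir / f"enrichment_{direction}.tsv"
                enr.to_csv(path, sep="\t", index=False, float_format="%.6g")
                outputs[f"enrichment_{direction}"] = path
                if config.make_plots and direction == "all" and len(enr):
                    ppath = outdir / "enrichment_all.svg"
                    enrichment_barplot(enr, ppath)
                    outputs["enrichment_plot"] = ppath
            if res.deg_genes:
                props = category_proportions(res.deg_genes, coll)
                ppath = outdir / "category_proportions.tsv"
                props.rename("proportion").rename_axis("category").to_csv(
                    ppath, sep="\t", float_format="%.6g"
                )
                outputs["category_proportions"] = ppath

        _enrich()

    # -- stage: network ----------------------------------------------------
    if config.edges:
        @_stage("network")
        def _network():
            for p in config.edges:
                inputs[f"edges:{Path(p).name}"] = Path(p)
            edges = merge_edge_lists(list(config.edges))
            G = induce_subnetwork(edges, res.deg_genes, res)
            if config.gmt is not None:
                coll = read_gmt(config.gmt)
                group_nodes(G, coll)
            sif, attrs, gml = (
                outdir / "network.sif",
                outdir / "node_attributes.tsv",
                outdir / "network.graphml",
            )
            write_sif(G, sif)
            write_node_attributes(G, attrs)
            write_graphml(G, gml)
            outputs.update(network_sif=sif, node_attributes=attrs, network_graphml=gml)
            logger.info(
                "network: %d nodes, %d edges", G.number_of_nodes(), G.number_of_edges()
            )

        _network()

    # -- stage: phenotype --------------------------------------------------
    if config.phenotypes is not None:
        @_stage("lbm")
        def _lbm():
            inputs["phenotypes"] = Path(config.phenotypes)
            df = pd.read_csv(config.phenotypes)
            out = add_lean_body_mass(df, fat_density=config.fat_density)
            path = outdir / "lean_body_mass.csv"
            out.to_csv(path, index=False)
            outputs["lean_body_mass"] = path

        _lbm()

    # -- manifest ----------------------------------------------------------
    import numpy, scipy  # versions recorded for provenance

    manifest = {
        "permdeg_version": __version__,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config": _jsonable(config),
        "inputs": {k: _sha256(v) for k, v in inputs.items()},
        "outputs": {k: _sha256(v) for k, v in sorted(outputs.items())},
        "summary": res.summary(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    stale.unlink(missing_ok=True)
    return manifest
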