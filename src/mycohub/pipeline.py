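"""End-to-end orchestration: one config, one seeded, manifest-hashed run.

Stages run in dependency order: (optional) simulation -> validation ->
diversity -> PHP screening -> nestedness -> per-category networks ->
differential abundance -> facilitator ranking -> report. Each stage writes
its outputs under the run directory and every file is hashed into
``manifest.json``, so two runs with the same config and seed can be compared
byte for byte. The global seed fans out to per-stage seeds by stable hashing
of the stage name, so adding a stage never shifts another stage's draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffabund as da
from . import diversity as dv
from . import io as mio
from . import nestedness as nest
from . import network as net
from . import php as phpmod
from . import synthetic as syn

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All stage parameters with the analysis defaults, plus input sources."""

    seed: int = 0
    outdir: str = "run"
    compound: str = "HupA"
    # either simulate (dict of SimulationConfig overrides per species role)
    # or inputs (paths); simulate wins when both are present
    simulate: dict | None = None
    inputs: dict | None = None
    rarefy_depth: int | str = "min"
    identity_min: float = 97.0
    tau_min: float = 0.4
    min_reads: int = 25
    n_perm_permanova: int = 999
    n_perm_network: int = 1000
    q_max: float = 0.05
    n_sims_nestedness: int = 1000
    n_random_graphs: int = 50
    padj_max: float = 0.01
    lfc_min: float = 2.0
    zi_thresh: float = 2.5
    pi_thresh: float = 0.62
    flag_min: int = 4
    categories: list = field(default_factory=list)

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def default_synthetic_config(seed: int = 0) -> PipelineConfig:
    """Two-species synthetic study: a producer and a non-producer plant."""
    return PipelineConfig(
        seed=seed,
        simulate={
            "producer": {"species": "H_asiatica"},
            "nonproducer": {
                "species": "D_complanatum",
                "tissue_names": ("leaf", "stem"),
                "n_tissues": 2,
                "gradient": (1.0, 0.5),
                "n_producers": 0,
                "tau_link_strength": 0.0,
                "n_asvs": 200,
                "asv_prefix": "DASV",
            },
        },
    )


def _default_categories(producer_species: str, nonproducer_species: str | None):
    cats = [
        net.CategoryDef(
            "A", (producer_species,), ("apical_shoot", "bulbil", "young_leaf"), True
        ),
        net.CategoryDef(
            "B", (producer_species,), ("young_leaf", "mature_leaf", "stem"), True
        ),
    ]
    if nonproducer_species:
        cats.append(net.CategoryDef("C", (nonproducer_species,), ("leaf", "stem"), False))
    return cats


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineRun:
    outdir: Path
    manifest: dict
    results: dict


def _load_inputs(cfg: PipelineConfig, datadir: Path):
    """Simulate or read the dataset; returns the component objects."""
    if cfg.simulate is not None:
        spec = dict(cfg.simulate)
        prod_overrides = dict(spec.get("producer", {}))
        prod_overrides.setdefault("seed", stage_seed(cfg.seed, "simulate_producer"))
        ds = syn.simulate_dataset(**prod_overrides)
        components = {
            "counts": ds.counts, "metadata": ds.metadata, "taxonomy": ds.taxonomy,
            "sequences": ds.sequences, "references": ds.references,
            "metabolites": ds.metabolites, "truth": ds.truth,
        }
        nonprod = spec.get("nonproducer")
        if nonprod:
            overrides = dict(nonprod)
            overrides.setdefault("seed", stage_seed(cfg.seed, "simulate_nonproducer"))
            overrides.setdefault("asv_prefix", "DASV")
            ds2 = syn.simulate_dataset(**overrides)
            merged, overlap = mio.merge_species_tables(ds.counts, ds2.counts)
            components["counts"] = merged
            components["metadata"] = mio.SampleMetadata(
                pd.concat([ds.metadata.table, ds2.metadata.table])
            )
            components["taxonomy"] = mio.TaxonomyTable(
                pd.concat([ds.taxonomy.table, ds2.taxonomy.table])
            )
            components["sequences"] = mio.SequenceSet(
                {**ds.sequences.records, **ds2.sequences.records}
            )
            components["overlap"] = overlap
            components["species"] = (ds.config.species, ds2.config.species)
            syn.write_dataset(ds2, datadir / "nonproducer")
        else:
            components["species"] = (ds.config.species, None)
        syn.write_dataset(ds, datadir)
        return components
    if cfg.inputs is None:
        raise ValueError("config needs either 'simulate' or 'inputs'")
    paths = cfg.inputs
    counts = mio.read_asv_table(paths["counts"])
    meta = mio.read_metadata(paths["metadata"])
    components = {
        "counts": counts,
        "metadata": meta,
        "taxonomy": mio.read_taxonomy(paths["taxonomy"]) if "taxonomy" in paths else None,
        "sequences": mio.read_fasta(paths["sequences"]) if "sequences" in paths else None,
        "references": mio.read_reference_strains(paths["ref_fasta"], paths["ref_info"])
        if "ref_fasta" in paths else None,
        "metabolites": mio.read_metabolites(paths["metabolites"])
        if "metabolites" in paths else None,
        "truth": None,
    }
    species = list(pd.unique(meta.species_of()))
    components["species"] = (species[0], species[1] if len(species) > 1 else None)
    return components


def run_pipeline(cfg: PipelineConfig, outdir=None) -> PipelineRun:
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    comp = _load_inputs(cfg, outdir / "data")
    counts: mio.AsvCountTable = comp["counts"]
    meta: mio.SampleMetadata = comp["metadata"]
    producer_species, nonproducer_species = comp["species"]

    # --- validation -------------------------------------------------------
    report = mio.validate_dataset(counts, meta, comp.get("taxonomy"), comp.get("sequences"))
    if not report.passed:
        raise ValueError("dataset validation failed: " + "; ".join(report.messages()))
    results["validation"] = report.messages()

    prod_samples = meta.table.index[meta.species_of() == producer_species]
    prod_counts = mio.AsvCountTable(
        counts.counts.loc[prod_samples].loc[:, counts.counts.loc[prod_samples].sum() > 0].copy()
    )
    prod_meta = meta.subset(prod_samples)

    # --- diversity --------------------------------------------------------
    divdir = outdir / "diversity"
    divdir.mkdir(exist_ok=True)
    depth = cfg.rarefy_depth
    if depth == "min":
        depth = int(counts.counts.sum(axis=1).min())
    rarefied = dv.rarefy_counts(counts, int(depth), seed=stage_seed(cfg.seed, "rarefy"))
    alpha = dv.alpha_diversity(rarefied)
    alpha.to_csv(divdir / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
    dm = dv.bray_curtis_matrix(counts)
    dm.to_frame().to_csv(divdir / "bray_curtis.tsv", sep="\t", index_label="sample_id")
    ord_res = dv.nmds(dm, seed=stage_seed(cfg.seed, "nmds"))
    ord_res.to_frame().to_csv(divdir / "nmds.tsv", sep="\t", index_label="sample_id")
    prod_dm = dv.bray_curtis_matrix(prod_counts)
    perma = dv.permanova(
        prod_dm,
        prod_meta.tissue_of().loc[prod_dm.ids],
        n_perm=cfg.n_perm_permanova,
        seed=stage_seed(cfg.seed, "permanova"),
    )
    alpha_prod = alpha.loc[[s for s in alpha.index if s in set(prod_samples)]]
    kw = dv.group_difference_tests(
        alpha_prod["shannon"], prod_meta.tissue_of().loc[alpha_prod.index]
    )
    results["diversity"] = {
        "rarefy_depth": int(depth),
        "nmds_stress": ord_res.stress,
        "permanova_F": perma.pseudo_F,
        "permanova_p": perma.p,
        "kruskal_H": kw.statistic,
        "kruskal_p": kw.p,
    }

    # --- PHP --------------------------------------------------------------
    phpdir = outdir / "php"
    phpdir.mkdir(exist_ok=True)
    calls = None
    if comp.get("sequences") is not None and comp.get("references") is not None:
        hits = phpmod.screen_by_identity(
            comp["sequences"], comp["references"], identity_min=cfg.identity_min
        )
        if comp.get("metabolites") is not None:
            means = phpmod.tissue_mean_abundance(prod_counts, prod_meta)
            corr = phpmod.screen_by_correlation(
                means, comp["metabolites"], cfg.compound, tau_min=cfg.tau_min
            )
        else:
            logger.warning("metabolite table absent: correlation screen skipped")
            corr = {}
        calls = phpmod.merge_php_calls(
            hits, corr, identity_min=cfg.identity_min, tau_min=cfg.tau_min
        )
        calls.to_frame().to_csv(phpdir / "php_calls.tsv", sep="\t", index=False)
        summary = phpmod.php_tissue_summary(calls, prod_counts, prod_meta)
        summary.to_csv(phpdir / "php_tissue_summary.tsv", sep="\t")
        results["php"] = calls.counts()
    else:
        logger.warning("sequences or references absent: PHP stage skipped")

    # --- nestedness -------------------------------------------------------
    nestdir = outdir / "nestedness"
    nestdir.mkdir(exist_ok=True)
    nres = nest.nestedness_analysis(
        prod_counts,
        prod_meta,
        n_sims=cfg.n_sims_nestedness,
        seed=stage_seed(cfg.seed, "nestedness"),
    )
    pm = nest.build_presence_matrix(prod_counts, prod_meta)
    pm.to_frame().to_csv(nestdir / "presence_matrix.tsv", sep="\t", index_label="tissue")
    pd.Series(nres.null_temperatures, name="temperature").to_csv(
        nestdir / "null_temperatures.tsv", sep="\t", index=False
    )
    results["nestedness"] = {
        "nodf": nres.nodf, "temperature": nres.temperature,
        "fill": nres.fill, "p_value": nres.p_value,
    }
    (nestdir / "summary.json").write_text(
        json.dumps(results["nestedness"], indent=1, sort_keys=True)
    )

    # --- networks ---------------------------------------------------------
    netdir = outdir / "network"
    netdir.mkdir(exist_ok=True)
    categories = cfg.categories or _default_categories(producer_species, nonproducer_species)
    categories = [
        c if isinstance(c, net.CategoryDef) else net.CategoryDef(**c) for c in categories
    ]
    networks: dict[str, tuple[net.CoocNetwork, net.ModulePartition]] = {}
    producer_networks = set()
    results["networks"] = {}
    php_ids = calls.asv_ids if calls is not None else set()
    for cat in categories:
        try:
            sub = net.filter_category_asvs(counts, meta, cat, min_reads=cfg.min_reads)
        except ValueError as exc:
            logger.warning("category %s skipped: %s", cat.name, exc)
            continue
        if sub.counts.shape[0] < 8:
            logger.warning("category %s skipped: fewer than 8 samples", cat.name)
            continue
        g = net.infer_network(
            sub,
            n_perm=cfg.n_perm_network,
            q_max=cfg.q_max,
            seed=stage_seed(cfg.seed, f"network_{cat.name}"),
            category=cat.name,
        )
        net.annotate_nodes(g, comp.get("taxonomy"), php_ids)
        part = net.fast_greedy_modules(g)
        roles = net.classify_roles(
            net.zi_pi(g, part), zi_thresh=cfg.zi_thresh, pi_thresh=cfg.pi_thresh
        )
        summary = net.random_graph_baseline(
            g, R=cfg.n_random_graphs, seed=stage_seed(cfg.seed, f"baseline_{cat.name}")
        )
        fit = net.degree_powerlaw_fit(g)
        net.export_graph(g, netdir / f"network_{cat.name}.graphml",
                         partition=part, roles=roles, fmt="graphml")
        net.roles_frame(roles).assign(
            module=lambda df: [part.assignment[n] for n in df.index]
        ).to_csv(netdir / f"roles_{cat.name}.tsv", sep="\t", index_label="node")
        networks[cat.name] = (g, part)
        if cat.producer_plant:
            producer_networks.add(cat.name)
        role_counts = pd.Series([r.role for r in roles]).value_counts().to_dict()
        results["networks"][cat.name] = {
            "n_nodes": summary.n_nodes, "n_edges": summary.n_edges,
            "modularity_Q": summary.modularity_Q,
            "avg_clustering": summary.avg_clustering,
            "null_Q_mean": summary.null_Q_mean, "null_Q_sd": summary.null_Q_sd,
            "powerlaw_R2": fit["R2"], "powerlaw_gamma": fit["gamma"],
            "roles": role_counts,
        }

    # --- differential abundance ------------------------------------------
    if nonproducer_species is not None:
        dadir = outdir / "diffabund"
        dadir.mkdir(exist_ok=True)
        tissue_map = {"young_leaf": "leaf", "mature_leaf": "leaf", "leaf": "leaf"}
        leafy = meta.table["tissue"].map(tissue_map).eq("leaf")
        leaf_samples = meta.table.index[leafy]
        leaf_counts_df = counts.counts.loc[[s for s in counts.counts.index if s in set(leaf_samples)]]
        leaf_counts = mio.AsvCountTable(
            leaf_counts_df.loc[:, leaf_counts_df.sum() > 0].copy()
        )
        dres = da.differential_abundance(
            leaf_counts, meta, (producer_species, nonproducer_species),
            padj_max=cfg.padj_max, lfc_min=cfg.lfc_min,
        )
        dres.table.to_csv(dadir / "diffabund_leaf.tsv", sep="\t", index_label="asv_id")
        results["diffabund"] = dres.direction_counts()

    # --- facilitators -----------------------------------------------------
    if networks and comp.get("taxonomy") is not None and php_ids:
        fac = net.facilitator_ranking(
            networks, php_ids, comp["taxonomy"], producer_networks, flag_min=cfg.flag_min
        )
        fac.to_csv(netdir / "facilitators.tsv", sep="\t", index=False)
        results["facilitators"] = {
            "n_genera": int(len(fac)),
            "n_flagged": int(fac["flagged"].sum()) if len(fac) else 0,
            "n_cautioned": int(fac["cautioned"].sum()) if len(fac) else 0,
        }

    # --- manifest and report ---------------------------------------------
    (outdir / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    manifest = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest[str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    render_report(outdir)
    # re-hash with the report included
    manifest = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest[str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineRun(outdir=outdir, manifest=manifest, results=results)


def render_report(outdir) -> Path:
    """Human-readable Markdown summary of a finished run."""
    outdir = Path(outdir)
    results_path = outdir / "results.json"
    if not results_path.exists():
        raise FileNotFoundError("results.json missing; run the pipeline first")
    results = json.loads(results_path.read_text())
    lines = ["# Mycobiome analysis report", ""]

    divr = results.get("diversity")
    if divr:
        lines += [
            "## Diversity",
            "",
            f"- rarefaction depth: {divr['rarefy_depth']}",
            f"- NMDS stress (Kruskal stress-1): {divr['nmds_stress']:.4f}",
            f"- PERMANOVA (tissue): pseudo-F = {divr['permanova_F']:.3f}, "
            f"p = {divr['permanova_p']:.4g}",
            f"- Kruskal-Wallis on Shannon: H = {divr['kruskal_H']:.3f}, "
            f"p = {divr['kruskal_p']:.4g}",
            "",
        ]
    phpr = results.get("php")
    if phpr:
        lines += [
            "## Potential producer (PHP) ASVs",
            "",
            f"- identity evidence: {phpr['n_clustering']}",
            f"- correlation evidence: {phpr['n_correlation']}",
            f"- dual evidence: {phpr['n_both']}",
            f"- union: {phpr['n_union']} "
            f"(= {phpr['n_clustering']} + {phpr['n_correlation']} - {phpr['n_both']})",
            "",
        ]
    else:
        lines += ["## Potential producer (PHP) ASVs", "", "_stage absent_", ""]
    nr = results.get("nestedness")
    if nr:
        lines += [
            "## Nestedness",
            "",
            f"- NODF: {nr['nodf']:.3f}",
            f"- temperature: {nr['temperature']:.3f} (p = {nr['p_value']:.4g} "
            "against the occurrence-preserving null)",
            f"- fill: {nr['fill']:.3f}",
            "",
        ]
    nets = results.get("networks", {})
    if nets:
        lines += ["## Networks", "",
                  "| category | nodes | edges | Q | null Q (mean±sd) | clustering | roles |",
                  "|---|---|---|---|---|---|---|"]
        for cat, s in sorted(nets.items()):
            roles = ", ".join(f"{k}: {v}" for k, v in sorted(s["roles"].items()))
            lines.append(
                f"| {cat} | {s['n_nodes']} | {s['n_edges']} | {s['modularity_Q']:.3f} | "
                f"{s['null_Q_mean']:.3f}±{s['null_Q_sd']:.3f} | "
                f"{s['avg_clustering']:.3f} | {roles} |"
            )
        lines.append("")
    dar = results.get("diffabund")
    if dar:
        lines += ["## Differential abundance (leaf contrast)", ""]
        lines += [f"- {k}: {v}" for k, v in sorted(dar.items())]
        lines.append("")
    fac = results.get("facilitators")
    if fac:
        lines += [
            "## Facilitator genera",
            "",
            f"- genera co-occurring with PHP ASVs: {fac['n_genera']}",
            f"- flagged (>= threshold modules in a producer network): {fac['n_flagged']}",
            f"- cautioned (support only in the non-producer network): {fac['n_cautioned']}",
            "",
        ]
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
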