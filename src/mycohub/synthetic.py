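"""Seeded synthetic mycobiome datasets with planted ground truth.

The generator emulates the post-denoising state of a tissue-resolved amplicon
survey of a metabolite-producing plant: an integer ASV count table over
tissues x replicates, nested per-tissue ASV pools (young tissues carry a
subset of the pools of older ones), a monotone decreasing metabolite gradient
from the youngest tissue, a planted set of "producer" ASVs whose sequences
stay close to reference producer strains and whose tissue-mean abundance
tracks the gradient, and latent-factor co-abundance modules that a
co-occurrence network method should recover.

Count model, per sample s in tissue t and ASV j:

    w_js = base_j * mask_j(t) * link_j(t) * F_{m(j),s} * eps_js
    counts_s ~ Multinomial(depth_s, w_s / sum(w_s)),  depth_s ~ LogNormal

where ``mask`` is the nested tissue-pool indicator, ``link`` ties producer
abundance to the metabolite gradient, ``F`` is a lognormal factor shared by
all members of a planted module, and ``eps`` is mean-one gamma overdispersion
noise. Base abundances follow a power-law rank-abundance curve aligned with
pool membership: widespread taxa are abundant and the taxa added by the
larger pools of older tissues are rare. That choice is what keeps the
closure (multinomial) denominator nearly constant across tissues — without
it, every ubiquitous ASV's relative abundance would fall mechanically with
pool size and mimic the metabolite gradient. Everything is drawn from one
``numpy`` Generator, so a seed fixes the whole dataset byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd

from .io import (
    AsvCountTable,
    MetaboliteTable,
    ReferenceStrainSet,
    SampleMetadata,
    SequenceSet,
    TaxonomyTable,
    TAXONOMY_RANKS,
)

DEFAULT_TISSUES = (
    "apical_shoot",
    "bulbil",
    "young_leaf",
    "mature_leaf",
    "stem",
    "sporangium",
)

# monotone decreasing metabolite means (ug/g fresh weight) from the youngest
# tissue; the end points follow reported apical-shoot / mature-leaf HupA levels
DEFAULT_GRADIENT = (360.27, 300.0, 220.0, 160.0, 110.0, 60.0)

_GENERA = (
    "Penicillium",
    "Trichoderma",
    "Colletotrichum",
    "Fusarium",
    "Cladosporium",
    "Alternaria",
    "Dioszegia",
    "Exobasidium",
    "Lycoperdon",
    "Mucor",
    "Epicoccum",
    "Acremonium",
    "Phaeosphaeria",
    "Leptosphaeria",
    "Aureobasidium",
    "Ramularia",
)


class ConfigError(ValueError):
    """Raised for an infeasible simulation configuration."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset; defaults are the study-like conditions."""

    seed: int = 0
    species: str = "H_asiatica"
    tissue_names: tuple[str, ...] = DEFAULT_TISSUES
    n_tissues: int = 6
    replicates_per_tissue: int = 6
    n_asvs: int = 300
    depth_log_mean: float = log(70_000.0)
    depth_log_sd: float = 0.35
    # per-tissue pool sizes aligned with tissue_names; None -> linear ramp
    # from pool_min up to n_asvs (youngest tissue poorest, nested upward)
    tissue_pool_sizes: tuple[int, ...] | None = None
    pool_min: int = 30
    n_producers: int = 20
    producer_divergence: float = 0.02
    nonproducer_divergence: float = 0.15
    gradient: tuple[float, ...] = DEFAULT_GRADIENT
    compound: str = "HupA"
    tau_link_strength: float = 1.0
    n_modules: int = 8
    module_size: int = 10
    factor_sd: float = 1.0
    dispersion: float = 0.2
    rank_decay: float = 2.0
    producer_base: float = 0.01
    module_base: float = 1e-3
    pool_noise: float = 0.0
    n_reference_strains: int = 48
    ref_length_mean: float = 300.0
    asv_prefix: str = "ASV"

    def __post_init__(self) -> None:
        if self.n_tissues != len(self.tissue_names):
            # allow n_tissues to trim/extend generic names
            if self.n_tissues <= len(self.tissue_names):
                self.tissue_names = tuple(self.tissue_names[: self.n_tissues])
            else:
                extra = tuple(
                    f"tissue_{i}" for i in range(len(self.tissue_names), self.n_tissues)
                )
                self.tissue_names = tuple(self.tissue_names) + extra
        if len(self.gradient) < self.n_tissues:
            raise ConfigError("gradient must cover every tissue")
        self.gradient = tuple(self.gradient[: self.n_tissues])
        if any(b >= a for a, b in zip(self.gradient, self.gradient[1:])):
            raise ConfigError("metabolite gradient must be strictly decreasing")
        if self.replicates_per_tissue < 3:
            raise ConfigError("need at least 3 replicates per tissue")
        if not (0.0 <= self.producer_divergence <= 1.0 and 0.0 <= self.nonproducer_divergence <= 1.0):
            raise ConfigError("divergences must lie in [0, 1]")
        if self.n_modules * self.module_size > self.n_asvs:
            raise ConfigError("module_size * n_modules exceeds n_asvs")
        if self.pool_sizes()[0] < self.n_producers:
            raise ConfigError("smallest tissue pool cannot hold all producers")
        if self.n_producers + self.n_modules * self.module_size > self.n_asvs:
            raise ConfigError("producers plus planted modules exceed n_asvs")

    def pool_sizes(self) -> tuple[int, ...]:
        if self.tissue_pool_sizes is not None:
            sizes = tuple(int(x) for x in self.tissue_pool_sizes)
            if len(sizes) != self.n_tissues:
                raise ConfigError("tissue_pool_sizes must match n_tissues")
            if max(sizes) > self.n_asvs or min(sizes) < 1:
                raise ConfigError("pool sizes must lie in [1, n_asvs]")
            return sizes
        return tuple(
            int(round(x))
            for x in np.linspace(self.pool_min, self.n_asvs, self.n_tissues)
        )


@dataclass
class SyntheticTruth:
    """Planted structure, serialized alongside the data files."""

    producer_asv_ids: set[str]
    module_assignment: dict[str, int]  # only ASVs inside a planted module
    tissue_pools: dict[str, set[str]]
    reference_map: dict[str, str]  # producer ASV -> source strain

    def to_json(self) -> str:
        return json.dumps(
            {
                "producer_asv_ids": sorted(self.producer_asv_ids),
                "module_assignment": self.module_assignment,
                "tissue_pools": {t: sorted(v) for t, v in self.tissue_pools.items()},
                "reference_map": self.reference_map,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        obj = json.loads(text)
        return cls(
            producer_asv_ids=set(obj["producer_asv_ids"]),
            module_assignment={k: int(v) for k, v in obj["module_assignment"].items()},
            tissue_pools={t: set(v) for t, v in obj["tissue_pools"].items()},
            reference_map=dict(obj["reference_map"]),
        )


@dataclass
class SyntheticDataset:
    counts: AsvCountTable
    metadata: SampleMetadata
    taxonomy: TaxonomyTable
    sequences: SequenceSet
    references: ReferenceStrainSet
    metabolites: MetaboliteTable
    truth: SyntheticTruth
    config: SimulationConfig = field(repr=False)


# ---------------------------------------------------------------------------
# sequence primitives

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_sequences(
    n: int, length_mean: float = 300.0, seed: int | np.random.Generator = 0, length_sd: float = 30.0
) -> SequenceSet:
    """i.i.d. uniform ACGT sequences, lengths Normal(mean, sd) truncated at 150."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = {}
    for i in range(n):
        length = max(150, int(round(rng.normal(length_mean, length_sd))))
        seq = rng.choice(_BASES, size=length).tobytes().decode()
        records[f"seq{i + 1:04d}"] = seq
    return SequenceSet(records)


def mutate_sequence(seq: str, rate: float, seed: int | np.random.Generator = 0) -> str:
    """Substitute each position to a different base with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        others = _BASES[_BASES != arr[i]]
        arr[i] = others[rng.integers(len(others))]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# dataset generator


def simulate_dataset(config: SimulationConfig | None = None, **kwargs) -> SyntheticDataset:
    """Draw one complete synthetic dataset; deterministic given config.seed."""
    if config is None:
        config = SimulationConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config object or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    T, R, J = config.n_tissues, config.replicates_per_tissue, config.n_asvs
    n_samples = T * R
    asv_ids = [f"{config.asv_prefix}{i + 1:04d}" for i in range(J)]
    tissues = list(config.tissue_names)
    pool_sizes = config.pool_sizes()

    # --- planted structure ------------------------------------------------
    # producers sit inside the smallest (youngest-tissue) pool, a little below
    # the very top ranks so a few core non-producers remain ubiquitous
    smallest = pool_sizes[0] if config.tissue_pool_sizes is None else min(pool_sizes)
    p_start = max(0, min(5, smallest - config.n_producers))
    producer_idx = np.arange(p_start, p_start + config.n_producers)

    module_of = np.full(J, -1)
    start = smallest  # planted modules sit just above the smallest pool
    if start + config.n_modules * config.module_size > J:
        start = p_start + config.n_producers
    for m in range(config.n_modules):
        lo = start + m * config.module_size
        module_of[lo : lo + config.module_size] = m

    mask = np.zeros((T, J), dtype=bool)
    for t, size in enumerate(pool_sizes):
        mask[t, :size] = True
    if config.pool_noise > 0:
        # de-nesting noise: swap present/absent pairs, preserving row totals
        for t in range(T):
            n_swaps = rng.binomial(J, config.pool_noise)
            present = np.flatnonzero(mask[t])
            absent = np.flatnonzero(~mask[t])
            n_swaps = min(n_swaps, len(present), len(absent))
            if n_swaps:
                out_idx = rng.choice(present, n_swaps, replace=False)
                in_idx = rng.choice(absent, n_swaps, replace=False)
                mask[t, out_idx] = False
                mask[t, in_idx] = True

    grad = np.asarray(config.gradient, dtype=float)
    link = np.ones((T, J))
    s_link = config.tau_link_strength
    link[:, producer_idx] = ((1.0 - s_link) + s_link * (grad / grad.max()))[:, None]

    # rank-abundance: widespread (low-rank) taxa abundant, pool-tail taxa rare
    ranks = np.arange(1, J + 1, dtype=float)
    base = ranks**-config.rank_decay * rng.lognormal(0.0, 0.5, size=J)
    base[producer_idx] = config.producer_base * rng.lognormal(
        0.0, 0.3, size=config.n_producers
    )
    in_mod_idx = module_of >= 0
    base[in_mod_idx] = config.module_base * rng.lognormal(0.0, 0.3, size=in_mod_idx.sum())

    # --- counts -----------------------------------------------------------
    sample_rows = []
    counts = np.zeros((n_samples, J), dtype=np.int64)
    depths = np.maximum(
        1000, rng.lognormal(config.depth_log_mean, config.depth_log_sd, size=n_samples)
    ).astype(np.int64)
    s = 0
    for t, tissue in enumerate(tissues):
        for r in range(R):
            factors = np.ones(J)
            if config.n_modules:
                f = rng.lognormal(0.0, config.factor_sd, size=config.n_modules)
                in_mod = module_of >= 0
                factors[in_mod] = f[module_of[in_mod]]
            if config.dispersion > 0:
                shape = 1.0 / config.dispersion
                eps = rng.gamma(shape, config.dispersion, size=J)
            else:
                eps = np.ones(J)
            w = base * mask[t] * link[t] * factors * eps
            total = w.sum()
            if total <= 0:
                raise ConfigError("degenerate weights: empty tissue pool")
            counts[s] = rng.multinomial(depths[s], w / total)
            sample_rows.append(
                {
                    "sample_id": f"{config.species}_{tissue}_r{r + 1}",
                    "species": config.species,
                    "tissue": tissue,
                    "replicate": r + 1,
                }
            )
            s += 1

    meta_df = pd.DataFrame(sample_rows).set_index("sample_id")
    count_df = pd.DataFrame(counts, index=meta_df.index.copy(), columns=asv_ids)
    # guard the no-empty-sample invariant at tiny depths
    empty = count_df.sum(axis=1) == 0
    if empty.any():
        first_pool = np.flatnonzero(mask[:, 0])[0]
        count_df.loc[empty, asv_ids[first_pool]] = 1

    # --- sequences and references ----------------------------------------
    refs = simulate_sequences(
        config.n_reference_strains, config.ref_length_mean, rng
    )
    ref_ids = [f"strain{i + 1:03d}" for i in range(config.n_reference_strains)]
    ref_seqs = SequenceSet(dict(zip(ref_ids, refs.records.values())))
    ref_genus = [
        _GENERA[rng.integers(len(_GENERA))] for _ in range(config.n_reference_strains)
    ]
    ref_info = pd.DataFrame(
        {"genus": ref_genus, "source_tag": ["synthetic" for _ in ref_ids]},
        index=pd.Index(ref_ids, name="strain_id"),
    )
    references = ReferenceStrainSet(ref_seqs, ref_info)

    seq_records: dict[str, str] = {}
    reference_map: dict[str, str] = {}
    genus_of: dict[str, str] = {}
    for j, asv in enumerate(asv_ids):
        src = ref_ids[rng.integers(len(ref_ids))]
        if j in producer_idx:
            seq_records[asv] = mutate_sequence(
                ref_seqs[src], config.producer_divergence, rng
            )
            reference_map[asv] = src
            genus_of[asv] = str(ref_info.at[src, "genus"])
        else:
            seq_records[asv] = mutate_sequence(
                ref_seqs[src], config.nonproducer_divergence, rng
            )
            # ~10% of non-producers left unclassified at genus level
            if rng.random() < 0.1:
                genus_of[asv] = ""
            else:
                genus_of[asv] = _GENERA[rng.integers(len(_GENERA))]
    sequences = SequenceSet(seq_records)

    tax_df = pd.DataFrame(
        {r: ["" for _ in asv_ids] for r in TAXONOMY_RANKS},
        index=pd.Index(asv_ids, name="asv_id"),
    )
    tax_df["kingdom"] = "Fungi"
    tax_df["genus"] = [genus_of[a] for a in asv_ids]
    taxonomy = TaxonomyTable(tax_df)

    metab = MetaboliteTable(
        pd.DataFrame(
            {
                "tissue": tissues,
                "compound": [config.compound] * T,
                "mean_concentration": grad,
            }
        )
    )

    truth = SyntheticTruth(
        producer_asv_ids={asv_ids[i] for i in producer_idx},
        module_assignment={
            asv_ids[j]: int(module_of[j]) for j in range(J) if module_of[j] >= 0
        },
        tissue_pools={
            tissue: {asv_ids[j] for j in range(J) if mask[t, j]}
            for t, tissue in enumerate(tissues)
        },
        reference_map=reference_map,
    )

    return SyntheticDataset(
        counts=AsvCountTable(count_df),
        metadata=SampleMetadata(meta_df),
        taxonomy=taxonomy,
        sequences=sequences,
        references=references,
        metabolites=metab,
        truth=truth,
        config=config,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every component in the pipeline's input formats plus truth files."""
    from pathlib import Path

    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "asv_counts.tsv",
        "metadata": outdir / "sample_metadata.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "sequences": outdir / "asv_sequences.fasta",
        "ref_fasta": outdir / "reference_strains.fasta",
        "ref_info": outdir / "reference_strains.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "truth": outdir / "truth.json",
    }
    mio.write_asv_table(ds.counts, paths["counts"])
    mio.write_metadata(ds.metadata, paths["metadata"])
    mio.write_taxonomy(ds.taxonomy, paths["taxonomy"])
    mio.write_fasta(ds.sequences, paths["sequences"])
    mio.write_reference_strains(ds.references, paths["ref_fasta"], paths["ref_info"])
    mio.write_metabolites(ds.metabolites, paths["metabolites"])
    paths["truth"].write_text(ds.truth.to_json())
    return {k: str(v) for k, v in paths.items()}
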