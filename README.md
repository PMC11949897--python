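# mycohub

Tissue-resolved mycobiome analysis for paired plant species: one species that
accumulates an alkaloid of interest along a tissue gradient (modeled on
huperzine A, "HupA") and a related non-accumulating species. The package
covers the full analysis arc — data ingestion, alpha/beta diversity,
identification of potential producer ASVs, nestedness of tissue communities,
co-occurrence networks with topological node roles, and differential
abundance — plus a seeded synthetic-data generator with planted ground truth
and a deterministic end-to-end pipeline.

## What it computes

| Module | Contents |
| --- | --- |
| `mycohub.io` | TSV/FASTA/JSON readers and writers, schema validation, two-species table merging |
| `mycohub.synthetic` | Seeded generator: nested tissue pools, planted producer ASVs, planted co-occurrence modules, NB counts, reference strains, metabolite gradient, truth JSON |
| `mycohub.diversity` | Rarefaction, Shannon/observed richness, Bray-Curtis, NMDS (with stress), PERMANOVA, rank-based group tests, Holm/Dunn corrections |
| `mycohub.php` | Potential-HupA-producer (PHP) screen: semi-global ≥97% identity against reference producer strains OR Kendall tau-b > 0.4 against the tissue metabolite gradient; union with per-ASV evidence flags |
| `mycohub.nestedness` | NODF, a tie-invariant matrix-temperature variant, occurrence-preserving null model with one-sided p |
| `mycohub.network` | CLR + Spearman + permutation FDR co-occurrence networks, greedy-modularity modules, Zi–Pi node roles, random-graph baselines, power-law degree fit |
| `mycohub.diffabund` | Negative-binomial Wald differential abundance with median-of-ratios size factors and BH correction |
| `mycohub.pipeline` / `mycohub.cli` | Config-driven orchestration, per-stage seed fan-out, Markdown report, SHA-256 output manifest; `mycohub` console command |

Methodological details and parameter rationale are in
[`docs/methods.md`](docs/methods.md).

## Worked example

Everything below is reproducible; these are actual outputs, not placeholders.

```python
from mycohub.synthetic import simulate_dataset
from mycohub.php import (screen_by_identity, screen_by_correlation,
                         tissue_mean_abundance, merge_php_calls)
from mycohub.nestedness import nestedness_analysis

ds = simulate_dataset(seed=1)          # 36 samples x 300 ASVs, planted truth
hits = screen_by_identity(ds.sequences, ds.references)
corr = screen_by_correlation(
    tissue_mean_abundance(ds.counts, ds.metadata), ds.metabolites, "HupA")
calls = merge_php_calls(hits, corr)
calls.counts()
# {'n_clustering': 17, 'n_correlation': 20, 'n_both': 17, 'n_union': 20}

res = nestedness_analysis(ds.counts, ds.metadata, n_sims=1000, seed=0)
# res.nodf = 82.98, res.temperature = 0.03, res.p_value = 1/1001
```

The same counting logic on a real two-evidence screen: if identity
clustering flags 24 ASVs, the gradient correlation flags 4, and exactly 1
ASV carries both kinds of evidence, the union is 24 + 4 − 1 = 27 PHP ASVs.

From the command line, the full pipeline on a synthetic two-species demo:

```sh
mycohub run --seed 29 --out demo/
cat demo/report.md          # diversity, PHP, nestedness, networks, diffabund
cat demo/manifest.json      # SHA-256 of every output file
```

Running the same command twice with the same seed produces byte-identical
manifests. Individual stages are also available as subcommands:
`simulate`, `diversity`, `php`, `nestedness`, `network`, `diffabund`,
`report`.

## Determinism

Every stochastic step takes an explicit seed. The pipeline derives one
sub-seed per stage from the master seed (`stage_seed`, a CRC-32 mix kept
below 2^31), so adding or reordering stages does not silently change the
randomness of the others.
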