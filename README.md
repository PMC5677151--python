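# demoscope

Concordance analysis for piecewise demographic models: encode published
population-size histories, predict the summaries of genetic variation they
imply — the site frequency spectrum (SFS), windowed heterozygosity, and
linkage-disequilibrium (LD) decay — and rank the models against an observed
SFS with multinomial and Poisson log-likelihoods.  A built-in coalescent
simulator (unlinked genealogies plus an SMC′ sequence simulator) stands in
for genome data, so the whole analysis runs without external downloads.

## What's inside

| module | purpose |
| --- | --- |
| `demoscope.demography` | piecewise histories: epochs, splits, migration, pulses; MSMC-style table parsing, trajectory averaging/stepwise conversion, trimming, ancestral-size and mutation-rate rescaling, ms-style command emission/parsing |
| `demoscope.sfs_engine` | `SFSSpectrum` and transforms (fold, hypergeometric projection, joint-SFS marginalization, count scaling, singleton handling) plus two prediction engines: exact analytic (single-population, via matrix-exponential occupancies of the lineage-count chain) and Monte-Carlo (structured models with migration and admixture pulses) |
| `demoscope.coalsim` | synthetic data: unlinked genealogy simulation and recombining sequence blocks under the SMC′ transition, per-block recombination-rate sampling, VCF 4.2 output |
| `demoscope.popgen_summaries` | windowed π (with BED callability masks), genotype-r² LD decay in 51 × 1-kb bins, empirical SFS; VCF/BED input |
| `demoscope.model_fit` | multinomial/Poisson log-likelihoods, data-to-data reference, ΔLL ranking tables |
| `demoscope.pipeline` / `demoscope.cli` | YAML-configured end-to-end runs, fixture generation, provenance headers |

`demoscope.models` provides built-in families (constant, two-epoch
bottleneck, exponential growth, archaic pulse, a symmetric three-island
toy) and the three-population out-of-Africa model of Gutenkunst et al.
(2009) with migration, in physical units.

## CLI

```sh
demoscope fixture two-epoch --seed 1 --out-dir fix/      # demography YAML + synthetic observed SFS
demoscope predict-sfs fix/model_two_epoch.yaml -n 20 -o sfs.tsv
demoscope simulate fix/model_two_epoch.yaml --n-blocks 200 -o sim.vcf
demoscope summarize sim.vcf --out-dir summaries/
demoscope compare config.yaml                            # full run: predictions + fit table
```

A compare config lists models (built-in family or YAML/MSMC-table path),
the observed SFS, summary toggles, and simulation scale; see
`tests/test_pipeline.py::toy_config` for a minimal example.  All tabular
outputs are TSV with `#`-prefixed provenance headers (version, seed,
config hash).

## Conventions

- Time is in generations before present; years only at I/O boundaries via
  each model's generation time.  Sizes are diploid; `k` lineages coalesce
  at rate `k(k−1)/2 · 1/(2N)` per generation.
- MSMC-style scaling: `t = scaled_time/μ`, `N = 1/(2μλ)`.
- Unfolded spectra index derived-allele counts `1..n−1`; folded spectra
  minor-allele counts `1..⌊n/2⌋`; fixed classes excluded everywhere.
- Multinomial LL is `Σ xᵢ ln pᵢ` (no combinatorial constant); Poisson LL
  keeps the `−ln Γ(x+1)` term.  ΔLL is relative to the data-to-data
  maximum and is convention-invariant.
- Genotype (dosage) r² for LD; singletons are minor-allele-count-1 sites.
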