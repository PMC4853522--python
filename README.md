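# traitsam

Trait-weighted quantitative SAM (Significance Analysis of Microarrays) for
multi-genotype expression profiling, with permutation-based FDR, GO singular
enrichment analysis, chromosome mapping and interaction-subnetwork
extraction.

## The problem

Stress-response transcriptomics usually contrasts a handful of genotypes
with extreme phenotypes, which makes the resulting gene lists
genotype-specific.  An alternative is to treat a *continuous*
morpho-physiological trait (shoot Na⁺, shoot Na⁺/K⁺, root K⁺, biomass,
shoot Cl⁻, …) measured across a panel of diverse genotypes as a
quantitative response, and ask which transcripts track the gradient of that
trait across the whole panel.  `traitsam` implements this analysis for
one-color microarray-style data from a panel design of 8 genotypes × 2
conditions (control / salt-stressed) × 3 replicates, and ships a
synthetic-data generator that reproduces the design with trait-linked
spike-in probes so the entire pipeline is testable without any download.

## The statistic

For probe *i* with (quantile-normalized, log₂) expression *x·ᵢⱼ* and
per-sample response *yⱼ* — the genotype's trait value rescaled to [0, 1] by
min–max weighting (rank weighting available), shared by all replicates of
the genotype — the score is

    dᵢ = rᵢ / (sᵢ + s₀)

where *rᵢ* is the least-squares slope of *xᵢ* on *y*, *sᵢ* the standard
error of that slope, and *s₀* a fudge factor chosen among percentiles of
the *s* distribution to make the score spread independent of *s*
(coefficient-of-variation criterion).  Significance comes from permuting
*y* across sample columns (B = 100 by default; all distinct arrangements
are enumerated exactly when there are at most B of them): for each
threshold Δ, asymmetric cut-offs on the sorted observed scores versus their
expected null order statistics define the called set, permutation
false-call counts (90th-percentile summary by default) and a π₀ estimate
give an FDR, and each probe's q-value is the smallest FDR at which it is
called.  Genes are selected by the combined rule **q ≤ 5 % and |d| ≥ 2**,
split into positively and negatively expressed lists per trait and
condition.  Downstream stages test GO-term over-representation of each list
(exact hypergeometric against a reference background, Benjamini–Hochberg
within namespace), tally genes per rice chromosome directly from RAP locus
ids (`Os09g0286400` → chromosome 9), convert RAP to MSU (TIGR) identifiers
through a mapping table, and induce protein-interaction subnetworks with
per-component hub detection.

## Worked example

```python
import traitsam as ts

cfg = ts.SimulationConfig(n_probes=2000, seed=7,
                          spiked_traits=("shoot_Na",), spike_fraction=0.025)
matrix, traits, truth = ts.generate_dataset(cfg)          # 2000 x 48, linear scale

norm = ts.log2_transform(ts.quantile_normalize(matrix))
control, stressed = ts.split_by_condition(norm)           # 24 + 24 columns

res = ts.run_trait_sam(stressed, traits, "shoot_Na", condition="stressed",
                       config=ts.SamConfig(permutations=100, seed=1))
sig = res.significant
print(f"s0 = {res.scores.s0:.3f}, pi0 = {res.fdr_table.pi0:.3f}")
print(f"significant: {len(sig.positive)} positive, {len(sig.negative)} negative")
spiked = set(truth["probe_id"])
called = set(sig.table["probe_id"])
print(f"true spikes recovered: {len(called & spiked)}/{len(spiked)}")
print(sig.table.head(3).to_string(index=False))

annotation = ts.generate_go_annotation(matrix.probe_ids, truth, cfg)
top = ts.run_sea(list(called), annotation)[0]
print(f"top GO term: {top.term} x={top.x}/{top.n} K={top.K}/{top.M} "
      f"p={top.p:.3g} fdr={top.fdr:.3g}")
```

prints

```
s0 = 0.491, pi0 = 0.936
significant: 48 positive, 45 negative
true spikes recovered: 93/100
    probe_id         d  q_percent direction
Os10g2783940  5.947402        0.0  positive
Os11g1264235 -5.375843        0.0  negative
Os12g0124643 -5.162706        0.0  negative
top GO term: GO:7700001 x=72/93 K=114/2000 p=3.27e-82 fdr=3.59e-81
```

The dataset planted 100 spike-in probes (5 %) whose log₂ expression rises
or falls linearly with the weighted shoot-Na⁺ value of each genotype; the
combined rule recovers 93 of them with no false positives at these
settings, the most extreme scores carry q = 0 %, and the GO term planted
among the spiked probes dominates the enrichment ranking.

The same pipeline is available from the shell:

```sh
traitsam simulate --config config.yaml --out sim/
traitsam preprocess --expr sim/expression.tsv --sheet sim/sample_sheet.tsv --out norm/
traitsam sam --expr norm/normalized.tsv --sheet norm/sample_sheet.tsv \
             --traits sim/traits.tsv --all-traits --seed 1 --out sam/
traitsam enrich --query sam/significant_shoot_Na_stressed.tsv \
                --annotation sim/go_annotation.tsv --out sea.tsv
traitsam network --genes sam/significant_shoot_Na_stressed.tsv \
                 --edges sim/edges.tsv --out subnet.tsv
```

`sam --all-traits` also writes `summary_counts.tsv`, the per-trait ×
condition table of positively/negatively expressed probe counts.

## Layout

| module | contents |
| --- | --- |
| `traitsam.io_formats` | TSV/GAF readers and writers, RAP locus parsing, domain containers |
| `traitsam.synthetic_data` | study-design simulator with spike-ins, planted GO term, planted hub |
| `traitsam.preprocess` | quantile normalization, log₂ transform, condition split, trait weighting |
| `traitsam.sam_core` | scores, fudge factor, permutation null, FDR/q-values, selection |
| `traitsam.enrichment` | exact hypergeometric SEA with BH/BY control |
| `traitsam.downstream` | RAP→MSU mapping, chromosome tallies, interaction subnetworks |
| `traitsam.cli` | `traitsam` command with one subcommand per stage |

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
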