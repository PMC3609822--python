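# riverhap

Phylogeography of maternally inherited haplotypes on a river-structured
landscape. `riverhap` takes an aligned mtDNA control-region FASTA, per-sample
metadata (population, sex, GPS coordinates) and a river map, and produces the
full analysis chain used in basin-scale surveys of forest mammals such as
bonobos, where large tributaries are candidate barriers to gene flow:

1. **Haplotypes** — samples with identical aligned sequences are collapsed
   into haplotypes with per-population (and per-sex) counts; locality
   specificity (how many haplotypes are private to one site) is tallied.
2. **Distances and trees** — pairwise difference counts and Tamura–Nei
   (TN93) distances with pairwise deletion; Saitou–Nei neighbor joining with
   a seeded site bootstrap; branches under 70% support are collapsed and the
   surviving clusters become *haplogroups* (clades); clade-level mean
   pairwise differences, within, between and net
   (`net = between − (within_i + within_j)/2`).
3. **Population structure** — haplotype (gene) diversity
   `h = n/(n−1)(1 − Σp_i²)`, mean pairwise differences Π, nucleotide
   diversity π = Π/L (Nei estimators with their standard errors);
   distance-based pairwise F_ST (the two-stratum AMOVA Φ-statistic) with an
   individual-permutation test; one-level AMOVA over populations or pooled
   cohorts; UPGMA population tree on net distances.
4. **Riverine-barrier inference** — three geographic indices per population
   pair (great-circle distance between sample centroids, number of
   large-river crossings of the straight line, and the *detoured* distance:
   the shortest route that crosses no large river, rounding headwaters,
   solved on a visibility graph); Pearson correlations, a KS normality
   check, and Gaussian-identity GLMs of F_ST on the indices compared by AIC
   (`AIC = n·ln(2πRSS/n) + n + 2(k+2)`, the convention of R's `AIC` on a
   gaussian `glm`), with leave-one-population sensitivity runs. This is the
   `RiverineBarrierModel` → `fit()` → results-with-`summary()` core.
5. **Synthetic data** — a generator that emulates the study conditions
   (1121-site alignment, six deeply diverged clades totalling 54 haplotypes,
   seven populations of 7–37 samples, a river network) with known truth, so
   the entire pipeline runs and is tested end to end with no external data.

## Worked example

```python
import riverhap as rh

ds = rh.simulate_samples(rh.SimulationConfig(seed=7), outdir="demo")
cfg = rh.RunConfig(
    alignment="demo/samples.fasta", metadata="demo/metadata.tsv",
    rivers="demo/rivers.geojson",
    cohorts={p.name: p.cohort for p in ds.config.populations},
    outdir="demo/out", n_boot=200, n_perm=1023, seed=7,
    tree_metric="diff_count",
)
artifacts = rh.run_pipeline(cfg)
```

The run log for this seed reports 136 samples collapsing to 44 observed
haplotypes in 6 supported clades, of which 29 are locality-specific and 15
shared, and a KS normality check on the 21 pairwise F_ST values of
D = 0.258, p = 0.101 (a normal response is not rejected, so the Gaussian
GLM is defensible). The AIC ranking in `demo/out/glm_aic.tsv`:

```
             model  n        AIC
          detoured 21 -19.285691
          straight 21 -18.955586
straight+crossings 21 -16.955624
         crossings 21 -10.150808
```

Detoured and straight distance are nearly tied (Δ AIC ≈ 0.3 — no real
evidence for the river detour over plain isolation by distance), crossings
alone fits far worse, and adding crossings to straight costs more than the
2-unit penalty it buys. The diversity table (`demo/out/diversity.tsv`)
gives, e.g., Iyondji n=18, 12 haplotypes, h=0.935, Π=16.01, π=0.0143, and
the peripheral TL2 population the lowest diversity (Π=5.58, π=0.0050) —
the centre-rich/edge-poor pattern the generator builds in.

The same pipeline runs from the shell:

```sh
riverhap simulate --seed 7 --out demo
riverhap all --config run.json
riverhap barriers --fst demo/out/net_distances.tsv \
                  --geo demo/out/geo_indices.tsv --exclude TL2
```

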