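# basinflow

Demographic inference and isolation-by-resistance analysis for small sets
of fragmented populations.

The package takes a reduced-representation SNP data set (VCF plus a
population map) sampled from a few localities nested in a small number of
genetic groups, and runs a complete landscape-genomic workflow:

1. **Population statistics** — per-population diversity (π, H_o, H_e,
   F_IS) and pairwise Weir–Cockerham F_ST with permutation tests.
2. **Folded joint SFS** — a three-group joint site-frequency spectrum
   folded on the global minor allele, with missing data handled by
   hypergeometric projection to fixed sample sizes.
3. **Coalescent model comparison** — six split-with-migration demographic
   models fitted to the SFS by maximum composite likelihood over
   simulated genealogies, compared by AIC with Akaike-weight model
   averaging, and parametric-bootstrap confidence intervals.
4. **Isolation by resistance** — circuit-theory effective-resistance
   distances over raster resistance scenarios (barriers, habitat,
   lithology, slope), scanned over a grid of resistance values.
5. **MMRR** — multiple matrix regression with randomization, with
   backward elimination of non-significant distance predictors.

A synthetic-data generator produces a complete miniature study (genotype
matrix, landscape rasters, distance matrices) with known generating
parameters, so every stage can be exercised and validated end to end
without any empirical data.

## Command-line usage

```sh
# generate a synthetic study to try the pipeline
basinflow synth --outdir study --seed 42 --loci 2000

# diversity and differentiation
basinflow stats --vcf study/genotypes.vcf --popmap study/popmap.tsv \
    --out-prefix study/run

# build the folded joint SFS (7/8/4 diploids per group)
basinflow sfs --vcf study/genotypes.vcf --popmap study/popmap.tsv \
    --groups north:TAJU,BELI --groups central:PHUE,SALI,BONI \
    --groups south:ORCE --targets 7,8,4 --out study/obs.sfs

# fit one model and build an AIC table
basinflow fit --sfs study/obs.sfs --model F --theta-s 78571.4 --out fitF.json
basinflow fit --sfs study/obs.sfs --model E --theta-s 78571.4 --out fitE.json
basinflow model-table fitF.json fitE.json --out table.tsv

# resistance distances and the resistance-value scan
basinflow resistance --scenario basin_barrier --raster study/basin.asc \
    --popmap study/popmap.tsv --resistance 100 --out dist.tsv
basinflow scan --scenario basin_barrier --raster study/basin.asc \
    --fst study/run_fst.tsv --popmap study/popmap.tsv --out scan.tsv

# matrix regression with backward selection
basinflow mmrr --y study/run_fst.tsv --x resistance=dist.tsv
```

Every command with a stochastic component takes `--seed`; identical seeds
give identical output.

## Library usage

```python
from basinflow import (
    read_vcf, pop_stats, pairwise_fst,
    thin_one_snp_per_locus, downsample_projection, build_folded_sfs,
    InferenceConfig, fit_battery, model_table, parametric_bootstrap,
)

G = read_vcf("study/genotypes.vcf", "study/popmap.tsv")
stats = pop_stats(G)
fst = pairwise_fst(G)

G1 = thin_one_snp_per_locus(G, rule="random", seed=1)
proj = downsample_projection(
    G1,
    groups={"north": ["TAJU", "BELI"],
            "central": ["PHUE", "SALI", "BONI"],
            "south": ["ORCE"]},
    targets={"north": 7, "central": 8, "south": 4},
)
obs = build_folded_sfs(proj)

cfg = InferenceConfig(theta_s=78571.4, seed=0)
# fit simplest-first so each model warm-starts from its nested variants,
# which keeps the lnL values AIC-comparable (see docs/methods.md)
fits = fit_battery(obs, ["F", "E", "D", "C", "B", "A"], cfg)
table = model_table(list(fits.values()))
boot = parametric_bootstrap(fits["F"], obs, cfg)
```

See `docs/methods.md` for the statistical model, the fitting algorithm
and all parameter conventions.

## SFS text format

A folded joint SFS is stored as plain text: an optional comment header,
one line with the three haploid sample sizes, then the counts array
flattened in row-major (C) order — the last axis varies fastest.

Worked example for haploid sample sizes (1, 1, 1), i.e. a 2×2×2 counts
array. The pooled sample size is 3, so folding zeroes every cell whose
total alternate count exceeds 3/2: cell (0,1,1) (total 2) is folded onto
its complement (1,0,0), and likewise (1,0,1)→(0,1,0), (1,1,0)→(0,0,1).
The monomorphic corners (0,0,0) and (1,1,1) are masked to zero. Suppose
the folded array is

```text
index (i,j,k):  (0,0,0) (0,0,1) (0,1,0) (0,1,1)   # i = north count
counts:            0      12       9       0
index (i,j,k):  (1,0,0) (1,0,1) (1,1,0) (1,1,1)
counts:           20       0       0       0
```

Then the file reads:

```text
# basinflow folded joint SFS
1 1 1
0.0 12.0 9.0 0.0 20.0 0.0 0.0 0.0
```

Counts may be real-valued because hypergeometric projection distributes
each site's mass across cells. `FoldedJointSFS.read`/`.write` implement
this format; body values may be split across any number of lines.

## Testing

```sh
python -m pytest
```

The suite contains unit and property-based tests for every module, an
independent msprime cross-check of the coalescent engine, and an
acceptance suite exercising the full pipeline. `scripts/acceptance.py`
runs the main computations end to end:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
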