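# resorb

Leaf nutrient resorption metrics and phylogenetic comparative statistics
for plant communities with contrasting sodium-regulation strategies.

## The problem

Before a leaf is shed, plants withdraw part of its nutrient capital back
into living tissue.  Two standard quantities describe this process for a
nutrient with green-leaf concentration `Nu_green` and senesced-leaf
concentration `Nu_senesced` (both mass-based, mg g⁻¹):

- **Resorption efficiency**, corrected for the dry-mass loss that
  accompanies senescence:

  `RE = (1 − Nu_senesced / Nu_green × MLCF) × 100 %`

  where `MLCF` (mass loss correction factor) is the senesced-to-green
  dry-mass ratio.  Negative RE means the element *accumulated* during
  senescence — the typical fate of Na in euhalophytes, which store salt in
  their foliage and discard it with the leaf.
- **Resorption proficiency**, `RP = Nu_senesced`: the terminal
  concentration itself, with lower values meaning more complete
  withdrawal.

In desert floras the interesting comparison is across groups that handle
salt differently: euhalophytes (Eu, foliar Na compartmentalisation),
secretohalophytes (Se, salt glands), pseudohalophytes (Ps, Na exclusion)
and glycophytes (Gl).  Because related species tend to resemble each
other, cross-species comparisons need the comparative-methods toolkit:

- **Blomberg's K** measures phylogenetic signal as a ratio of variance
  ratios, `K = (MSE0/MSE)_obs / (MSE0/MSE)_expected`, with the observed
  part built from the GLS mean under the tree's variance–covariance
  matrix `C` and the expectation evaluated under Brownian motion (K = 1
  under BM).  Significance comes from a tip-shuffling permutation test on
  the variance of standardised independent contrasts.
- **Felsenstein's independent contrasts (PIC)** turn n tip values into
  n − 1 standardised, phylogenetically independent differences; trait
  co-variation is then the contrast correlation through the origin.
- **SMA (standardised major axis) regression** fits symmetric bivariate
  lines (`slope = sign(r)·sd(y)/sd(x)`) when neither trait is the
  response.
- **Sequential variance partitioning** (Type I sums of squares) splits
  trait variance among site and plant group (or family).

Field datasets of this kind are rarely deposited, so the package is built
around a **synthetic-data generator** with known ground truth: seeded Yule
trees, Brownian trait evolution, clade-clustered group labels, and paired
green/senesced leaf samples whose senesced concentrations invert the RE
formula exactly.  Every downstream statistic can therefore be tested
against the truth that generated the data.

## Worked example

```python
from resorb import RunConfig, run_pipeline

result = run_pipeline(RunConfig(outdir="results", seed=42))
gm = result["tables"]["group_means"]
na = gm[(gm.status == "green") & (gm.element == "Na")].iloc[0]
for g in ("Eu", "Se", "Ps", "Gl"):
    print(f"{g}: {na[f'{g}_mean']:.1f} ± {na[f'{g}_se']:.1f} {na[f'{g}_letter']}")
```

prints the green-leaf Na group means (mg g⁻¹, ± SE of species means) with
compact letters from Tukey HSD at α = 0.05:

```
Eu: 52.0 ± 2.5 a
Se: 25.0 ± 1.5 b
Ps: 3.3 ± 0.4 c
Gl: 14.9 ± 4.6 b
```

Euhalophytes carry far more foliar Na than every other group; groups
sharing a letter are statistically indistinguishable.  The same run's
resorption summary shows net Na accumulation in euhalophytes (mean RE
−14.0 %, one-sample t vs 0 %: p = 0.009), its signal table gives the
plant-group coding K = 0.22 (permutation p = 0.025, 999 permutations) and
senesced-leaf Na K = 0.41 (p = 0.001), and the variance partition credits
plant group with 61 % of green-leaf Na variance after site.  All tables
land in `results/` as CSV together with `run_metadata.json` (seed, config,
versions); re-running the same config reproduces every file byte for
byte.

The same pipeline is scriptable from a shell:

```sh
resorb simulate --n-species 36 --seed 42 --out data/
resorb run --seed 42 --out results/
resorb signal --traits data/traits.csv --tree data/tree.nwk --nperm 999 --seed 42 --out signal.csv
```

To analyse real data instead of simulations, point a YAML config at a
long-format trait CSV and a Newick tree
(`resorb run --config config.yaml` with `simulate: false`,
`traits_path`, `tree_path`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the full pipeline from scratch (simulation, resorption metrics,
group statistics, phylogenetic signal, variance partitioning) at the given
seed and writes the results JSON; the generated tables are placed next to
it under `pipeline_tables/`.

See `docs/methods.md` for the statistical model, the generator's design
and its limitations.
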