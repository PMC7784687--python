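# phenoqg

Quantitative genetics of tree phenology in clonally replicated pedigree
trials.

Deciduous trees time their growing season by two sets of transitions —
spring budburst and autumn coloration/leaf shed — and how much of that
timing is heritable, and how it is genetically coupled to growth,
determines whether populations can track a shifting climate.  `phenoqg`
implements the full analysis chain for ordinal phenology surveys of a
clonal pedigree trial (the emulated design is a two-year *Populus
trichocarpa* plantation: 120 genotypes from a 9 × 10 factorial producing 34
full-sib families, 564 clonal ramets):

1. **Transition-day imputation** — surveys every 2–5 days score ordinal
   stages (budburst 1–5, crown colouration 1–8, leaf senescence 1–3); a
   LOESS developmental curve per tree × trait × year converts them to
   continuous milestone days (bb2, bb4, co3, co8, ls3), keeping only
   estimates bracketed by observations on either side.  Canopy duration is
   CD = day(co3) − day(bb2).
2. **Pedigree animal models by Gibbs sampling** — multivariate mixed
   models `y = Xβ + Zu + e` with `vec(U) ~ N(0, G ⊗ A)`, where A is the
   additive relationship matrix among genotypes (tabular method) and
   clonal ramets are repeated measures of their genotype.  A bivariate
   cross-year form estimates year-to-year genetic consistency; a 7-trait
   form with a fixed year effect estimates the trait–trait genetic
   covariance, with missing responses (e.g. DBH measured once) handled by
   data augmentation.
3. **Posterior genetics** — per-draw narrow-sense heritability
   h² = V<sub>a</sub>/(V<sub>a</sub> + V<sub>ε</sub>), genetic correlations
   r = G<sub>ij</sub>/√(G<sub>ii</sub>G<sub>jj</sub>), HPD/quantile
   credible intervals, ESS and autocorrelation diagnostics.
4. **A synthetic trial generator** — first-class, tested code that draws
   breeding values from the A ⊗ G structure, simulates latent transition
   days and the ordinal surveys that observe them, and records the
   realized generative parameters for parameter-recovery experiments.

See `docs/methods.md` for the models, priors, numerical choices and the
generator's scope.

## Worked example

Estimate the heritability of lifetime growth (DBH) on a synthetic trial
(`examples/03_growth_heritability.py`):

```python
import phenoqg as pq

dataset = pq.generate_dataset()                       # 564 trees, 120 genotypes
records = dataset.trial.dbh.rename(columns={"dbh_cm": "dbh"})
system = pq.assemble_design(records, pq.ModelSpec(traits=["dbh"]),
                            dataset.trial.clone_map, dataset.trial.relationship)
draws = pq.gibbs_run(system, pq.PriorSpec(),          # variance 1, belief 0.002
                     pq.ChainSettings(iterations=20_000, burn_in=2_000, thinning=20))
series, summary = pq.heritability(draws, "dbh")
```

prints

```
posterior median h2(DBH) = 0.733
95% HPD interval         = (0.662, 0.791)
ESS = 897, lag-1 autocorrelation = +0.002
generative truth         = 0.760
```

— the posterior median recovers the generative heritability to within a
few hundredths, the interval width reflects 120 genotypes in 34 families,
and an ESS near the retained-draw count (900) says the thinned chain is
effectively independent.

The 7-trait fit (`examples/04_trait_correlations.py`) prints the
lower-triangle genetic-correlation matrix in report form, e.g.

```
                        bb2                    bb4                   co3  ...
bb4     0.793 (0.682,0.871)*
co3     0.248 (0.031,0.446)*   0.236 (0.025,0.439)*
...
cd   -0.614 (-0.754,-0.488)*  -0.460 (-0.626,-0.264)*  0.618 (0.479,0.747)* ...
dbh  -0.240 (-0.422,-0.024)*  -0.407 (-0.575,-0.223)*  0.211 (-0.025,0.408) ...
```

with `median (95% HPD)` per cell and `*` flagging intervals that exclude
zero: spring and autumn phenology are strongly coupled within season but
nearly independent of each other, and early budburst / long canopy
duration are genetically associated with higher lifetime growth.

The other examples cover trial simulation (`01`), imputation and its
holdout validation (`02`), and cross-year genetic correlations (`05`).

A thin CLI wraps the same pipeline for shell use:

```bash
phenoqg simulate --seed 1 --out trial/
phenoqg impute trial/survey.csv --out trial/transitions.csv
phenoqg fit trial/transitions.csv --pedigree trial/pedigree.csv \
        --clones trial/clone_map.csv --dbh trial/dbh.csv \
        --config model.yaml --out fit/
phenoqg recover trial/truth.json fit/summary.csv --out recovery.csv
```

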