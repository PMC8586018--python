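# glacierseg

Movement-ecology pipeline for quantifying how tidewater glacier fronts
structure the foraging trips of colonial central-place foragers — breeding
black-legged kittiwakes (*Rissa tridactyla*) in a glacial fjord — and how
differential front use drives fine-scale spatial segregation among
neighbouring colonies.

It is written for spatial ecologists who have per-individual GPS fix
tables, colony metadata and glacier-front geometries, and want a tested,
reproducible route from raw fixes to segregation statistics.  Because the
motivating field data are not bundled, the package ships a first-class
synthetic-study generator with known ground truth against which every
stage is validated.

## What it computes

1. **Trips** — fixes are subsampled to 10 min, speed-filtered at 80 km/h,
   segmented into foraging trips (runs of fixes > 200 m from the colony
   centroid lasting ≥ 50 min) and filtered for ≥ 50% over-land locations.
2. **Utilization distributions** — per individual, the IID,
   Ornstein–Uhlenbeck (OU) and OU-Foraging (OUF) continuous-time position
   models are fitted by exact maximum likelihood and selected by AICc;
   the UD is a kernel density on a 500-m grid whose bandwidth uses the
   effective sample size N̂_area = duration/τ_pos (individuals with
   N̂_area < 4.5 are excluded).
3. **Segregation** — pairwise segregation index SI = 1 − BA, where
   BA = Σ√(p·q) is the Bhattacharyya overlap of two UDs; tested globally
   and per colony dyad with rank-based ANOSIM
   (R = (r̄_between − r̄_within)/(n(n−1)/4), label permutations,
   Benjamini–Hochberg across dyads), plus a multivariate
   dispersion-homogeneity check.
4. **Front use** — a front counts as used on a trip when two consecutive
   10-min fixes fall inside its 400-m buffer; use probability is modelled
   with a binomial GLMM, logit(P(use)) ~ distance + sex + colony + (1 |
   individual), fitted by Laplace maximum likelihood with likelihood-ratio
   tests, Nakagawa's conditional R² and a simulation-based dispersion
   check.
5. **Drivers of segregation** — individual front-use profiles p_ik give
   the proportional-similarity overlap H_ij = Σ_k min(p_ik, p_jk) and its
   complement DH = 1 − H; multiple regression on distance matrices (MRM)
   regresses SI on colony-size difference (Manhattan), colony separation
   (Euclidean) and DH, with significance from 999 row/column permutations
   of the response.

## Worked example

Simulate a default study (5 colonies, 25 fronts, 8 birds per colony,
front-choice log-odds decaying at −0.22 per km) and run the full analysis:

```python
from glacierseg.synthetic import SimConfig
from glacierseg.pipeline import run_pipeline

res = run_pipeline(SimConfig(seed=1), n_perm=999)
```

Formatting the result fields prints:

```text
individuals tracked      : 40
individuals with a UD    : 36  (N_area >= 4.5)
complete foraging trips  : 172
global ANOSIM            : R = 0.62, p = 0.001
GLMM distance effect     : -0.222 per km, 95% CI [-0.259, -0.184]
MRM: DH coef = 0.20 (p = 0.002), size p = 0.11, R2 = 36%
```

Reading the numbers: 4 of the 40 simulated birds are dropped by the
effective-sample-size filter.  ANOSIM R = 0.62 with the permutation floor
p = 0.001 says space use differs far more between colonies than within
them.  The GLMM recovers a strongly negative distance effect on front use
(the generator's true choice slope is −0.22 per km), and the MRM shows
that segregation increases with front-use dissimilarity (positive DH
coefficient, significant) but not with colony-size difference — the
qualitative headline pattern of the emulated study.

The same pipeline is available from the shell:

```sh
glacierseg simulate --seed 1 --out simdata
glacierseg preprocess --data simdata --out trips.csv
glacierseg run-all --seed 1 --out report.json
```

See `docs/methods.md` for the models, defaults, numerical choices and
known limitations.

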