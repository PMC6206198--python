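# bandfec

Estimating annual fecundity — and with it, population growth — from ordinary
bird-banding data.

Large ringing and banding schemes routinely yield age-specific survival
estimates from dead-recovery (tag-recovery) models, but fecundity has usually
required separate field programs. `bandfec` implements a joint model that
extracts all three vital rates from the banding data alone, using three
streams that standard operations already produce:

1. **Dead-recovery m-arrays** per age class (cohorts of newly banded
   juveniles/adults × occasion of recovery) identify first-year survival
   `S_j`, adult survival `S_a`, and recovery probabilities `r_j`, `r_a`
   under the Seber survival/reporting parameterization: a bird banded at
   occasion *t* is first recovered at occasion *k* with probability
   `[∏ S]·(1−S_k)·r_k` (juveniles use `S_j`, `r_j` for their first interval
   and adult rates thereafter).
2. **Within-season live recaptures** give age-specific capture
   probabilities via `f2 ~ Bin(M, p)` for each age class, where `M` birds
   were banded and `f2` of them handled twice during the initial season.
3. **Age composition at banding**, `M_j ~ Bin(M_j + M_a, c_j)`, gives the
   juvenile fraction among new bandings.

The pieces combine into derived parameters:

- relative vulnerability to capture `V = p_j / p_a`,
- vulnerability-adjusted fecundity `F_t = [c_{j,t}/(1−c_{j,t})] / V`
  (the raw age ratio corrected for juveniles being easier or harder to
  catch), and
- finite population growth `λ_t = S_{a,t} + F_t·S_{j,t}` under a one-stage
  projection model.

A closed-form, non-Bayesian route is included as well: Chao's
closed-population abundance estimator `N̂ = M + f1²/(2·f2)` applied per age
class, with `F̂ = N̂_j/N̂_a` and `V̂ = (M_j/M_a)/F̂`.

## Worked example

The dark-eyed junco dataset reduces, for the capture components, to four
printed totals: 248,939 juveniles and 107,998 adults banded, of which 45 and
15 were recaptured during the initial season. Fitting the time-constant
model to those counts:

```python
import bandfec as bf

rs = bf.RecaptureSummary.from_counts(M_j=248_939, f2_j=45, M_a=107_998, f2_a=15)
model = bf.TagRecoveryModel(bf.BandingDataset(recaptures=rs))
res = model.fit(bf.MCMCSettings.sparse(seed=1))   # 3 x 250,000 iterations
print(res.summary().round(5).to_string())
```

prints

```
              mean       sd       q5      q95       cv  sd_t     rhat
parameter
p.juv      0.00018  0.00003  0.00014  0.00023  0.14769   NaN  0.99998
p.ad       0.00015  0.00004  0.00009  0.00021  0.25040   NaN  0.99999
V          1.33303  0.41037  0.79547  2.09008  0.30785   NaN  1.00000
Mj/Ma      2.30502  0.00840  2.29120  2.31893  0.00364   NaN  0.99998
F          1.88562  0.55566  1.10303  2.89735  0.29468   NaN  0.99999
```

Read: juncos caught for banding run 2.305 juveniles per adult, but juveniles
are about 1.33× more catchable than adults (very imprecisely estimated —
the 90% credible interval 0.80–2.09 spans 1), so the vulnerability-adjusted
fecundity estimate is 1.89 juveniles per adult female with a wide interval.
All R-hat values are below 1.01, and because the capture components'
posteriors are exactly Beta, the chain means can be checked against conjugate
closed forms (they agree to Monte Carlo error; the test suite enforces this).

The closed-form route from the same counts:

```python
print(round(bf.adjusted_fecundity(rs), 3))   # 1.771  (Chao-based F-hat)
```

With full m-arrays the same `TagRecoveryModel` also estimates survival and
`λ`, and `temporal=("S_j", "S_a", "r_j", "r_a", "c_j")` switches any subset
of parameters to logit-normal year effects, yielding annual `F_t` and `λ_t`
posteriors.

A `bandfec` console script exposes the same functionality
(`bandfec chao|fit|simulate|evaluate --help`).

## Simulation harness

`bandfec.simulate` generates replicate 24-year banding programs with known
truths (`S_a=0.60`, `S_j=0.50`, `F=0.80`, so `λ=1`) and encounter rates
drawn per replicate from uniform ranges, and `bandfec.evaluate` aggregates
the resulting point estimates into bias, CV and RMSE, optionally binned by
the amount of data (e.g., total within-season recaptures). This reproduces
the estimator's key operating characteristic: adjusted fecundity is reliable
(CV < 0.10) once a program accumulates more than ~1,000 within-season
recaptures, and usable (CV < 0.20) above ~300.

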