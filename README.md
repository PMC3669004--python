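# eelgrass-allometry

Estimation of eelgrass (*Zostera marina*) leaf growth rates, and the
exact bias algebra that relates the three field proxies — leaf marking,
allometric projection, and the plastochrone method — to the true in situ
rate.

## The problem

Leaf productivity of eelgrass meadows is usually estimated from marked
shoots retrieved after an interval Δt (typically two weeks).  Three
proxies are in common use, and each misses part of the true growth:

* **leaf marking** weighs the tissue produced above a reference mark at
  the top of the sheath, so growth still inside the sheath is missed;
* **allometric projection** converts leaf *lengths* into dry weights
  through the power law ω = α·l^β, so any change in weight that is not a
  change in length (thickening of maturing tissue) is missed;
* the **plastochrone method** divides the dry weight of the third leaf
  ω₃ by the plastochrone interval p (the mean time between the
  appearance of two consecutive leaves, estimated as
  p = shoots × days / new leaves) — a single leaf standing in for the
  growth of every leaf on the shoot.

This package implements, for shoots s carrying leaves j:

* the in situ rate `Lg_s = Σ_j Δω_js / Δt` and its campaign mean Lg;
* the marking rate Lgm (three constructions: the formal `Σ α(Δl)^β/Δt`,
  a length-only field variant on above-mark increments, and the
  subtraction of measured within-sheath production from Lg);
* the allometric rate `Lga_s = Σ_j α·l_js(t+Δt)^β·δ_js / Δt`, where
  `δ = 1 − (1 − Δl/l(t+Δt))^β` is the fraction of the leaf's final
  allometric biomass gained over the interval;
* the plastochrone rate `Lgp_s = ω₃s / p`;

and the algebra connecting them.  Each shoot satisfies exactly

```
Lga_s = Csap·Lgp_s + Rsap ,    Csap = δ₃s·p/Δt ,
Rsap  = Σ_{j≠3} δ_js·ω_js(t+Δt)/Δt ≥ 0 ,
```

which averages to `Lga = Cap·Lgp + Bap` with `0 ≤ Cap ≤ p/Δt` and
`Bap > 0` whenever any non-third leaf grew.  Since a biased factor and a
positive remainder can never cancel simultaneously, the plastochrone
proxy is *structurally* biased; when p ≤ Δt the bias is an
underestimate.  The same algebra with the new-tissue/maturation split
`α·l^β·δ = α(Δl)^β + α·l^β(δ − λ^β)` (λ = Δl/l) links the marking rate:
`Lgm = Cap·Lgp + Bmp`.  Bounds `Bap − Lgp ≤ Bp ≤ Bap − Lgp + (p/Δt)·Lgp`
follow from the range of Cap.

Method agreement is scored the way the seagrass literature does it:
RMSE against the observed series, Lin's concordance correlation
coefficient with an asymptotic 95% CI, and regression through the
origin (with an intercept fallback when the origin-constrained fit is
poor).

Because shoot-marking field data are rarely archived, the package ships
a synthetic meadow generator (`simulate` module) that emulates a
biweekly marking study — plastochrone-clocked leaf appearance, seasonal
elongation, within-sheath growth, immature-tissue density deficits,
maturation thickening, lognormal weight noise and retrieval losses —
with a ground-truth channel, so every identity, inequality and method
comparison is testable at desk scale.

## Worked example

```python
from eelgrass_allometry import SimulationConfig, RunOptions, run_pipeline

result = run_pipeline(simulate=True, config=SimulationConfig(seed=0),
                      options=RunOptions())
for m in result.report.methods:
    ci = m.ccc_ci
    print(f"{m.method:>12}: RMSE={m.rmse:.6f} g/day  CCC={m.ccc:.3f} "
          f"(95% CI {ci[0]:.3f}-{ci[1]:.3f})  slope={m.slope:.3f}  r2={m.r_squared:.3f}")
print(f"Bm < Ba < Bp on {100*result.report.bias_ordering_fraction:.0f}% of campaigns")
```

prints

```
     marking: RMSE=0.000129 g/day  CCC=0.988 (95% CI 0.979-0.992)  slope=1.029  r2=0.998
  allometric: RMSE=0.000785 g/day  CCC=0.621 (95% CI 0.491-0.724)  slope=1.216  r2=0.973
plastochrone: RMSE=0.001998 g/day  CCC=0.109 (95% CI 0.045-0.171)  slope=1.174  r2=0.433
Bm < Ba < Bp on 100% of campaigns
```

Reading this: the marking estimate tracks the in situ rate almost
perfectly (its only loss is within-sheath growth, ≈3% of production
here); the allometric projection is precise but biased low by the
maturation flux it cannot see (observed-on-proxy slope 1.22, i.e. it
underestimates by ≈18%); the plastochrone proxy is both biased (its mean
is 45% below Lg) and noisy — a single leaf per shoot and an estimated
interval p explain less than half the variance of the observed series.
The bias ordering Bm < Ba < Bp held on every campaign of this season.

The same pipeline runs from the shell:

```
eelgrass-allometry simulate --out fixtures/ --seed 0
eelgrass-allometry run --out results/ --data fixtures/leaves.csv \
    --sidecar fixtures/campaigns.csv
```

writing `rates.csv`, `bias.csv`, `audit.json` and `report.json`.  Input
CSVs use unit-suffixed headers (`length_end_mm`, `dry_weight_end_g`, …);
see `eelgrass_allometry/io.py` for the schema.

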