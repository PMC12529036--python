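# dyng

Stomatal conductance (g_sw) from thermal imaging, calibrated on the fly
against artificial reference leaves with known pore conductance.

## The problem

Leaf temperature tracks transpiration, so a thermal camera can in principle
monitor the stomatal conductance of whole plants without touching them. The
classic route is the conductance index

    I_g = (T_dry − T_leaf) / (T_leaf − T_wet)

which locates a leaf's temperature between a non-transpiring (dry) and a
freely evaporating (wet) reference surface. I_g is proportional to
conductance, I_g = g·G, but the scaling G drifts with wind speed, air
temperature and humidity — so in any realistically fluctuating environment
the raw index conflates stomatal behavior with microclimate.

This package implements the dynamic-calibration solution: image, alongside
the targets, at least three porous artificial leaves (ALs) whose
water-vapor conductances g_pw are fixed and known. At every timepoint the
slope of I_g against g_pw re-estimates G ("DynG"), so the
I_g → conductance mapping tracks the current microclimate. The retrieval
chain per timepoint is

1. I_g of every AL and target;
2. boundary-layer conductance g_bw from the dry/wet pair's steady-state
   energy-balance difference (their latent-flux contrast is pinned by the
   long-wave emission difference σ(T_dry⁴ − T_wet⁴)(ε_B + ε_F));
3. DynG = through-origin slope of I_g vs g_pw;
4. total conductance g_tw = 1/(DynG/I_g + 1/g_bw);
5. g_sw from g_tw by the two-sided stomatal-ratio (SR) inversion, which
   reduces to g_sw = 2·I_g·g_bw/(I_g + 2·DynG·g_bw) for amphistomatous
   leaves (SR = 1) and to the single-face series inversion for one-sided
   evaporators (SR = 0);
6. transpiration E = 0.018·(g_bw·g_sw/(g_bw + g_sw))·(e_s(T_leaf) − e_a)/P.

Supporting pieces: Buck-formula psychrometrics, the pore-diffusion model
g_pw = PD·D·PA/(V·(l + n·√(PA/π))) with end-correction factor n for film
characterization, a lysimetric g_bw estimator, a full energy-balance g_sw
inversion for cross-checking, and a steady-state forward simulator that
generates reference-set thermograms under scripted wind/light protocols —
every inversion in the package is validated by round-trip against it.

Audience: plant ecophysiologists and phenotyping engineers working with
radiometric thermal cameras in growth rooms or phenotyping platforms.

## Worked example

`examples/estimate_conductance.py` simulates the benchmark protocol — five
references plus a target AL of fixed conductance 0.31 mol m⁻² s⁻¹ under
wind steps 0.1/0.4/0.9 m s⁻¹ with 0.03 K camera noise — and runs the full
retrieval both ways:

```
per-wind-step mean estimate of the target's conductance (truth 0.31 mol m-2 s-1):
  wind     DynG  I_g only    g_bw   slope
   0.1    0.309     1.691   0.283   5.473
   0.4    0.311     1.011   0.513   3.249
   0.9    0.312     0.731   0.745   2.344
```

The calibrated estimate stays within ~1% of the true conductance at every
wind speed because the falling calibration slope (5.47 → 2.34) absorbs the
boundary-layer change (g_bw 0.28 → 0.75 mol m⁻² s⁻¹); the raw index, read
directly as a conductance, varies 2.3-fold over the same protocol. The
other examples cover film characterization, the two boundary-layer
estimators, reference-set kinetics, and the sensitivity sweep.

A thin CLI wraps the same calls, e.g.:

```bash
dyng characterize-al --pa-um2 2000 --pd-per-mm2 10 --l-um 20
dyng simulate --config scenario.csv --seed 1 -o temps.csv --env-output env.csv
dyng estimate-gsw --temps temps.csv --env env.csv \
    --gpw low=0.10,medium=0.20,high=0.29 --target target --sr 0 -o out.csv
```

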