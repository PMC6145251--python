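# extractkin

Empirical kinetics of solid–liquid extraction: model fitting, ranking,
and process-time prediction.

When a bioactive compound — here the motivating case is anthocyanin
pigment leaching from dried jambolan (*Syzygium cumini*) fruit granules
into an acidified ethanol solvent — is extracted in an agitated vessel,
the solvent-phase concentration X(t) rises from 0 toward an equilibrium
X_eq. Process engineers need three things from such a kinetics run: a
model that describes the curve, the instantaneous extraction rate, and
the time needed to reach a stated fraction of equilibrium. `extractkin`
provides all three for the five classical one- and two-parameter
empirical families, each with closed-form forward, derivative, and
inverse expressions on the dimensionless scale
X\*(t) = (X − X_eq)/(X_i − X_eq), so that X(t) = X_eq·(1 − X\*(t)) when
the initial solvent concentration X_i is zero:

| model | X\* = f(t; a, b) | inverse t(X\*) |
|---|---|---|
| Lewis | e^(−at) | −ln X\*/a |
| Henderson–Pabis | a·e^(−bt) | −ln(X\*/a)/b |
| Peleg | 1 − t/(a + bt) | a(1 − X\*)/(1 − b + bX\*) |
| Page | e^(−a·t^b) | (−ln X\*/a)^(1/b) |
| Silva | e^(−at − b√t) | t = u², u the positive root of au² + bu + ln X\* = 0 |

Models are fitted in concentration space by bounded nonlinear least
squares (deterministic linearised starting points, trust-region
optimiser) minimising Σᵢ[Xᵢ − X_eq(1 − f(tᵢ; a, b))]², and ranked by
χ² (the unweighted residual sum of squares, with an optional per-point
σ vector) and R². Derived quantities follow in closed form: the
extraction rate dX/dt = −X_eq·df/dt — for the Page model
X_eq·a·b·t^(b−1)·e^(−a·t^b) — and the process time for a target
fraction p of equilibrium from the inverse at X\* = 1 − p (p = 0.97,
i.e. X\* = 0.03, by default).

A seeded synthetic-data generator produces kinetics series with known
ground truth on the standard dense-early sampling schedule
(0, 2, 4, 6, 8, 10, 15, 20, 30, 40, …, 130 min), including a
four-condition reference panel (agitation at 0/50/100/150 rpm, shared
X_eq = 13.1 mg/100 g) built from published Page parameters.

## Worked example

Simulate the four-condition reference panel (σ = 0.3 mg/100 g
measurement noise), then run the full pipeline — tail-mean equilibrium
estimate, all five models fitted per condition, χ²/R² ranking, and
predictions from each condition's best model:

```sh
extractkin simulate --panel --seed 7 --out panel.csv
extractkin fit panel.csv --x-eq-mode tail_mean --tail 3 --out-dir report
```

prints (abridged):

```json
{
  "equilibrium": { "tail_observations": 3, "x_eq_mg_per_100g": 13.390 },
  "process_times": {
    "target_fraction": 0.97,
    "minutes_rounded": { "0 rpm": 176, "50 rpm": 102, "100 rpm": 93, "150 rpm": 29 }
  },
  "percent_extracted": {
    "at_time_min": 28.0,
    "percent": { "0 rpm": 54.3, "50 rpm": 68.7, "100 rpm": 80.0, "150 rpm": 96.7 }
  }
}
```

The equilibrium estimate (13.39 mg/100 g) is the mean of the last three
observations of the fastest condition; the process times say how long
each agitation level needs to reach 97% of equilibrium — agitation at
150 rpm is roughly six times faster than no agitation — and the percent
column reads off how far each run has progressed at the 28-minute mark.
`report/fit_report.csv` holds the ranked fit table; its first rows for
the 0 rpm condition:

```
condition,model,a,b,r_squared,chi_square,n_obs,converged
0 rpm,page,0.05138,0.81721,0.99653,1.16590,19,True
0 rpm,peleg,26.65388,0.85900,0.99645,1.19109,19,True
...
```

The fitted Page parameters (a = 0.0514, b = 0.817) recover the
generator's truth (a = 0.05171, b = 0.8319) to within the noise level,
and R² ≈ 0.9965 is typical of careful spectrophotometric kinetics.

`extractkin predict --model page --a 0.3047 --b 0.7336` evaluates the
closed-form process time and percent-extracted for given parameters
without any fitting, and `extractkin benchmark` checks the embedded
reference parameter sets against their published headline figures.

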