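# sharkescape

Shark nurseries are usually explained by predator avoidance: newborns live
where big sharks rarely go. `sharkescape` implements the quantitative
machinery for a complementary hypothesis — that nurseries lower
*post-encounter* risk by offering the temperatures, depths and structure in
which a newborn blacktip reef shark (*Carcharhinus melanopterus*) escapes
best. It is written for ecophysiologists and biomechanists who work with
intermittent-flow respirometry, high-speed escape-response video and field
temperature loggers, and it ships a seeded synthetic-data generator so the
entire pipeline is testable without any raw recordings.

## What it computes

**Aerobic scope from respirometry.** A 24-h post-exercise trial (DO sampled
every 2 s for 5 min at 10-min intervals → 96 decline slopes, 14 400
readings) yields per-window uptake rates Ṁ_O2 = −b·V_eff·3600, mass-scaled
by kg⁻⁰·⁸⁹. Ṁ_O2Min is the mean of the lowest 10 % of determinations,
Ṁ_O2Max the steepest 30-s rolling regression in the first hour, and the
absolute aerobic scope AAS = Ṁ_O2Max − Ṁ_O2Min.

**Thermal performance curves.** Gaussian
f(T) = a·exp(−½((T−T_opt)/σ)²) and quadratic families fitted by
64-multistart NLLS, compared by AICc; peak AAS, optimum temperature and the
80 %-of-peak performance breadth with residual-bootstrap BCa 95 % intervals;
Holm–Šidák pairwise contrasts between temperature groups. Exposed both as
functions and as a scikit-learn-style estimator
(`ThermalPerformanceCurve().fit(T, aas)`).

**Fast-start kinematics.** From 240-fps tracks: responsiveness, escape
latency (frame-quantized, truncated to 4.16-ms steps), maximum Stage-1
turning rate ω_S1, maximum speed and acceleration (Savitzky–Golay smoothed
derivatives), single- vs double-bend classification, fastest-of-three
maximal performance, and temperature regressions with Grubbs/Bartlett QC.

**Submergence depth index.** SDI = z/B (water depth over caudal-fin
height); per-life-stage regressions over a 0.1–1.5 m depth grid, the
critical depths where SDI crosses 3, and the depth band in which newborns
keep full fast-start thrust while adult-sized predators do not.

**Diel thermal regimes.** Cross-validated LOESS smooths of pooled hourly
logger records per site × month, cycle parameters (mean, extrema, times,
range), an hour-wise signed thermal-volatility index, and the hours per day
the cycle spends inside the aerobic-scope performance window.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from sharkescape import simulate as sim, tpc, sdi, thermal as th

# --- thermal performance curve at the study design (27/29/31 C, n = 9/8/8)
data = sim.gen_aas_dataset(seed=7)
g = tpc.fit_model(data, "gaussian", seed=7)
q = tpc.fit_model(data, "quadratic", seed=7)
best, table = tpc.aicc_select([g, q])
d = tpc.derive_params(best)
boot, iv = tpc.bootstrap_bca(best, data, n_boot=999, seed=7)
print("selected:", best.shape)
print(f"peak AAS {d.aas_max:.1f} at {d.t_peak:.2f} C, 80% breadth {d.breadth:.2f} C "
      f"({d.lower:.2f}-{d.upper:.2f} C)")
r = iv.loc["t_peak"]
print(f"optimum BCa 95% CI: [{r.bca_low:.2f}, {r.bca_high:.2f}]")

# --- submergence depth index on simulated fin-height cohorts
fins = sim.gen_fin_heights("newborn", seed=0) + sim.gen_fin_heights("adult", seed=1)
model = sdi.sdi_regression(fins)
print("critical depths (m):", {k: round(v, 2) for k, v in model.critical_depths.items()},
      " advantage band:", tuple(round(x, 2) for x in model.advantage_band))

# --- diel cycle for one nursery site x month
params, start = sim.params_from_field_row("Papetoai", "November")
logs = sim.gen_temperature_log(params, site="Papetoai", start=start)
cycle = th.fit_diel_loess(th.hourly_aggregate(logs, site="Papetoai"), seed=0)
p = th.derive_cycle_params(cycle)
hours, frac = th.time_in_breadth(cycle, d.lower, d.upper)
print(f"diel cycle: mean {p.mean_c:.2f} C, max {p.max_c:.2f} C at {p.time_max_h:.0f} h00; "
      f"{hours:.1f} h/day inside the aerobic-scope window")
```

This prints:

```
selected: gaussian
peak AAS 310.2 at 28.97 C, 80% breadth 3.00 C (27.47-30.48 C)
optimum BCa 95% CI: [28.80, 29.14]
critical depths (m): {'adult': 0.95, 'newborn': 0.31}  advantage band: (0.31, 0.95)
diel cycle: mean 28.24 C, max 30.66 C at 14 h00; 11.4 h/day inside the aerobic-scope window
```

Read: on this simulated cohort the fitted aerobic scope peaks at ~310
mg O₂ h⁻¹ kg⁻⁰·⁸⁹ near 29 °C and stays above 80 % of that peak over a ~3 °C
window; adults lose significant fast-start thrust in water shallower than
~0.95 m while newborns only do so below ~0.31 m, so depths between the two
favour the newborn; and the November diel cycle at this site keeps the
water inside the high-performance thermal window for about half of each
day. (At a three-temperature design the Gaussian and quadratic families fit
the three group means equally well, so selection falls to the documented
first-listed tie rule.)

A command-line pipeline wraps the same functions
(`sharkescape all --config run.toml`, stages `simulate`, `respiro`, `tpc`,
`kinematics`, `sdi`, `thermal`, plus `validate` for CSV schema checks); it
writes CSV outputs, JSON reports and a run manifest recording seed,
parameters and row counts.

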