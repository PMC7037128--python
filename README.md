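# monofold

Quantitative analysis of cyclic Langmuir-trough surface pressure–area
(Π–A) isotherms of model lung-surfactant monolayers.

When a phospholipid film at the air–water interface is repeatedly
compressed past its collapse pressure and re-expanded — the trough
analogue of breathing — some material leaves the interface each cycle.
`monofold` turns raw trough logs (time, trough area, surface pressure)
into the per-cycle observables used to quantify that loss:

- **Cycle segmentation** from the barrier (area) signal alone, robust to
  pressure noise.
- **Hysteresis "area under the curve" (AUC)**: the area enclosed by each
  compression/expansion loop, computed as the absolute shoelace (Gauss)
  area of the measured polygon, usually reported as log₁₀(AUC).
- **Lift-off area**: the trough area where the compression first leaves
  its gas-phase pressure baseline.
- **Collapse localization** via the compressibility modulus
  C_s⁻¹ = −A·(dΠ/dA), whose sharp maximum marks collapse.
- **Volmer equation-of-state fits** of the liquid-expanded (LE) region,

      Π(A_T) = (kT/ω₀) · ω_eff / (A_T − ω_eff) − Π_coh,

  where the fitted effective molecular area ω_eff = n·ω [cm²] is
  proportional to the number of molecules at the interface; its
  cycle-to-cycle ratio estimates the per-cycle material retention.
- **Control-vs-treated statistics**: per-cycle mean differences
  (control − treated, so positive = less material in the treated group)
  with the propagated SD σ_total = √(σ_control² + σ_treated²).
- A **synthetic trace generator** with ground-truth per-cycle retention,
  collapse plateau and expansion hysteresis, so the whole pipeline is
  testable end to end without instrument data.

The intended users are membrane-biophysics labs analyzing ribbon-trough
compression/expansion experiments (e.g. nanoparticle–surfactant
interaction studies) who want the isotherm bookkeeping to be scripted,
deterministic and tested rather than done by hand in a plotting tool.

## Worked example

```python
from monofold import SyntheticModel, analyze_trace, simulate_trace

trace = simulate_trace(SyntheticModel(seed=17))   # 5 cycles, 166→46 cm²
metrics, fits = analyze_trace(trace)
for m, f in zip(metrics, fits):
    print(m.cycle_index, round(m.auc, 1), round(m.log_auc, 3),
          round(f.params.omega_eff, 2))
```

prints (noise SD 0.1 mN/m; see `examples/` for the same run step by step):

```
1 4501.3 3.653 58.9
2 4016.2 3.604 51.94
3 3536.6 3.549 47.88
4 3064.4 3.486 42.39
5 2606.3 3.416 38.21
```

Reading: the hysteresis loop shrinks every cycle (log₁₀ AUC 3.65 → 3.42)
and the fitted effective molecular area falls from ≈58 to ≈38 cm² — both
signatures of ~10% of the film's material being lost per cycle, which is
exactly the generator's ground truth (consecutive ω_eff ratios ≈ 0.9).

Each script in `examples/` is a short narrative of one capability:
simulation + segmentation, hysteresis AUC, Volmer material-loss
tracking, collapse localization, and the cohort comparison.

A thin CLI wraps the same functions for shell use:

```sh
monofold simulate --out trace.csv --seed 17
monofold segment trace.csv --turn-tolerance 1.0 --liftoff-delta 1.0
monofold metrics trace.csv
monofold volmer trace.csv --pi-min 2 --pi-max 30
monofold compare --control c1.csv --control c2.csv --treated t1.csv --metric log_auc
```

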