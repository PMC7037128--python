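"""Quantify per-cycle hysteresis: the area enclosed by each Pi-A loop.

The loop area ("area under the curve", mN/m·cm²) is the shoelace area
of the polygon formed by the measured compression + expansion points.
Its decay across cycles measures loss of material from the interface;
the paper-style convention reports it on a log10 scale.
"""

from monofold import SyntheticModel, analyze_trace, simulate_trace

trace = simulate_trace(SyntheticModel(seed=17))
metrics, _ = analyze_trace(trace, fit=False)

print("cycle  AUC [mN/m.cm2]  log10(AUC)")
for m in metrics:
    print(f"{m.cycle_index:>5}  {m.auc:>14.1f}  {m.log_auc:>10.3f}")

drop = metrics[0].log_auc - metrics[-1].log_auc
print(f"\nlog-AUC drop over {len(metrics)} cycles: {drop:.3f}")
# A drop of ~0.24 in log10 means the enclosed loop shrank to ~58% of its
# first-cycle area — the signature of irreversible material loss.
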