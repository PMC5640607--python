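"""Global versus selective saccadic suppression in the virtual-neuron model.

Runs the 71-neuron virtual population twice with identical statistics:
once with the same suppression kernel applied to every neuron (global)
and once with congruent suppression plus incongruent enhancement applied
by tuning sign (selective). Only the selective mode produces a deep
compression of decoded heading.
"""

from perisacc.model import ModelConfig, compare_modes, run_model

rg = run_model(ModelConfig(kernel_mode="global", seed=1))
rs = run_model(ModelConfig(kernel_mode="selective", seed=1))
cmp_ = compare_modes(rg, rs)

print(f"global suppression:    min normalized SD {cmp_.min_global:.2f} "
      f"at {cmp_.t_min_global_ms:.0f} ms")
print(f"selective suppression: min normalized SD {cmp_.min_selective:.2f} "
      f"at {cmp_.t_min_selective_ms:.0f} ms")
print("-> global gain changes rescale all tuning lines alike and barely")
print("   compress the decoded headings; selective suppression of the driven")
print("   neurons plus release from inhibition of the others collapses the")
print("   decoded headings toward straight ahead ~100 ms after saccade onset.")
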