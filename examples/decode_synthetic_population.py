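"""Decode heading from a synthetic MST/VIP-like population around saccades.

Builds optokinetic eye traces and spike trains for 71 linearly tuned
neurons under selective perisaccadic modulation, detects saccades, cuts
isolated perisaccadic snippets, fits each neuron's tuning line, decodes
the population, and prints the decoded headings at the moment of maximum
compression.
"""

import numpy as np

from perisacc.pipeline import RunConfig, pipeline_run

config = RunConfig(seed=1, trace_duration_s=60.0)
result = pipeline_run(config)

comp = result.summary["compression"]
print(f"snippets per heading: {result.summary['n_snippets']}")
print(f"tuned neurons: {result.summary['n_tuned']} "
      f"(left {result.summary['subpopulations']['left']}, "
      f"right {result.summary['subpopulations']['right']})")
print(f"maximum compression at {comp['t_max_compression_ms']:.0f} ms after "
      f"saccade onset (normalized SD {comp['min_normalized_sd']:.2f})")
print("-> a normalized SD near 0 means the decoded headings have collapsed")
print("   toward a common central value; 1 means full separation, as during")
print("   slow tracking.")
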