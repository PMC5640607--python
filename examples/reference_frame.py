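"""Where is heading compressed to - head, body, screen, or gaze?

Simulates the two offset conditions of the reference-frame experiment:
head turned 15 deg left with gaze straight, and gaze 15 deg left with the
head straight. The compression center follows the eyes, not the head, so
the analysis classifies the effect as gaze-centered.
"""

from perisacc.psychophysics import reference_frame_analysis
from perisacc.synthetic import (BehavioralGenParams,
                                gaussian_compression_profile,
                                generate_behavioral_trials)


def condition(gaze=0.0, head=0.0, seed=0):
    params = BehavioralGenParams(
        compression_profile=gaussian_compression_profile(peak=1.0),
        gaze_offset=gaze, head_offset=head, report_noise_sd=2.0)
    return generate_behavioral_trials(params, seed=seed)


result = reference_frame_analysis({
    "head_offset": condition(head=-15.0, seed=1),
    "gaze_offset": condition(gaze=-15.0, seed=2)})

for name, center in result.centers.items():
    print(f"{name:12s}: compression center at {center:+6.1f} deg "
          f"(max compression at {result.t_max_compression[name]:+.1f} ms)")
print(f"classified reference frame: {result.classified}")
print("-> with the head turned the center stays at the screen midline, but")
print("   with the eyes turned it moves with gaze: compression is organized")
print("   in eye-centered coordinates.")
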