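"""The headline computational result: more noise slows the response but
does not delay its onset.

Starting from a young-typical model, the endogenous-noise intensity is
quadrupled and the optimal controller re-derived.  The closed-loop response
magnitude drops (especially at higher frequencies: slowing), yet the
cross-correlation latency measured on re-simulated sessions is unchanged.
"""

import numpy as np

import visuotrack as vt
from visuotrack.latency import subject_latency

constants = vt.TaskConstants()
young = vt.SubjectParameters(0.26, 1.8e-3, 8.9, 0.19)
noisy = young.replace(noise_intensity=4 * young.noise_intensity)

omega = np.array([1.0, 5.0, 10.0, 20.0])
print("       |H_ud| at omega =", omega, "rad/s")
for label, p in (("baseline", young), ("4x noise", noisy)):
    plant = vt.assemble_plant(constants, p)
    H, _ = vt.predicted_response(plant, vt.design_lqg(plant), omega)
    print(f"{label:9s}", np.round(np.abs(H.siso()), 4))

d_list = vt.generate_perturbations(constants, 8, seed=42)
for label, p in (("baseline", young), ("4x noise", noisy)):
    trials = vt.simulate_subject(constants, p, d_list, seed=11)
    lat = subject_latency(trials, constants)
    print(f"{label:9s} cross-correlation latency = {lat * 1e3:.0f} ms")
print("\nThe response magnitude falls at mid/high frequencies (slower,")
print("more cautious corrections) while the onset latency stays put.")
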