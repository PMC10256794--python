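"""Generate one synthetic multimodal participant and inspect it.

A participant bundles white-matter contacts, a sparse streamline-backed
structural network, 2000 Hz LFP-like signals whose synchronization
tracks the structural weights, and TR = 2 s BOLD-like signals derived
from a hemodynamically convolved activity envelope.
"""

import numpy as np

from wmcoupling import SynthConfig, generate_participant

cfg = SynthConfig(
    n_contacts=20, box_extent=80.0, lfp_duration=15.0,
    bold_n_volumes=120, coupling_strength=0.5, seed=1,
)
part = generate_participant(cfg, render_volume=True)

n_pairs = cfg.n_contacts * (cfg.n_contacts - 1) // 2
n_edges = int((part.truth.sc_weights > 0).sum() // 2)
print(f"contacts: {len(part.contacts)} (all white matter)")
print(f"structural edges: {n_edges} of {n_pairs} pairs "
      f"({len(part.streamlines)} streamlines)")
print(f"SEEG panel: {part.seeg.n_channels} ch x {part.seeg.duration:.0f} s "
      f"@ {part.seeg.fs:.0f} Hz")
print(f"BOLD panel: {part.bold.n_samples} volumes @ TR {cfg.bold_tr:.0f} s")
print(f"BOLD volume grid: {part.volume.grid_shape} voxels "
      f"@ {part.volume.voxel_mm:.0f} mm")

iu = np.triu_indices(cfg.n_contacts, 1)
fc = np.corrcoef(part.seeg.values)[iu]
print(f"broadband LFP FC over edges: min {fc.min():.2f}, max {fc.max():.2f}")
# The strongest functional edges should be the heaviest structural edges:
# at coupling_strength 0.5 the model sits near criticality, and pairwise
# synchronization is a monotone function of streamline count.
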