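"""Recover a planted eccentricity-preference map from simulated voxels.

Simulates a retinotopy run on a population whose voxels each prefer one
of five eccentricity rings (centre to far periphery), fits the GLM, and
builds the winner-take-all preference map with top1 - top2 strength.
"""

import numpy as np

from fullfield import analysis, design, synthetic

des, events = design.build_run("retinotopy", np.random.default_rng(5))
ntr = design.compute_run_timing(des)["TRs"]
bands = ("ecc1_center", "ecc2", "ecc3", "ecc4", "ecc5_farperiphery")

pop = synthetic.synth_retinotopic_population(500, margin=1.0, sigma=0.3,
                                             phi=0.3, seed=9)
conds = tuple(sorted(set(events["trial_type"]) - {"fixation"}))
amp = np.full((500, len(conds)), 1.0)
for j, c in enumerate(conds):
    if c in bands:
        amp[:, j] = pop.amplitudes[:, bands.index(c)]

bold, _ = synthetic.synth_bold(
    synthetic.SimSpec(amp, conds, sigma=0.3, phi=0.3, seed=pop.seed),
    events, n_scans=ntr,
)
betas = analysis.fit_glm(bold, analysis.build_design_matrix(events, 2.0, ntr))
cols = [betas.condition_labels.index(b) for b in bands]
prefs = analysis.preference_map(betas.betas[:, cols], list(bands))

recovery = np.mean(prefs.index == pop.preferred)
print(f"winner-take-all recovery of planted band preference: {recovery:.1%}")
print(f"mean preference strength (top1 - top2): {prefs.strength.mean():.2f} PSC")
for i, b in enumerate(bands):
    print(f"  {b:20s} {np.mean(prefs.index == i):6.1%} of voxels")
print("With a 1-PSC margin over 0.3-PSC noise the planted map is "
      "recovered essentially perfectly, the high-SNR regime of the "
      "cortical eccentricity maps.")
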