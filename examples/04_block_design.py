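"""Build the three run protocols and print their timing and structure.

Each run is a blocked design with a one-back repetition task; block
order is randomised per epoch with no condition appearing twice in a
row, and every total must be a whole number of 2-second TRs.
"""

import numpy as np

from fullfield import design

for protocol in ("retinotopy", "exp2", "exp3"):
    des, events = design.build_run(protocol, np.random.default_rng(0))
    timing = design.compute_run_timing(des)
    n_cond = len(des.conditions)
    print(f"{protocol:10s}: {n_cond:2d} conditions, "
          f"{timing['seconds']:5.0f} s = {timing['TRs']} TRs, "
          f"{len(events)} events, {int(events['is_target'].sum())} one-back targets")

des, events = design.build_run("exp2", np.random.default_rng(0))
labels = events.loc[events["trial_type"] != "rest", "trial_type"]
blocks = labels[labels.ne(labels.shift())].tolist()
print("\nexp2 block order (no label repeats back-to-back):")
print(" -> ".join(blocks[:6]), "-> ...")
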