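"""Build one of every stimulus class on the 1024 x 768 canvas.

Writes PNGs under ./example_stimuli/: an eccentricity-ring checkerboard,
a phase-scrambled scene, a postcard scene, a scotoma condition and a
13-face array, plus the full 400-image scotoma set manifest head.
"""

from pathlib import Path

import numpy as np
from PIL import Image

from fullfield import stimgen, synthetic

out = Path("example_stimuli")
out.mkdir(exist_ok=True)


def save(name, img):
    Image.fromarray(np.clip(img, 0, 255).astype(np.uint8)).save(out / name)


ring = stimgen.make_ring_checkerboard(stimgen.RingSpec(6.3, 16.5))
save("ring_6.3-16.5deg.png", ring)

scene = synthetic.synth_images("scene", 1, seed=0)[0]
save("scene.png", scene)
scrambled = stimgen.phase_scramble(scene, np.random.default_rng(1))
save("scene_scrambled.png", scrambled)
print(f"phase scramble preserves mean luminance: "
      f"{scene.mean():.2f} -> {scrambled.mean():.2f}")

save("scene_postcard.png", stimgen.make_postcard(scene))

scotoma = stimgen.apply_scotoma(scene, stimgen.ScotomaSpec(58.0))
save("scene_scotoma58.png", scotoma)

faces = synthetic.synth_images("face", 58, seed=2)
array, table = stimgen.layout_item_array(faces, rng=np.random.default_rng(3))
save("face_array.png", array)
sizes = sorted(int(d) for d in table["diameter_px"].unique())
print(f"face array places {len(table)} items "
      f"(sizes {sizes} px, larger toward "
      "the periphery to counter cortical magnification)")

print(f"stimuli written to {out}/")
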