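"""2D classification and good/bad class selection.

Windows truth particles of a two-species mixture, classifies them into
capacity-constrained classes, trains the selector to accept only the
ring species, and shows how the selector partitions new classes.
"""

import warnings

import numpy as np

from emloop import classify2d, select2d, simdata
from emloop.types import Box, Micrograph

warnings.filterwarnings("ignore", category=UserWarning)

specs = simdata.default_class_specs(abundances=(0.5, 0.5))
config = simdata.SimConfig(seed=31, particles_per_micrograph=40,
                           contamination_rate=0.0)
movies, truth = simdata.generate_dataset(config, 15, specs)

parts, labels = [], []
for movie in movies:
    mic = Micrograph(movie.frames[0], micrograph_id=movie.micrograph_id)
    for x, y, cid in truth[movie.micrograph_id].particles:
        got = classify2d.window_particles(mic, [Box(x, y, 24)], 32)
        if got:
            parts.append(got[0])
            labels.append(cid)

result = classify2d.classify(parts, (20, 40), seed=0)
print(f"{len(parts)} particles -> {len(result.classes)} classes "
      f"(20-40 members each), {len(result.unaccounted)} unaccounted")

labeled, purities = [], []
for cls in result.classes:
    ring_frac = np.mean([labels[i] == "class_ring" for i in cls.member_ids])
    purities.append(max(ring_frac, 1 - ring_frac))
    labeled.append(select2d.LabeledClass(
        cls, select2d.GOOD if ring_frac >= 0.5 else select2d.BAD))
print(f"mean class purity (majority species fraction): "
      f"{np.mean(purities):.2f}")

selector = select2d.train_selector(labeled, seed=0)
decisions = select2d.select([c.average for c in labeled], selector, 0.1)
agree = np.mean([lab == lc.label
                 for (lab, _), lc in zip(decisions, labeled)])
print(f"selector trained good=ring / bad=disc; training-set agreement "
      f"{agree:.2f} at the permissive 0.1 acceptance threshold")
print("In the feedback loop this selector decides which particles are "
      "allowed to re-train the picker.")
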