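"""Hydrogen-bond partner profile across constructed umbrella windows.

Builds labelled frames in which permeant-water contacts fade and
lipid contacts appear as the window center moves from bulk water toward
the bilayer core, then prints the per-window partner breakdown (the
water column falls, the lipids column rises, and total = lipids + water
+ self exactly).
"""

import numpy as np

from permeapath.hbonds import HBondCriteria, hbond_profile
from permeapath.synthetic import make_hbond_frame

rng = np.random.default_rng(0)
windows = []
for center in (0.4, 1.2, 2.0, 2.8, 3.6, 4.4):
    n_water = int(round(4 * center / 4.4))          # fades toward the core
    n_cer = 2 if 0.8 <= center <= 3.0 else 0        # headgroup/tail contacts
    frames = []
    for _ in range(50):
        entries = [("permeant", "water", (0, i, 0), (0.1, i, 0), (0.32, i, 0))
                   for i in range(n_water)]
        entries += [("permeant", "CER", (5, i, 0), (5.1, i, 0), (5.3, i, 0))
                    for i in range(n_cer)]
        entries = entries or [("permeant", "water", (0, 0, 0), (0.1, 0, 0), (2, 0, 0))]
        frames.append(make_hbond_frame(entries))
    windows.append((center, frames))

profile = hbond_profile(windows, HBondCriteria())
print(profile.table[["water", "lipids", "self", "total"]].round(2))
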