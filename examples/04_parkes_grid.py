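"""Grade glucose predictions on the type-2 Parkes consensus error grid.

Classifies a cloud of noisy "predictions" around the identity diagonal and
prints the zone distribution, then renders the grid with the scatter to
scratch/parkes_grid.png.
"""

import numpy as np

from cgmcast.clinical import parkes_zone, plot_parkes_scatter, zone_distribution

rng = np.random.default_rng(0)
reference = rng.uniform(50, 350, size=2000)
predicted = np.clip(reference + rng.normal(0, 25, size=2000), 0, 550)

dist = zone_distribution(reference, predicted)
print("zone distribution (% of predictions):")
for zone, pct in dist.items():
    print(f"  {zone}: {pct:5.1f}")
print(f"\nexact prediction   (120, 120) -> zone {parkes_zone(120, 120)}")
print(f"gross overshoot    (100, 350) -> zone {parkes_zone(100, 350)}")
print("Zone A means no effect on clinical action; D/E would mean a "
      "dangerous failure to detect or a false alarm.")

ax = plot_parkes_scatter(reference, predicted, title="synthetic predictions")
import pathlib
pathlib.Path("scratch").mkdir(exist_ok=True)
ax.figure.savefig("scratch/parkes_grid.png", dpi=120)
print("figure written to scratch/parkes_grid.png")
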