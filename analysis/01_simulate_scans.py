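#!/usr/bin/env python
"""Generate synthetic pre/post film-scan pairs for all three plaque models.

Writes each pair (plus the ground-truth dose raster and the generator
spec) under scratch/sims/<model>/ — these are the inputs every later
stage can be run against through the file-based interface.
"""

from pathlib import Path

from plaquefilm.plaque_geometry import load_model
from plaquefilm.synthetic_data import SyntheticSpec, simulate_dataset

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "sims"
CENTER_DOSE_GY = 1.8  # planar films after the 15-min irradiation


def main() -> None:
    for i, name in enumerate(("CCA", "COB", "CIB")):
        spec = SyntheticSpec(model=load_model(name), seed=100 + i)
        paths = simulate_dataset(spec, SCRATCH / name.lower(), center_dose_Gy=CENTER_DOSE_GY)
        print(f"{name}: wrote {paths['pre']}, {paths['post']} "
              f"(dpi {spec.dpi:.0f}, noise SD {spec.pixel_noise_sd:.0f} counts, seed {spec.seed})")
    print(f"done — scan pairs under {SCRATCH}")


if __name__ == "__main__":
    main()
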