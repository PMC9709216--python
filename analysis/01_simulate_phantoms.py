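"""Generate the study phantoms and write them to results/phantoms/.

Two synthetic datasets drive the whole validation study:

* a 64³ slab with a spatially uniform myocyte axis (HA=30°, IA=0°) —
  the geometry-free test bed for the orientation estimator;
* a 128³ truncated prolate-spheroidal shell (mid-wall Ra=100 µm,
  Rb=65 µm) carrying the linear +60°→−60° transmural helical-angle law,
  in a noise-free (kappa=inf) and a moderately disordered (kappa=20)
  variant.

Volumes and label masks are written as NRRD; the ground-truth axis
field of each phantom as a 3-component NRRD; the generating parameters
as YAML next to them.
"""

from pathlib import Path

import numpy as np
import yaml

import myoarch as ma
from myoarch.volume import write_nrrd, write_volume

OUT = Path(__file__).resolve().parent.parent / "results" / "phantoms"


def save(name, spec, volume, mask, truth):
    d = OUT / name
    d.mkdir(parents=True, exist_ok=True)
    write_volume(volume, d / "volume.nrrd")
    write_nrrd(d / "mask.nrrd", mask, (spec.voxel_size_um,) * 3)
    write_nrrd(d / "truth_axis.nrrd",
               np.moveaxis(truth.axis, -1, 0).astype(np.float32),
               (spec.voxel_size_um,) * 3, vector_axis=True)
    (d / "spec.yaml").write_text(yaml.safe_dump(spec.to_dict()))
    wall = int((mask > 0).sum())
    print(f"{name}: {volume.shape} volume, {wall} wall voxels -> {d}")


def main():
    slab = ma.PhantomSpec(shape=(64, 64, 64), geometry_kind="slab",
                          ha_endo_deg=30.0, ia_deg=0.0, seed=11)
    save("slab", slab, *ma.make_slab_phantom(slab))

    clean = ma.PhantomSpec(shape=(128, 128, 128), ha_endo_deg=60.0,
                           ha_epi_deg=-60.0, seed=4)
    vol, mask, truth, _ = ma.make_shell_phantom(clean)
    save("shell_clean", clean, vol, mask, truth)

    noisy = ma.PhantomSpec(shape=(128, 128, 128), ha_endo_deg=60.0,
                           ha_epi_deg=-60.0, kappa=20.0, seed=2)
    vol, mask, truth, _ = ma.make_shell_phantom(noisy)
    save("shell_kappa20", noisy, vol, mask, truth)


if __name__ == "__main__":
    main()
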