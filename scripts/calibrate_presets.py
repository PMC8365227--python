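"""Calibrate device-preset metal widths and max compaction factors.

Published single-device coverage values over a 5.27 mm neck on a 4 mm
parent artery are used as calibration targets:

    enterprise (laser-cut, single)   MCR 7.0 %
    lvis       (braided,  single)    MCR 20.4 %,  compacted 35.4 %
    pipeline   (braided,  single)    MCR 26.8 %,  compacted 47.8 %

Lattice pitches, wire counts and braid angles are fixed a priori at
values representative of the device classes; only the metal width (one
scalar per device) and the maximum compaction factor (braided devices)
are solved for, by bisection on the raster MCR.  Run from the repo root:

    python scripts/calibrate_presets.py

and paste the printed YAML into src/aneuflow/data/device_presets.yaml.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq

from aneuflow.stent_model import compact, compute_mcr, generate_pattern

NECK_RECT = (5.27e-3, math.pi * 4.0e-3)
RASTER = 4.0e-6  # fixed raster so the objective is smooth in width

FIXED = {
    "enterprise": dict(device_class="laser_cut",
                       axial_pitch=1.2e-3, circumferential_pitch=1.2e-3),
    "lvis": dict(device_class="braided", n_wires=16, braid_angle=65.0),
    "pipeline": dict(device_class="braided", n_wires=48, braid_angle=70.0),
}
TARGETS = {"enterprise": 0.070, "lvis": 0.204, "pipeline": 0.268}
COMPACTION_TARGETS = {"lvis": 0.354, "pipeline": 0.478}


def mcr_of_width(name: str, width: float) -> float:
    cfg = dict(FIXED[name])
    cls = cfg.pop("device_class")
    key = "strut_width" if cls == "laser_cut" else "wire_diameter"
    cfg[key] = width
    pat = generate_pattern(cls, cfg)
    return compute_mcr(pat, NECK_RECT, RASTER).mcr


def mcr_compacted(name: str, width: float, factor: float) -> float:
    cfg = dict(FIXED[name])
    cls = cfg.pop("device_class")
    cfg["wire_diameter"] = width
    pat = compact(generate_pattern(cls, cfg), factor)
    return compute_mcr(pat, NECK_RECT, RASTER).mcr


def main() -> None:
    out = {}
    for name, target in TARGETS.items():
        w = brentq(lambda w: mcr_of_width(name, w) - target,
                   1.6e-5, 1.5e-4, xtol=1e-9)
        out[name] = w
        print(f"{name}: width = {w * 1e3:.6f} mm  "
              f"(raster MCR {mcr_of_width(name, w):.4f})")
    for name, target in COMPACTION_TARGETS.items():
        w = out[name]
        f = brentq(lambda f: mcr_compacted(name, w, f) - target,
                   1.01, 4.0, xtol=1e-6)
        print(f"{name}: max_compaction = {f:.4f}  "
              f"(raster MCR {mcr_compacted(name, w, f):.4f})")


if __name__ == "__main__":
    main()
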