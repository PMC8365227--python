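"""Parametric virtual stent patterns and metal coverage rate (MCR).

A deployed device is modeled on the unrolled neck rectangle
(``neck_width`` axially x ``pi * parent_diameter`` circumferentially) as a
union of periodic stripe families:

* ``laser_cut`` -- a closed-cell diamond lattice, i.e. two strut families
  at +/-theta from the axial direction with theta set by the cell pitches;
* ``braided`` -- two counter-wound wire families at +/-braid_angle from
  the axial direction, ``n_wires`` wires per circumference in total.

Overlapping unions shifted copies of the lattice; compaction (braided
devices only) divides the axial pitch and steepens the braid angle, as a
push-pull maneuver does.  MCR is always measured by rasterizing the metal
mask, never from the analytic stripe formulas (those serve as independent
oracles in the tests).

Device presets (enterprise / lvis / pipeline) live in
``data/device_presets.yaml``; their widths and maximum compaction factors
were calibrated once against published single-device coverage values with
``scripts/calibrate_presets.py``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "DegeneratePatternError",
    "UnsupportedOperationError",
    "IncompatibilityError",
    "ResolutionError",
    "StentPattern",
    "MCRResult",
    "generate_pattern",
    "overlap",
    "compact",
    "compute_mcr",
    "solidity_profile",
    "load_presets",
    "preset_pattern",
    "DEFAULT_CIRCUMFERENCE",
]

#: unrolled circumference of the default 4 mm parent artery
DEFAULT_CIRCUMFERENCE = math.pi * 4.0e-3


class DegeneratePatternError(ValueError):
    """Strut/wire width at or beyond its pitch: the lattice closes up."""


class UnsupportedOperationError(ValueError):
    """Operation not defined for this device class."""


class IncompatibilityError(ValueError):
    """Patterns do not share a raster frame and cannot be combined."""


class ResolutionError(ValueError):
    """Raster spacing too coarse for the feature size."""


@dataclass(frozen=True)
class StentPattern:
    """A periodic planar metal lattice over the unrolled neck rectangle.

    ``width`` is the strut width (laser-cut) or wire diameter (braided).
    ``braid_angle`` is measured from the axial direction in degrees.
    ``layer_offsets`` holds one (axial, transverse) shift per layer, the
    first always (0, 0).  ``compaction_factor`` 1 means nominal.
    """

    device_class: str  # 'laser_cut' | 'braided'
    width: float
    axial_pitch: float
    circumferential_pitch: float | None = None  # laser-cut cell height
    n_wires: int | None = None                  # braided
    braid_angle: float | None = None            # degrees, braided
    circumference: float = DEFAULT_CIRCUMFERENCE
    lattice: str = "diamond"  # laser_cut: 'diamond' | 'orthogonal'
    layers: int = 1
    layer_offsets: tuple[tuple[float, float], ...] = ((0.0, 0.0),)
    compaction_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.device_class not in ("laser_cut", "braided"):
            raise ValueError(f"unknown device class {self.device_class!r}")
        if self.width <= 0:
            raise DegeneratePatternError("width must be positive")
        if self.compaction_factor < 1.0:
            raise ValueError("compaction_factor must be >= 1")
        if self.layers != len(self.layer_offsets):
            raise ValueError("need one (axial, transverse) offset per layer")
        if tuple(self.layer_offsets[0]) != (0.0, 0.0):
            raise ValueError("first layer offset must be (0, 0)")
        for _, p_perp, _ in self._families():
            if self.width >= p_perp:
                raise DegeneratePatternError(
                    f"width {self.width:g} >= effective pitch {p_perp:g}")

    # alias accessors matching device vocabulary
    @property
    def strut_width(self) -> float:
        return self.width

    @property
    def wire_diameter(self) -> float:
        return self.width

    def _families(self) -> list[tuple[float, float, float]]:
        """Stripe families as (angle_rad from axial, perpendicular pitch,
        phase).  The second family is phase-staggered by half a pitch so
        crossings of the two families do not align."""
        if self.device_class == "laser_cut":
            if self.lattice == "orthogonal":
                # axis-aligned rectangular strut grid (test/oracle pattern)
                return [(0.0, self.circumferential_pitch, 0.0),
                        (0.5 * math.pi, self.axial_pitch, 0.0)]
            theta = math.atan2(self.circumferential_pitch, self.axial_pitch)
            p_perp = self.circumferential_pitch * math.cos(theta)
        else:
            beta = math.radians(self.braid_angle)
            spacing_y = self.circumference / (self.n_wires // 2)
            p_perp = spacing_y * math.cos(beta)
            theta = beta
        return [(theta, p_perp, 0.0), (-theta, p_perp, 0.5 * p_perp)]

    def metal(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean metal indicator at points (x, y) of the unrolled neck."""
        out = np.zeros(np.broadcast(x, y).shape, dtype=bool)
        half_w = 0.5 * self.width
        for dx, dy in self.layer_offsets:
            xs, ys = x - dx, y - dy
            for theta, p_perp, phase in self._families():
                proj = -math.sin(theta) * xs + math.cos(theta) * ys
                d = np.mod(proj - phase, p_perp)
                out |= (d < half_w) | (d > p_perp - half_w)
        return out


@dataclass(frozen=True)
class MCRResult:
    """Raster measurement of the metal coverage rate over the neck."""

    mcr: float
    metal_mask: np.ndarray
    raster_spacing: float

    def __post_init__(self) -> None:
        frac = float(np.count_nonzero(self.metal_mask)) / self.metal_mask.size
        if abs(frac - self.mcr) > 1e-12:
            raise ValueError("mcr must equal the exact mask fraction")


def generate_pattern(device_class: str, params: dict) -> StentPattern:
    """Build a single-layer pattern from device parameters.

    Laser-cut params: ``strut_width``, ``axial_pitch``,
    ``circumferential_pitch``.  Braided params: ``wire_diameter``,
    ``n_wires``, ``braid_angle`` (degrees).  Optional for both:
    ``circumference``.  Lengths in meters.
    """
    circ = params.get("circumference", DEFAULT_CIRCUMFERENCE)
    if device_class == "laser_cut":
        return StentPattern(
            device_class="laser_cut",
            width=params["strut_width"],
            axial_pitch=params["axial_pitch"],
            circumferential_pitch=params["circumferential_pitch"],
            circumference=circ,
            lattice=params.get("lattice", "diamond"),
        )
    if device_class == "braided":
        n_wires = int(params["n_wires"])
        if n_wires < 4 or n_wires % 2:
            raise ValueError("n_wires must be an even count >= 4")
        beta = float(params["braid_angle"])
        if not 0.0 < beta < 90.0:
            raise ValueError("braid_angle must be in (0, 90) degrees")
        spacing_y = circ / (n_wires // 2)
        axial_pitch = spacing_y / math.tan(math.radians(beta))
        return StentPattern(
            device_class="braided",
            width=params["wire_diameter"],
            axial_pitch=axial_pitch,
            n_wires=n_wires,
            braid_angle=beta,
            circumference=circ,
        )
    raise ValueError(f"unknown device class {device_class!r}")


def overlap(patterns: list[StentPattern],
            offsets: list[tuple[float, float]] | None = None) -> StentPattern:
    """Union several telescoped copies of the same device into one pattern.

    All patterns must share the raster frame (device class and lattice
    parameters).  Default offsets shift each successive layer axially by
    ``axial_pitch / (2 * n_layers)`` -- a constant inter-layer gap.
    """
    if not patterns:
        raise ValueError("need at least one pattern")
    base = patterns[0]
    for p in patterns[1:]:
        same = (p.device_class == base.device_class
                and p.width == base.width
                and p.axial_pitch == base.axial_pitch
                and p.circumferential_pitch == base.circumferential_pitch
                and p.n_wires == base.n_wires
                and p.braid_angle == base.braid_angle
                and p.circumference == base.circumference)
        if not same:
            raise IncompatibilityError(
                "overlapped patterns must share the same raster frame")
    n_total = sum(p.layers for p in patterns)
    if offsets is None:
        gap = base.axial_pitch / (2.0 * n_total)
        offsets = [(k * gap, 0.0) for k in range(len(patterns))]
    if len(offsets) != len(patterns):
        raise ValueError("need one offset per pattern")
    if tuple(offsets[0]) != (0.0, 0.0):
        raise ValueError("first pattern must stay unshifted")
    all_offsets: list[tuple[float, float]] = []
    for p, (dx, dy) in zip(patterns, offsets):
        for (lx, ly) in p.layer_offsets:
            all_offsets.append((lx + dx, ly + dy))
    return replace(base, layers=n_total, layer_offsets=tuple(all_offsets))


def compact(pattern: StentPattern, factor: float) -> StentPattern:
    """Axially compress a braided pattern by ``factor`` (push-pull).

    The axial pitch is divided by the factor and the braid angle is
    recomputed so the wires themselves are only reoriented, not resized:
    tan(beta') = factor * tan(beta).  Laser-cut cells are rigid and the
    operation is rejected for them.
    """
    if pattern.device_class != "braided":
        raise UnsupportedOperationError(
            "only braided devices can be compacted")
    if factor < 1.0:
        raise ValueError("compaction factor must be >= 1")
    if factor == 1.0:
        return pattern
    beta = math.radians(pattern.braid_angle)
    beta_new = math.degrees(math.atan(factor * math.tan(beta)))
    # compaction shrinks offsets along with the lattice
    new_offsets = tuple((dx / factor, dy) for dx, dy in pattern.layer_offsets)
    return replace(
        pattern,
        axial_pitch=pattern.axial_pitch / factor,
        braid_angle=beta_new,
        layer_offsets=new_offsets,
        compaction_factor=pattern.compaction_factor * factor,
    )


def compute_mcr(pattern: StentPattern | None,
                neck_rect: tuple[float, float],
                raster_spacing: float | None = None) -> MCRResult:
    """Raster the metal mask over ``neck_rect`` = (axial, circumferential)
    extents and return the exact covered fraction.

    Default raster spacing is width/8; anything coarser than width/4 is
    refused.  ``pattern=None`` means an empty (metal-free) neck.
    """
    lx, ly = neck_rect
    if pattern is None:
        spacing = raster_spacing or min(lx, ly) / 64.0
        nx = max(int(round(lx / spacing)), 1)
        nyc = max(int(round(ly / spacing)), 1)
        mask = np.zeros((nx, nyc), dtype=bool)
        return MCRResult(mcr=0.0, metal_mask=mask, raster_spacing=spacing)
    if raster_spacing is None:
        raster_spacing = pattern.width / 8.0
    if raster_spacing > pattern.width / 4.0:
        raise ResolutionError(
            "raster spacing must be at most a quarter of the metal width")
    nx = max(int(round(lx / raster_spacing)), 1)
    nyc = max(int(round(ly / raster_spacing)), 1)
    x = (np.arange(nx) + 0.5) * (lx / nx)
    y = (np.arange(nyc) + 0.5) * (ly / nyc)
    mask = pattern.metal(x[:, None], y[None, :])
    mcr = float(np.count_nonzero(mask)) / mask.size
    return MCRResult(mcr=mcr, metal_mask=mask, raster_spacing=raster_spacing)


def solidity_profile(pattern: StentPattern | None,
                     neck_rect: tuple[float, float],
                     n_positions: int,
                     raster_spacing: float | None = None) -> np.ndarray:
    """Column-averaged metal fraction along the neck chord.

    Returns ``n_positions`` solidity samples, one per flow-grid neck face,
    by averaging the metal mask circumferentially within equal axial bins.
    The mean of the profile equals the raster MCR up to binning remainder.
    """
    res = compute_mcr(pattern, neck_rect, raster_spacing)
    nx = res.metal_mask.shape[0]
    col_frac = res.metal_mask.mean(axis=1)
    edges = np.linspace(0, nx, n_positions + 1)
    prof = np.empty(n_positions)
    for k in range(n_positions):
        lo, hi = int(edges[k]), max(int(edges[k + 1]), int(edges[k]) + 1)
        prof[k] = col_frac[lo:hi].mean()
    return prof


# ---------------------------------------------------------------------------
# presets

def load_presets() -> dict:
    """Device preset registry (lengths in mm inside the file)."""
    text = (resources.files("aneuflow.data") / "device_presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_pattern(name: str, layers: int = 1,
                   compaction: float | str = 1.0) -> StentPattern:
    """Instantiate a preset device, optionally overlapped and compacted.

    ``compaction`` may be a numeric factor or ``"max"`` for the preset's
    calibrated maximum.  Compaction is applied after overlapping, to the
    combined pattern, matching a push-pull on the deployed stack.
    """
    presets = load_presets()
    if name not in presets:
        raise KeyError(f"unknown device preset {name!r}; "
                       f"have {sorted(presets)}")
    cfg = presets[name]
    params = {k: v * 1e-3 for k, v in cfg.items()
              if k.endswith("_mm")}
    params = {k[:-3]: v for k, v in params.items()}
    params["n_wires"] = cfg.get("n_wires")
    params["braid_angle"] = cfg.get("braid_angle_deg")
    params = {k: v for k, v in params.items() if v is not None}
    single = generate_pattern(cfg["device_class"], params)
    pattern = overlap([single] * layers) if layers > 1 else single
    if compaction == "max":
        compaction = cfg.get("max_compaction", 1.0)
    if compaction != 1.0:
        pattern = compact(pattern, float(compaction))
    return pattern
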