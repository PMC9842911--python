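"""Construction of the modelled vascular unit from mass-flux conservation.

The unit is centred on the principal intracortical veins (V1-V4, classed
by penetration depth) surrounded by an arterial ring with a 2-to-1
artery-to-vein ratio.  At steady state the blood mass flux through a
vessel trunk in a given layer equals the flux drained from the capillary
bed of that layer plus the flux accumulated in deeper layers.  With a
linear velocity-diameter relation v = alpha * d the flux is

    p = r^2 * v = d^3 * alpha / 4        (the constant pi is dropped
                                          consistently throughout)

which lets diameters and velocities of every vein and artery be derived
from per-layer capillary counts, and conversely capillary counts from a
table of vein diameters.

Baseline cerebral blood volume (CBV) has two parts: the laminar network
(arterioles, capillaries, venules; depth-dependent, 2.0-2.7% of voxel
volume, mean 2.3%) and the intracortical vessels, whose per-depth CBV
follows pi*d^2/4 / l^2 per vessel, calibrated to peak at 1.4% (veins)
and 1.2% (arteries) at the surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import DEFAULT_GRID, LAYER_ORDER, DepthGrid

# --------------------------------------------------------------------------
# Microvascular reference values (velocity-diameter relation)
# --------------------------------------------------------------------------

#: Single-capillary geometry: d = 8 um, v = 1.6 mm/s.
CAPILLARY_DIAMETER_UM = 8.0
CAPILLARY_VELOCITY_UM_S = 1600.0

#: Post-capillary (venous) velocity-to-diameter ratio: v=2 mm/s at d=12.5 um.
ALPHA_POST = 2000.0 / 12.5  # 160 s^-1
#: Pre-capillary (arterial) ratio: v=4 mm/s at d=12.5 um.
ALPHA_PRE = 4000.0 / 12.5  # 320 s^-1

#: Each vein's drainage territory is supplied by twice as many arteries,
#: so the paired artery carries half the vein trunk flux.
ARTERY_VEIN_RATIO = 2.0

#: Reference average diameters (um) of the intracortical veins by the
#: deepest layer they reach, from histology-anchored estimates for human
#: V1.  These are the anchor data from which the default capillary
#: allocation is inverted.
REFERENCE_VEIN_DIAMETERS_UM: dict[str, dict[str, float]] = {
    "V4": {"VI": 44.0, "V": 56.0, "IV": 62.0, "II/III": 67.0, "I": 69.0},
    "V3": {"IV": 41.0, "II/III": 51.0, "I": 53.0},
    "V2": {"II/III": 26.0, "I": 32.0},
    "V1": {"I": 20.0},
}

ARTERY_OF_VEIN = {"V4": "A4", "V3": "A3", "V2": "A2", "V1": "A1"}
VEIN_OF_ARTERY = {a: v for v, a in ARTERY_OF_VEIN.items()}

#: Vessels per voxel footprint.  Veins: one of each class.  Arteries: the
#: unit's ring pairs two A3 and two A4 with the principal veins; the
#: smaller A1/A2 classes are more numerous, and their counts are the
#: calibration knob for the printed intracortical CBV ranges.
DEFAULT_VEIN_MULTIPLICITY = {"V4": 1, "V3": 1, "V2": 1, "V1": 1}
DEFAULT_ARTERY_MULTIPLICITY = {"A4": 2, "A3": 2, "A2": 3, "A1": 4}

#: Across-depth maxima of intracortical baseline CBV (volume fractions).
ICV_CBV_MAX = 0.014
ICA_CBV_MAX = 0.012

# --------------------------------------------------------------------------
# Laminar (microvascular) baseline
# --------------------------------------------------------------------------

#: Depth-dependent laminar baseline CBV (fraction of voxel volume), white
#: matter border first.  Synthetic stand-in for the smooth, mid-peaked
#: microvascular density curve measured in macaque V1: minimum 2.0% at the
#: WM border, maximum 2.7% in the middle of the cortex (layer IV), mean
#: exactly 2.3%.
LAMINAR_CBV_PROFILE = np.array(
    [2.00, 2.10, 2.25, 2.45, 2.70, 2.60, 2.45, 2.30, 2.10, 2.05]
) / 100.0

#: Average split of the laminar volume between compartments (human
#: cortex: arterial side denser than venous).
LAMINAR_SPLIT = {"arterioles": 0.43, "capillaries": 0.36, "venules": 0.21}
#: Rodent-like alternative with the arteriole:venule ratio reversed.
LAMINAR_SPLIT_REVERSED = {"arterioles": 0.21, "capillaries": 0.36, "venules": 0.43}

#: Amplitude of the linear depth tilt of the venular volume share: venous
#: drainage converges toward the intracortical veins, so the venular share
#: of the laminar bed rises toward the surface while the arteriolar share
#: is larger at depth.  The volume-weighted mean shares stay exactly at
#: the split above.
VENULE_SHARE_TILT = 0.04

MICRO_COMPARTMENTS = ("arterioles", "capillaries", "venules")
COMPARTMENTS = ("arterioles", "capillaries", "venules", "icas", "icvs")


def capillary_flux(radius_um: float, velocity_um_s: float) -> float:
    """Mass flux p = r^2 * v through a single vessel (um^3/s, pi dropped)."""
    if radius_um < 0 or velocity_um_s < 0:
        raise ValueError("radius and velocity must be non-negative")
    return radius_um**2 * velocity_um_s


#: Flux through one capillary (d = 8 um, v = 1.6 mm/s): 25 600 um^3/s.
P_CAP = capillary_flux(CAPILLARY_DIAMETER_UM / 2.0, CAPILLARY_VELOCITY_UM_S)


def geometry_from_flux(flux_um3_s: float, alpha: float) -> tuple[float, float]:
    """Diameter (um) and velocity (mm/s) of a trunk carrying a given flux.

    Inverts p = d^3 * alpha / 4 and applies v = alpha * d.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if flux_um3_s < 0:
        raise ValueError("flux must be non-negative")
    d = (4.0 * flux_um3_s / alpha) ** (1.0 / 3.0)
    return d, alpha * d / 1000.0


def artery_diameter_from_vein(
    d_vein_um: float,
    alpha_pre: float = ALPHA_PRE,
    alpha_post: float = ALPHA_POST,
) -> float:
    """Diameter of the artery paired with a vein of diameter ``d_vein_um``.

    The vein trunk flux d_v^3*alpha_post/4 is split over twice as many
    arteries, so d_a = d_v * (alpha_post / (2*alpha_pre))^(1/3); with the
    default alphas this is d_v * (1/4)^(1/3) ~ 0.63 d_v.
    """
    if d_vein_um < 0:
        raise ValueError("diameter must be non-negative")
    if alpha_pre <= 0 or alpha_post <= 0:
        raise ValueError("alpha values must be positive")
    return d_vein_um * (alpha_post / (ARTERY_VEIN_RATIO * alpha_pre)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class CapillaryAllocation:
    """Number of capillaries drained by each vein in each layer."""

    n_caps: Mapping[tuple[str, str], int]

    def count(self, vein: str, layer: str) -> int:
        return int(self.n_caps.get((vein, layer), 0))

    def veins(self) -> tuple[str, ...]:
        return tuple(sorted({v for v, _ in self.n_caps}))

    def total(self, vein: str) -> int:
        return sum(n for (v, _), n in self.n_caps.items() if v == vein)


def allocation_from_vein_diameters(
    vein_diameters: Mapping[str, Mapping[str, float]] | None = None,
    alpha_post: float = ALPHA_POST,
    p_cap: float = P_CAP,
) -> CapillaryAllocation:
    """Invert a per-layer vein diameter table into capillary counts.

    The count added in a layer is the flux increment between the layer and
    the next deeper one, divided by the single-capillary flux:

        n(vein, layer) = round((d_layer^3 - d_deeper^3) * alpha / (4 * p_cap))

    with d = 0 below the vein's deepest layer.  Feeding the result forward
    through :func:`cumulative_flux` and :func:`geometry_from_flux`
    reproduces the input diameters to well under 0.5 um.
    """
    if vein_diameters is None:
        vein_diameters = REFERENCE_VEIN_DIAMETERS_UM
    counts: dict[tuple[str, str], int] = {}
    for vein, by_layer in vein_diameters.items():
        d_prev = 0.0
        for layer in LAYER_ORDER:
            if layer not in by_layer:
                continue
            d = float(by_layer[layer])
            if d < d_prev:
                raise ValueError(
                    f"{vein}: diameter decreases toward the surface at layer {layer}"
                )
            n = float(np.rint((d**3 - d_prev**3) * alpha_post / (4.0 * p_cap)))
            counts[(vein, layer)] = int(n)
            d_prev = d
    return CapillaryAllocation(counts)


def cumulative_flux(
    allocation: CapillaryAllocation,
    vessel: str,
    grid: DepthGrid = DEFAULT_GRID,
    p_cap: float = P_CAP,
) -> np.ndarray:
    """Per-depth trunk flux (um^3/s) of an intracortical vessel.

    Flux accumulates from the white-matter border: within each layer the
    trunk carries the capillary flux drained in that layer plus everything
    from deeper layers.  Depths below the vessel's deepest layer carry 0.
    Arteries carry the paired vein's flux divided by the 2:1 artery count.
    """
    if vessel in VEIN_OF_ARTERY:
        return cumulative_flux(allocation, VEIN_OF_ARTERY[vessel], grid, p_cap) / ARTERY_VEIN_RATIO
    if vessel not in ARTERY_OF_VEIN:
        raise ValueError(f"unknown intracortical vessel class {vessel!r}")

    flux = np.zeros(grid.n_depths)
    cum = 0.0
    started = False
    for layer in LAYER_ORDER:  # deep -> surface
        n = allocation.count(vessel, layer)
        if n:
            started = True
        cum += n * p_cap
        if started:
            flux[grid.depths_of_layer(layer)] = cum
    return flux


# --------------------------------------------------------------------------
# Baseline CBV
# --------------------------------------------------------------------------


def laminar_compartment_fractions(
    grid: DepthGrid = DEFAULT_GRID,
    total_profile: np.ndarray | None = None,
    split: Mapping[str, float] | None = None,
    tilt: float = VENULE_SHARE_TILT,
) -> dict[str, np.ndarray]:
    """Per-depth volume share of each laminar compartment.

    Shares sum to 1 at every depth.  The venular share rises linearly
    toward the surface and the arteriolar share falls by the same amount;
    the tilt is centred so that the CBV-weighted mean shares equal the
    prescribed split exactly.
    """
    if split is None:
        split = LAMINAR_SPLIT
    if total_profile is None:
        total_profile = LAMINAR_CBV_PROFILE
    w = np.asarray(total_profile, dtype=float)
    ramp = np.linspace(-1.0, 1.0, grid.n_depths)
    delta = tilt * (ramp - np.average(ramp, weights=w))
    fractions = {
        "arterioles": split["arterioles"] - delta,
        "capillaries": np.full(grid.n_depths, split["capillaries"]),
        "venules": split["venules"] + delta,
    }
    for name, f in fractions.items():
        if np.any(f <= 0) or np.any(f >= 1):
            raise ValueError(f"{name} volume share left (0, 1); reduce the tilt")
    return fractions


def laminar_baseline(
    mode: str = "depth_dependent",
    grid: DepthGrid = DEFAULT_GRID,
    profile: np.ndarray | None = None,
    split: Mapping[str, float] | None = None,
    tilt: float = VENULE_SHARE_TILT,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Baseline CBV of the laminar network.

    Returns the per-depth total (volume fraction) and its decomposition
    into arterioles, capillaries and venules.

    ``mode="depth_dependent"`` uses the packaged mid-peaked curve
    (min 2.0%, max 2.7% at a middle depth, mean 2.3%);
    ``mode="constant"`` uses the across-depth average, a flat 2.3%.
    """
    if mode == "depth_dependent":
        total = LAMINAR_CBV_PROFILE.copy() if profile is None else np.asarray(profile, float)
    elif mode == "constant":
        base = LAMINAR_CBV_PROFILE if profile is None else np.asarray(profile, float)
        total = np.full(grid.n_depths, float(np.mean(base)))
    else:
        raise ValueError(f"unknown laminar baseline mode {mode!r}")
    if total.shape != (grid.n_depths,):
        raise ValueError("baseline profile length must match the depth grid")
    if np.any(total <= 0) or np.any(total >= 1):
        raise ValueError("baseline CBV values must lie in (0, 1)")
    fractions = laminar_compartment_fractions(grid, total, split, tilt)
    return total, {name: total * f for name, f in fractions.items()}


def intracortical_baseline(
    diameters_um: Mapping[str, np.ndarray],
    multiplicity: Mapping[str, int],
    grid: DepthGrid = DEFAULT_GRID,
    scale: float = 1.0,
) -> np.ndarray:
    """Per-depth baseline CBV fraction of a set of diving vessels.

    Each vessel contributes multiplicity * (pi d^2 / 4) / l^2 at every
    depth it reaches; ``scale`` is the per-class census calibration.
    """
    if grid.voxel_footprint_um <= 0:
        raise ValueError("voxel footprint must be positive")
    cbv = np.zeros(grid.n_depths)
    for vessel, d in diameters_um.items():
        d = np.asarray(d, dtype=float)
        cbv += multiplicity.get(vessel, 1) * math.pi * d**2 / 4.0 / grid.footprint_area_um2
    return scale * cbv


# --------------------------------------------------------------------------
# The assembled unit
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VascularUnit:
    """Constructed vascular unit: geometry plus baseline blood volume.

    Attributes
    ----------
    grid : DepthGrid
    diameters_um, velocities_mm_s : dict
        Per vessel class (V1..V4, A1..A4), arrays over depth; zero where
        the vessel does not reach.
    cbv_base : dict
        Baseline CBV fraction per compartment (arterioles, capillaries,
        venules, icas, icvs), arrays over depth.
    allocation : CapillaryAllocation
    laminar_split : dict
        Volume-weighted mean compartment shares of the laminar network.
    baseline_mode : str
        "depth_dependent" or "constant" laminar baseline.
    """

    grid: DepthGrid
    diameters_um: Mapping[str, np.ndarray]
    velocities_mm_s: Mapping[str, np.ndarray]
    cbv_base: Mapping[str, np.ndarray]
    allocation: CapillaryAllocation
    laminar_split: Mapping[str, float]
    baseline_mode: str
    census: Mapping[str, int] = field(default_factory=dict)
    calibration_scales: Mapping[str, float] = field(default_factory=dict)

    @property
    def total_cbv_base(self) -> np.ndarray:
        return np.sum([self.cbv_base[c] for c in COMPARTMENTS], axis=0)

    def vessel_table(self) -> pd.DataFrame:
        """Long-format table vessel,layer,diameter_um,velocity_mm_s."""
        rows = []
        for vessel in sorted(self.diameters_um):
            d = self.diameters_um[vessel]
            v = self.velocities_mm_s[vessel]
            for layer in self.grid.layers_present():
                i = self.grid.depths_of_layer(layer)[0]
                if d[i] > 0:
                    rows.append(
                        {"vessel": vessel, "layer": layer,
                         "diameter_um": float(d[i]), "velocity_mm_s": float(v[i])}
                    )
        return pd.DataFrame(rows, columns=["vessel", "layer", "diameter_um", "velocity_mm_s"])

    def reported_diameters(self) -> dict[str, dict[str, int]]:
        """Diameters rounded to integer um, keyed vessel -> layer."""
        out: dict[str, dict[str, int]] = {}
        for vessel, d in self.diameters_um.items():
            by_layer = {}
            for layer in self.grid.layers_present():
                i = self.grid.depths_of_layer(layer)[0]
                if d[i] > 0:
                    by_layer[layer] = int(np.rint(d[i]))
            out[vessel] = by_layer
        return out


def build_vascular_unit(
    grid: DepthGrid = DEFAULT_GRID,
    baseline_mode: str = "depth_dependent",
    vein_diameters: Mapping[str, Mapping[str, float]] | None = None,
    allocation: CapillaryAllocation | None = None,
    vein_multiplicity: Mapping[str, int] | None = None,
    artery_multiplicity: Mapping[str, int] | None = None,
    laminar_split: str | Mapping[str, float] = "human",
    laminar_profile: np.ndarray | None = None,
    venule_share_tilt: float = VENULE_SHARE_TILT,
    icv_cbv_max: float = ICV_CBV_MAX,
    ica_cbv_max: float = ICA_CBV_MAX,
) -> VascularUnit:
    """Build the default vascular unit of human V1.

    Vein geometry is derived from the capillary allocation by the
    mass-flux recursion; arteries carry half the paired vein flux with the
    pre-capillary alpha.  Intracortical baseline CBV profiles are scaled
    so their across-depth maxima match ``icv_cbv_max``/``ica_cbv_max``.
    """
    if allocation is None:
        allocation = allocation_from_vein_diameters(vein_diameters)

    diameters: dict[str, np.ndarray] = {}
    velocities: dict[str, np.ndarray] = {}
    for vein, artery in ARTERY_OF_VEIN.items():
        for vessel, alpha in ((vein, ALPHA_POST), (artery, ALPHA_PRE)):
            flux = cumulative_flux(allocation, vessel, grid)
            d = np.zeros(grid.n_depths)
            v = np.zeros(grid.n_depths)
            nz = flux > 0
            if nz.any():
                d[nz] = (4.0 * flux[nz] / alpha) ** (1.0 / 3.0)
                v[nz] = alpha * d[nz] / 1000.0
            diameters[vessel] = d
            velocities[vessel] = v

    if isinstance(laminar_split, str):
        split = {"human": LAMINAR_SPLIT, "rat": LAMINAR_SPLIT_REVERSED}[laminar_split]
    else:
        split = dict(laminar_split)

    _, laminar = laminar_baseline(
        baseline_mode, grid, profile=laminar_profile, split=split, tilt=venule_share_tilt
    )

    vein_mult = dict(DEFAULT_VEIN_MULTIPLICITY if vein_multiplicity is None else vein_multiplicity)
    art_mult = dict(
        DEFAULT_ARTERY_MULTIPLICITY if artery_multiplicity is None else artery_multiplicity
    )
    icv_raw = intracortical_baseline(
        {v: diameters[v] for v in ARTERY_OF_VEIN}, vein_mult, grid
    )
    ica_raw = intracortical_baseline(
        {a: diameters[a] for a in VEIN_OF_ARTERY}, art_mult, grid
    )
    scale_icv = icv_cbv_max / icv_raw.max()
    scale_ica = ica_cbv_max / ica_raw.max()

    cbv = dict(laminar)
    cbv["icvs"] = scale_icv * icv_raw
    cbv["icas"] = scale_ica * ica_raw

    total = np.sum([cbv[c] for c in COMPARTMENTS], axis=0)
    if np.any(total >= 1.0):
        raise ValueError("total baseline CBV reaches 100% of the voxel")

    return VascularUnit(
        grid=grid,
        diameters_um=diameters,
        velocities_mm_s=velocities,
        cbv_base=cbv,
        allocation=allocation,
        laminar_split=split,
        baseline_mode=baseline_mode,
        census={**vein_mult, **art_mult},
        calibration_scales={"icvs": scale_icv, "icas": scale_ica},
    )
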