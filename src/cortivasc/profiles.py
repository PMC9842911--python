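"""Depth-dependent BOLD and VASO percent-signal-change profiles.

Combines a :class:`~cortivasc.vascular.VascularUnit` with hemodynamic
parameters (per-compartment blood-volume change and oxygen saturations)
into smoothed depth profiles.

Activation strength is depth-dependent: the relative CBV change at a
depth is beta(depth)/beta(middle) times the prescribed middle-layer
change dCBV_mid, with beta = 1.5 in middle layers (and, for the diving
vessels, also in superficial layers that drain them) and beta = 1
elsewhere.  Simulated profiles are convolved with a small partial-volume
kernel and the two zero-padded edge depths are dropped, leaving 8 valid
points on the default 10-depth grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .grid import DEFAULT_GRID, DepthGrid
from .signal import (
    DEFAULT_ACQUISITION,
    DEFAULT_RELAXATION,
    AcquisitionConstants,
    RelaxationConstants,
    bold_percent_change,
    vaso_percent_change,
)
from .vascular import COMPARTMENTS, VascularUnit

__all__ = [
    "HemodynamicParams",
    "DepthProfile",
    "DEFAULT_SMOOTHING_KERNEL",
    "BETA_ELEVATED",
    "beta_profile",
    "apply_activation",
    "smooth_profile",
    "simulate_profile",
    "reported_group_changes",
]

#: Partial-volume smoothing kernel (normalised); one-voxel support on
#: each side, approximating the point spread of depth sampling.
DEFAULT_SMOOTHING_KERNEL = (0.2, 0.6, 0.2)

#: Activation elevation factor for middle layers (laminar network) and
#: middle+superficial layers (intracortical vessels).
BETA_ELEVATED = 1.5

#: Compartment class of each compartment for the beta scheme.
_BETA_CLASS = {
    "arterioles": "laminar",
    "capillaries": "laminar",
    "venules": "laminar",
    "icas": "intracortical",
    "icvs": "intracortical",
}

_DEFAULT_Y_BASE = {
    "arterioles": 0.95,
    "capillaries": 0.85,
    "venules": 0.70,
    "icvs": 0.70,
    "icas": 0.95,
}
_DEFAULT_Y_ACT = {
    "arterioles": 1.00,
    "capillaries": 0.95,
    "venules": 0.90,
    "icvs": 0.90,
    "icas": 1.00,
}


@dataclass(frozen=True)
class HemodynamicParams:
    """Per-compartment blood-volume and oxygenation changes.

    Parameters
    ----------
    dcbv_mid : mapping
        Middle-layer relative CBV change per compartment, in percent of
        baseline (0-90).  Arterioles and capillaries are conventionally
        coupled to one value when fitting.
    y_base, y_act : mapping
        Oxygen saturation (fraction) per compartment at baseline and
        activation.  Venules and ICVs share one value when fitting.
    equal_activation : bool
        If True, beta = 1 at every depth (uniform activation strength).
    """

    dcbv_mid: Mapping[str, float] = field(
        default_factory=lambda: dict.fromkeys(COMPARTMENTS, 0.0)
    )
    y_base: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_Y_BASE))
    y_act: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_Y_ACT))
    equal_activation: bool = False

    def __post_init__(self) -> None:
        for comp in COMPARTMENTS:
            d = self.dcbv_mid.get(comp, 0.0)
            if not 0.0 <= d <= 90.0:
                raise ValueError(f"dCBV_mid[{comp}] = {d} outside [0, 90]%")
            for y_map, name in ((self.y_base, "y_base"), (self.y_act, "y_act")):
                y = y_map.get(comp)
                if y is None or not 0.0 <= y <= 1.0:
                    raise ValueError(f"{name}[{comp}] missing or outside [0, 1]")

    def with_dcbv(self, **dcbv_mid: float) -> "HemodynamicParams":
        new = dict(self.dcbv_mid)
        new.update(dcbv_mid)
        return replace(self, dcbv_mid=new)

    def with_venous_oxygenation(self, y_base: float, y_act: float) -> "HemodynamicParams":
        """Set the coupled venule/ICV saturation pair."""
        yb = dict(self.y_base)
        ya = dict(self.y_act)
        yb["venules"] = yb["icvs"] = y_base
        ya["venules"] = ya["icvs"] = y_act
        return replace(self, y_base=yb, y_act=ya)


@dataclass(frozen=True)
class DepthProfile:
    """Percent-signal-change values over cortical depth.

    ``values`` holds one value per retained depth; ``depth_indices`` are
    the 1-based depth indices (2..9 after trimming on the default grid).
    VASO values follow the activation-positive display convention.
    """

    values: np.ndarray
    contrast: str
    smoothed: bool = True
    trimmed: bool = True
    depth_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")
        if self.depth_indices is None:
            start = 2 if self.trimmed else 1
            object.__setattr__(
                self,
                "depth_indices",
                np.arange(start, start + self.values.size),
            )


def beta_profile(
    compartment_class: str,
    grid: DepthGrid = DEFAULT_GRID,
    equal_activation: bool = False,
    elevated: float = BETA_ELEVATED,
) -> np.ndarray:
    """Per-depth activation scale beta.

    Laminar network: ``elevated`` in middle depths, 1 elsewhere.
    Intracortical vessels: ``elevated`` in middle and superficial depths
    (they drain the activated middle layers), 1 in deep depths.
    ``equal_activation`` returns all ones.
    """
    if compartment_class not in ("laminar", "intracortical"):
        raise ValueError(f"unknown compartment class {compartment_class!r}")
    if equal_activation:
        return np.ones(grid.n_depths)
    beta = np.ones(grid.n_depths)
    beta[grid.group_mask("middle")] = elevated
    if compartment_class == "intracortical":
        beta[grid.group_mask("superficial")] = elevated
    return beta


def relative_change_profile(
    compartment: str,
    params: HemodynamicParams,
    grid: DepthGrid = DEFAULT_GRID,
) -> np.ndarray:
    """Per-depth relative CBV change (fraction of baseline CBV).

    The prescribed dCBV_mid applies at middle depths; other depths are
    scaled by beta(depth)/beta(middle), i.e. divided by 1.5 outside the
    elevated region (everywhere equal under equal_activation).
    """
    beta = beta_profile(
        _BETA_CLASS[compartment], grid, equal_activation=params.equal_activation
    )
    beta_mid = beta[grid.group_mask("middle")][0]
    return params.dcbv_mid.get(compartment, 0.0) / 100.0 * beta / beta_mid


def apply_activation(
    unit: VascularUnit,
    params: HemodynamicParams,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Baseline and activation CBV maps (compartment -> per-depth fraction).

    CBV_act = CBV_base * (1 + beta/beta_mid * dCBV_mid).
    """
    base = {c: np.asarray(unit.cbv_base[c], dtype=float) for c in COMPARTMENTS}
    act = {
        c: base[c] * (1.0 + relative_change_profile(c, params, unit.grid))
        for c in COMPARTMENTS
    }
    total_act = np.sum([act[c] for c in COMPARTMENTS], axis=0)
    if np.any(total_act >= 1.0):
        raise ValueError("activated total CBV reaches 100% of the voxel")
    return base, act


def smooth_profile(values: np.ndarray, kernel=DEFAULT_SMOOTHING_KERNEL) -> np.ndarray:
    """Zero-padded convolution with a normalised kernel; keeps length."""
    values = np.asarray(values, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size > values.size:
        raise ValueError("kernel longer than the profile")
    if not np.isclose(kernel.sum(), 1.0):
        raise ValueError("smoothing kernel must be normalised to sum 1")
    return np.convolve(values, kernel, mode="same")


def _trim(values: np.ndarray) -> np.ndarray:
    """Drop the two edge depths contaminated by zero padding."""
    return values[1:-1]


def simulate_profile(
    unit: VascularUnit,
    params: HemodynamicParams,
    contrast: str,
    acq: AcquisitionConstants = DEFAULT_ACQUISITION,
    relax: RelaxationConstants = DEFAULT_RELAXATION,
    smoothing: bool = True,
    trim: bool = True,
    kernel=DEFAULT_SMOOTHING_KERNEL,
) -> DepthProfile:
    """Simulate a depth-dependent percent-signal-change profile.

    VASO: per depth, -100 * sum_i dCBV_abs_i / (1 - CBV_base,tot), then
    negated so that activation plots positive.  BOLD: full intra- plus
    extravascular signal assembly at baseline and activation.
    """
    contrast = contrast.lower()
    if contrast not in ("vaso", "bold"):
        raise ValueError(f"unknown contrast {contrast!r}")

    base, act = apply_activation(unit, params)
    if contrast == "vaso":
        cbv_base_tot = np.sum([base[c] for c in COMPARTMENTS], axis=0)
        dcbv_abs = np.sum([act[c] - base[c] for c in COMPARTMENTS], axis=0)
        raw = -vaso_percent_change(cbv_base_tot, dcbv_abs)  # activation-positive
    else:
        y_base = np.array([params.y_base[c] for c in COMPARTMENTS])[:, None]
        y_act = np.array([params.y_act[c] for c in COMPARTMENTS])[:, None]
        cbv_base = np.stack([base[c] for c in COMPARTMENTS])
        cbv_act = np.stack([act[c] for c in COMPARTMENTS])
        raw = bold_percent_change(y_base, cbv_base, y_act, cbv_act, relax, acq)

    values = smooth_profile(raw, kernel) if smoothing else raw
    if trim:
        values = _trim(values)
    return DepthProfile(values=values, contrast=contrast, smoothed=smoothing, trimmed=trim)


def reported_group_changes(
    params: HemodynamicParams,
    grid: DepthGrid = DEFAULT_GRID,
) -> dict[str, dict[str, int]]:
    """Relative CBV change per depth group, rounded to integer percent.

    The reporting convention of the fitted tables: deep laminar change is
    mid/1.5; intracortical deep change is mid/1.5 and superficial equals
    mid.
    """
    out: dict[str, dict[str, int]] = {}
    for group in ("deep", "middle", "superficial"):
        i = grid.depths_of_group(group)[0]
        out[group] = {
            c: int(np.rint(100.0 * relative_change_profile(c, params, grid)[i]))
            for c in COMPARTMENTS
        }
    return out
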