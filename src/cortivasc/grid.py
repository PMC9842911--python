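"""Cortical depth grid for the modelled vascular unit.

The simulated patch of primary visual cortex is 2.5 mm thick and is
discretised into 10 stacked voxels of 0.75 x 0.75 x 0.25 mm^3.  Depth
index 0 sits at the white-matter border, index 9 at the pial surface.
Each depth belongs to one histological layer (VI, V, IV, II/III, I) and
to one of three depth groups (deep, middle, superficial) used when
prescribing activation strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Histological layers ordered from the white-matter border to the surface.
LAYER_ORDER: tuple[str, ...] = ("VI", "V", "IV", "II/III", "I")

DEPTH_GROUPS: tuple[str, ...] = ("deep", "middle", "superficial")

_DEFAULT_LAYER_OF_DEPTH = (
    "VI", "VI", "V", "V", "IV", "IV", "II/III", "II/III", "I", "I",
)
_DEFAULT_DEPTH_GROUP = (
    "deep", "deep", "deep", "deep",
    "middle", "middle",
    "superficial", "superficial", "superficial", "superficial",
)


@dataclass(frozen=True)
class DepthGrid:
    """Equi-thickness depth grid spanning the cortical ribbon.

    Parameters
    ----------
    n_depths : int
        Number of simulated voxels across the cortex (default 10).
    voxel_footprint_um : float
        In-plane voxel edge length ``l`` in micrometres (default 750).
    voxel_height_um : float
        Voxel extent along the cortical normal in micrometres (default 250).
    layer_of_depth : tuple of str
        Histological layer assigned to each depth, white matter first.
    depth_group : tuple of str
        Activation group ("deep", "middle", "superficial") per depth.
    """

    n_depths: int = 10
    voxel_footprint_um: float = 750.0
    voxel_height_um: float = 250.0
    layer_of_depth: tuple[str, ...] = field(default=_DEFAULT_LAYER_OF_DEPTH)
    depth_group: tuple[str, ...] = field(default=_DEFAULT_DEPTH_GROUP)

    def __post_init__(self) -> None:
        if self.n_depths <= 2:
            raise ValueError("need at least 3 depths (edges are trimmed)")
        if self.voxel_footprint_um <= 0 or self.voxel_height_um <= 0:
            raise ValueError("voxel dimensions must be positive")
        if len(self.layer_of_depth) != self.n_depths:
            raise ValueError("layer_of_depth must label every depth")
        if len(self.depth_group) != self.n_depths:
            raise ValueError("depth_group must label every depth")
        for lab in self.layer_of_depth:
            if lab not in LAYER_ORDER:
                raise ValueError(f"unknown layer label {lab!r}")
        for grp in self.depth_group:
            if grp not in DEPTH_GROUPS:
                raise ValueError(f"unknown depth group {grp!r}")

    @property
    def cortical_thickness_um(self) -> float:
        return self.n_depths * self.voxel_height_um

    @property
    def footprint_area_um2(self) -> float:
        """Voxel cross-section l^2 perpendicular to the diving vessels."""
        return self.voxel_footprint_um**2

    def depths_of_layer(self, layer: str) -> np.ndarray:
        """Depth indices belonging to a histological layer."""
        if layer not in LAYER_ORDER:
            raise ValueError(f"unknown layer label {layer!r}")
        return np.flatnonzero(np.asarray(self.layer_of_depth) == layer)

    def depths_of_group(self, group: str) -> np.ndarray:
        if group not in DEPTH_GROUPS:
            raise ValueError(f"unknown depth group {group!r}")
        return np.flatnonzero(np.asarray(self.depth_group) == group)

    def group_mask(self, group: str) -> np.ndarray:
        return np.asarray(self.depth_group) == group

    def layers_present(self) -> tuple[str, ...]:
        """Layers in anatomical order that appear on this grid."""
        return tuple(l for l in LAYER_ORDER if l in self.layer_of_depth)


DEFAULT_GRID = DepthGrid()
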