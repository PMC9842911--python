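"""Fixture bundles, published best-fit parameter sets, and synthetic
group profiles.

The measured group profiles this model was fitted against exist only in
graphical form, so self-contained experiments work on synthetic
stand-ins: noiseless forward simulations, optionally perturbed per
subject with seeded Gaussian noise, averaged into a mean profile with a
standard error per depth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .grid import DEFAULT_GRID
from .io import constants_dict, write_profiles
from .profiles import DepthProfile, HemodynamicParams, simulate_profile
from .signal import DEFAULT_ACQUISITION, AcquisitionConstants
from .vascular import (
    ARTERY_OF_VEIN,
    DEFAULT_ARTERY_MULTIPLICITY,
    DEFAULT_VEIN_MULTIPLICITY,
    LAMINAR_CBV_PROFILE,
    LAMINAR_SPLIT,
    REFERENCE_VEIN_DIAMETERS_UM,
    VascularUnit,
    allocation_from_vein_diameters,
    build_vascular_unit,
)

__all__ = [
    "best_fit_params",
    "SyntheticSpec",
    "SyntheticMeasurement",
    "synth_measured",
    "make_fixtures",
]

#: Group best-fit compartmental changes (percent of baseline, middle
#: layers) and coupled venous saturations, per baseline scenario.
_BEST_FITS = {
    "depth_dependent": {
        "dcbv": {"arterioles": 56, "capillaries": 56, "venules": 2, "icas": 21, "icvs": 5},
        "y_venous": (0.70, 0.90),
    },
    "constant": {
        "dcbv": {"arterioles": 65, "capillaries": 65, "venules": 0, "icas": 3, "icvs": 2},
        "y_venous": (0.71, 0.90),
    },
}


def best_fit_params(scenario: str = "depth_dependent") -> HemodynamicParams:
    """Published best-fit hemodynamics for a baseline-CBV scenario.

    ``depth_dependent``: 56% in arterioles/capillaries, 2% venules,
    21% ICAs, 5% ICVs (middle layers), venous Y 70% -> 90%.
    ``constant``: 65/0/3/2 with venous Y 71% -> 90%.
    """
    if scenario not in _BEST_FITS:
        raise ValueError(f"unknown scenario {scenario!r}")
    entry = _BEST_FITS[scenario]
    params = HemodynamicParams().with_dcbv(
        **{k: float(v) for k, v in entry["dcbv"].items()}
    )
    return params.with_venous_oxygenation(*entry["y_venous"])


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic measured-group dataset.

    noise_sd is the per-depth, per-subject Gaussian standard deviation in
    percent signal change (may differ per contrast); n_subjects emulates
    the analysed group size; seed fixes all randomness.
    """

    generating_params: HemodynamicParams = field(
        default_factory=lambda: best_fit_params("depth_dependent")
    )
    noise_sd: float | dict = 0.1
    n_subjects: int = 7
    seed: int = 0

    def sd_for(self, contrast: str) -> float:
        sd = (
            self.noise_sd.get(contrast, 0.0)
            if isinstance(self.noise_sd, dict)
            else float(self.noise_sd)
        )
        if sd < 0:
            raise ValueError("noise sd must be non-negative")
        return sd


@dataclass(frozen=True)
class SyntheticMeasurement:
    """Synthetic group data for one contrast."""

    contrast: str
    truth: DepthProfile
    subjects: np.ndarray  # (n_subjects, n_depths)
    mean: np.ndarray
    sem: np.ndarray

    def mean_profile(self) -> DepthProfile:
        return DepthProfile(
            values=self.mean,
            contrast=self.contrast,
            smoothed=self.truth.smoothed,
            trimmed=self.truth.trimmed,
            depth_indices=self.truth.depth_indices,
        )


def synth_measured(
    spec: SyntheticSpec,
    unit: VascularUnit | None = None,
    acq: AcquisitionConstants = DEFAULT_ACQUISITION,
    contrasts: tuple[str, ...] = ("vaso", "bold"),
    outdir: str | Path | None = None,
) -> dict[str, SyntheticMeasurement]:
    """Generate per-subject noisy profiles plus their mean and SEM.

    With ``noise_sd = 0`` the mean reproduces the forward model exactly;
    the same seed always yields byte-identical CSV output.
    """
    if spec.n_subjects < 1:
        raise ValueError("need at least one subject")
    unit = unit if unit is not None else build_vascular_unit()
    rng = np.random.default_rng(spec.seed)
    out: dict[str, SyntheticMeasurement] = {}
    for contrast in contrasts:
        truth = simulate_profile(unit, spec.generating_params, contrast, acq)
        sd = spec.sd_for(contrast)
        if sd == 0.0:
            # exact: the group mean IS the forward model
            subjects = np.tile(truth.values, (spec.n_subjects, 1))
            mean = truth.values.copy()
            sem = np.zeros_like(mean)
        else:
            noise = rng.normal(0.0, sd, size=(spec.n_subjects, truth.values.size))
            subjects = truth.values[None, :] + noise
            mean = subjects.mean(axis=0)
            sem = (
                subjects.std(axis=0, ddof=1) / np.sqrt(spec.n_subjects)
                if spec.n_subjects > 1
                else np.zeros_like(mean)
            )
        out[contrast] = SyntheticMeasurement(
            contrast=contrast, truth=truth, subjects=subjects, mean=mean, sem=sem
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_profiles(
            outdir / "group_mean.csv",
            {c: m.mean_profile() for c, m in out.items()},
            sem={c: m.sem for c, m in out.items()},
        )
        rows = []
        for contrast, m in out.items():
            for s in range(spec.n_subjects):
                for idx, val in zip(m.truth.depth_indices, m.subjects[s]):
                    rows.append(
                        f"{int(idx)},{contrast},{s + 1},{val!r}"
                    )
        (outdir / "subjects.csv").write_text(
            "depth_index,contrast,subject,percent_signal_change\n"
            + "\n".join(rows) + "\n"
        )
    return out


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixtures(outdir: str | Path, baseline_mode: str = "depth_dependent") -> dict[str, str]:
    """Write the census, allocation, baseline and constants fixtures.

    Output is deterministic: a fixed configuration always produces
    byte-identical files.  Returns {filename: sha256}.  Raises if the
    paired A3/A4 census breaks the 2:1 artery:vein rule of the unit.
    """
    vein_mult = dict(DEFAULT_VEIN_MULTIPLICITY)
    art_mult = dict(DEFAULT_ARTERY_MULTIPLICITY)
    for vein in ("V3", "V4"):
        artery = ARTERY_OF_VEIN[vein]
        if art_mult[artery] != 2 * vein_mult[vein]:
            raise ValueError(
                f"census inconsistent: {artery} count must be twice {vein} count"
            )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    census = {
        "vein_multiplicity": vein_mult,
        "artery_multiplicity": art_mult,
        "vein_diameters_um": {
            v: dict(d) for v, d in REFERENCE_VEIN_DIAMETERS_UM.items()
        },
    }
    (outdir / "census.yaml").write_text(yaml.safe_dump(census, sort_keys=True))

    allocation = allocation_from_vein_diameters()
    alloc_ser = {
        vein: {
            layer: allocation.count(vein, layer)
            for layer in DEFAULT_GRID.layers_present()
            if allocation.count(vein, layer)
        }
        for vein in allocation.veins()
    }
    (outdir / "allocation.yaml").write_text(yaml.safe_dump(alloc_ser, sort_keys=True))

    if baseline_mode == "constant":
        profile = [float(np.mean(LAMINAR_CBV_PROFILE))] * DEFAULT_GRID.n_depths
    else:
        profile = [float(x) for x in LAMINAR_CBV_PROFILE]
    baseline = {
        "mode": baseline_mode,
        "laminar_cbv_fraction": profile,
        "laminar_split": dict(LAMINAR_SPLIT),
    }
    (outdir / "laminar_baseline.yaml").write_text(
        yaml.safe_dump(baseline, sort_keys=True)
    )

    (outdir / "constants.json").write_text(
        json.dumps(constants_dict(), indent=2, sort_keys=True) + "\n"
    )

    return {
        name: _file_hash(outdir / name)
        for name in (
            "census.yaml", "allocation.yaml", "laminar_baseline.yaml", "constants.json"
        )
    }
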