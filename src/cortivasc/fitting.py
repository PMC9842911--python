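"""Exhaustive grid-search fitting of simulated to measured depth profiles.

The objective is the unweighted root-mean-squared error over the eight
retained depth points.  VASO fits search four relative blood-volume
changes (arterioles+capillaries coupled, venules, intracortical arteries,
intracortical veins) on a 1-percentage-point grid; because the VASO
forward model is exactly linear in those parameters, each candidate is a
dot product with four precomputed per-compartment basis profiles, which
makes the full 91^4 grid tractable.  BOLD fits hold the blood-volume
changes fixed (taken from a prior VASO fit) and search the coupled
venule/ICV oxygen saturation pair at baseline and activation.

Parameter uncertainty is summarised by the 20%-RMSE envelope: the set of
grid points whose RMSE is at most 1.2x the minimum, reported as
per-parameter ranges and as a per-depth band of simulated profiles.

Estimators follow the scikit-learn protocol (``fit``, fitted attributes
with trailing underscores, ``get_params``/``set_params``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator

from .profiles import HemodynamicParams, simulate_profile
from .signal import (
    DEFAULT_ACQUISITION,
    DEFAULT_RELAXATION,
    AcquisitionConstants,
    RelaxationConstants,
)
from .vascular import VascularUnit, build_vascular_unit

__all__ = [
    "rmse",
    "GridSpec",
    "FitResult",
    "VasoProfileFitter",
    "BoldProfileFitter",
    "envelope",
    "fit_vaso",
    "fit_bold",
]

#: Fitted VASO parameter groups, in tie-breaking order, and the model
#: compartments each group drives.
VASO_FIT_GROUPS: dict[str, tuple[str, ...]] = {
    "arterioles_capillaries": ("arterioles", "capillaries"),
    "venules": ("venules",),
    "icas": ("icas",),
    "icvs": ("icvs",),
}

BOLD_FIT_PARAMS = ("y_base", "y_act")


def rmse(sim, meas) -> float:
    """Root-mean-squared error between two equal-length profiles."""
    sim = np.asarray(sim, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if sim.shape != meas.shape:
        raise ValueError(f"profile length mismatch: {sim.shape} vs {meas.shape}")
    return float(np.sqrt(np.mean((sim - meas) ** 2)))


@dataclass(frozen=True)
class GridSpec:
    """Inclusive integer search ranges (lower, upper, step) per parameter."""

    axes: Mapping[str, tuple[int, int, int]]

    def __post_init__(self) -> None:
        if not self.axes:
            raise ValueError("empty grid")
        for name, (lo, hi, step) in self.axes.items():
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")
            if step <= 0:
                raise ValueError(f"{name}: step must be positive")

    def axis(self, name: str) -> np.ndarray:
        lo, hi, step = self.axes[name]
        return np.arange(lo, hi + 1, step)

    @property
    def n_points(self) -> int:
        n = 1
        for name in self.axes:
            n *= self.axis(name).size
        return n

    @classmethod
    def default_vaso(cls) -> "GridSpec":
        return cls({g: (0, 90, 1) for g in VASO_FIT_GROUPS})

    @classmethod
    def default_bold(cls) -> "GridSpec":
        return cls({"y_base": (60, 75, 1), "y_act": (75, 90, 1)})


@dataclass(frozen=True)
class FitResult:
    """Outcome of an exhaustive grid search.

    best_params maps fitted parameter names to their grid values (percent);
    envelope maps each to the (min, max) over all grid points with
    RMSE <= factor * rmse_min; band is the per-depth (min, max) of the
    simulated profiles over that set.
    """

    best_params: dict[str, int]
    rmse_min: float
    envelope: dict[str, tuple[int, int]]
    band: np.ndarray
    profile: np.ndarray
    grid: GridSpec
    n_evaluated: int
    envelope_factor: float = 1.2
    landscape: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "best_params": dict(self.best_params),
            "rmse_min": self.rmse_min,
            "envelope": {k: list(v) for k, v in self.envelope.items()},
            "band": self.band.tolist(),
            "profile": self.profile.tolist(),
            "n_evaluated": self.n_evaluated,
            "envelope_factor": self.envelope_factor,
        }


def envelope(rmse_values, param_tuples, factor: float = 1.2):
    """Membership and per-parameter ranges of the RMSE envelope.

    Given a flat array of RMSE values and the aligned parameter tuples,
    returns (member_mask, ranges) where ranges[j] = (min, max) of
    parameter j over the set {RMSE <= factor * min(RMSE)}.
    """
    if factor < 1.0:
        raise ValueError("envelope factor must be >= 1")
    rmse_values = np.asarray(rmse_values, dtype=float)
    if rmse_values.size == 0:
        raise ValueError("empty landscape")
    members = rmse_values <= factor * rmse_values.min()
    pts = np.asarray(param_tuples, dtype=float).reshape(rmse_values.size, -1)
    ranges = [
        (pts[members, j].min(), pts[members, j].max()) for j in range(pts.shape[1])
    ]
    return members, ranges


class VasoProfileFitter(BaseEstimator):
    """Exhaustive grid search of the VASO forward model.

    Exploits the exact linearity of the VASO profile in the four fitted
    dCBV_mid values: the simulated profile at a grid point theta is
    B @ theta with per-group basis profiles B, so the squared error is a
    quadratic form evaluated in vectorised chunks over the full grid.
    Ties in RMSE are broken by the lexicographically smallest parameter
    tuple in the order arterioles_capillaries, venules, icas, icvs.

    Parameters
    ----------
    unit : VascularUnit, optional
        Vascular unit to simulate with (default: the packaged unit with
        depth-dependent baseline).
    grid : GridSpec, optional
        Search ranges (default 0-90% in 1% steps on all four axes).
    envelope_factor : float
        RMSE multiple defining the uncertainty envelope (default 1.2).
    compute_envelope : bool
        Skip the envelope pass when False (halves the work).
    store_landscape : bool
        Keep the full RMSE array (only sensible for coarse grids).
    smoothing : bool
        Apply the partial-volume kernel to simulated profiles.

    Attributes
    ----------
    best_params_ : dict, rmse_min_ : float, envelope_ : dict,
    band_ : ndarray, result_ : FitResult
    """

    def __init__(
        self,
        unit: VascularUnit | None = None,
        grid: GridSpec | None = None,
        envelope_factor: float = 1.2,
        compute_envelope: bool = True,
        store_landscape: bool = False,
        smoothing: bool = True,
        base_params: HemodynamicParams | None = None,
        acq: AcquisitionConstants = DEFAULT_ACQUISITION,
        relax: RelaxationConstants = DEFAULT_RELAXATION,
    ):
        self.unit = unit
        self.grid = grid
        self.envelope_factor = envelope_factor
        self.compute_envelope = compute_envelope
        self.store_landscape = store_landscape
        self.smoothing = smoothing
        self.base_params = base_params
        self.acq = acq
        self.relax = relax

    # -- internals ---------------------------------------------------------

    def _basis(self, unit: VascularUnit, base: HemodynamicParams) -> np.ndarray:
        """Columns: simulated VASO profile per 1% dCBV_mid of each group."""
        cols = []
        for group, comps in VASO_FIT_GROUPS.items():
            params = base.with_dcbv(
                **{c: 0.0 for c in HemodynamicParams().dcbv_mid},
            ).with_dcbv(**{c: 1.0 for c in comps})
            prof = simulate_profile(
                unit, params, "vaso", self.acq, self.relax, smoothing=self.smoothing
            )
            cols.append(prof.values)
        return np.column_stack(cols)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the measured VASO profile ``X`` (array of 8 depth values)."""
        measured = np.asarray(X, dtype=float).ravel()
        unit = self.unit if self.unit is not None else build_vascular_unit()
        base = self.base_params if self.base_params is not None else HemodynamicParams()
        grid = self.grid if self.grid is not None else GridSpec.default_vaso()
        if set(grid.axes) != set(VASO_FIT_GROUPS):
            raise ValueError(f"VASO grid must define axes {tuple(VASO_FIT_GROUPS)}")
        if self.envelope_factor < 1.0:
            raise ValueError("envelope factor must be >= 1")

        B = self._basis(unit, base)
        n_pts = B.shape[0]
        if measured.shape != (n_pts,):
            raise ValueError(
                f"measured profile has {measured.size} points, expected {n_pts}"
            )

        names = list(VASO_FIT_GROUPS)
        ax = [grid.axis(n).astype(float) for n in names]
        a_ax, b_ax, c_ax, d_ax = ax
        G = B.T @ B
        cvec = B.T @ measured
        yy = float(measured @ measured)

        # Quadratic form over the (b, c, d) sub-grid, reused for every a.
        b3 = b_ax[:, None, None]
        c3 = c_ax[None, :, None]
        d3 = d_ax[None, None, :]
        T = (
            G[1, 1] * b3**2 + G[2, 2] * c3**2 + G[3, 3] * d3**2
            + 2.0 * (G[1, 2] * b3 * c3 + G[1, 3] * b3 * d3 + G[2, 3] * c3 * d3)
            - 2.0 * (cvec[1] * b3 + cvec[2] * c3 + cvec[3] * d3)
        )
        U = G[0, 1] * b3 + G[0, 2] * c3 + G[0, 3] * d3

        best_sse = np.inf
        best_idx = (0, 0, 0, 0)
        landscape = (
            np.empty([a.size for a in ax]) if self.store_landscape else None
        )
        for i, a in enumerate(a_ax):
            sse = T + (2.0 * a) * U + (G[0, 0] * a * a - 2.0 * cvec[0] * a)
            j = int(np.argmin(sse))  # first occurrence: lexicographic in (b,c,d)
            if sse.flat[j] < best_sse:  # strict <: earlier a wins ties
                best_sse = float(sse.flat[j])
                best_idx = (i, *np.unravel_index(j, sse.shape))
            if landscape is not None:
                landscape[i] = np.sqrt(np.maximum(sse + yy, 0.0) / n_pts)

        best = {n: int(ax[k][best_idx[k]]) for k, n in enumerate(names)}
        theta_best = np.array([float(best[n]) for n in names])
        best_profile = B @ theta_best
        # direct evaluation avoids the cancellation error of the
        # quadratic-form route when the fit is (near) exact
        rmse_min = rmse(best_profile, measured)

        env: dict[str, tuple[int, int]] = {n: (best[n], best[n]) for n in names}
        band = np.vstack([best_profile, best_profile])
        if self.compute_envelope:
            sse_thr = n_pts * (self.envelope_factor * rmse_min) ** 2 - yy
            # keep the best point a member despite float cancellation
            sse_thr = max(sse_thr, best_sse) + 1e-12 * (1.0 + abs(yy))
            lo = {n: np.inf for n in names}
            hi = {n: -np.inf for n in names}
            band_lo = np.full(n_pts, np.inf)
            band_hi = np.full(n_pts, -np.inf)
            for i, a in enumerate(a_ax):
                sse = T + (2.0 * a) * U + (G[0, 0] * a * a - 2.0 * cvec[0] * a)
                mask = sse <= sse_thr
                if not mask.any():
                    continue
                lo[names[0]] = min(lo[names[0]], a)
                hi[names[0]] = max(hi[names[0]], a)
                kb, kc, kd = np.nonzero(mask)
                for n, kk, axis in (
                    (names[1], kb, b_ax), (names[2], kc, c_ax), (names[3], kd, d_ax)
                ):
                    lo[n] = min(lo[n], axis[kk.min()])
                    hi[n] = max(hi[n], axis[kk.max()])
                theta = np.column_stack(
                    [np.full(kb.size, a), b_ax[kb], c_ax[kc], d_ax[kd]]
                )
                profs = theta @ B.T
                band_lo = np.minimum(band_lo, profs.min(axis=0))
                band_hi = np.maximum(band_hi, profs.max(axis=0))
            env = {n: (int(lo[n]), int(hi[n])) for n in names}
            band = np.vstack([band_lo, band_hi])

        self.basis_ = B
        self.best_params_ = best
        self.rmse_min_ = rmse_min
        self.envelope_ = env
        self.band_ = band
        self.landscape_ = landscape
        self.result_ = FitResult(
            best_params=best,
            rmse_min=rmse_min,
            envelope=env,
            band=band,
            profile=best_profile,
            grid=grid,
            n_evaluated=grid.n_points,
            envelope_factor=self.envelope_factor,
            landscape=landscape,
        )
        return self

    def predict(self, X=None) -> np.ndarray:
        """Best-fit simulated profile."""
        return self.result_.profile

    def score(self, X, y=None) -> float:
        """Negative RMSE of the best fit against ``X``."""
        return -rmse(self.result_.profile, np.asarray(X, dtype=float).ravel())

    def best_hemodynamics(self) -> HemodynamicParams:
        """Best-fit parameters as a full HemodynamicParams object."""
        base = self.base_params if self.base_params is not None else HemodynamicParams()
        dcbv = {}
        for group, comps in VASO_FIT_GROUPS.items():
            for c in comps:
                dcbv[c] = float(self.best_params_[group])
        return base.with_dcbv(**dcbv)


class BoldProfileFitter(BaseEstimator):
    """Exhaustive 2-D search of the coupled venous oxygenation pair.

    Blood-volume changes are fixed (``dcbv`` in percent per compartment,
    typically the best fit of a prior VASO search); the grid runs over
    (Y_base, Y_act) of the venules and intracortical veins in integer
    percent.  Other compartments keep their fixed saturations.
    """

    def __init__(
        self,
        unit: VascularUnit | None = None,
        dcbv: Mapping[str, float] | None = None,
        grid: GridSpec | None = None,
        envelope_factor: float = 1.2,
        smoothing: bool = True,
        base_params: HemodynamicParams | None = None,
        acq: AcquisitionConstants = DEFAULT_ACQUISITION,
        relax: RelaxationConstants = DEFAULT_RELAXATION,
    ):
        self.unit = unit
        self.dcbv = dcbv
        self.grid = grid
        self.envelope_factor = envelope_factor
        self.smoothing = smoothing
        self.base_params = base_params
        self.acq = acq
        self.relax = relax

    def fit(self, X, y=None):
        measured = np.asarray(X, dtype=float).ravel()
        unit = self.unit if self.unit is not None else build_vascular_unit()
        base = self.base_params if self.base_params is not None else HemodynamicParams()
        if self.dcbv is not None:
            base = base.with_dcbv(**{k: float(v) for k, v in self.dcbv.items()})
        grid = self.grid if self.grid is not None else GridSpec.default_bold()
        if set(grid.axes) != set(BOLD_FIT_PARAMS):
            raise ValueError(f"BOLD grid must define axes {BOLD_FIT_PARAMS}")
        if self.envelope_factor < 1.0:
            raise ValueError("envelope factor must be >= 1")

        yb_ax = grid.axis("y_base")
        ya_ax = grid.axis("y_act")
        landscape = np.empty((yb_ax.size, ya_ax.size))
        profiles = np.empty((yb_ax.size, ya_ax.size, measured.size))
        for i, yb in enumerate(yb_ax):
            for j, ya in enumerate(ya_ax):
                params = base.with_venous_oxygenation(yb / 100.0, ya / 100.0)
                prof = simulate_profile(
                    unit, params, "bold", self.acq, self.relax, smoothing=self.smoothing
                )
                if prof.values.size != measured.size:
                    raise ValueError(
                        f"measured profile has {measured.size} points, "
                        f"expected {prof.values.size}"
                    )
                profiles[i, j] = prof.values
                landscape[i, j] = rmse(prof.values, measured)

        flat = int(np.argmin(landscape))  # first occurrence: lexicographic
        i0, j0 = np.unravel_index(flat, landscape.shape)
        rmse_min = float(landscape[i0, j0])
        best = {"y_base": int(yb_ax[i0]), "y_act": int(ya_ax[j0])}

        members = landscape <= self.envelope_factor * rmse_min
        ki, kj = np.nonzero(members)
        env = {
            "y_base": (int(yb_ax[ki.min()]), int(yb_ax[ki.max()])),
            "y_act": (int(ya_ax[kj.min()]), int(ya_ax[kj.max()])),
        }
        member_profiles = profiles[members]
        band = np.vstack([member_profiles.min(axis=0), member_profiles.max(axis=0)])

        self.best_params_ = best
        self.rmse_min_ = rmse_min
        self.envelope_ = env
        self.band_ = band
        self.landscape_ = landscape
        self.result_ = FitResult(
            best_params=best,
            rmse_min=rmse_min,
            envelope=env,
            band=band,
            profile=profiles[i0, j0].copy(),
            grid=grid,
            n_evaluated=grid.n_points,
            envelope_factor=self.envelope_factor,
            landscape=landscape,
        )
        return self

    def predict(self, X=None) -> np.ndarray:
        return self.result_.profile

    def score(self, X, y=None) -> float:
        return -rmse(self.result_.profile, np.asarray(X, dtype=float).ravel())


def fit_vaso(measured, unit=None, grid=None, **kwargs) -> FitResult:
    """Grid-search VASO fit; thin wrapper over :class:`VasoProfileFitter`."""
    return VasoProfileFitter(unit=unit, grid=grid, **kwargs).fit(measured).result_


def fit_bold(measured, unit=None, dcbv=None, grid=None, **kwargs) -> FitResult:
    """Grid-search BOLD fit; thin wrapper over :class:`BoldProfileFitter`."""
    return (
        BoldProfileFitter(unit=unit, dcbv=dcbv, grid=grid, **kwargs)
        .fit(measured)
        .result_
    )
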