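"""Steady-state BOLD and VASO MR signal equations for a GRE readout at 7 T.

The total gradient-echo signal of a voxel is the volume-weighted sum of
an extravascular (tissue) mono-exponential decay and the intravascular
signals of the five vascular compartments,

    S_tot = (1 - CBV_tot) * S0 * exp(-TE * R2*_EV)
            + sum_i S0 * exp(-TE * R2*_IV,i) * CBV_i

with transverse rates split into an intrinsic and a haemoglobin-induced
part.  Blood: R2*_IV = 67 + C*(1-Y)^2 with C = 536.48 s^-1 at 7 T.
Tissue: R2*_EV = 34 + sum_i (e * dnu_s(Y_i) + f * CBV_i[%]) where dnu_s
is the susceptibility-induced frequency shift at the vessel surface.

VASO images tissue while blood is nulled by inversion recovery; after
dynamic division (nulled / not-nulled) the T2* factor cancels and the
percent signal change reduces to -dCBV_abs / (1 - CBV_base), independent
of every oxygenation and timing parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AcquisitionConstants",
    "RelaxationConstants",
    "delta_nu_s",
    "r2star_iv",
    "r2star_ev",
    "compartment_signals",
    "total_signal",
    "bold_percent_change",
    "vaso_percent_change",
    "vaso_ev_signal",
]


@dataclass(frozen=True)
class AcquisitionConstants:
    """Sequence timings and scaling for the 7 T acquisition.

    te, ti, tr : s — echo time, blood-nulling inversion time, repetition
    time.  t1_blood/t1_tissue : s — longitudinal relaxation times.
    epsilon — inversion efficiency in [0, 1].  s0 — effective spin
    density (blood and tissue set equal; only relative changes matter).
    """

    te: float = 0.025
    ti: float = 1.1
    tr: float = 4.5
    t1_blood: float = 2.1
    t1_tissue: float = 1.8
    epsilon: float = 1.0
    s0: float = 1.0

    def __post_init__(self) -> None:
        if min(self.te, self.ti, self.tr, self.t1_blood, self.t1_tissue) <= 0:
            raise ValueError("all times must be positive")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("inversion efficiency must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RelaxationConstants:
    """Relaxation-rate constants of the 7 T signal model.

    r2_iv_0, r2_ev_0 : s^-1 — intrinsic blood/tissue rates.
    c_iv : s^-1 — field-dependent blood constant in C*(1-Y)^2.
    e_coef, f_coef — fitted coefficients of the extravascular Hb term
    (f multiplies CBV expressed in percent).
    y_off — oxygen saturation with zero blood-tissue susceptibility
    difference.  hct — haematocrit.  dchi0_over_4pi — susceptibility of
    fully deoxygenated blood divided by 4*pi (ppm-scale, dimensionless).
    gamma : rad/s/T, b0 : T — the shift is used in angular-frequency
    convention by default ("hz" divides by 2*pi).
    ev_hb_form — "printed" sums e*dnu + f*CBV[%] per compartment;
    "cbv_scaled" uses (e*dnu + f) * CBV[%] instead.
    """

    r2_iv_0: float = 67.0
    r2_ev_0: float = 34.0
    c_iv: float = 536.48
    e_coef: float = 0.0453
    f_coef: float = -0.19
    y_off: float = 0.95
    hct: float = 0.40
    dchi0_over_4pi: float = 0.264e-6
    gamma: float = 2.675e8
    b0: float = 7.0
    frequency_convention: str = "angular"
    ev_hb_form: str = "printed"

    def __post_init__(self) -> None:
        if self.frequency_convention not in ("angular", "hz"):
            raise ValueError("frequency_convention must be 'angular' or 'hz'")
        if self.ev_hb_form not in ("printed", "cbv_scaled"):
            raise ValueError("ev_hb_form must be 'printed' or 'cbv_scaled'")

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_ACQUISITION = AcquisitionConstants()
DEFAULT_RELAXATION = RelaxationConstants()


def _check_y(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("oxygen saturation must lie in [0, 1]")
    return y


def delta_nu_s(y, k: RelaxationConstants = DEFAULT_RELAXATION):
    """Susceptibility-induced frequency shift at the vessel surface (s^-1).

    (dchi0/4pi) * Hct * (Y_off - Y) * gamma * B0; negative above Y_off.
    """
    y = _check_y(y)
    shift = k.dchi0_over_4pi * k.hct * (k.y_off - y) * k.gamma * k.b0
    if k.frequency_convention == "hz":
        shift = shift / (2.0 * math.pi)
    return shift


def r2star_iv(y, k: RelaxationConstants = DEFAULT_RELAXATION):
    """Intravascular transverse rate 67 + C*(1-Y)^2 (s^-1)."""
    y = _check_y(y)
    return k.r2_iv_0 + k.c_iv * (1.0 - y) ** 2


def r2star_ev(
    y: Sequence[float] | np.ndarray,
    cbv: Sequence[float] | np.ndarray,
    k: RelaxationConstants = DEFAULT_RELAXATION,
):
    """Extravascular transverse rate (s^-1) around a set of compartments.

    ``y`` and ``cbv`` are aligned per-compartment arrays (CBV as volume
    fraction; the f coefficient multiplies CBV in percent).  Broadcasts
    over a trailing depth axis if 2-D arrays (n_compartments, n_depths)
    are passed.
    """
    y = _check_y(y)
    cbv = np.asarray(cbv, dtype=float)
    dnu = delta_nu_s(y, k)
    cbv_pct = 100.0 * cbv
    if k.ev_hb_form == "printed":
        hb = k.e_coef * dnu + k.f_coef * cbv_pct
    else:  # cbv_scaled
        hb = (k.e_coef * dnu + k.f_coef) * cbv_pct
    return k.r2_ev_0 + np.sum(hb, axis=0)


def compartment_signals(
    y,
    cbv,
    k: RelaxationConstants = DEFAULT_RELAXATION,
    acq: AcquisitionConstants = DEFAULT_ACQUISITION,
):
    """Intravascular signal per compartment: S0*exp(-TE*R2*_IV)*CBV."""
    return acq.s0 * np.exp(-acq.te * r2star_iv(y, k)) * np.asarray(cbv, float)


def total_signal(
    y,
    cbv,
    k: RelaxationConstants = DEFAULT_RELAXATION,
    acq: AcquisitionConstants = DEFAULT_ACQUISITION,
):
    """Total GRE signal of one voxel state (per-compartment y and cbv)."""
    cbv = np.asarray(cbv, dtype=float)
    cbv_tot = np.sum(cbv, axis=0)
    if np.any(cbv_tot >= 1.0):
        raise ValueError("total CBV must stay below 1")
    s_ev = (1.0 - cbv_tot) * acq.s0 * np.exp(-acq.te * r2star_ev(y, cbv, k))
    s_iv = np.sum(compartment_signals(y, cbv, k, acq), axis=0)
    return s_ev + s_iv


def bold_percent_change(
    y_base,
    cbv_base,
    y_act,
    cbv_act,
    k: RelaxationConstants = DEFAULT_RELAXATION,
    acq: AcquisitionConstants = DEFAULT_ACQUISITION,
):
    """BOLD percent signal change between baseline and activation states."""
    s_base = total_signal(y_base, cbv_base, k, acq)
    s_act = total_signal(y_act, cbv_act, k, acq)
    return 100.0 * (s_act - s_base) / s_base


def vaso_percent_change(cbv_base_total, dcbv_abs_total):
    """VASO percent signal change -100 * dCBV_abs / (1 - CBV_base).

    ``dcbv_abs_total`` is the absolute blood-volume change summed over all
    compartments (fraction of voxel volume).  Negative for a volume
    increase; the activation-positive display sign is applied at the
    profile layer, not here.
    """
    cbv_base_total = np.asarray(cbv_base_total, dtype=float)
    if np.any(cbv_base_total < 0) or np.any(cbv_base_total >= 1.0):
        raise ValueError("baseline CBV must lie in [0, 1)")
    return -100.0 * np.asarray(dcbv_abs_total, dtype=float) / (1.0 - cbv_base_total)


def vaso_ev_signal(acq: AcquisitionConstants = DEFAULT_ACQUISITION, t1: float | None = None):
    """Steady-state blood-nulled tissue signal after dynamic division.

    1 - (1+eps)*exp(-TI/T1) + eps*exp(-TR/T1); the T2* factor of the
    nulled image cancels against the not-nulled image.  This absolute
    level cancels again in the VASO percent change, which is therefore
    independent of TI, TR, T1 and eps.
    """
    t1 = acq.t1_tissue if t1 is None else t1
    if t1 <= 0:
        raise ValueError("T1 must be positive")
    return (
        1.0
        - (1.0 + acq.epsilon) * math.exp(-acq.ti / t1)
        + acq.epsilon * math.exp(-acq.tr / t1)
    )
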