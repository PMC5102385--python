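"""¹⁵N spin relaxation of a rigid isotropic rotor and τc estimation.

For a backbone amide ¹⁵N relaxed by the N–H dipolar interaction and ¹⁵N
CSA, with isotropic spectral density J(ω) = (2/5)·τc/(1 + (ωτc)²):

    R1 = (d²/4)[J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + c²J(ωN)
    R2 = (d²/8)[4J(0) + J(ωH−ωN) + 3J(ωN) + 6J(ωH) + 6J(ωH+ωN)]
         + (c²/6)[4J(0) + 3J(ωN)]
    NOE = 1 + (d²/(4R1))(γH/γN)[6J(ωH+ωN) − J(ωH−ωN)]

where d = μ₀ħγHγN/(4π r³NH) and c² = (ΔσωN)²/3.  In the slow-tumbling
regime the T1/T2 ratio is a monotone function of τc, so the ensemble
rotational correlation time is obtained per residue by inverting that ratio
and averaging over residues whose heteronuclear NOE marks them as rigid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.stats import trim_mean

__all__ = [
    "SpinParams",
    "RelaxRecord",
    "TcEstimate",
    "GAMMA_H",
    "GAMMA_N",
    "spectral_density",
    "predict_relaxation",
    "fit_exponential_decay",
    "estimate_tc",
    "ensemble_tc",
]

GAMMA_H = 2.6752218744e8  # rad s⁻¹ T⁻¹
GAMMA_N = -2.7116e7  # rad s⁻¹ T⁻¹
HBAR = 1.054571817e-34  # J s
MU0 = 4.0e-7 * math.pi  # T² m³ J⁻¹


@dataclass
class SpinParams:
    """Interaction constants for the amide ¹⁵N spin pair.

    ``field`` is the ¹H Larmor frequency in MHz; rNH and the ¹⁵N CSA take
    the field-standard values unless overridden.
    """

    field: float  # ¹H frequency, MHz
    rNH: float = 1.02  # Å
    csa: float = -160.0  # ppm

    def __post_init__(self) -> None:
        if self.field <= 0 or self.rNH <= 0:
            raise ValueError("field and rNH must be positive")

    @property
    def omega_h(self) -> float:
        return 2.0 * math.pi * self.field * 1e6

    @property
    def omega_n(self) -> float:
        return self.omega_h * GAMMA_N / GAMMA_H

    @property
    def d(self) -> float:
        return MU0 * HBAR * GAMMA_H * GAMMA_N / (4.0 * math.pi * (self.rNH * 1e-10) ** 3)

    @property
    def c2(self) -> float:
        return (self.omega_n * self.csa * 1e-6) ** 2 / 3.0


@dataclass
class RelaxRecord:
    residue: str
    T1: float  # s
    T2: float  # s
    noe: float

    def __post_init__(self) -> None:
        if self.T1 <= 0 or self.T2 <= 0:
            raise ValueError("T1 and T2 must be positive")
        # in the slow-tumbling regime T2 ≤ T1; the reverse marks fast motion
        self.fast_motion_flag = self.T2 > self.T1


@dataclass
class TcEstimate:
    tau_c: float  # ns
    n_used: int
    cutoff: float


def spectral_density(omega: float, tau_c: float) -> float:
    """Isotropic-rotor spectral density J(ω) = (2/5)τc/(1 + (ωτc)²)."""
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    return 0.4 * tau_c / (1.0 + (omega * tau_c) ** 2)


def predict_relaxation(tau_c: float, sp: SpinParams) -> tuple[float, float, float]:
    """(T1, T2, NOE) of a rigid isotropic rotor with correlation time τc (s)."""
    wh, wn = sp.omega_h, sp.omega_n
    d2, c2 = sp.d**2, sp.c2
    J = lambda w: spectral_density(abs(w), tau_c)
    r1 = (d2 / 4.0) * (J(wh - wn) + 3 * J(wn) + 6 * J(wh + wn)) + c2 * J(wn)
    r2 = (d2 / 8.0) * (4 * J(0) + J(wh - wn) + 3 * J(wn) + 6 * J(wh) + 6 * J(wh + wn)) \
        + (c2 / 6.0) * (4 * J(0) + 3 * J(wn))
    noe = 1.0 + (d2 / (4.0 * r1)) * (GAMMA_H / GAMMA_N) * (6 * J(wh + wn) - J(wh - wn))
    return 1.0 / r1, 1.0 / r2, noe


def fit_exponential_decay(delays, intensities) -> tuple[float, float]:
    """Fit I(t) = I0·exp(−t/T) to a peak-intensity decay series.

    Returns (I0, T).  Requires at least three points, positive intensities
    and an overall decaying series.
    """
    t = np.asarray(delays, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 points")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive")
    order = np.argsort(t)
    t, y = t[order], y[order]
    if y[-1] >= y[0]:
        raise ValueError("not a decay")
    # log-linear seed, then nonlinear refinement
    slope, intercept = np.polyfit(t, np.log(y), 1)
    if slope >= 0:
        raise ValueError("not a decay")
    p0 = (math.exp(intercept), -1.0 / slope)
    popt, _ = curve_fit(lambda tt, i0, T: i0 * np.exp(-tt / T), t, y, p0=p0, maxfev=10000)
    return float(popt[0]), float(popt[1])


def _ratio(tau_c: float, sp: SpinParams) -> float:
    t1, t2, _ = predict_relaxation(tau_c, sp)
    return t1 / t2


def estimate_tc(record: RelaxRecord, sp: SpinParams,
                bracket_ns: tuple[float, float] = (0.1, 100.0)) -> float:
    """Invert the T1/T2 ratio to the rotational correlation time (s).

    The closed-form estimate τc ≈ (1/4πνN)·√(6T1/T2 − 7) seeds a bracketed
    root search of the full dipolar+CSA ratio on [0.1, 100] ns.
    """
    ratio_obs = record.T1 / record.T2
    arg = 6.0 * ratio_obs - 7.0
    if arg <= 0:
        raise ValueError("outside model range: 6·T1/T2 − 7 must be positive")
    lo, hi = bracket_ns[0] * 1e-9, bracket_ns[1] * 1e-9
    f = lambda tc: _ratio(tc, sp) - ratio_obs
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("outside model range: ratio not bracketed on [0.1, 100] ns")
    nu_n = abs(sp.omega_n) / (2.0 * math.pi)
    seed = math.sqrt(arg) / (4.0 * math.pi * nu_n)
    # brentq on a bracket tightened around the closed-form seed when possible
    lo2, hi2 = max(lo, seed / 3.0), min(hi, seed * 3.0)
    if f(lo2) <= 0 <= f(hi2):
        lo, hi = lo2, hi2
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=1e-13))


def ensemble_tc(records, sp: SpinParams, noe_cutoff: float = 0.75) -> TcEstimate:
    """Trimmed-mean τc (ns) over residues passing the rigidity filter.

    Residues with hetNOE above ``noe_cutoff`` are taken as rigid; each is
    inverted individually and a 10%-per-tail trimmed mean guards against
    loop residues that slip past the filter.
    """
    rigid = [r for r in records if r.noe > noe_cutoff]
    if not rigid:
        raise ValueError("no rigid residues pass the NOE cutoff")
    taus = np.array([estimate_tc(r, sp) for r in rigid]) * 1e9
    return TcEstimate(float(trim_mean(taus, 0.1)), len(rigid), noe_cutoff)
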