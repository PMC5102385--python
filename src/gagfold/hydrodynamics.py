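"""Sedimentation-equilibrium forward models and global fitting.

At sedimentation equilibrium the concentration of an ideal species of molar
mass M follows c(r) = c(r₀)·exp(σ(r² − r₀²)) with the reduced buoyant mass

    σ = M (1 − v̄ρ) ω² / (2RT)      [cm⁻²]

For a monomer–dimer self-association with association constant K_A (molar
monomer scale), the dimer concentration is K_A·c_m² at every radius and the
interference-type signal is mass-proportional, so the dimer contributes
twice the monomer signal per mole of dimer.  The global fit shares M_w
(single-species model) or K_A (monomer–dimer model, monomer mass fixed from
sequence) across all speeds and loadings, with per-profile reference
concentration and baseline free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BuoyancyParams",
    "SEProfile",
    "SEFitResult",
    "R_GAS_CGS",
    "reduced_buoyant_mass",
    "rpm_to_omega",
    "predict_se_profile",
    "fit_se_global",
    "ka_to_kd",
    "profiles_from_table",
]

#: Gas constant in CGS units (g·cm²·s⁻²·mol⁻¹·K⁻¹), matching g/mol, cm, rad/s.
R_GAS_CGS = 8.31446261815324e7

#: Default signal-per-molar conversion (fringe-like units per mol/L of
#: monomer equivalents) used by the synthetic generator; ~3.3 fringes per
#: mg/ml at a 12 mm optical path, times M/1000 to go from mg/ml to mM.
def default_epsilon(monomer_mass: float) -> float:
    return 3.3 * monomer_mass / 1000.0 * 1000.0  # per mol/L


@dataclass
class BuoyancyParams:
    M: float  # monomer molar mass, g/mol
    vbar: float  # partial specific volume, ml/g
    rho: float  # solvent density, g/ml
    T: float  # K
    omega: float = 0.0  # rad/s

    def __post_init__(self) -> None:
        if min(self.M, self.vbar, self.rho, self.T) <= 0:
            raise ValueError("all physical parameters must be positive")
        self.buoyancy_flagged = self.vbar * self.rho >= 1.0


@dataclass
class SEProfile:
    speed_rpm: float
    radii: np.ndarray  # cm, strictly increasing
    signal: np.ndarray
    r0: float  # reference radius, cm
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.radii) < 20:
            raise ValueError("profile needs at least 20 points")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")


@dataclass
class SEFitResult:
    model: str  # "single" | "monomer_dimer"
    Mw: float | None  # g/mol, single-species fit
    K_A: float | None  # M⁻¹, association fit
    K_D: float | None  # M
    c_refs: list[float]  # molar (monomer) at each profile's r0
    baselines: list[float]
    rms_per_profile: list[float]
    chi2_global: float
    n_points: int


def rpm_to_omega(rpm: float) -> float:
    return rpm * 2.0 * math.pi / 60.0


def reduced_buoyant_mass(p: BuoyancyParams) -> float:
    """σ = M(1 − v̄ρ)ω²/(2RT), in cm⁻²."""
    return p.M * (1.0 - p.vbar * p.rho) * p.omega**2 / (2.0 * R_GAS_CGS * p.T)


def predict_se_profile(
    p: BuoyancyParams,
    model: str,
    c_ref: float,
    radii: np.ndarray,
    r0: float,
    K_A: float = 0.0,
    baseline: float = 0.0,
    epsilon: float | None = None,
) -> np.ndarray:
    """Equilibrium signal at ``radii`` for a monomer (plus optional dimer).

    ``c_ref`` is the molar monomer concentration at the reference radius;
    the dimer term 2·K_A·c_m² carries the factor 2 because the signal is
    proportional to mass concentration.
    """
    if c_ref < 0:
        raise ValueError("reference concentration must be non-negative")
    if K_A < 0:
        raise ValueError("K_A must be non-negative")
    if model not in ("single", "monomer_dimer"):
        raise ValueError(f"unknown model {model!r}")
    eps = default_epsilon(p.M) if epsilon is None else epsilon
    sigma = reduced_buoyant_mass(p)
    radii = np.asarray(radii, dtype=float)
    xi = np.exp(sigma * (radii**2 - r0**2))
    monomer = c_ref * xi
    signal = monomer.copy()
    if model == "monomer_dimer":
        signal = signal + 2.0 * K_A * c_ref**2 * xi**2
    return eps * signal + baseline


def ka_to_kd(K_A: float) -> float:
    """K_D = 1/K_A (molar)."""
    if K_A <= 0:
        raise ValueError("K_A must be positive")
    return 1.0 / K_A


def _pack_profiles(profiles: list[SEProfile]):
    return np.concatenate([pr.signal for pr in profiles])


def fit_se_global(
    profiles: list[SEProfile],
    p: BuoyancyParams,
    model: str,
    epsilon: float | None = None,
    noise_sd: float | None = None,
) -> SEFitResult:
    """Global weighted least-squares fit over all speeds and loadings.

    The shared parameter is M_w (``single``) or K_A (``monomer_dimer``,
    monomer mass fixed at ``p.M``); each profile keeps its own reference
    concentration and baseline.  The association fit is started from five
    log-spaced K_A guesses (1e3–1e9 M⁻¹) and the best optimum kept.

    ``chi2_global`` is the reduced chi-square; residuals are weighted by
    ``noise_sd`` when given, else unweighted.
    """
    if len(profiles) < 2:
        raise ValueError("global fit needs at least 2 profiles")
    if model not in ("single", "monomer_dimer"):
        raise ValueError(f"unknown model {model!r}")
    eps = default_epsilon(p.M) if epsilon is None else epsilon
    y = _pack_profiles(profiles)
    n_prof = len(profiles)

    def unpack(theta):
        # log-parameterization keeps K_A/M/c_ref positive; clipping guards
        # the optimizer's trial steps against overflow
        shared = float(np.clip(theta[0], -60.0, 60.0))
        log_crefs = np.clip(theta[1 : 1 + n_prof], -60.0, 10.0)
        baselines = theta[1 + n_prof :]
        return shared, np.exp(log_crefs), baselines

    def residuals(theta):
        shared, crefs, baselines = unpack(theta)
        out = []
        for pr, c0, b in zip(profiles, crefs, baselines):
            pp = replace(p, omega=rpm_to_omega(pr.speed_rpm))
            if model == "single":
                pp = replace(pp, M=math.exp(shared))
                pred = predict_se_profile(
                    pp, "single", c0, pr.radii, pr.r0, baseline=b, epsilon=eps
                )
            else:
                pred = predict_se_profile(
                    pp, "monomer_dimer", c0, pr.radii, pr.r0,
                    K_A=math.exp(shared), baseline=b, epsilon=eps,
                )
            out.append(pred - pr.signal)
        res = np.concatenate(out)
        return res / noise_sd if noise_sd else res

    # data-driven starting guesses for the per-profile parameters
    c0_guess = [max(pr.signal.mean(), 1e-3 * abs(pr.signal).max() + 1e-12) / eps
                for pr in profiles]
    b_guess = [0.0] * n_prof
    if model == "single":
        starts = [math.log(p.M)]
    else:
        starts = [math.log(ka) for ka in np.logspace(3, 9, 5)]

    best = None
    for s0 in starts:
        theta0 = np.concatenate([[s0], np.log(c0_guess), b_guess])
        sol = least_squares(residuals, theta0, method="lm", xtol=1e-12, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e6:
        raise RuntimeError("fit failed: no optimizer start converged")

    shared, crefs, baselines = unpack(best.x)
    res = residuals(best.x)
    n_params = len(best.x)
    chi2 = float(2 * best.cost / max(len(y) - n_params, 1))
    rms = []
    i = 0
    for pr in profiles:
        m = len(pr.signal)
        r = res[i : i + m] * (noise_sd if noise_sd else 1.0)
        rms.append(float(np.sqrt(np.mean(r**2))))
        i += m
    if model == "single":
        return SEFitResult("single", math.exp(shared), None, None,
                           list(crefs), list(baselines), rms, chi2, len(y))
    ka = math.exp(shared)
    return SEFitResult("monomer_dimer", None, ka, ka_to_kd(ka),
                       list(crefs), list(baselines), rms, chi2, len(y))


def profiles_from_table(df) -> list[SEProfile]:
    """Build SEProfiles from a table with columns radius_cm, signal,
    speed_rpm, sample_id (one profile per (sample_id, speed_rpm))."""
    required = {"radius_cm", "signal", "speed_rpm", "sample_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    profiles = []
    for (sid, rpm), grp in df.groupby(["sample_id", "speed_rpm"], sort=True):
        grp = grp.sort_values("radius_cm")
        radii = grp["radius_cm"].to_numpy(dtype=float)
        profiles.append(
            SEProfile(float(rpm), radii, grp["signal"].to_numpy(dtype=float),
                      r0=float(radii[0]), sample_id=str(sid))
        )
    return profiles
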