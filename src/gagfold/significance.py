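"""Decoy-background Z-scores, panel-wide combination, and the
forward-vs-reverse pairing differential.

A native alignment score is standardized against its decoy background
(Z-score).  Z-scores for one domain pairing (NN, NC, CN or CC) across a
panel of viruses are combined into a single one-tailed probability, either
by Stouffer's method (Σz/√k against the normal upper tail) or by a
one-sample t-test of the Z values against zero.  The forward-vs-reverse
differential is the log10 ratio of the forward-pairing probability product
(NN·CC) to the reverse product (NC·CN); a positive −Δ favours the forward
(linear) domain correspondence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .decoys import DecoyBackground

__all__ = [
    "PAIRINGS",
    "ComparisonResult",
    "PairingTable",
    "CombinedSignificance",
    "DifferentialResult",
    "z_score",
    "combine_z",
    "differential_log_prob",
    "differential_from_log10",
    "log10_tail_from_z",
]

PAIRINGS = ("NN", "NC", "CN", "CC")


@dataclass
class ComparisonResult:
    virus: str
    pairing: str  # one of PAIRINGS
    score_native: float
    mu_d: float
    sigma_d: float
    z: float


@dataclass
class PairingTable:
    viruses: list[str]
    z: dict  # (virus, pairing) -> Z

    def column(self, pairing: str) -> list[float]:
        return [self.z[(v, pairing)] for v in self.viruses]


@dataclass
class CombinedSignificance:
    pairing: str
    method: str  # "stouffer" | "one_sample_t"
    statistic: float
    p: float  # one-tailed combined probability; may underflow to 0.0
    log10_p: float  # exact log10 of p (computed in log space)
    minus_log10_exponent: int  # magnitude of the base-10 exponent of p


@dataclass
class DifferentialResult:
    delta: float  # log10(T_NN·T_CC) − log10(T_NC·T_CN)
    minus_delta_rounded: int  # (expNN + expCC) − (expNC + expCN)


def z_score(score_native: float, background: DecoyBackground) -> ComparisonResult:
    """Standardize a native score against its decoy background."""
    if background.n < 2 or background.degenerate or background.sd <= 0:
        raise ValueError("degenerate background: sd must be positive")
    z = (score_native - background.mean) / background.sd
    return ComparisonResult("", "", score_native, background.mean, background.sd, z)


def _exponent_magnitude(log10_p: float) -> int:
    """Exponent magnitude of p in normalized scientific notation.

    9.47e-15 -> 15; 1.49e-6 -> 6 (i.e. −floor(log10 p))."""
    return int(-math.floor(log10_p))


def log10_tail_from_z(z: float) -> float:
    """log10 of the standard-normal upper-tail probability, underflow-safe."""
    return float(stats.norm.logsf(z) / math.log(10.0))


def combine_z(z_values, method: str = "stouffer", pairing: str = "") -> CombinedSignificance:
    """Combine per-virus Z-scores into one one-tailed probability.

    stouffer:     statistic = Σz/√k, p = P(N(0,1) > statistic)
    one_sample_t: statistic = mean/(sd/√k), p = P(t_{k−1} > statistic)
    """
    z = np.sort(np.asarray(list(z_values), dtype=float))  # exact permutation invariance
    k = len(z)
    if k < 2:
        raise ValueError("need at least 2 Z values to combine")
    if method == "stouffer":
        statistic = float(z.sum() / math.sqrt(k))
        logp = stats.norm.logsf(statistic)
    elif method == "one_sample_t":
        statistic = float(z.mean() / (z.std(ddof=1) / math.sqrt(k)))
        logp = stats.t.logsf(statistic, df=k - 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    log10_p = float(logp / math.log(10.0))
    return CombinedSignificance(
        pairing, method, statistic, float(np.exp(logp)), log10_p,
        _exponent_magnitude(log10_p),
    )


def differential_log_prob(t_nn: float, t_cc: float, t_nc: float, t_cn: float) -> DifferentialResult:
    """Forward-vs-reverse differential from four pairing probabilities.

    ``delta = log10(t_nn·t_cc) − log10(t_nc·t_cn)`` (negative when the
    forward pairing is the more significant) and the integer variant built
    from exponent magnitudes, matching the convention of quoting −log10
    values as the printed exponents.
    """
    probs = (t_nn, t_cc, t_nc, t_cn)
    if any((not np.isfinite(p)) or p <= 0 or p > 1 for p in probs):
        raise ValueError("probabilities must be in (0, 1]")
    logs = [math.log10(p) for p in probs]
    return differential_from_log10(*logs)


def differential_from_log10(
    l_nn: float, l_cc: float, l_nc: float, l_cn: float
) -> DifferentialResult:
    """Differential from log10 probabilities (safe for underflowing p)."""
    delta = (l_nn + l_cc) - (l_nc + l_cn)
    minus_delta = (
        _exponent_magnitude(l_nn) + _exponent_magnitude(l_cc)
        - _exponent_magnitude(l_nc) - _exponent_magnitude(l_cn)
    )
    return DifferentialResult(float(delta), int(minus_delta))
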