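"""Double-dynamic-programming structural alignment of Cα traces.

Each residue is described by its *structural environment*: the vector of
distances from its Cα to every other Cα in the same chain.  A low-level
dynamic program scores how well two residues' environments superpose when
walked in parallel along the two chains; the resulting pair-score matrix is
sharpened by a fixed number of soft path-reinforcement cycles and a
high-level dynamic program (free end gaps) selects the final residue
pairing.  The whole procedure uses internal distances only, so the score is
invariant under independent rigid motions of either input, and it is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .structures import StructureModel
from .superpose import kabsch_superpose

__all__ = [
    "Alignment",
    "environment_views",
    "pair_score_matrix",
    "align",
    "SIGMA_D0",
    "WEIGHT_OFFSET",
    "ENV_WINDOW",
]

#: Distance-difference scale (Å) of the low-level element similarity
#: s(Δd) = 1 / (1 + (Δd/σ)²).
SIGMA_D0 = 3.0
#: Neighbour down-weighting w(d) = 1 / (10 + d), d in Å (mean of the two
#: compared distances), so remote neighbours contribute little.
WEIGHT_OFFSET = 10.0
#: Environments are compared over this many sequence neighbours on each side
#: of the anchored pair; distant neighbours carry almost no weight, so a
#: finite window loses little signal while bounding the low-level cost.
ENV_WINDOW = 15
#: Gap penalty per skipped element in the low-level environment DP (same
#: units as the element similarity, whose ceiling is 1/WEIGHT_OFFSET).
LOW_GAP = 0.02
#: High-level DP internal gap penalty per residue; end gaps are free.
HIGH_GAP = 1.0
#: Soft-iteration cycles: best path cells are up-weighted (×2) and the
#: high-level selection repeated.
N_ITER = 3
#: Cells below this fraction of the matrix maximum do not contribute to the
#: raw score sum (noise floor).
NOISE_FLOOR = 0.05


@dataclass
class Alignment:
    pairs: list[tuple[int, int]]  # strictly increasing in both coordinates
    score_raw: float
    score_norm: float  # score_raw / min(n1, n2)
    rmsd: float  # Å over the paired Cα after optimal superposition
    pair_scores: list[float] | None = None  # converged matrix value per pair

    def to_tsv(self) -> str:
        scores = self.pair_scores or [float("nan")] * len(self.pairs)
        lines = ["i\tj\tscore"]
        lines += [f"{i}\t{j}\t{s:.6g}" for (i, j), s in zip(self.pairs, scores)]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "pairs": self.pairs,
                "score_raw": self.score_raw,
                "score_norm": self.score_norm,
                "rmsd": self.rmsd,
            }
        )


def environment_views(model: StructureModel) -> np.ndarray:
    """Full pairwise Cα distance matrix of one model (Å).

    Row *i* is residue *i*'s structural environment.  Depends on internal
    geometry only.
    """
    if len(model) < 2:
        raise ValueError("degenerate model: need at least 2 residues")
    return cdist(model.ca_coords, model.ca_coords)


@njit(cache=True)
def _env_dp(pa, pb, gap):  # pragma: no cover - numba
    """Global alignment score of two short distance profiles."""
    la, lb = pa.shape[0], pb.shape[0]
    if la == 0 or lb == 0:
        return 0.0
    prev = np.empty(lb + 1)
    cur = np.empty(lb + 1)
    for l in range(lb + 1):
        prev[l] = -gap * l
    for k in range(1, la + 1):
        cur[0] = -gap * k
        dk = pa[k - 1]
        for l in range(1, lb + 1):
            dl = pb[l - 1]
            dd = dk - dl
            if dd < 0.0:
                dd = -dd
            w = 1.0 / (10.0 + 0.5 * (dk + dl))
            s = w / (1.0 + (dd / 3.0) ** 2)
            best = prev[l - 1] + s
            if prev[l] - gap > best:
                best = prev[l] - gap
            if cur[l - 1] - gap > best:
                best = cur[l - 1] - gap
            cur[l] = best
        prev, cur = cur, prev
    return prev[lb]


@njit(cache=True)
def _lowlevel_matrix(da, db, window, gap):  # pragma: no cover - numba
    n1, n2 = da.shape[0], db.shape[0]
    m = np.zeros((n1, n2))
    for i in range(n1):
        lo_a = i - window if i - window > 0 else 0
        hi_a = i + 1 + window if i + 1 + window < n1 else n1
        left_a = da[i, lo_a:i][::-1].copy()  # walk outward from the anchor
        right_a = da[i, i + 1 : hi_a].copy()
        for j in range(n2):
            lo_b = j - window if j - window > 0 else 0
            hi_b = j + 1 + window if j + 1 + window < n2 else n2
            left_b = db[j, lo_b:j][::-1].copy()
            right_b = db[j, j + 1 : hi_b].copy()
            s = _env_dp(left_a, left_b, gap) + _env_dp(right_a, right_b, gap)
            m[i, j] = s if s > 0.0 else 0.0
    return m


@njit(cache=True)
def _high_dp(m, gap):  # pragma: no cover - numba
    """Global DP with free end gaps; returns the matched (i, j) path.

    Tie-break is fixed (up preferred over diagonal over left) so the result
    is deterministic.
    """
    n1, n2 = m.shape
    h = np.zeros((n1 + 1, n2 + 1))
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            diag = h[i - 1, j - 1] + m[i - 1, j - 1]
            up = h[i - 1, j] - (gap if j != n2 else 0.0)
            left = h[i, j - 1] - (gap if i != n1 else 0.0)
            best = up
            if diag > best:
                best = diag
            if left > best:
                best = left
            h[i, j] = best
    # traceback from the corner (end gaps free along the last row/column)
    pairs = np.empty((min(n1, n2), 2), dtype=np.int64)
    k = 0
    i, j = n1, n2
    while i > 0 and j > 0:
        up = h[i - 1, j] - (gap if j != n2 else 0.0)
        diag = h[i - 1, j - 1] + m[i - 1, j - 1]
        left = h[i, j - 1] - (gap if i != n1 else 0.0)
        if h[i, j] == up:
            i -= 1
        elif h[i, j] == diag:
            k += 1
            pairs[min(n1, n2) - k, 0] = i - 1
            pairs[min(n1, n2) - k, 1] = j - 1
            i -= 1
            j -= 1
        else:
            j -= 1
    return pairs[min(n1, n2) - k :, :].copy()


def pair_score_matrix(
    a: StructureModel,
    b: StructureModel,
    iterations: int = N_ITER,
    window: int = ENV_WINDOW,
) -> np.ndarray:
    """Converged residue-pair score matrix (n1 × n2, non-negative).

    Entry (i, j) is the low-level DP score of walking residue i's and
    residue j's distance profiles in parallel (outward from the anchored
    pair, both directions), multiplied by the soft-iteration weight built up
    by ``iterations`` cycles of best-path reinforcement.
    """
    da = environment_views(a)
    db = environment_views(b)
    m0 = _lowlevel_matrix(da, db, window, LOW_GAP)
    weights = np.ones_like(m0)
    for _ in range(iterations):
        pairs = _high_dp(m0 * weights, HIGH_GAP)
        weights[pairs[:, 0], pairs[:, 1]] *= 2.0
    return m0 * weights


def align(a: StructureModel, b: StructureModel) -> Alignment:
    """Align two Cα traces; returns the pairing and decoy-comparable scores.

    ``score_raw`` sums the converged matrix entries on the selected path,
    ignoring cells below ``NOISE_FLOOR`` of the matrix maximum;
    ``score_norm`` divides by the shorter chain length so models of
    different size are comparable.
    """
    m = pair_score_matrix(a, b)
    pairs_arr = _high_dp(m, HIGH_GAP)
    pairs = [(int(i), int(j)) for i, j in pairs_arr]
    floor = NOISE_FLOOR * m.max() if m.size else 0.0
    on_path = m[pairs_arr[:, 0], pairs_arr[:, 1]] if len(pairs) else np.empty(0)
    score_raw = float(on_path[on_path >= floor].sum())
    score_norm = score_raw / min(len(a), len(b))
    if len(pairs) >= 3:
        rmsd = kabsch_superpose(
            a.ca_coords[pairs_arr[:, 0]], b.ca_coords[pairs_arr[:, 1]]
        ).rmsd
    else:
        rmsd = float("nan")
    return Alignment(pairs, score_raw, score_norm, rmsd, [float(s) for s in on_path])
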