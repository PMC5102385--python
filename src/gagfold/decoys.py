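"""Random compact decoy models matched to a native's secondary structure.

Significance of a native-vs-native alignment score is judged against a
background of alignments between *decoys*: random compact models with
exactly the native's ordered secondary-structure segment list (helix and
strand segments with ideal local geometry, coil segments as self-avoiding
walks), so that the null distribution reflects chance similarity between
structures of the same size and composition, not between arbitrary folds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from . import sap_align
from .structures import StructureModel, assign_ss, segment_list

__all__ = [
    "DecoySpec",
    "DecoyBackground",
    "generate_decoy",
    "decoy_background",
    "spec_from_model",
    "child_seed",
    "RG_COEFF",
    "RG_EXPONENT",
    "RG_SLACK",
]

#: Compactness constraint: radius of gyration ≤ RG_SLACK · RG_COEFF · N^RG_EXPONENT Å,
#: the empirical globular-protein scaling with 30% slack.
RG_COEFF = 2.2
RG_EXPONENT = 0.38
RG_SLACK = 1.3

CA_STEP = 3.8  # Å, bonded Cα–Cα
STEP_TOL = 0.2  # Å, allowed deviation at segment junctions
CLASH_DIST = 4.0  # Å, minimum non-bonded (|i−j| > 2) Cα–Cα separation
MAX_ATTEMPTS = 10_000
_CANDIDATES_PER_SEGMENT = 40  # random orientations tried per placement round


@dataclass
class DecoySpec:
    """Recipe for one decoy: the native's ordered (class, length) segments."""

    length: int
    segments: list[tuple[str, int]]
    seed: int

    def __post_init__(self) -> None:
        if sum(n for _, n in self.segments) != self.length:
            raise ValueError("segment lengths must sum to length")
        if any(c not in "HEC" or n < 1 for c, n in self.segments):
            raise ValueError("invalid segment list")


@dataclass
class DecoyBackground:
    scores: np.ndarray  # score_norm of each decoy-vs-decoy alignment
    n: int
    mean: float
    sd: float
    seed: int
    degenerate: bool = False  # sd == 0


def spec_from_model(
    model: StructureModel, seed: int, composition_only: bool = False
) -> DecoySpec:
    """Decoy recipe matched to a model's assigned secondary structure.

    By default the native's full ordered segment list is preserved (the
    strictest reading of matched composition).  ``composition_only``
    additionally shuffles the segment order (seeded), keeping only the
    class composition; this looser null is available for comparison but is
    not used by the default pipeline.
    """
    if not model.ss:
        model = assign_ss(model)
    segments = segment_list(model.ss)
    if composition_only:
        rng = np.random.default_rng(seed)
        segments = [segments[i] for i in rng.permutation(len(segments))]
    return DecoySpec(len(model), segments, seed)


def child_seed(master: int, label: str, index: int) -> int:
    """Deterministic, well-mixed child seed (< 2**31) for one replicate."""
    digest = hashlib.sha256(f"{master}:{label}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _ideal_helix_segment(n: int) -> np.ndarray:
    """Cα helix: radius 2.3 Å, rise 1.5 Å/residue, 100°/residue."""
    t = np.arange(n) * np.deg2rad(100.0)
    return np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)])


def _ideal_strand_segment(n: int) -> np.ndarray:
    """Planar zigzag with 3.8 Å steps and d(i,i+2) ≈ 6.7 Å."""
    half_angle = np.arcsin(6.7 / (2 * CA_STEP))
    rise = CA_STEP * np.sin(half_angle)
    sway = CA_STEP * np.cos(half_angle)
    x = np.arange(n) * rise
    y = np.where(np.arange(n) % 2 == 0, 0.0, sway)
    return np.column_stack([x, y, np.zeros(n)])


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """(n, 3, 3) uniform random rotation matrices from unit quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    rot = np.empty((n, 3, 3))
    rot[:, 0, 0] = 1 - 2 * (y**2 + z**2)
    rot[:, 0, 1] = 2 * (x * y - w * z)
    rot[:, 0, 2] = 2 * (x * z + w * y)
    rot[:, 1, 0] = 2 * (x * y + w * z)
    rot[:, 1, 1] = 1 - 2 * (x**2 + z**2)
    rot[:, 1, 2] = 2 * (y * z - w * x)
    rot[:, 2, 0] = 2 * (x * z - w * y)
    rot[:, 2, 1] = 2 * (y * z + w * x)
    rot[:, 2, 2] = 1 - 2 * (x**2 + y**2)
    return rot


def _clash_free_mask(coords: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Which candidate segment placements avoid the built coordinates.

    ``candidates`` is (C, m, 3).  The two residues of the built chain bonded
    or next-bonded to the segment start (sequence separation ≤ 2) are
    exempt; segment-internal geometry is clash-free by construction.
    """
    n_old = len(coords)
    if n_old == 0:
        return np.ones(len(candidates), dtype=bool)
    d = np.linalg.norm(candidates[:, :, None, :] - coords[None, None, :, :], axis=3)
    # old residue index o, new local index k -> separation (n_old - o) + k
    sep = (n_old - np.arange(n_old))[None, None, :] + np.arange(candidates.shape[1])[None, :, None]
    return ~np.any((d < CLASH_DIST) & (sep > 2), axis=(1, 2))


def _segment_template(cls: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if cls == "H":
        return _ideal_helix_segment(n)
    if cls == "E":
        return _ideal_strand_segment(n)
    # coil: self-avoiding random walk at fixed step length
    pts = [np.zeros(3)]
    for _ in range(n - 1):
        for _attempt in range(50):
            step = rng.standard_normal(3)
            step *= CA_STEP / np.linalg.norm(step)
            cand = pts[-1] + step
            prior = np.array(pts[:-2]) if len(pts) > 2 else None
            if prior is None or np.all(np.linalg.norm(prior - cand, axis=1) >= CLASH_DIST):
                break
        pts.append(cand)
    return np.array(pts)


def _rg(coords: np.ndarray) -> float:
    c = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(c**2, axis=1))))


def generate_decoy(spec: DecoySpec) -> StructureModel:
    """Build one random compact model realizing ``spec``.

    Segments keep ideal internal geometry (helix/strand) or are drawn as
    self-avoiding walks (coil); successive segments are attached at a bonded
    step (3.8 ± 0.2 Å) under random orientations, accepting, among the
    clash-free candidates of each round, the one giving the most compact
    intermediate (greedy compaction keeps the radius of gyration inside the
    globular envelope while the packing stays random across seeds).

    Deterministic for a given spec (including seed).  Raises ``RuntimeError``
    if no clash-free compact arrangement is found within the attempt budget.
    """
    rg_limit = RG_SLACK * RG_COEFF * spec.length**RG_EXPONENT
    rng = np.random.default_rng(spec.seed)
    attempts = 0
    c_batch = _CANDIDATES_PER_SEGMENT
    for _restart in range(20):
        coords = np.empty((0, 3))
        ok = True
        for cls, n in spec.segments:
            template = _segment_template(cls, n, rng)
            template = template - template[0]
            attempts += c_batch
            if attempts > MAX_ATTEMPTS:
                raise RuntimeError(
                    f"decoy construction failed (seed={spec.seed}, attempts={attempts})"
                )
            rots = _random_rotations(rng, c_batch)
            cands = np.einsum("cij,nj->cni", rots, template)
            if len(coords):
                steps = CA_STEP + rng.uniform(-STEP_TOL, STEP_TOL, size=c_batch)
                dirs = rng.standard_normal((c_batch, 3))
                dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
                cands = cands + (coords[-1] + steps[:, None] * dirs)[:, None, :]
            free = _clash_free_mask(coords, cands)
            if not np.any(free):
                ok = False
                break
            # greedy compaction: among clash-free placements take the one
            # minimizing the running radius of gyration
            free_idx = np.nonzero(free)[0]
            n_tot = len(coords) + n
            sums = coords.sum(axis=0) + cands[free_idx].sum(axis=1)
            sq = (coords**2).sum() + (cands[free_idx] ** 2).sum(axis=(1, 2))
            rg2 = sq / n_tot - (sums**2).sum(axis=1) / n_tot**2
            placed = cands[free_idx[np.argmin(rg2)]]
            coords = np.vstack([coords, placed])
        if ok and _rg(coords) <= rg_limit:
            model = StructureModel(
                f"decoy-{spec.seed}", [str(i + 1) for i in range(spec.length)], coords
            )
            return assign_ss(model)
    raise RuntimeError(
        f"decoy construction failed (seed={spec.seed}, attempts={attempts})"
    )


def decoy_background(
    a: StructureModel, b: StructureModel, n: int, seed: int
) -> DecoyBackground:
    """Null score distribution: n alignments of (decoy~a) vs (decoy~b).

    Child seeds derive deterministically from the master seed, the pair
    label and the replicate index, so every decoy is individually
    reproducible.
    """
    if n < 10:
        raise ValueError("need at least 10 background comparisons")
    label = f"{a.id}|{b.id}"
    scores = np.empty(n)
    for k in range(n):
        da = generate_decoy(spec_from_model(a, child_seed(seed, label + "/a", k)))
        db = generate_decoy(spec_from_model(b, child_seed(seed, label + "/b", k)))
        scores[k] = sap_align.align(da, db).score_norm
    sd = float(scores.std(ddof=1))
    return DecoyBackground(
        scores, n, float(scores.mean()), sd, seed, degenerate=(sd == 0.0)
    )
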