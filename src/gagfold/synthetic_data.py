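"""Seeded generators for every input class the pipeline consumes.

Three families of synthetic data emulate the study's inputs:

* toy helical-bundle domains — a 4-helix "N-terminal-like" layout and a
  5-helix "C-terminal-like" layout — with controllable kinship between
  pairs (shared template plus coordinate noise vs unrelated layouts);
* multi-speed, multi-loading sedimentation-equilibrium profiles of a
  monomer–dimer self-associating species;
* per-residue ¹⁵N relaxation records of a rigid isotropic rotor, with a
  configurable fraction of flexible "loop" residues that fail the
  heteronuclear-NOE rigidity filter.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import decoys as _decoys
from .decoys import child_seed
from .hydrodynamics import BuoyancyParams, SEProfile, predict_se_profile, rpm_to_omega
from .relaxation import RelaxRecord, SpinParams, predict_relaxation
from .structures import StructureModel, assign_ss

__all__ = [
    "BundleSpec",
    "HomologyQuartet",
    "build_ideal_helix",
    "build_bundle",
    "perturb",
    "make_homology_quartet",
    "generate_se_dataset",
    "generate_relaxation_dataset",
    "N_LAYOUT",
    "C_LAYOUT",
]

#: Default segment layouts of the two toy domains: a 4-helix bundle
#: (N-terminal-like) and a 5-helix bundle (C-terminal-like).  Sizes are kept
#: small (~40–50 residues) so the decoy-background simulations run quickly;
#: helix/loop proportions mirror compact all-α domains.
N_LAYOUT = [("H", 9), ("C", 4), ("H", 8), ("C", 4), ("H", 9), ("C", 4), ("H", 8)]
C_LAYOUT = [("H", 8), ("C", 4), ("H", 7), ("C", 4), ("H", 8), ("C", 4),
            ("H", 7), ("C", 4), ("H", 8)]

HELIX_RADIUS = 2.3  # Å
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue


def build_ideal_helix(n: int) -> StructureModel:
    """Cα trace of an ideal α-helix (radius 2.3 Å, rise 1.5 Å, 100°/res)."""
    if n < 1:
        raise ValueError("need at least one residue")
    t = np.arange(n) * np.deg2rad(HELIX_TWIST)
    coords = np.column_stack(
        [HELIX_RADIUS * np.cos(t), HELIX_RADIUS * np.sin(t), HELIX_RISE * np.arange(n)]
    )
    model = StructureModel("ideal-helix", [str(i + 1) for i in range(n)], coords)
    return assign_ss(model)


@dataclass
class BundleSpec:
    segments: list[tuple[str, int]]
    inter_helix_distance: float = 10.5  # Å between neighbouring helix axes
    antiparallel: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments or any(n < 1 for _, n in self.segments):
            raise ValueError("need at least one segment of positive length")


@dataclass
class HomologyQuartet:
    """Four toy domains with designed kinship.

    ``spuma_n``/``ortho_n`` are independent noisy copies of one shared
    4-helix template, ``spuma_c``/``ortho_c`` of one shared 5-helix
    template, so the forward pairs (NN, CC) are true structural kin and the
    cross pairs (NC, CN) are not.
    """

    spuma_n: StructureModel
    spuma_c: StructureModel
    ortho_n: StructureModel
    ortho_c: StructureModel
    seed: int = 0

    def pair(self, pairing: str) -> tuple[StructureModel, StructureModel]:
        return {
            "NN": (self.spuma_n, self.ortho_n),
            "CC": (self.spuma_c, self.ortho_c),
            "NC": (self.spuma_n, self.ortho_c),
            "CN": (self.spuma_c, self.ortho_n),
        }[pairing]


_CA_STEP = 3.8
_CLASH = 4.0


def _helix_coords(n: int, phase: float, origin: np.ndarray, reverse: bool) -> np.ndarray:
    """Ideal helix along +z (or −z when reversed) starting at z of ``origin``."""
    t = np.arange(n) * np.deg2rad(HELIX_TWIST) + phase
    z = HELIX_RISE * np.arange(n)
    if reverse:
        z = z[::-1].copy()  # runs top-to-bottom; residue order preserved
        t = t[::-1].copy()
    return np.column_stack(
        [HELIX_RADIUS * np.cos(t), HELIX_RADIUS * np.sin(t), z]
    ) + origin


def _bridge_loop(
    start: np.ndarray,
    target: np.ndarray | None,
    n: int,
    context: np.ndarray,
    context_idx: np.ndarray,
    start_idx: int,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Random walk of ``n`` residues from ``start`` toward ``target``.

    Steps are 3.8 Å; the implicit final bond (last loop residue → target)
    must land in the bonded range.  ``context``/``context_idx`` are the
    coordinates and global residue indices of everything else in the chain
    (built and future); the loop occupies global indices ``start_idx`` ..
    ``start_idx + n − 1`` and candidates must stay ≥ 4 Å from every context
    residue at sequence separation > 2.  ``target=None`` drops the bridging
    constraints (free terminal walk).  Returns None when the draw fails.
    """
    pts: list[np.ndarray] = []
    pos = start.copy()
    for k in range(n):
        g = start_idx + k
        sep_ok = np.abs(context_idx - g) > 2
        obstacles = context[sep_ok]
        bonds_left = n - k  # bonds remaining after this one, incl. final
        placed = None
        for _try in range(60):
            if target is None:
                direction = rng.standard_normal(3)
            else:
                u = target - pos
                d = np.linalg.norm(u)
                u = u / d if d > 0 else rng.standard_normal(3)
                w = rng.uniform(0.2, 1.0)
                direction = w * u + (1.0 - w) * rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            cand = pos + _CA_STEP * direction
            if target is not None:
                d_next = np.linalg.norm(target - cand)
                if d_next > bonds_left * _CA_STEP * 0.95:
                    continue  # would strand the walk too far from the target
                if bonds_left == 1 and not (2.9 <= d_next <= 4.1):
                    continue  # final bond must be a plausible Cα–Cα step
            if len(obstacles) and np.any(
                np.linalg.norm(obstacles - cand, axis=1) < _CLASH
            ):
                continue
            if len(pts) > 2 and np.any(
                np.linalg.norm(np.array(pts[:-2]) - cand, axis=1) < _CLASH
            ):
                continue
            placed = cand
            break
        if placed is None:
            return None
        pts.append(placed)
        pos = placed
    return np.array(pts)


def build_bundle(spec: BundleSpec) -> StructureModel:
    """Helical bundle: helices on a serpentine grid, loops as bridging walks.

    Helix axes sit at ``inter_helix_distance`` within a row and slightly
    closer between rows, visited in serpentine order so consecutive helices
    are spatial neighbours; odd-numbered helices run antiparallel when
    requested.  Loop segments are clash-avoiding random walks bridging
    consecutive helix ends.  Deterministic for a given spec (including
    seed); raises ``RuntimeError`` when no clash-free build is found.
    """
    helices = [(cls, n) for cls, n in spec.segments if cls == "H"]
    rng = np.random.default_rng(spec.seed)
    for _attempt in range(100):
        # fix all helix placements first so loop walks know their targets
        placements = []
        for h, (_, n) in enumerate(helices):
            row, col = h // 2, h % 2
            if row % 2 == 1:
                col = 1 - col  # serpentine: consecutive helices stay adjacent
            origin = np.array(
                [col * spec.inter_helix_distance,
                 row * spec.inter_helix_distance * 0.85, 0.0]
            )
            reverse = spec.antiparallel and h % 2 == 1
            placements.append(_helix_coords(n, rng.uniform(0, 2 * np.pi), origin, reverse))

        # global residue index of every segment start
        seg_starts = np.cumsum([0] + [n for _, n in spec.segments[:-1]])
        helix_starts = [s for s, (c, _) in zip(seg_starts, spec.segments) if c == "H"]

        coords_parts: list[np.ndarray] = []
        ok = True
        h = 0
        for si, (cls, n) in enumerate(spec.segments):
            if cls == "H":
                coords_parts.append(placements[h])
                h += 1
                continue
            built = np.vstack(coords_parts) if coords_parts else np.empty((0, 3))
            start = built[-1] if len(built) else np.zeros(3)
            # clash context: everything built plus the fixed future helices,
            # tagged with global indices so bonded neighbours are exempt
            ctx = [built] + placements[h:]
            ctx_idx = [np.arange(len(built))] + [
                hs + np.arange(len(pl))
                for hs, pl in zip(helix_starts[h:], placements[h:])
            ]
            context = np.vstack(ctx)
            context_idx = np.concatenate(ctx_idx)
            target = placements[h][0] if h < len(placements) else None
            seg = None
            for _retry in range(20):
                seg = _bridge_loop(start, target, n, context, context_idx,
                                   int(seg_starts[si]), rng)
                if seg is not None:
                    break
            if seg is None:
                ok = False
                break
            coords_parts.append(seg)
        if not ok:
            continue
        coords = np.vstack(coords_parts)
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        d = cdist(coords, coords)
        i, j = np.triu_indices(len(coords), k=3)
        if np.all((steps > 2.8) & (steps < 4.2)) and np.all(d[i, j] >= _CLASH):
            model = StructureModel(
                f"bundle-{spec.seed}",
                [str(k + 1) for k in range(len(coords))],
                coords,
            )
            return assign_ss(model)
    raise RuntimeError(f"bundle construction failed (seed={spec.seed})")


def perturb(model: StructureModel, sigma: float, seed: int) -> StructureModel:
    """Add independent zero-mean Gaussian noise (per-coordinate sd ``sigma``)
    to every Cα and re-assign secondary structure."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    coords = model.ca_coords + rng.normal(0.0, sigma, size=model.ca_coords.shape)
    out = StructureModel(f"{model.id}~p{seed}", list(model.residue_ids), coords)
    return assign_ss(out)


TEMPLATE_NOISE_SIGMA = 1.0  # Å; keeps kin pairs clearly above decoy noise


def _noisy_copy(template: StructureModel, sigma: float, seed: int) -> StructureModel:
    """Template plus iid coordinate noise, keeping the template's secondary
    structure.

    Quartet members carry their template's SS as construction ground truth
    (the kinship design fixes the composition); re-deriving it from the
    noisy geometry would fragment the segment list the decoy generator must
    match.
    """
    rng = np.random.default_rng(seed)
    coords = template.ca_coords + rng.normal(0.0, sigma, size=template.ca_coords.shape)
    return StructureModel(f"{template.id}~n{seed}", list(template.residue_ids),
                          coords, ss=template.ss)


def make_homology_quartet(seed: int) -> HomologyQuartet:
    """Two kin pairs (shared templates + 1.0 Å noise) and two cross pairs."""
    n_template = build_bundle(BundleSpec(N_LAYOUT, seed=child_seed(seed, "quartet/Nt", 0)))
    c_template = build_bundle(BundleSpec(C_LAYOUT, seed=child_seed(seed, "quartet/Ct", 0)))
    s = TEMPLATE_NOISE_SIGMA
    quartet = HomologyQuartet(
        spuma_n=_noisy_copy(n_template, s, child_seed(seed, "quartet/sn", 1)),
        ortho_n=_noisy_copy(n_template, s, child_seed(seed, "quartet/on", 2)),
        spuma_c=_noisy_copy(c_template, s, child_seed(seed, "quartet/sc", 3)),
        ortho_c=_noisy_copy(c_template, s, child_seed(seed, "quartet/oc", 4)),
        seed=seed,
    )
    for name in ("spuma_n", "spuma_c", "ortho_n", "ortho_c"):
        model = getattr(quartet, name)
        model.id = f"{name}-{seed}"
    return quartet


def generate_se_dataset(
    p: BuoyancyParams,
    kd: float,
    loadings,
    speeds,
    noise_sd_frac: float = 0.005,
    seed: int = 0,
    n_points: int = 40,
    r_meniscus: float = 6.9,
    r_base: float = 7.4,
) -> list[SEProfile]:
    """Multi-speed, multi-loading monomer–dimer equilibrium profiles.

    ``kd`` is the dissociation constant in molar (0 disables association);
    ``loadings`` are molar monomer reference concentrations; noise is
    Gaussian with sd ``noise_sd_frac`` of the loading's reference signal
    ε·c₀ (a constant per profile, like the read noise of interference
    optics, rather than a fraction of the steeply graded signal itself).
    """
    from dataclasses import replace

    if kd < 0:
        raise ValueError("kd must be non-negative")
    ka = 0.0 if kd == 0 else 1.0 / kd
    rng = np.random.default_rng(seed)
    radii = np.linspace(r_meniscus, r_base, n_points)
    profiles = []
    for li, c0 in enumerate(loadings):
        for rpm in speeds:
            pp = replace(p, omega=rpm_to_omega(rpm))
            model = "monomer_dimer" if ka > 0 else "single"
            signal = predict_se_profile(pp, model, c0, radii, r0=radii[0], K_A=ka)
            if noise_sd_frac > 0:
                from .hydrodynamics import default_epsilon

                sd = noise_sd_frac * default_epsilon(p.M) * c0
                signal = signal + rng.normal(0.0, sd, size=signal.shape)
            profiles.append(
                SEProfile(rpm, radii.copy(), signal, r0=radii[0], sample_id=f"load{li}")
            )
    return profiles


def generate_relaxation_dataset(
    tau_c: float,
    sp: SpinParams,
    n_residues: int = 50,
    noise_frac: float = 0.0,
    loop_fraction: float = 0.0,
    seed: int = 0,
) -> list[RelaxRecord]:
    """Per-residue relaxation records of a rigid rotor plus flexible loops.

    Rigid residues get the forward-model T1/T2 with fractional Gaussian
    noise and NOE drawn in [0.76, 0.86]; the first ``loop_fraction`` of
    residues mimic flexible termini/loops (NOE in [−0.2, 0.6], inflated T2)
    and therefore fail the 0.75 rigidity cutoff by construction.
    """
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    rng = np.random.default_rng(seed)
    t1, t2, _ = predict_relaxation(tau_c, sp)
    n_loop = int(round(loop_fraction * n_residues))
    records = []
    for i in range(n_residues):
        if i < n_loop:
            noe = rng.uniform(-0.2, 0.6)
            rec = RelaxRecord(
                f"R{i + 1}",
                t1 * rng.uniform(0.6, 0.9),
                t2 * rng.uniform(3.0, 8.0),  # fast internal motion lengthens T2
                noe,
            )
        else:
            noe = rng.uniform(0.76, 0.86)
            f1 = 1.0 + noise_frac * rng.standard_normal()
            f2 = 1.0 + noise_frac * rng.standard_normal()
            rec = RelaxRecord(f"R{i + 1}", t1 * max(f1, 0.1), t2 * max(f2, 0.1), noe)
        records.append(rec)
    return records
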