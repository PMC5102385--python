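"""Cα-trace structure models and geometry-based secondary-structure assignment.

The alignment pipeline operates on Cα traces only: a structure is an ordered
list of Cα coordinates plus a per-residue secondary-structure string over the
three-state alphabet ``{H, E, C}``.  Secondary structure is assigned from
Cα–Cα distances alone (P-SEA-style criteria), so that natives and decoys are
classified by exactly the same rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "StructureModel",
    "SSComposition",
    "ChainBreakWarning",
    "load_ca_model",
    "assign_ss",
    "ss_composition",
    "segment_list",
    "write_ca_pdb",
]

SS_CLASSES = ("H", "E", "C")

#: Cα(i)–Cα(i+k) distance windows (Å) for helix (k = 2, 3, 4; 5-residue
#: window) and strand (k = 2; 3-residue window) assignment.
HELIX_D13 = (5.1, 6.1)
HELIX_D14 = (4.8, 5.8)
HELIX_D15 = (5.7, 6.7)
STRAND_D13 = (6.4, 7.0)

#: Plausible range for a bonded Cα–Cα step (Å); cis-proline low end, and a
#: generous high end before we call it a chain break.
CA_CA_RANGE = (2.8, 4.2)


class ChainBreakWarning(UserWarning):
    """A consecutive Cα–Cα distance exceeded the bonded range."""


@dataclass
class StructureModel:
    """One chain reduced to its Cα trace.

    Parameters
    ----------
    id
        Free-form label (file stem, chain, synthetic tag).
    residue_ids
        Original residue identifiers, kept as labels only; internal indexing
        is positional.
    ca_coords
        ``(n, 3)`` float array of Cα positions in Å.
    ss
        Secondary-structure string over ``{H, E, C}``, same length as the
        trace; empty string means "not yet assigned".
    """

    id: str
    residue_ids: list[str]
    ca_coords: np.ndarray
    ss: str = ""

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        if len(self.residue_ids) != len(self.ca_coords):
            raise ValueError("residue_ids and ca_coords length mismatch")
        if self.ss and len(self.ss) != len(self.ca_coords):
            raise ValueError("ss length must match trace length")
        if self.ss and set(self.ss) - set(SS_CLASSES):
            raise ValueError(f"ss may contain only {SS_CLASSES}")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.ca_coords)


@dataclass
class SSComposition:
    counts: dict
    fractions: dict
    undefined: bool = False  # set for the empty model, where fractions have no meaning


def load_ca_model(path: str | Path, chain: str | None = None) -> StructureModel:
    """Read a PDB file and reduce it to a Cα trace.

    Only the first MODEL is used (NMR ensembles are multi-model) and only
    alternate-location indicators blank or ``'A'`` are accepted.  Residues
    appear in file order; insertion codes are kept in the residue labels.

    Raises
    ------
    ValueError
        If the file contains no CA atoms ("empty structure") or the requested
        chain is absent ("unknown chain").
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:  # pragma: no cover - biopython always yields a model
        raise ValueError(f"empty structure: no models in {path}")

    chain_ids = [c.id for c in model]
    if chain is not None and chain not in chain_ids:
        raise ValueError(f"unknown chain {chain!r}; file has {chain_ids}")

    residue_ids: list[str] = []
    coords: list[np.ndarray] = []
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            if "CA" not in res:
                continue
            ca = res["CA"]
            if ca.is_disordered():
                ca = ca.disordered_get("A") if ca.disordered_has_id("A") else None
                if ca is None:
                    continue
            elif ca.get_altloc() not in (" ", "A"):
                continue
            het, num, icode = res.id
            if het.strip():  # HETATM or water
                continue
            residue_ids.append(f"{ch.id}:{num}{icode.strip()}")
            coords.append(ca.get_coord().astype(float))
        if chain is None and coords:
            break  # first chain encountered that has CA atoms

    if not coords:
        raise ValueError(f"empty structure: no CA atoms in {path}")

    model_out = StructureModel(path.stem, residue_ids, np.array(coords))
    steps = np.linalg.norm(np.diff(model_out.ca_coords, axis=0), axis=1)
    if len(steps) and np.any(steps > CA_CA_RANGE[1]):
        where = int(np.argmax(steps > CA_CA_RANGE[1]))
        warnings.warn(
            f"chain break after residue {residue_ids[where]} "
            f"({steps[where]:.2f} Å)",
            ChainBreakWarning,
            stacklevel=2,
        )
    return model_out


def _in(window: tuple[float, float], d: np.ndarray) -> np.ndarray:
    return (d >= window[0]) & (d <= window[1])


def assign_ss(model: StructureModel) -> StructureModel:
    """Assign three-state secondary structure from Cα geometry.

    Helix: d(i,i+2), d(i,i+3), d(i,i+4) simultaneously inside their canonical
    α-helical windows for every position of a 5-residue stretch; all five
    residues are marked ``H``.  Strand: d(i,i+2) in the extended window over a
    3-residue stretch.  Everything else is coil.  The rule depends on internal
    distances only, so it is invariant under rigid motion.
    """
    n = len(model)
    ss = np.full(n, "C", dtype="U1")
    xyz = model.ca_coords
    if n >= 5:
        d13 = np.linalg.norm(xyz[2:] - xyz[:-2], axis=1)
        d14 = np.linalg.norm(xyz[3:] - xyz[:-3], axis=1)
        d15 = np.linalg.norm(xyz[4:] - xyz[:-4], axis=1)
        helical = _in(HELIX_D13, d13[:-2]) & _in(HELIX_D14, d14[:-1]) & _in(HELIX_D15, d15)
        # helical[i] True -> residues i..i+4 form one α turn
        for i in np.nonzero(helical)[0]:
            ss[i : i + 5] = "H"
    if n >= 3:
        d13 = np.linalg.norm(xyz[2:] - xyz[:-2], axis=1)
        extended = _in(STRAND_D13, d13)
        for i in np.nonzero(extended)[0]:
            sl = slice(i, i + 3)
            ss[sl] = np.where(ss[sl] == "H", ss[sl], "E")
    return replace(model, ss="".join(ss))


def ss_composition(ss: str) -> SSComposition:
    """Exact per-class counts and fractions of a secondary-structure string."""
    counts = {c: ss.count(c) for c in SS_CLASSES}
    total = len(ss)
    if total == 0:
        return SSComposition(counts, {c: float("nan") for c in SS_CLASSES}, undefined=True)
    return SSComposition(counts, {c: counts[c] / total for c in SS_CLASSES})


def segment_list(ss: str) -> list[tuple[str, int]]:
    """Run-length encode a secondary-structure string into (class, length) segments."""
    segments: list[tuple[str, int]] = []
    for c in ss:
        if segments and segments[-1][0] == c:
            segments[-1] = (c, segments[-1][1] + 1)
        else:
            segments.append((c, 1))
    return segments


def write_ca_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal CA-only PDB file (fixed-width ATOM records)."""
    lines = []
    for i, (rid, xyz) in enumerate(zip(model.residue_ids, model.ca_coords), start=1):
        chain = "A"
        resnum = i
        if ":" in rid:
            chain_part, num_part = rid.split(":", 1)
            chain = (chain_part or "A")[0]
            digits = "".join(ch for ch in num_part if ch.isdigit() or ch == "-")
            if digits not in ("", "-"):
                resnum = int(digits)
        lines.append(
            f"ATOM  {i:5d}  CA  GLY {chain}{resnum:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
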