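"""Secondary-structure assignment, turn detection and solvent accessibility.

Helices are assigned from backbone dihedrals: a residue is helical when its
(phi, psi) fall within +/-35 degrees of the ideal alpha values (-57, -47),
and maximal runs of at least four helical residues become spans (so a span
from residue 20 to 33 has length 14).  Beta turns are four consecutive
non-helical residues whose first and fourth C-alpha atoms are less than
7 Angstrom apart; gamma turns are three consecutive residues with a
hydrogen bond between the first and third, flagged "classic" when the
central residue's dihedrals are near (75, -64).

Solvent accessibility uses Shrake-Rupley sphere-point sampling with a
1.4-Angstrom probe; buried/exposed labels come from relative accessibility
against Gly-X-Gly reference values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chemdata import MAX_ASA, VDW_RADII
from .geometry import dihedral
from .structio import Residue, Structure

__all__ = [
    "SecondaryStructureSpan",
    "AccessibilityRecord",
    "assign_helices",
    "detect_beta_turns",
    "detect_gamma_turns",
    "asa_shrake_rupley",
    "classify_exposure",
]

HELIX_PHI, HELIX_PSI, HELIX_WINDOW = -57.0, -47.0, 35.0
MIN_HELIX_LENGTH = 4
BETA_TURN_CA_CUTOFF = 7.0       # strict <
GAMMA_HBOND_H_CUTOFF = 2.5      # H...acceptor, inclusive
GAMMA_HBOND_HEAVY_CUTOFF = 3.5  # N...O fallback when hydrogens absent
CLASSIC_GAMMA_PHI, CLASSIC_GAMMA_PSI, CLASSIC_GAMMA_WINDOW = 75.0, -64.0, 30.0


@dataclass
class SecondaryStructureSpan:
    kind: str        # "helix" | "beta_turn" | "gamma_turn"
    chain_id: str
    start: int       # 1-based residue numbers, inclusive on both ends
    end: int
    classic: bool = False  # gamma turns only

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def covers(self, number: int) -> bool:
        return self.start <= number <= self.end


@dataclass
class AccessibilityRecord:
    chain_id: str
    number: int
    residue_name: str
    absolute_asa: float          # Angstrom^2
    relative_asa: float | None   # vs Gly-X-Gly reference; None if no reference
    label: str | None = None     # "b" buried | "e" exposed


def _residue_dihedrals(chain_residues: list[Residue]) -> dict[int, tuple[float, float]]:
    out = {}
    res = chain_residues
    for i in range(1, len(res) - 1):
        try:
            phi = dihedral(res[i - 1].atom("C").position, res[i].atom("N").position,
                           res[i].atom("CA").position, res[i].atom("C").position)
            psi = dihedral(res[i].atom("N").position, res[i].atom("CA").position,
                           res[i].atom("C").position, res[i + 1].atom("N").position)
        except KeyError:
            continue
        out[i] = (phi, psi)
    return out


def assign_helices(structure: Structure) -> list[SecondaryStructureSpan]:
    """Maximal runs of >= 4 residues with helical dihedrals."""
    spans = []
    for chain in structure.chains:
        if chain.polymer != "protein":
            continue
        res = chain.residues
        dih = _residue_dihedrals(res)
        helical = [
            i in dih
            and abs(dih[i][0] - HELIX_PHI) <= HELIX_WINDOW
            and abs(dih[i][1] - HELIX_PSI) <= HELIX_WINDOW
            for i in range(len(res))
        ]
        i = 0
        while i < len(res):
            if helical[i]:
                j = i
                while j + 1 < len(res) and helical[j + 1]:
                    j += 1
                if j - i + 1 >= MIN_HELIX_LENGTH:
                    spans.append(SecondaryStructureSpan(
                        "helix", chain.id, res[i].number, res[j].number))
                i = j + 1
            else:
                i += 1
    return spans


def _in_helix(chain_id: str, number: int, helix_spans) -> bool:
    return any(s.chain_id == chain_id and s.covers(number) for s in helix_spans)


def detect_beta_turns(
    structure: Structure,
    helix_spans: list[SecondaryStructureSpan] | None = None,
) -> list[SecondaryStructureSpan]:
    """Four consecutive non-helical residues with CA(i)-CA(i+3) < 7 A.

    Maximal non-overlapping windows, scanning N to C.
    """
    if helix_spans is None:
        helix_spans = assign_helices(structure)
    turns = []
    for chain in structure.chains:
        if chain.polymer != "protein":
            continue
        res = chain.residues
        i = 0
        while i + 3 < len(res):
            window = res[i : i + 4]
            if any(_in_helix(chain.id, r.number, helix_spans) for r in window):
                i += 1
                continue
            try:
                d = np.linalg.norm(window[0].atom("CA").position - window[3].atom("CA").position)
            except KeyError:
                i += 1
                continue
            if d < BETA_TURN_CA_CUTOFF:
                turns.append(SecondaryStructureSpan(
                    "beta_turn", chain.id, window[0].number, window[3].number))
                i += 4
            else:
                i += 1
    return turns


def _amide_hydrogen(res: Residue) -> np.ndarray | None:
    """Hydrogen bonded to the backbone N (within 1.3 A), if present."""
    if not res.has_atom("N"):
        return None
    n_pos = res.atom("N").position
    for a in res.atoms:
        if a.element == "H" and np.linalg.norm(a.position - n_pos) <= 1.3:
            return a.position
    return None


def detect_gamma_turns(structure: Structure) -> list[SecondaryStructureSpan]:
    """Three consecutive residues with an O(i)...N(i+2) hydrogen bond;
    flagged classic when the central residue's (phi, psi) are within 30
    degrees of (75, -64)."""
    turns = []
    for chain in structure.chains:
        if chain.polymer != "protein":
            continue
        res = chain.residues
        dih = _residue_dihedrals(res)
        i = 0
        while i + 2 < len(res):
            first, middle, third = res[i], res[i + 1], res[i + 2]
            try:
                o_pos = first.atom("O").position
                n_pos = third.atom("N").position
            except KeyError:
                i += 1
                continue
            h_pos = _amide_hydrogen(third)
            if h_pos is not None:
                bonded = np.linalg.norm(o_pos - h_pos) <= GAMMA_HBOND_H_CUTOFF
            else:
                bonded = np.linalg.norm(o_pos - n_pos) <= GAMMA_HBOND_HEAVY_CUTOFF
            if bonded:
                classic = False
                if i + 1 in dih:
                    phi, psi = dih[i + 1]
                    classic = (abs(phi - CLASSIC_GAMMA_PHI) <= CLASSIC_GAMMA_WINDOW
                               and abs(psi - CLASSIC_GAMMA_PSI) <= CLASSIC_GAMMA_WINDOW)
                turns.append(SecondaryStructureSpan(
                    "gamma_turn", chain.id, first.number, third.number, classic=classic))
                i += 3
            else:
                i += 1
    return turns


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def asa_shrake_rupley(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
) -> list[AccessibilityRecord]:
    """Per-residue solvent-accessible surface area by Shrake-Rupley sampling.

    Each atom's accessible sphere (vdW radius + probe) is sampled with
    *n_points* quasi-uniform points; a point is accessible if it lies outside
    every neighbouring atom's accessible sphere.  Residue ASA is the sum of
    its atoms' accessible areas.
    """
    residues = list(structure.iter_residues())
    atoms = [(r, a) for r in residues for a in r.atoms]
    if not atoms:
        raise ValueError("empty structure")
    radii = np.empty(len(atoms))
    for i, (_, a) in enumerate(atoms):
        try:
            radii[i] = VDW_RADII[a.element.upper()]
        except KeyError:
            raise ValueError(f"unknown element {a.element!r} on atom {a.name}") from None
    xyz = np.array([a.position for _, a in atoms])
    expanded = radii + probe
    tree = cKDTree(xyz)
    unit = _sphere_points(n_points)
    per_res: dict[int, float] = {}
    max_reach = 2.0 * expanded.max()
    for i, (res, _) in enumerate(atoms):
        pts = xyz[i] + expanded[i] * unit
        neighbours = [j for j in tree.query_ball_point(xyz[i], max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d = np.linalg.norm(pts - xyz[j], axis=1)
            accessible &= d >= expanded[j]
        area = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
        per_res[id(res)] = per_res.get(id(res), 0.0) + area
    records = []
    for res in residues:
        absolute = per_res.get(id(res), 0.0)
        ref = MAX_ASA.get(res.name.upper())
        rel = absolute / ref if ref else None
        records.append(AccessibilityRecord(res.chain_id, res.number, res.name, absolute, rel))
    return records


def classify_exposure(
    records: list[AccessibilityRecord],
    threshold: float = 0.25,
) -> list[AccessibilityRecord]:
    """Label residues buried ("b") when relative ASA < threshold (strict),
    exposed ("e") otherwise.  Records without a reference area keep None."""
    for rec in records:
        if rec.relative_asa is None:
            rec.label = None
        else:
            rec.label = "b" if rec.relative_asa < threshold else "e"
    return records
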