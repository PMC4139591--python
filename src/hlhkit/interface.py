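"""Noncovalent interaction detection, in-silico mutation and rigid docking.

Detectors cover the categories an interface report needs for a protein-DNA
complex (and, in intramolecular mode, for a single protein): salt bridges
(positively charged nitrogen to negatively charged oxygen, <= 5.0 A),
hydrogen bonds (polar hydrogen to O/N acceptor, <= 2.5 A), attractive
charge pairs (<= 5.6 A), pi-pi stacking (ring centroids <= 5.5 A), alkyl
(aliphatic carbon groups <= 5.5 A) and pi-alkyl (ring centroid to aliphatic
group <= 6.0 A).  All cutoffs are inclusive (strict <=).

Charge-reversal mutation rebuilds side chains with idealized geometry along
the CA->CB direction; the rewiring report diffs two interaction-record sets
at the (category, residue-pair) level.  Docking samples seeded random rigid
poses of a protein around an ideal B-DNA duplex and scores them by charged
contacts minus steric clashes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .chemdata import (
    ALIPHATIC_ATOMS,
    AROMATIC_RINGS,
    CTERM_NEGATIVE,
    NEGATIVE_ATOMS,
    POSITIVE_ATOMS,
    SUPPORTED_MUTATION_TYPES,
    ideal_side_chain,
)
from .structio import Residue, Structure, normalize_atom_names

__all__ = [
    "InteractionRecord",
    "RewiringReport",
    "DockPose",
    "SALT_BRIDGE_CUTOFF",
    "HBOND_CUTOFF",
    "detect_salt_bridges",
    "detect_hydrogen_bonds",
    "detect_other_interactions",
    "interaction_report",
    "mutate_residues",
    "rewiring",
    "dock_to_bdna",
    "groove_assignment",
]

SALT_BRIDGE_CUTOFF = 5.0
HBOND_CUTOFF = 2.5
HBOND_HEAVY_CUTOFF = 3.5
ELECTROSTATIC_CUTOFF = 5.6
PI_PI_CUTOFF = 5.5
ALKYL_CUTOFF = 5.5
PI_ALKYL_CUTOFF = 6.0

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H"}
_DNA_ONE_LETTER = {"DA": "A", "DT": "T", "DG": "G", "DC": "C"}


def _spec_text(res: Residue, atom_name: str | None = None) -> str:
    """Table-style atom/group spec: protein residues title-case three-letter
    ("A:Lys65:NZ"), DNA residues single-letter ("C:A7:OP2")."""
    name = _DNA_ONE_LETTER.get(res.name, res.name.capitalize())
    base = f"{res.chain_id}:{name}{res.number}"
    return f"{base}:{atom_name}" if atom_name else base


@dataclass(frozen=True)
class InteractionRecord:
    category: str
    from_spec: str
    to_spec: str
    distance: float
    from_residue: tuple[str, int]  # (chain, number)
    to_residue: tuple[str, int]

    @property
    def key(self) -> tuple[str, frozenset]:
        """Identity at the (category, residue pair) level, used for rewiring."""
        return (self.category, frozenset((self.from_residue, self.to_residue)))


@dataclass
class RewiringReport:
    lost: set
    gained: set
    conserved: set
    lost_records: list[InteractionRecord] = field(default_factory=list)
    gained_records: list[InteractionRecord] = field(default_factory=list)


@dataclass
class DockPose:
    rotation: np.ndarray
    translation: np.ndarray
    score: float
    cluster: int | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# partner bookkeeping
# ---------------------------------------------------------------------------

def _residue_sides(structure: Structure, partners):
    """Two residue lists to pair across.  *partners* is a
    (receptor_chain_ids, ligand_chain_ids) pair, or "intra" for all distinct
    residue pairs within the structure."""
    residues = list(structure.iter_residues())
    if partners == "intra":
        return residues, residues, True
    receptor_ids, ligand_ids = partners
    side_a = [r for r in residues if r.chain_id in receptor_ids]
    side_b = [r for r in residues if r.chain_id in ligand_ids]
    return side_a, side_b, False


def _pair_ok(res_a: Residue, res_b: Residue, intra: bool) -> bool:
    if res_a is res_b:
        return False
    if intra:
        # canonical order so each pair is visited once
        return (res_a.chain_id, res_a.number) < (res_b.chain_id, res_b.number)
    return True


def _charged_atoms(res: Residue, sign: str, his_positive: bool):
    name = res.name.upper()
    out = []
    if sign == "positive":
        table = POSITIVE_ATOMS if his_positive else {
            k: v for k, v in POSITIVE_ATOMS.items() if k != "HIS"}
        for atom_name in table.get(name, ()):
            if res.has_atom(atom_name):
                out.append(res.atom(atom_name))
    else:
        for atom_name in NEGATIVE_ATOMS.get(name, ()):
            if res.has_atom(atom_name):
                out.append(res.atom(atom_name))
        if res.has_atom(CTERM_NEGATIVE):
            out.append(res.atom(CTERM_NEGATIVE))
    return out


def _charged_pairs(structure, partners, max_dist, his_positive):
    side_a, side_b, intra = _residue_sides(structure, partners)
    seen = set()
    for res_a in side_a:
        for res_b in side_b:
            if not _pair_ok(res_a, res_b, intra):
                continue
            for sign_a, sign_b in (("positive", "negative"), ("negative", "positive")):
                for at_a in _charged_atoms(res_a, sign_a, his_positive):
                    for at_b in _charged_atoms(res_b, sign_b, his_positive):
                        d = float(np.linalg.norm(at_a.position - at_b.position))
                        if d <= max_dist:
                            ident = frozenset((
                                (res_a.chain_id, res_a.number, at_a.name),
                                (res_b.chain_id, res_b.number, at_b.name),
                            ))
                            if ident in seen:
                                continue
                            seen.add(ident)
                            yield res_a, at_a, res_b, at_b, d


def detect_salt_bridges(
    structure: Structure,
    partners="intra",
    max_dist: float = SALT_BRIDGE_CUTOFF,
    his_positive: bool = True,
) -> list[InteractionRecord]:
    """Positively charged N (Lys NZ; Arg NH1/NH2/NE; His ND1/NE2) within
    *max_dist* of a negatively charged O (Asp/Glu carboxylates, DNA
    phosphate OP1/OP2, C-terminal OXT).  Distances are atom-pairwise."""
    records = []
    for res_a, at_a, res_b, at_b, d in _charged_pairs(structure, partners, max_dist, his_positive):
        records.append(InteractionRecord(
            "salt_bridge",
            _spec_text(res_a, at_a.name), _spec_text(res_b, at_b.name), round(d, 4),
            (res_a.chain_id, res_a.number), (res_b.chain_id, res_b.number),
        ))
    return records


def _polar_hydrogens(res: Residue):
    """(H atom, bonded heavy atom) pairs where the H sits on an N or O."""
    heavies = [a for a in res.atoms if a.element.upper() in ("N", "O")]
    out = []
    for a in res.atoms:
        if a.element.upper() != "H":
            continue
        for h in heavies:
            if np.linalg.norm(a.position - h.position) <= 1.3:
                out.append((a, h))
                break
    return out


def detect_hydrogen_bonds(
    structure: Structure,
    partners="intra",
    max_dist: float = HBOND_CUTOFF,
) -> list[InteractionRecord]:
    """Polar-hydrogen to O/N-acceptor contacts with H...acceptor <= 2.5 A.

    When the structure carries no hydrogens at all, falls back to donor
    N/O to acceptor heavy-atom distances <= 3.5 A (records then name the
    donor heavy atom instead of its hydrogen).
    """
    has_h = any(a.element.upper() == "H" for _, a in structure.iter_atoms())
    side_a, side_b, intra = _residue_sides(structure, partners)
    records = []
    seen = set()
    for res_d, res_acc in ((a, b) for a in side_a for b in side_b):
        for res_donor, res_acceptor in ((res_d, res_acc), (res_acc, res_d)):
            if res_donor is res_acceptor:
                continue
            acceptors = [a for a in res_acceptor.atoms if a.element.upper() in ("O", "N")]
            if has_h:
                donors = _polar_hydrogens(res_donor)
                cutoff = max_dist
            else:
                donors = [(a, a) for a in res_donor.atoms if a.element.upper() in ("N", "O")]
                cutoff = HBOND_HEAVY_CUTOFF
            for h_atom, _heavy in donors:
                for acc in acceptors:
                    d = float(np.linalg.norm(h_atom.position - acc.position))
                    if d <= cutoff:
                        ident = frozenset((
                            (res_donor.chain_id, res_donor.number, h_atom.name),
                            (res_acceptor.chain_id, res_acceptor.number, acc.name),
                        ))
                        if ident in seen:
                            continue
                        seen.add(ident)
                        records.append(InteractionRecord(
                            "hydrogen_bond",
                            _spec_text(res_donor, h_atom.name),
                            _spec_text(res_acceptor, acc.name), round(d, 4),
                            (res_donor.chain_id, res_donor.number),
                            (res_acceptor.chain_id, res_acceptor.number),
                        ))
    return records


def _rings(res: Residue):
    out = []
    for ring_names in AROMATIC_RINGS.get(res.name.upper(), ()):
        if all(res.has_atom(n) for n in ring_names):
            centroid = np.mean([res.atom(n).position for n in ring_names], axis=0)
            out.append(centroid)
    return out


def _alkyl_coords(res: Residue) -> np.ndarray | None:
    names = ALIPHATIC_ATOMS.get(res.name.upper(), ())
    pts = [res.atom(n).position for n in names if res.has_atom(n)]
    return np.array(pts) if pts else None


def detect_other_interactions(
    structure: Structure,
    partners="intra",
    his_positive: bool = True,
) -> list[InteractionRecord]:
    """Attractive-charge, pi-pi stacking, alkyl and pi-alkyl contacts.

    Attractive charge is atom-pairwise between opposite formal charges
    (<= 5.6 A); stacking uses ring-centroid distance (<= 5.5 A); alkyl and
    pi-alkyl use the closest approach between aliphatic groups (<= 5.5 A)
    or between a ring centroid and an aliphatic group (<= 6.0 A).
    """
    records = []
    for res_a, at_a, res_b, at_b, d in _charged_pairs(
            structure, partners, ELECTROSTATIC_CUTOFF, his_positive):
        records.append(InteractionRecord(
            "electrostatic_attractive",
            _spec_text(res_a, at_a.name), _spec_text(res_b, at_b.name), round(d, 4),
            (res_a.chain_id, res_a.number), (res_b.chain_id, res_b.number),
        ))

    side_a, side_b, intra = _residue_sides(structure, partners)
    for res_a in side_a:
        rings_a = _rings(res_a)
        alkyl_a = _alkyl_coords(res_a)
        for res_b in side_b:
            if not _pair_ok(res_a, res_b, intra):
                continue
            rings_b = _rings(res_b)
            alkyl_b = _alkyl_coords(res_b)
            for ca in rings_a:
                for cb in rings_b:
                    d = float(np.linalg.norm(ca - cb))
                    if d <= PI_PI_CUTOFF:
                        records.append(InteractionRecord(
                            "pi_pi_stacked", _spec_text(res_a), _spec_text(res_b),
                            round(d, 4),
                            (res_a.chain_id, res_a.number), (res_b.chain_id, res_b.number)))
            if alkyl_a is not None and alkyl_b is not None:
                d = float(np.min(np.linalg.norm(
                    alkyl_a[:, None, :] - alkyl_b[None, :, :], axis=-1)))
                if d <= ALKYL_CUTOFF:
                    records.append(InteractionRecord(
                        "alkyl", _spec_text(res_a), _spec_text(res_b), round(d, 4),
                        (res_a.chain_id, res_a.number), (res_b.chain_id, res_b.number)))
            for ring_res, ring_cents, alk_res, alk in (
                    (res_a, rings_a, res_b, alkyl_b), (res_b, rings_b, res_a, alkyl_a)):
                if alk is None:
                    continue
                for cent in ring_cents:
                    d = float(np.min(np.linalg.norm(alk - cent, axis=1)))
                    if d <= PI_ALKYL_CUTOFF:
                        records.append(InteractionRecord(
                            "pi_alkyl", _spec_text(ring_res), _spec_text(alk_res),
                            round(d, 4),
                            (ring_res.chain_id, ring_res.number),
                            (alk_res.chain_id, alk_res.number)))
    return records


_CATEGORY_ORDER = [
    "salt_bridge", "hydrogen_bond", "electrostatic_attractive",
    "pi_pi_stacked", "alkyl", "pi_alkyl",
]


def interaction_report(
    structure: Structure,
    receptor_chains=None,
    ligand_chains=None,
    his_positive: bool = True,
) -> list[InteractionRecord]:
    """Union of the three detectors, deduplicated and sorted by category then
    distance.  With both chain selections given, contacts are detected across
    the receptor/ligand partition; with neither, intramolecularly.

    A charged pair already reported as a salt bridge is not repeated as an
    attractive-charge record.
    """
    structure = normalize_atom_names(structure)
    if (receptor_chains is None) != (ligand_chains is None):
        raise ValueError("give both receptor and ligand chains, or neither")
    if receptor_chains is None:
        partners = "intra"
    else:
        partners = (tuple(receptor_chains), tuple(ligand_chains))
        side_a, side_b, _ = _residue_sides(structure, partners)
        if not side_a or not side_b:
            raise ValueError("empty receptor or ligand selection")
    sb = detect_salt_bridges(structure, partners, his_positive=his_positive)
    hb = detect_hydrogen_bonds(structure, partners)
    other = detect_other_interactions(structure, partners, his_positive=his_positive)
    sb_pairs = {frozenset((r.from_spec, r.to_spec)) for r in sb}
    merged = sb + hb + [
        r for r in other
        if not (r.category == "electrostatic_attractive"
                and frozenset((r.from_spec, r.to_spec)) in sb_pairs)
    ]
    merged.sort(key=lambda r: (_CATEGORY_ORDER.index(r.category), r.distance,
                               r.from_spec, r.to_spec))
    return merged


def mutate_residues(structure: Structure, substitutions: dict) -> Structure:
    """Substitute residue types, keeping the backbone and rebuilding the side
    chain with idealized geometry along the CA->CB direction.

    *substitutions* maps (chain_id, residue_number) to a new residue type in
    {GLU, ASP, LYS, ARG, ALA}.  Glycine targets (no CB to define the growth
    direction) are an error.
    """
    out = structure.copy()
    for (chain_id, number), new_type in substitutions.items():
        new_type = new_type.upper()
        if new_type not in SUPPORTED_MUTATION_TYPES:
            raise ValueError(f"unsupported substitution type {new_type!r}")
        res = out.chain(chain_id).residue(number)
        if not res.has_atom("CB"):
            raise ValueError(
                f"{chain_id}:{res.name}{number} has no CB; cannot orient the new side chain")
        ca = res.atom("CA").position
        cb = res.atom("CB").position
        res.atoms = [a for a in res.atoms if a.name in _BACKBONE_NAMES]
        res.atoms.extend(ideal_side_chain(new_type, ca, cb - ca))
        res.name = new_type
    return out


def rewiring(
    wt_records: list[InteractionRecord],
    mut_records: list[InteractionRecord],
) -> RewiringReport:
    """Diff of two interaction-record sets keyed by (category, residue pair)."""
    wt_keys = {r.key for r in wt_records}
    mut_keys = {r.key for r in mut_records}
    lost = wt_keys - mut_keys
    gained = mut_keys - wt_keys
    return RewiringReport(
        lost=lost,
        gained=gained,
        conserved=wt_keys & mut_keys,
        lost_records=[r for r in wt_records if r.key in lost],
        gained_records=[r for r in mut_records if r.key in gained],
    )


# ---------------------------------------------------------------------------
# rigid-body docking to B-DNA
# ---------------------------------------------------------------------------

def _positive_coords(structure: Structure, his_positive: bool = True) -> np.ndarray:
    pts = []
    for res in structure.iter_residues():
        for a in _charged_atoms(res, "positive", his_positive):
            pts.append(a.position)
    return np.array(pts) if pts else np.empty((0, 3))


def _negative_coords(structure: Structure) -> np.ndarray:
    pts = []
    for res in structure.iter_residues():
        for a in _charged_atoms(res, "negative", True):
            pts.append(a.position)
    return np.array(pts) if pts else np.empty((0, 3))


def dock_to_bdna(
    protein: Structure,
    dna: Structure,
    n_poses: int = 500,
    seed: int = 0,
    weights: tuple[float, float] = (1.0, 1.0),
    cluster_rmsd: float = 3.0,
) -> list[list[DockPose]]:
    """Seeded random rigid poses of *protein* around the duplex, scored as
    w_attr * (attractive-charge pairs <= 5.6 A) - w_clash * (heavy-atom pairs
    < 2.5 A), greedily clustered at *cluster_rmsd* on protein coordinates.

    Returns clusters ranked by their best member's score.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    w_attr, w_clash = weights
    dna = normalize_atom_names(dna)
    dna_heavy = np.array([a.position for _, a in dna.iter_atoms() if a.element.upper() != "H"])
    dna_neg = _negative_coords(dna)
    prot_xyz = protein.coords()
    centroid = prot_xyz.mean(axis=0)
    prot_local = prot_xyz - centroid
    prot_heavy_idx = [i for i, (_, a) in enumerate(protein.iter_atoms())
                      if a.element.upper() != "H"]
    pos_local = _positive_coords(protein) - centroid if len(_positive_coords(protein)) else np.empty((0, 3))
    extent = float(np.linalg.norm(prot_local, axis=1).max())

    # placement shell around the duplex axis (the duplex from the builder
    # runs along z; recompute from coordinates to stay transform-safe)
    from .geometry import fit_axis
    axis_point, axis_dir = fit_axis(dna_heavy)
    proj = (dna_heavy - axis_point) @ axis_dir
    radial = np.linalg.norm(dna_heavy - axis_point - np.outer(proj, axis_dir), axis=1)
    r_surface = float(radial.max())
    # two in-plane unit vectors orthogonal to the axis
    seed_vec = np.array([1.0, 0.0, 0.0]) if abs(axis_dir[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis_dir, seed_vec); e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis_dir, e1)

    rng = np.random.default_rng(seed)
    neg_tree = cKDTree(dna_neg) if len(dna_neg) else None
    heavy_tree = cKDTree(dna_heavy)
    poses = []
    for _ in range(n_poses):
        rot = Rotation.random(rng=rng).as_matrix()
        t_axis = rng.uniform(proj.min() - 3.0, proj.max() + 3.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        radius = rng.uniform(r_surface - 2.0, r_surface + extent + 2.0)
        center = (axis_point + t_axis * axis_dir
                  + radius * (np.cos(phase) * e1 + np.sin(phase) * e2))
        placed = prot_local @ rot.T + center
        heavy = placed[prot_heavy_idx]
        # clash contract is strict < 2.5 A; query_ball_point is inclusive,
        # so exact-boundary hits are discarded
        clash = 0
        for h, hits in zip(heavy, heavy_tree.query_ball_point(heavy, 2.5)):
            for j in hits:
                if np.linalg.norm(dna_heavy[j] - h) < 2.5:
                    clash += 1
        attr = 0
        if neg_tree is not None and len(pos_local):
            pos_placed = pos_local @ rot.T + center
            attr = sum(len(hits) for hits in neg_tree.query_ball_point(
                pos_placed, ELECTROSTATIC_CUTOFF))
        score = w_attr * attr - w_clash * clash
        poses.append(DockPose(rot, center, float(score)))

    # greedy clustering, best score first
    order = sorted(range(len(poses)), key=lambda i: -poses[i].score)
    reps: list[np.ndarray] = []
    clusters: list[list[DockPose]] = []
    for i in order:
        pose = poses[i]
        placed = prot_local @ pose.rotation.T + pose.translation
        assigned = False
        for ci, rep in enumerate(reps):
            rmsd = float(np.sqrt(np.mean(np.sum((placed - rep) ** 2, axis=1))))
            if rmsd <= cluster_rmsd:
                pose.cluster = ci
                clusters[ci].append(pose)
                assigned = True
                break
        if not assigned:
            pose.cluster = len(reps)
            reps.append(placed)
            clusters.append([pose])
    clusters.sort(key=lambda c: -max(p.score for p in c))
    return clusters


_BACKBONE_DNA_NAMES = {"P", "OP1", "OP2", "O5'", "O3'", "C1'", "C2'", "C3'", "C4'", "C5'", "O4'"}


def groove_assignment(dna: Structure, point) -> str:
    """Classify a point as minor-groove, major-groove, backbone or distal
    relative to a duplex built by :func:`hlhkit.synthetic.build_bdna`.

    The minor-groove direction at each base-pair level is the bisector of
    the two glycosidic (axis -> C1') directions; the point's angular sector
    around the fitted helical axis decides minor vs major, after backbone
    proximity (nearest backbone atom within 4 A) and distal (> 10 A from
    the nearest atom) checks.
    """
    point = np.asarray(point, float)
    dna = normalize_atom_names(dna)
    atoms = [(r, a) for r, a in dna.iter_atoms()]
    dists = np.array([np.linalg.norm(a.position - point) for _, a in atoms])
    nearest = int(np.argmin(dists))
    if dists[nearest] > 10.0:
        return "distal"
    if atoms[nearest][1].name in _BACKBONE_DNA_NAMES and dists[nearest] <= 4.0:
        return "backbone"

    chain_c = dna.chain("C")
    chain_d = dna.chain("D")
    n = len(chain_c.residues)
    c1_pairs = []
    for i, res_c in enumerate(chain_c.residues):
        partner_number = chain_d.residues[0].number + (n - 1 - i)
        try:
            res_d = chain_d.residue(partner_number)
            c1_pairs.append((res_c.atom("C1'").position, res_d.atom("C1'").position))
        except KeyError:
            continue
    if not c1_pairs:
        raise ValueError("duplex lacks paired C1' atoms; was it built by build_bdna?")
    mids = np.array([(a + b) / 2.0 for a, b in c1_pairs])
    all_c1 = np.array([p for pair in c1_pairs for p in pair])
    from .geometry import fit_cylinder_axis
    axis_point, axis_dir = fit_cylinder_axis(all_c1)

    def perp(v):
        v = v - np.dot(v, axis_dir) * axis_dir
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v

    level = int(np.argmin(np.abs((mids - point) @ axis_dir)))
    u = perp(mids[level] - axis_point)      # minor-groove bisector
    v = perp(point - axis_point)
    angle = np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))
    if angle <= 70.0:
        return "minor"
    if angle >= 110.0:
        return "major"
    return "backbone"
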