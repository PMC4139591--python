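"""Synthetic input generators.

Every input the analysis stages consume can be generated here: ideal-geometry
peptide backbones with prescribed helical spans, fiber-model B-DNA duplexes,
conformational ensembles with per-span order/disorder schedules, multi-program
site-prediction tables with controllable agreement, and motif-embedded
sequences.  All generators are deterministic under a fixed seed.

The default generator settings describe a 100-residue helix-loop-helix
protein with three helices spanning residues 20-33, 65-72 and 80-98, a
G/R/K-rich DNA-binding core at residues 60-66 with a second basic cluster
near the C terminus, and docking against an ideal A10-T10 B-DNA duplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemdata import AA1_TO_3, ideal_side_chain
from .geometry import place_atom
from .structio import Atom, Chain, Residue, Structure

__all__ = [
    "HelixSchedule",
    "PredictorTableSpec",
    "DEFAULT_SEQUENCE",
    "DEFAULT_HELIX_SPANS",
    "build_backbone",
    "build_ideal_helix",
    "build_bdna",
    "generate_ensemble",
    "generate_prediction_table",
    "embed_motifs",
    "add_ideal_side_chains",
    "build_candidate_models",
    "build_cationic_peptide",
    "build_neutral_peptide",
    "build_interaction_showcase",
]

# Helical and extended backbone dihedrals (degrees)
PHI_HELIX, PSI_HELIX = -57.0, -47.0
PHI_EXT, PSI_EXT = -120.0, 120.0

# Ideal backbone bond lengths (Angstrom) and angles (degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 116.2, 121.7

#: three helices of lengths 14, 8 and 19 (1-based, inclusive)
DEFAULT_HELIX_SPANS: list[tuple[int, int]] = [(20, 33), (65, 72), (80, 98)]

#: 100-residue default sequence: an N-terminal P/E/S/T-rich stretch, a
#: leucine-spaced export-signal pattern at 29-38, a G/R/K-rich DNA-binding
#: core at 60-66 (RKGRTKR) and a basic C-terminal cluster (KKRGARR at 90-96).
DEFAULT_SEQUENCE = (
    "MATESPDSTE" "PESAQDPTSA"          # 1-20
    "EELAKEAQ" + "LADQLSALSL" + "DG"   # 21-40 (NES pattern at 29-38)
    "SEPTAQDAHE" "STAEDAQSA"           # 41-59
    "RKGRTKR" + "EAEDTSAQSE" "EAE"     # 60-66 DBD core, 67-79
    "HAKKARELSA" + "KKRGARR" + "AEA"   # 80-99 (NLS core 82-85, cluster 90-96)
    "R"                                # 100
)
assert len(DEFAULT_SEQUENCE) == 100


@dataclass
class HelixSchedule:
    """Per-span order probabilities for ensemble generation.

    ``spans`` are 1-based inclusive residue spans; ``probabilities[i]`` is the
    chance that span *i* is helical in any given frame; ``noise`` is the
    Gaussian positional noise amplitude in Angstrom applied to every frame.
    """

    spans: list[tuple[int, int]]
    probabilities: list[float]
    noise: float = 0.05

    def __post_init__(self) -> None:
        if len(self.spans) != len(self.probabilities):
            raise ValueError("one probability per span required")
        for p in self.probabilities:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for (s1, e1) in self.spans:
            if s1 > e1:
                raise ValueError(f"span ({s1}, {e1}) reversed")
        ordered = sorted(self.spans)
        for (_, e1), (s2, _) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError("spans overlap")


@dataclass
class PredictorTableSpec:
    """Shape of a synthetic multi-program site-prediction table."""

    n_sites: int = 20
    programs: dict[str, list[str]] = field(default_factory=lambda: {
        "phospho": [f"phos_prog{i}" for i in range(1, 10)],
        "acetyl": [f"ac_prog{i}" for i in range(1, 9)],
        "methyl": [f"me_prog{i}" for i in range(1, 5)],
        "ubiq": [f"ub_prog{i}" for i in range(1, 4)],
        "sumo": [f"su_prog{i}" for i in range(1, 7)],
    })
    agreement: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.agreement <= 1.0:
            raise ValueError("agreement must be in [0, 1]")


def _check_spans(spans, n: int) -> None:
    for (s, e) in spans:
        if not (1 <= s <= e <= n):
            raise ValueError(f"span ({s}, {e}) out of range for length {n}")


def build_backbone(
    sequence: str,
    phis: np.ndarray,
    psis: np.ndarray,
    chain_id: str = "A",
) -> Structure:
    """Build an all-backbone (N, CA, C, O, CB except Gly) peptide chain from
    per-residue phi/psi dihedrals with ideal bond lengths and angles.

    ``phis[0]`` has no effect (the first residue has no preceding carbonyl).
    """
    n = len(sequence)
    if len(phis) != n or len(psis) != n:
        raise ValueError("need one phi and one psi per residue")
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psis[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phis[i])

    residues = []
    for i, letter in enumerate(sequence):
        try:
            name3 = AA1_TO_3[letter.upper()]
        except KeyError:
            raise ValueError(f"unknown amino-acid letter {letter!r}") from None
        res = Residue(chain_id, i + 1, name3)
        res.atoms.append(Atom("N", "N", N[i]))
        res.atoms.append(Atom("CA", "C", CA[i]))
        res.atoms.append(Atom("C", "C", C[i]))
        o_pos = place_atom(N[i], CA[i], C[i], _B_C_O, 120.8, psis[i] + 180.0)
        res.atoms.append(Atom("O", "O", o_pos))
        if name3 != "GLY":
            cb_pos = place_atom(C[i], N[i], CA[i], _B_CA_CB, 110.5, 123.0)
            res.atoms.append(Atom("CB", "C", cb_pos))
        residues.append(res)
    return Structure([[Chain(chain_id, "protein", residues)]])


def build_ideal_helix(
    sequence: str,
    helical_spans: list[tuple[int, int]],
    seed: int = 0,
    noise: float = 0.0,
    chain_id: str = "A",
) -> Structure:
    """Peptide with helical dihedrals inside *helical_spans* (1-based,
    inclusive) and extended dihedrals elsewhere, plus optional seeded
    Gaussian positional noise."""
    n = len(sequence)
    _check_spans(helical_spans, n)
    phis = np.full(n, PHI_EXT)
    psis = np.full(n, PSI_EXT)
    for (s, e) in helical_spans:
        phis[s - 1 : e] = PHI_HELIX
        psis[s - 1 : e] = PSI_HELIX
    st = build_backbone(sequence, phis, psis, chain_id)
    if noise > 0.0:
        rng = np.random.default_rng(seed)
        xyz = st.coords()
        st.set_coords(xyz + rng.normal(0.0, noise, xyz.shape))
    return st


# ---------------------------------------------------------------------------
# B-DNA fiber model
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

TWIST_PER_BP = 36.0   # degrees
RISE_PER_BP = 3.38    # Angstrom
_R_P = 8.9            # phosphorus radius
_R_C1 = 6.0           # glycosidic C1' radius
_R_BASE = 2.3         # base-ring centroid radius
_GLYCO_HALF_ANGLE = 60.0  # half-angle between paired C1' atoms (minor-groove side)


def _cyl(radius: float, phase_deg: float, z: float) -> np.ndarray:
    t = np.radians(phase_deg)
    return np.array([radius * np.cos(t), radius * np.sin(t), z])


def _nucleotide(base: str, number: int, chain_id: str, level: int, strand: float) -> Residue:
    """One nucleotide of the fiber model; *strand* is +1 (given) or -1
    (complementary)."""
    theta = level * TWIST_PER_BP
    z = level * RISE_PER_BP
    phase = theta + strand * _GLYCO_HALF_ANGLE
    res = Residue(chain_id, number, "D" + base)
    p = _cyl(_R_P, phase + strand * 25.0, z - strand * 1.7)
    u_r = np.array([np.cos(np.radians(phase + strand * 25.0)),
                    np.sin(np.radians(phase + strand * 25.0)), 0.0])
    res.atoms.append(Atom("P", "P", p))
    res.atoms.append(Atom("OP1", "O", p + 1.48 * u_r))
    res.atoms.append(Atom("OP2", "O", p + 1.48 * np.array([0.3 * u_r[0], 0.3 * u_r[1], 0.95 * strand])))
    c1 = _cyl(_R_C1, phase, z)
    res.atoms.append(Atom("O5'", "O", p + 0.4 * (c1 - p)))
    res.atoms.append(Atom("C1'", "C", c1))
    ring = _PURINE_RING if base in "AG" else _PYRIMIDINE_RING
    center = _cyl(_R_BASE, phase, z)
    in_plane = np.array([-np.sin(np.radians(phase)), np.cos(np.radians(phase)), 0.0])
    radial = np.array([np.cos(np.radians(phase)), np.sin(np.radians(phase)), 0.0])
    m = len(ring)
    for k, name in enumerate(ring):
        a = 2.0 * np.pi * k / m
        pos = center + 1.2 * (np.cos(a) * radial + np.sin(a) * in_plane)
        res.atoms.append(Atom(name, name[0], pos))
    if base == "T":
        res.atoms.append(Atom("C7", "C", center + 2.4 * radial))
    return res


def build_bdna(sequence: str) -> Structure:
    """Ideal B-DNA duplex (fiber model: 36 deg twist, 3.38 A rise per bp).

    The given strand becomes chain C (residues 1..n, 5'->3'); the reverse
    complement becomes the antiparallel chain D (residues n+1..2n).  Each
    nucleotide carries P, OP1, OP2, O5', C1' and its base-ring atoms; the
    helical axis of the as-built duplex is the z axis.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty DNA sequence")
    for b in seq:
        if b not in _COMPLEMENT:
            raise ValueError(f"invalid DNA base {b!r}")
    n = len(seq)
    chain_c = Chain("C", "dna", [
        _nucleotide(seq[i], i + 1, "C", i, +1.0) for i in range(n)
    ])
    # chain D runs antiparallel: its j-th residue (5'->3') pairs with C's
    # residue n-j, i.e. sits at helical level n-1-j
    chain_d = Chain("D", "dna", [
        _nucleotide(_COMPLEMENT[seq[n - 1 - j]], n + 1 + j, "D", n - 1 - j, -1.0)
        for j in range(n)
    ])
    return Structure([[chain_c, chain_d]])


# ---------------------------------------------------------------------------
# Conformational ensembles
# ---------------------------------------------------------------------------

def _chain_sequence(st: Structure) -> str:
    from .chemdata import AA3_TO_1

    chain = st.chains[0]
    return "".join(AA3_TO_1.get(r.name, "A") for r in chain.residues)


def _backbone_dihedrals(st: Structure) -> tuple[np.ndarray, np.ndarray]:
    from .geometry import dihedral

    chain = st.chains[0]
    n = len(chain.residues)
    phis = np.full(n, PHI_EXT)
    psis = np.full(n, PSI_EXT)
    res = chain.residues
    for i in range(n):
        try:
            if i > 0:
                phis[i] = dihedral(
                    res[i - 1].atom("C").position, res[i].atom("N").position,
                    res[i].atom("CA").position, res[i].atom("C").position,
                )
            if i < n - 1:
                psis[i] = dihedral(
                    res[i].atom("N").position, res[i].atom("CA").position,
                    res[i].atom("C").position, res[i + 1].atom("N").position,
                )
        except KeyError:
            pass
    return phis, psis


def generate_ensemble(base: Structure, schedule: HelixSchedule, n_frames: int, seed: int = 0):
    """Ensemble of *n_frames* rebuilt conformations of *base*.

    Each frame keeps each scheduled span helical with its probability and
    otherwise re-dihedralizes the span to random coil (dihedrals drawn
    uniformly from a broad beta-region window, unambiguously non-helical).
    Residues outside every span keep the base dihedrals.  Frames share one
    topology; positional noise per the schedule.
    """
    from .ensemble import Ensemble

    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    seq = _chain_sequence(base)
    _check_spans(schedule.spans, len(seq))
    base_phis, base_psis = _backbone_dihedrals(base)
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        phis = base_phis.copy()
        psis = base_psis.copy()
        for (s, e), p in zip(schedule.spans, schedule.probabilities):
            if rng.random() < p:
                phis[s - 1 : e] = PHI_HELIX
                psis[s - 1 : e] = PSI_HELIX
            else:
                k = e - s + 1
                phis[s - 1 : e] = rng.uniform(-160.0, -75.0, k)
                psis[s - 1 : e] = rng.uniform(95.0, 175.0, k)
        frame = build_backbone(seq, phis, psis, base.chains[0].id)
        if schedule.noise > 0.0:
            xyz = frame.coords()
            frame.set_coords(xyz + rng.normal(0.0, schedule.noise, xyz.shape))
        frames.append(frame)
    return Ensemble(frames, source="synthetic")


# ---------------------------------------------------------------------------
# Predictor tables and motif sequences
# ---------------------------------------------------------------------------

_CLASS_RESIDUE = {"phospho": "S", "acetyl": "K", "methyl": "K", "ubiq": "K", "sumo": "K"}


def generate_prediction_table(spec: PredictorTableSpec) -> pd.DataFrame:
    """Synthetic per-site per-program score table (columns: site, residue,
    class, program, score, cutoff).

    Per site and program the raw score lands above the program cutoff with
    probability ``spec.agreement``, so the fraction of predicting programs at
    a site approximates the agreement level.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for site in range(1, spec.n_sites + 1):
        for mod_class, progs in spec.programs.items():
            residue = _CLASS_RESIDUE.get(mod_class, "K")
            for prog in progs:
                cutoff = 0.5
                if rng.random() < spec.agreement:
                    score = rng.uniform(0.55, 1.0)
                else:
                    score = rng.uniform(0.0, 0.45)
                rows.append((site, residue, mod_class, prog, score, cutoff))
    return pd.DataFrame(rows, columns=["site", "residue", "class", "program", "score", "cutoff"])


#: letters withheld from random backgrounds so planted motifs stay unique:
#: the basic/glycine letters the NLS and DNA-binding scanners key on and the
#: leucine anchor of the export-signal pattern
MOTIF_ANCHOR_LETTERS = frozenset("KRGL")
_BACKGROUND_ALPHABET = [a for a in "ACDEFHIMNPQSTVWY"]


def embed_motifs(length: int, placements: list[tuple[str, int]], seed: int = 0) -> str:
    """Random background sequence with motifs placed verbatim.

    Placements are (motif, 1-based start).  The background alphabet excludes
    K/R/G/L so no spurious motif copies arise; overlapping placements are an
    error.
    """
    rng = np.random.default_rng(seed)
    seq = [str(rng.choice(_BACKGROUND_ALPHABET)) for _ in range(length)]
    occupied: set[int] = set()
    for motif, start in placements:
        end = start + len(motif) - 1
        if not (1 <= start and end <= length):
            raise ValueError(f"motif {motif!r} at {start} does not fit in length {length}")
        span = set(range(start, end + 1))
        if span & occupied:
            raise ValueError(f"motif {motif!r} at {start} overlaps a previous placement")
        occupied |= span
        seq[start - 1 : end] = list(motif)
    return "".join(seq)


# ---------------------------------------------------------------------------
# Fixture complexes and docking toys
# ---------------------------------------------------------------------------

def add_ideal_side_chains(structure: Structure) -> Structure:
    """Extend supported residue types (Lys/Arg/Glu/Asp/Ala) of a backbone-only
    model with idealized straight side chains grown along CA->CB."""
    out = structure.copy()
    for model_i in range(len(out.models)):
        for res in out.iter_residues(model_i):
            if res.name not in ("LYS", "ARG", "GLU", "ASP"):
                continue
            if not (res.has_atom("CA") and res.has_atom("CB")):
                continue
            ca = res.atom("CA").position
            cb = res.atom("CB").position
            res.atoms = [a for a in res.atoms if a.name not in
                         ("CB", "CG", "CD", "CE", "NZ", "NE", "CZ", "NH1", "NH2",
                          "OE1", "OE2", "OD1", "OD2")]
            res.atoms.extend(ideal_side_chain(res.name, ca, cb - ca))
    return out


def build_candidate_models(
    sequence: str = DEFAULT_SEQUENCE,
    spans: list[tuple[int, int]] | None = None,
    noise_levels: tuple[float, ...] = (0.3, 0.6, 1.0, 1.5, 2.2),
    seed: int = 0,
) -> dict[str, Structure]:
    """A candidate model set plus one unrelated negative-control fold.

    Candidates are the ideal helix-loop-helix build perturbed at increasing
    noise; the control is an all-extended chain of the same sequence (a fold
    unrelated to the helical candidates).
    """
    spans = DEFAULT_HELIX_SPANS if spans is None else spans
    models = {}
    for i, noise in enumerate(noise_levels, start=1):
        models[f"model_{i}"] = build_ideal_helix(sequence, spans, seed=seed + i, noise=noise)
    models["control"] = build_ideal_helix(sequence, [], seed=seed + 99, noise=0.5)
    return models


def build_cationic_peptide(n: int = 12, seed: int = 0) -> Structure:
    """Poly-lysine helix with full idealized side chains: a cationic-patch toy
    protein for minor-groove docking."""
    st = build_ideal_helix("K" * n, [(1, n)], seed=seed, noise=0.0)
    return add_ideal_side_chains(st)


def build_neutral_peptide(n: int = 12, seed: int = 0) -> Structure:
    """Poly-alanine helix: the uncharged docking control."""
    return build_ideal_helix("A" * n, [(1, n)], seed=seed, noise=0.0)


def _bare_residue(chain_id: str, number: int, name: str, atoms: list[Atom]) -> Residue:
    return Residue(chain_id, number, name, atoms)


def build_interaction_showcase() -> tuple[Structure, dict[str, float]]:
    """Protein-DNA complex with exactly one engineered contact per interaction
    category (synthetic fixture; coordinates are hand-placed).

    Returns the structure and a dict mapping category name to the engineered
    distance.  Regions are separated by 20 A so no accidental extra contacts
    arise.
    """
    A: list[Residue] = []
    C: list[Residue] = []

    def ring_atoms(names, center, radius=1.2, plane=((1, 0, 0), (0, 1, 0))):
        u, v = np.asarray(plane[0], float), np.asarray(plane[1], float)
        out = []
        m = len(names)
        for k, nm in enumerate(names):
            a = 2 * np.pi * k / m
            out.append(Atom(nm, nm[0], np.asarray(center, float) + radius * (np.cos(a) * u + np.sin(a) * v)))
        return out

    # region 1 (x ~ 0): Lys NZ 2.53 A from a phosphate OP2 -> salt bridge
    p = np.array([0.0, 0.0, 0.0])
    # (only one phosphate oxygen here: a second would sit inside the 5.6 A
    # attractive-charge shell of the engineered lysine and add a record)
    C.append(_bare_residue("C", 1, "DA", [
        Atom("P", "P", p),
        Atom("OP2", "O", p + (0, 1.48, 0)),
        Atom("O5'", "O", p + (0, 0, 1.4)),
        Atom("C1'", "C", p + (0, 0, 2.9)),
    ]))
    A.append(_bare_residue("A", 65, "LYS", [Atom("NZ", "N", p + (0, 1.48 + 2.53, 0))]))

    # region 2 (x ~ 20): backbone amide H 2.00 A from O5' -> hydrogen bond
    # (neutral donor and acceptor, so no charged-pair record fires here)
    q = np.array([20.0, 0.0, 0.0])
    C.append(_bare_residue("C", 2, "DA", [
        Atom("P", "P", q + (0, -3.0, 0)),
        Atom("OP1", "O", q + (1.48, -3.0, 0)),
        Atom("OP2", "O", q + (0, -4.48, 0)),
        Atom("O5'", "O", q),
        Atom("C1'", "C", q + (0, 0, 2.9)),
    ]))
    hn = q + (0.0, 2.0, 0.0)
    A.append(_bare_residue("A", 59, "GLY", [
        Atom("N", "N", hn + (0.0, 1.01, 0.0)),
        Atom("H", "H", hn),
    ]))

    # region 3 (x ~ 40): Arg NH2 5.50 A from OP1 -> attractive charge
    # (beyond the 5.0 A salt-bridge cutoff, inside the 5.6 A electrostatic one)
    r = np.array([40.0, 0.0, 0.0])
    C.append(_bare_residue("C", 3, "DA", [
        Atom("P", "P", r),
        Atom("OP1", "O", r + (1.48, 0, 0)),
    ]))
    A.append(_bare_residue("A", 99, "ARG", [Atom("NH2", "N", r + (1.48 + 5.50, 0, 0))]))

    # region 4 (x ~ 60): His imidazole stacked 4.0 A above an adenine ring
    s = np.array([60.0, 0.0, 0.0])
    C.append(_bare_residue("C", 4, "DA",
                           ring_atoms(_PURINE_RING, s) + [Atom("C1'", "C", s + (9.0, 0, 0))]))
    A.append(_bare_residue("A", 80, "HIS",
                           ring_atoms(("CG", "ND1", "CD2", "CE1", "NE2"), s + (0, 0, 4.0))))

    # region 5 (x ~ 80): Ala CB 4.0 A from a deoxyribose C1' -> alkyl
    t = np.array([80.0, 0.0, 0.0])
    C.append(_bare_residue("C", 5, "DA", [
        Atom("O5'", "O", t + (0, -1.4, 0)),
        Atom("C1'", "C", t),
    ]))
    A.append(_bare_residue("A", 33, "ALA", [Atom("CB", "C", t + (0, 4.0, 0))]))

    # region 6 (x ~ 100): Tyr ring centroid 4.8 A from a deoxyribose C1' -> pi-alkyl
    u = np.array([100.0, 0.0, 0.0])
    C.append(_bare_residue("C", 6, "DA", [
        Atom("O5'", "O", u + (0, -1.4, 0)),
        Atom("C1'", "C", u),
    ]))
    A.append(_bare_residue("A", 30, "TYR",
                           ring_atoms(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), u + (0, 4.8, 0))))

    st = Structure([[Chain("A", "protein", A), Chain("C", "dna", C)]])
    expected = {
        "salt_bridge": 2.53,
        "hydrogen_bond": 2.00,
        "electrostatic_attractive": 5.50,
        "pi_pi_stacked": 4.00,
        "alkyl": 4.00,
        "pi_alkyl": 4.80,
    }
    return st, expected
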