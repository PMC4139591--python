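"""Structure data model and PDB input/output.

The in-memory model is a thin chain/residue/atom hierarchy with coordinates
in Angstrom.  Parsing and writing of the fixed-column PDB format is delegated
to gemmi; this module adds atom-name dialect normalization (``O1P``/``O2P``
phosphate oxygens to the canonical ``OP1``/``OP2``) and the compact
``chain:ResnameNumber:atomname`` atom-spec notation used in interface
reports (e.g. ``A:Arg60:NH2``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "AtomSpec",
    "PDBParseError",
    "parse_pdb",
    "write_pdb",
    "normalize_atom_names",
    "parse_atom_spec",
    "format_atom_spec",
]

#: residue names recognised as DNA, mapped to their canonical two-letter form
DNA_NAMES = {
    "DA": "DA", "DT": "DT", "DG": "DG", "DC": "DC",
    "A": "DA", "T": "DT", "G": "DG", "C": "DC",
}

_PHOSPHATE_ALIASES = {"O1P": "OP1", "O2P": "OP2"}


class PDBParseError(ValueError):
    """Raised for malformed fixed-width PDB records (carries the line number)."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) float, Angstrom

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.name:
            raise ValueError("atom name must be nonempty")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")


@dataclass
class Residue:
    chain_id: str
    number: int
    name: str  # 3-letter amino-acid code or canonical DNA code (DA/DT/DG/DC)
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.chain_id}:{self.name}{self.number} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def is_dna(self) -> bool:
        return self.name in ("DA", "DT", "DG", "DC")


@dataclass
class Chain:
    id: str
    polymer: str  # "protein" | "dna"
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int) -> Residue:
        for r in self.residues:
            if r.number == number:
                return r
        raise KeyError(f"chain {self.id} has no residue {number}")


@dataclass
class Structure:
    """One or more models; each model is an ordered collection of chains."""

    models: list[list[Chain]] = field(default_factory=list)

    @property
    def chains(self) -> list[Chain]:
        """Chains of the first model."""
        return self.models[0]

    def chain(self, chain_id: str, model: int = 0) -> Chain:
        for c in self.models[model]:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def iter_residues(self, model: int = 0):
        for c in self.models[model]:
            yield from c.residues

    def iter_atoms(self, model: int = 0):
        for r in self.iter_residues(model):
            for a in r.atoms:
                yield r, a

    def n_atoms(self, model: int = 0) -> int:
        return sum(len(r.atoms) for r in self.iter_residues(model))

    def coords(self, model: int = 0) -> np.ndarray:
        return np.array([a.position for _, a in self.iter_atoms(model)], dtype=float)

    def set_coords(self, xyz: np.ndarray, model: int = 0) -> None:
        atoms = [a for _, a in self.iter_atoms(model)]
        if len(atoms) != len(xyz):
            raise ValueError("coordinate array does not match atom count")
        for a, p in zip(atoms, xyz):
            a.position = np.asarray(p, dtype=float)

    def calpha(self, model: int = 0, chain_id: str | None = None):
        """(residue, CA atom) pairs for protein residues that have a CA."""
        out = []
        for c in self.models[model]:
            if chain_id is not None and c.id != chain_id:
                continue
            if c.polymer != "protein":
                continue
            for r in c.residues:
                if r.has_atom("CA"):
                    out.append((r, r.atom("CA")))
        return out

    def copy(self) -> "Structure":
        return Structure(
            [
                [
                    Chain(
                        c.id,
                        c.polymer,
                        [
                            Residue(
                                r.chain_id,
                                r.number,
                                r.name,
                                [Atom(a.name, a.element, a.position.copy()) for a in r.atoms],
                            )
                            for r in c.residues
                        ],
                    )
                    for c in model
                ]
                for model in self.models
            ]
        )


@dataclass(frozen=True)
class AtomSpec:
    """Parsed form of the compact ``chain:ResnameNumber:atomname`` notation.

    ``residue_name`` keeps the text as written (tables abbreviate adenine to
    ``A``), so formatting is the exact inverse of parsing.
    """

    chain_id: str
    residue_name: str
    residue_number: int
    atom_name: str


def parse_atom_spec(text: str) -> AtomSpec:
    parts = text.split(":")
    if len(parts) != 3 or not all(parts):
        raise ValueError(f"atom spec {text!r}: expected three colon-separated fields")
    chain_id, resfield, atom_name = parts
    # residue name and number split at the first digit
    for i, ch in enumerate(resfield):
        if ch.isdigit():
            name, num = resfield[:i], resfield[i:]
            break
    else:
        raise ValueError(f"atom spec {text!r}: no residue number in {resfield!r}")
    if not name:
        raise ValueError(f"atom spec {text!r}: no residue name in {resfield!r}")
    return AtomSpec(chain_id, name, int(num), atom_name)


def format_atom_spec(spec: AtomSpec) -> str:
    return f"{spec.chain_id}:{spec.residue_name}{spec.residue_number}:{spec.atom_name}"


def _prescan(text: str) -> None:
    """Validate coordinate columns of ATOM/HETATM records before handing to gemmi."""
    n_coord_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        n_coord_records += 1
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: record too short for coordinates")
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            fieldtxt = line[lo:hi].strip()
            try:
                float(fieldtxt)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed coordinate field {fieldtxt!r}"
                ) from None
    if n_coord_records == 0:
        raise PDBParseError("no ATOM/HETATM records found")


def _residue_polymer(name: str) -> str:
    return "dna" if name.upper() in DNA_NAMES else "protein"


def parse_pdb(text: str) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    MODEL/ENDMDL blocks yield multiple models.  Only the first altloc of a
    disordered atom is kept (with a warning); DNA residue names are stored
    canonically as DA/DT/DG/DC.
    """
    _prescan(text)
    st = gemmi.read_pdb_string(text)
    out = Structure()
    for gmodel in st:
        chains: list[Chain] = []
        for gchain in gmodel:
            residues: list[Residue] = []
            polymer_votes = {"protein": 0, "dna": 0}
            for gres in gchain:
                rname = gres.name.upper().strip()
                rname = DNA_NAMES.get(rname, rname)
                res = Residue(gchain.name, gres.seqid.num, rname)
                if gres.seqid.icode not in (" ", "", "\x00"):
                    warnings.warn(
                        f"insertion code on {gchain.name}:{rname}{gres.seqid.num} ignored"
                    )
                seen = set()
                for ga in gres:
                    if ga.name in seen:
                        warnings.warn(
                            f"altloc atoms on {gchain.name}:{rname}{gres.seqid.num}:"
                            f"{ga.name}; keeping the first"
                        )
                        continue
                    seen.add(ga.name)
                    elem = ga.element.name if ga.element.name else ga.name[0]
                    res.atoms.append(
                        Atom(ga.name, elem, np.array([ga.pos.x, ga.pos.y, ga.pos.z]))
                    )
                polymer_votes[_residue_polymer(gres.name)] += 1
                residues.append(res)
            if residues:
                polymer = max(polymer_votes, key=polymer_votes.get)
                chains.append(Chain(gchain.name, polymer, residues))
        if chains:
            out.models.append(chains)
    if not out.models:
        raise PDBParseError("no models with atoms found")
    return out


def write_pdb(structure: Structure) -> str:
    """Serialize a :class:`Structure` to PDB text (fixed columns, via gemmi)."""
    st = gemmi.Structure()
    for i, model in enumerate(structure.models, start=1):
        gmodel = gemmi.Model(i)
        for chain in model:
            gchain = gemmi.Chain(chain.id)
            for res in chain.residues:
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(res.number, " ")
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.position)
                    gres.add_atom(ga)
                gchain.add_residue(gres)
            gmodel.add_chain(gchain)
        st.add_model(gmodel)
    st.setup_entities()
    return st.make_pdb_string(gemmi.PdbWriteOptions(seqres_records=False, ter_records=True))


def normalize_atom_names(structure: Structure) -> Structure:
    """Return a copy with phosphate oxygens named canonically (O1P -> OP1 etc.).

    Idempotent; coordinates and atom counts are untouched.
    """
    out = structure.copy()
    for model in range(len(out.models)):
        for _, atom in out.iter_atoms(model):
            atom.name = _PHOSPHATE_ALIASES.get(atom.name, atom.name)
    return out
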