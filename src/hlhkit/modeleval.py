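"""Candidate-model quality assessment.

Given a set of alternative structural models of one sequence plus an
unrelated negative-control fold, this stage superposes every pair
(least-squares rigid Kabsch fit on matched C-alpha atoms), builds
all-against-all RMSD and alignment Z-score matrices, aggregates them into
per-model consensus statistics and ranks the candidates.  A Ramachandran
summary gives the stereochemistry side of model quality.

The Z-score of a pair measures how far the observed alignment statistic
(number of matched C-alpha pairs within 4 Angstrom after superposition,
i.e. fraction matched times alignment length) lies above a null built by
re-threading one structure's residue order on its own backbone trace with
seeded random shuffles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import dihedral
from .structio import Structure

__all__ = [
    "SuperpositionResult",
    "ScoreMatrix",
    "ZScoreNull",
    "ConsensusStats",
    "RamachandranSummary",
    "superpose",
    "rmsd_matrix",
    "alignment_zscore",
    "consensus_stats",
    "rank_models",
    "ramachandran",
    "backbone_dihedrals",
    "classify_rama_region",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, det +1
    translation: np.ndarray   # 3-vector, Angstrom
    rmsd: float               # over matched C-alpha, Angstrom
    n_matched: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ScoreMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str                       # "rmsd" | "zscore"
    control_label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if self.control_label is not None and self.control_label not in self.labels:
            raise ValueError(f"control label {self.control_label!r} not in labels")

    def entry(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class ZScoreNull:
    """Null-distribution bookkeeping for one alignment Z-score."""

    observed: float
    null_mean: float
    null_sd: float
    null_size: int
    seed: int


@dataclass
class ConsensusStats:
    label: str
    mean_rmsd: float        # over the other candidates, control excluded
    sd_rmsd: float          # population SD of the same entries
    mean_z: float           # quadratic mean over other candidates + control
    pearson_r: float | None  # RMSD vs Z over others + control; descriptive
    rank: int | None = None


@dataclass
class RamachandranSummary:
    residues: list[tuple[str, int, float, float, str]]  # chain, number, phi, psi, region
    percentages: dict[str, float] = field(default_factory=dict)


def _matched_calpha(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of C-alpha atoms shared by both structures, keyed by
    (chain, residue number); residue-name mismatches are an error."""
    ca_a = {(r.chain_id, r.number): (r, at) for r, at in a.calpha()}
    ca_b = {(r.chain_id, r.number): (r, at) for r, at in b.calpha()}
    keys = [k for k in ca_a if k in ca_b]
    if not keys:
        raise ValueError("no common C-alpha atoms between the two structures")
    for k in keys:
        ra, rb = ca_a[k][0], ca_b[k][0]
        if ra.name != rb.name:
            raise ValueError(
                f"residue mismatch at {k[0]}:{k[1]}: {ra.name} vs {rb.name}"
            )
    xa = np.array([ca_a[k][1].position for k in keys])
    xb = np.array([ca_b[k][1].position for k in keys])
    return xa, xb


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc)
    rmat = rot.as_matrix()
    rmsd = float(rssd / np.sqrt(len(mobile)))
    translation = rc - rmat @ mc
    return SuperpositionResult(rmat, translation, rmsd, len(mobile))


def superpose(mobile: Structure, reference: Structure, selection: str = "calpha") -> SuperpositionResult:
    """Optimal rigid-body superposition (reflections excluded) of *mobile*
    onto *reference* over matched atoms; RMSD computed after the fit.

    ``selection`` is ``"calpha"`` (default, matching the published protocol)
    or ``"all"`` for all atoms matched by chain/residue/atom name.
    """
    if selection == "calpha":
        xm, xr = _matched_calpha(mobile, reference)
    elif selection == "all":
        am = {(r.chain_id, r.number, a.name): a.position for r, a in mobile.iter_atoms()}
        ar = {(r.chain_id, r.number, a.name): a.position for r, a in reference.iter_atoms()}
        keys = [k for k in am if k in ar]
        xm = np.array([am[k] for k in keys])
        xr = np.array([ar[k] for k in keys])
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if len(xm) < 3:
        raise ValueError(f"need at least 3 matched atoms, got {len(xm)}")
    return _kabsch(xm, xr)


def rmsd_matrix(models: dict[str, Structure], control_label: str | None = None) -> ScoreMatrix:
    """Symmetric all-against-all C-alpha RMSD matrix over a named model set."""
    labels = list(models)
    if len(labels) < 2:
        raise ValueError("need at least two models")
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = superpose(models[labels[i]], models[labels[j]]).rmsd
            values[i, j] = values[j, i] = r
    return ScoreMatrix(labels, values, "rmsd", control_label)


def _alignment_statistic(xa: np.ndarray, xb: np.ndarray, contact: float = 4.0) -> float:
    """Fraction of matched C-alpha pairs within *contact* after superposition,
    times alignment length (= matched-pair count)."""
    fit = _kabsch(xb, xa)
    d = np.linalg.norm(fit.apply(xb) - xa, axis=1)
    frac = float(np.mean(d <= contact))
    return frac * len(xa)


def alignment_zscore(
    a: Structure,
    b: Structure,
    null_size: int = 200,
    seed: int = 0,
) -> tuple[float, ZScoreNull]:
    """Statistical significance of the structural alignment of *a* and *b*.

    The null re-threads *b*'s residue order on its own C-alpha trace
    (``null_size`` seeded random shuffles) and recomputes the alignment
    statistic for each; z = (S_obs - mean_null) / sd_null.
    """
    if null_size < 10:
        raise ValueError("null_size must be >= 10")
    xa, xb = _matched_calpha(a, b)
    s_obs = _alignment_statistic(xa, xb)
    rng = np.random.default_rng(seed)
    null = np.empty(null_size)
    for i in range(null_size):
        perm = rng.permutation(len(xb))
        null[i] = _alignment_statistic(xa, xb[perm])
    sd = float(null.std())
    if sd == 0.0:
        raise ValueError("null distribution has zero variance; increase null_size")
    z = (s_obs - float(null.mean())) / sd
    return float(z), ZScoreNull(s_obs, float(null.mean()), sd, null_size, seed)


def zscore_matrix(
    models: dict[str, Structure],
    control_label: str | None = None,
    null_size: int = 200,
    seed: int = 0,
) -> ScoreMatrix:
    """Symmetric all-against-all alignment Z-score matrix (the diagonal holds
    each model's self-alignment score)."""
    labels = list(models)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            z, _ = alignment_zscore(models[labels[i]], models[labels[j]],
                                    null_size=null_size, seed=seed + 997 * i + j)
            values[i, j] = values[j, i] = z
    return ScoreMatrix(labels, values, "zscore", control_label)


def consensus_stats(
    rmsd: ScoreMatrix,
    zscores: ScoreMatrix,
    control_label: str,
) -> dict[str, ConsensusStats]:
    """Per-candidate aggregates of the two matrices.

    mean/SD of RMSD are taken over the *other candidates* (self and control
    excluded; population SD).  The Z aggregate is the quadratic (root mean
    square) average over the other candidates plus the control — the
    combination under which the aggregate rewards consistently significant
    alignments.  Pearson r between a model's off-diagonal RMSD and Z entries
    (control included) is descriptive.
    """
    if rmsd.labels != zscores.labels:
        raise ValueError("matrices must share labels in the same order")
    if control_label not in rmsd.labels:
        raise ValueError(f"control {control_label!r} not in labels")
    candidates = [l for l in rmsd.labels if l != control_label]
    if len(candidates) < 3:
        raise ValueError("need at least three candidate models")
    out: dict[str, ConsensusStats] = {}
    for label in candidates:
        others = [l for l in candidates if l != label]
        r_vals = np.array([rmsd.entry(label, o) for o in others])
        z_vals = np.array([zscores.entry(label, o) for o in others + [control_label]])
        r_off = np.array([rmsd.entry(label, o) for o in others + [control_label]])
        if r_vals.std() == 0.0 or z_vals.std() == 0.0:
            pearson = None
        else:
            pearson = float(np.corrcoef(r_off, z_vals)[0, 1])
        out[label] = ConsensusStats(
            label=label,
            mean_rmsd=float(r_vals.mean()),
            sd_rmsd=float(r_vals.std()),     # population SD
            mean_z=float(np.sqrt(np.mean(z_vals ** 2))),
            pearson_r=pearson,
        )
    for rank, label in enumerate(rank_models(out), start=1):
        out[label].rank = rank
    return out


def rank_models(stats: dict[str, ConsensusStats]) -> list[str]:
    """Candidates sorted best-first: ascending mean RMSD, ties broken by
    descending Z aggregate, then label order.  The control is never ranked
    (it is not present in the stats)."""
    if not stats:
        raise ValueError("empty statistics")
    return sorted(stats, key=lambda l: (stats[l].mean_rmsd, -stats[l].mean_z, l))


# ---------------------------------------------------------------------------
# Ramachandran summaries
# ---------------------------------------------------------------------------

def _in_boxes(phi: float, psi: float, boxes) -> bool:
    return any(p0 <= phi <= p1 and s0 <= psi <= s1 for (p0, p1, s0, s1) in boxes)


# Three-level general-case region map built from rectangular basins: the
# alpha-helical, beta-sheet and left-handed-helical cores are "favored"; a
# generous envelope around each (covering, e.g., the classic gamma-turn
# center near (75, -64)) is "allowed"; everything else is "disallowed".
_FAVORED = [
    (-100.0, -30.0, -80.0, -5.0),     # alpha basin
    (-180.0, -45.0, 90.0, 180.0),     # beta basin
    (-180.0, -45.0, -180.0, -150.0),  # beta basin (psi wrap)
    (30.0, 100.0, 0.0, 80.0),         # left-handed alpha
]
_ALLOWED = [
    (-160.0, -20.0, -120.0, 30.0),
    (-180.0, -20.0, 60.0, 180.0),
    (-180.0, -20.0, -180.0, -140.0),
    (20.0, 110.0, -90.0, 100.0),      # includes the classic gamma-turn center
    (160.0, 180.0, 90.0, 180.0),
]


def classify_rama_region(phi: float, psi: float) -> str:
    if _in_boxes(phi, psi, _FAVORED):
        return "favored"
    if _in_boxes(phi, psi, _ALLOWED):
        return "allowed"
    return "disallowed"


def backbone_dihedrals(structure: Structure, chain_id: str | None = None):
    """(chain, residue number, phi, psi) for interior residues with a complete
    backbone; termini are skipped, incomplete residues skipped with a warning."""
    out = []
    for chain in structure.chains:
        if chain.polymer != "protein":
            continue
        if chain_id is not None and chain.id != chain_id:
            continue
        res = chain.residues
        for i in range(1, len(res) - 1):
            try:
                phi = dihedral(res[i - 1].atom("C").position, res[i].atom("N").position,
                               res[i].atom("CA").position, res[i].atom("C").position)
                psi = dihedral(res[i].atom("N").position, res[i].atom("CA").position,
                               res[i].atom("C").position, res[i + 1].atom("N").position)
            except KeyError as exc:
                warnings.warn(f"skipping residue {res[i].chain_id}:{res[i].number}: {exc}")
                continue
            out.append((chain.id, res[i].number, phi, psi))
    return out


def ramachandran(structure: Structure) -> RamachandranSummary:
    """Phi/psi dihedrals and region classification for every interior residue,
    with region percentages over the classified residues."""
    dihedrals = backbone_dihedrals(structure)
    if len(dihedrals) < 1:
        raise ValueError("need at least 3 consecutive residues for phi/psi")
    rows = []
    counts = {"favored": 0, "allowed": 0, "disallowed": 0}
    for chain_id, number, phi, psi in dihedrals:
        region = classify_rama_region(phi, psi)
        counts[region] += 1
        rows.append((chain_id, number, phi, psi, region))
    total = sum(counts.values())
    percentages = {k: 100.0 * v / total for k, v in counts.items()}
    return RamachandranSummary(rows, percentages)
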