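"""Conformational-ensemble analytics.

An ensemble is an ordered set of conformations sharing one topology (e.g.
the models of a multi-model PDB file standing in for sampled simulation
frames).  This module provides frame subsampling, per-residue RMSF about the
iteratively refined mean structure, all-against-all frame RMSD matrices
(heat-map substrate), per-span helix persistence, and the consensus of
per-residue disorder predictions (disordered iff probability > 0.5, strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modeleval import ScoreMatrix, _kabsch
from .secstruct import assign_helices
from .structio import Chain, Structure

__all__ = [
    "Ensemble",
    "sample_frames",
    "rmsf_per_residue",
    "pairwise_frame_rmsd",
    "helix_persistence",
    "disorder_consensus",
]


def _topology(st: Structure):
    return [
        (c.id, [(r.number, r.name, tuple(a.name for a in r.atoms)) for r in c.residues])
        for c in st.chains
    ]


@dataclass
class Ensemble:
    """Ordered conformations sharing one chain/residue/atom inventory."""

    frames: list[Structure]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("ensemble needs at least one frame")
        ref = _topology(self.frames[0])
        for k, frame in enumerate(self.frames[1:], start=1):
            if _topology(frame) != ref:
                raise ValueError(f"frame {k} does not share the ensemble topology")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Structure:
        return self.frames[i]

    @classmethod
    def from_multimodel(cls, structure: Structure, source: str = "") -> "Ensemble":
        frames = [Structure([model]).copy() for model in structure.models]
        return cls(frames, source)

    def to_multimodel(self) -> Structure:
        return Structure([f.chains for f in self.frames])

    def calpha_array(self) -> tuple[list, np.ndarray]:
        """Residue keys and an (n_frames, n_residues, 3) C-alpha coordinate
        array in consistent order."""
        keys = [(r.chain_id, r.number) for r, _ in self.frames[0].calpha()]
        coords = np.array([
            [at.position for _, at in frame.calpha()] for frame in self.frames
        ])
        return keys, coords


def sample_frames(ensemble: Ensemble, n: int, seed: int | None = None) -> Ensemble:
    """Subsample *n* frames: evenly spaced including both endpoints when
    *seed* is None, else a seeded uniform sample; frame order is preserved."""
    total = len(ensemble)
    if not 1 <= n <= total:
        raise ValueError(f"cannot sample {n} frames from {total}")
    if seed is None:
        if n == 1:
            idx = [0]
        else:
            step = total // (n - 1)
            idx = [min(i * step, total - 1) for i in range(n)]
    else:
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(total, size=n, replace=False).tolist())
    return Ensemble([ensemble.frames[i] for i in idx], source=ensemble.source)


def _mean_structure(coords: np.ndarray, refine_passes: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame onto an iteratively refined mean; returns the
    aligned coordinates and the final mean."""
    aligned = np.empty_like(coords)
    ref = coords[0]
    for _ in range(1 + refine_passes):
        for f in range(len(coords)):
            fit = _kabsch(coords[f], ref)
            aligned[f] = fit.apply(coords[f])
        ref = aligned.mean(axis=0)
    return aligned, ref


def rmsf_per_residue(ensemble: Ensemble) -> pd.DataFrame:
    """Per-residue root-mean-square fluctuation (Angstrom) about the mean
    C-alpha structure after iterative superposition (two refinement passes)."""
    if len(ensemble) < 2:
        raise ValueError("RMSF needs at least two frames")
    keys, coords = ensemble.calpha_array()
    aligned, mean = _mean_structure(coords)
    rmsf = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    return pd.DataFrame({
        "chain": [k[0] for k in keys],
        "residue": [k[1] for k in keys],
        "rmsf": rmsf,
    })


def pairwise_frame_rmsd(ensemble: Ensemble) -> ScoreMatrix:
    """Symmetric frame-vs-frame C-alpha RMSD matrix (zero diagonal)."""
    if len(ensemble) < 2:
        raise ValueError("need at least two frames")
    _, coords = ensemble.calpha_array()
    n = len(coords)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = _kabsch(coords[i], coords[j]).rmsd
    labels = [f"frame_{i}" for i in range(n)]
    return ScoreMatrix(labels, values, "rmsd")


def helix_persistence(
    ensemble: Ensemble,
    span: tuple[int, int],
    chain_id: str | None = None,
    coverage: float = 0.75,
) -> float:
    """Fraction of frames in which an assigned helix covers at least
    *coverage* of the span's residues (span is 1-based, inclusive)."""
    start, end = span
    chain_id = chain_id or ensemble.frames[0].chains[0].id
    residues = [r.number for r in ensemble.frames[0].chain(chain_id).residues
                if start <= r.number <= end]
    if not residues:
        raise ValueError(f"span ({start}, {end}) is outside the topology")
    needed = coverage * len(residues)
    present = 0
    for frame in ensemble.frames:
        spans = assign_helices(frame)
        covered = sum(
            1 for num in residues
            if any(s.chain_id == chain_id and s.covers(num) for s in spans)
        )
        if covered >= needed:
            present += 1
    return present / len(ensemble)


def disorder_consensus(table: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Consensus of per-residue disorder probabilities.

    *table* has residues as rows and predictors as columns (values in
    [0, 1]).  A predictor calls a residue disordered iff its probability is
    strictly greater than *threshold*; the consensus call is the majority
    vote and ``agreement`` is the fraction of predictors calling disorder.
    """
    if table.shape[1] < 1:
        raise ValueError("need at least one predictor column")
    values = table.to_numpy(dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise ValueError("disorder probabilities must lie in [0, 1]")
    calls = values > threshold  # strict: exactly 0.5 is ordered
    agreement = calls.mean(axis=1)
    return pd.DataFrame({
        "disordered": agreement > 0.5,
        "agreement": agreement,
    }, index=table.index)
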