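"""Sequence-level analyses: trafficking-signal and DNA-binding motif scans,
physicochemical profiles, alignment identity/conservation, and consensus
scoring of posttranslational-modification (PTM) site predictions.

Motif grammar
-------------
* Nuclear localization signal (NLS): the classic basic core ``K(K/R)X(K/R)``;
  a bipartite signal is reported when a second basic cluster (at least two
  K/R within a four-residue window) starts 8-14 residues downstream of the
  core start, extending the hit to the cluster's last basic residue.
* Nuclear export signal (NES): the leucine-spaced pattern
  ``L-x(3)-L-x(2)-L-x-L`` (strict leucine anchors by default).
* DNA-binding (AT-hook-like) core: a sliding window whose G/R/K fraction
  reaches a threshold; two cores separated by 10-40 residues pair into a
  bipartite DNA-binding domain.

All positions are 1-based and inclusive.  The PTM meta-score is the
fraction of registered programs (per modification class) whose raw score
strictly exceeds their cutoff, so unanimous prediction scores 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

__all__ = [
    "MotifHit",
    "scan_nls",
    "scan_nes",
    "scan_dbd",
    "hydropathy_profile",
    "physchem",
    "net_charge",
    "identity_matrix",
    "conservation_map",
    "ptm_meta_score",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifHit:
    motif_id: str       # nls | nes | dbd_core | dbd_bipartite
    start: int          # 1-based
    end: int            # inclusive
    sequence: str
    score: float
    bipartite: bool = False


def _check_protein(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"unknown amino-acid letters: {sorted(bad)}")
    return seq


def _basic_fraction(window: str) -> float:
    return sum(c in "KR" for c in window) / len(window)


def scan_nls(sequence: str, spacer: tuple[int, int] = (8, 14)) -> list[MotifHit]:
    """All K(K/R)X(K/R) cores, extended to bipartite signals where a second
    basic cluster begins *spacer* residues downstream of the core start."""
    seq = _check_protein(sequence)
    hits = []
    for m in re.finditer(r"(?=(K[KR].[KR]))", seq):
        start = m.start() + 1
        core_end = start + 3
        end, bipartite = core_end, False
        for offset in range(spacer[0], spacer[1] + 1):
            t = start + offset  # 1-based cluster window start
            window = seq[t - 1 : t + 3]
            if len(window) == 4 and sum(c in "KR" for c in window) >= 2:
                end = t + max(i for i, c in enumerate(window) if c in "KR")
                # run to the end of the contiguous basic stretch of the cluster
                while end < len(seq) and seq[end] in "KR":
                    end += 1
                bipartite = True
                break
        span = seq[start - 1 : end]
        hits.append(MotifHit("nls", start, end, span, _basic_fraction(span), bipartite))
    return hits


_NES_SPACING = (0, 4, 7, 9)  # anchor offsets within the 10-residue pattern


def scan_nes(sequence: str, extended_anchors: bool = False) -> list[MotifHit]:
    """Leucine-spaced export-signal pattern L-x(3)-L-x(2)-L-x-L.

    With ``extended_anchors`` the anchor alphabet widens to {L, I, V, F, M}
    (off by default); the score is the fraction of anchors that are leucine.
    """
    seq = _check_protein(sequence)
    anchors = set("LIVFM") if extended_anchors else {"L"}
    hits = []
    for i in range(len(seq) - 9):
        window = seq[i : i + 10]
        if all(window[o] in anchors for o in _NES_SPACING):
            score = sum(window[o] == "L" for o in _NES_SPACING) / len(_NES_SPACING)
            hits.append(MotifHit("nes", i + 1, i + 10, window, score))
    return hits


def scan_dbd(
    sequence: str,
    window: int = 7,
    grk_threshold: float = 0.7,
    pair_separation: tuple[int, int] = (10, 40),
) -> list[MotifHit]:
    """G/R/K-rich cores and bipartite core pairs.

    Overlapping qualifying windows are merged into one region, which reports
    its best-scoring window (leftmost on ties).  Two cores whose gap is
    within *pair_separation* residues additionally form a ``dbd_bipartite``
    hit spanning both.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    seq = _check_protein(sequence)
    n = len(seq)
    fracs = [
        sum(c in "GRK" for c in seq[i : i + window]) / window
        for i in range(n - window + 1)
    ]
    qualifying = [i for i, f in enumerate(fracs) if f >= grk_threshold]
    cores: list[MotifHit] = []
    run: list[int] = []
    for i in qualifying + [None]:
        if i is not None and (not run or i <= run[-1] + window - 1):
            run.append(i)
            continue
        if run:
            best = max(run, key=lambda j: (fracs[j], -j))
            cores.append(MotifHit(
                "dbd_core", best + 1, best + window, seq[best : best + window], fracs[best]))
        run = [i] if i is not None else []
    hits = list(cores)
    for a in range(len(cores)):
        for b in range(a + 1, len(cores)):
            first, second = cores[a], cores[b]
            gap = second.start - first.end - 1
            if pair_separation[0] <= gap <= pair_separation[1]:
                hits.append(MotifHit(
                    "dbd_bipartite", first.start, second.end,
                    seq[first.start - 1 : second.end],
                    (first.score + second.score) / 2.0, bipartite=True))
    return hits


def hydropathy_profile(sequence: str, window: int = 9) -> np.ndarray:
    """Centered sliding-window mean of the Kyte-Doolittle hydropathy scale;
    profile length is ``len(sequence) - window + 1`` (ends truncated)."""
    seq = _check_protein(sequence)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(seq):
        raise ValueError("window longer than sequence")
    values = np.array([KYTE_DOOLITTLE[c] for c in seq])
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


# EMBOSS-style pKa set for the Henderson-Hasselbalch net-charge function
_PKA_POSITIVE = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEGATIVE = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


def net_charge(sequence: str, ph: float) -> float:
    """Net charge at a given pH from per-group Henderson-Hasselbalch terms."""
    seq = _check_protein(sequence)
    counts = {aa: seq.count(aa) for aa in "KRHDECY"}
    charge = 0.0
    for group, pka in _PKA_POSITIVE.items():
        n = 1 if group == "nterm" else counts[group]
        charge += n / (1.0 + 10.0 ** (ph - pka))
    for group, pka in _PKA_NEGATIVE.items():
        n = 1 if group == "cterm" else counts[group]
        charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def physchem(sequence: str) -> tuple[float, float]:
    """(average molecular weight in Da, isoelectric point).

    MW is the residue-mass sum plus one water; pI is found by bisection of
    the net-charge function (tolerance 1e-6 charge units).
    """
    seq = _check_protein(sequence)
    if not seq:
        raise ValueError("empty sequence")
    mw = float(molecular_weight(seq, seq_type="protein"))
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid)
        if abs(q) < 1e-6:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mw, mid


def _msa_rows(msa) -> tuple[list[str], list[str]]:
    """Accept a list of strings, list of (id, seq) pairs, or a Biopython
    MultipleSeqAlignment; return (labels, aligned sequences)."""
    try:
        from Bio.Align import MultipleSeqAlignment
        if isinstance(msa, MultipleSeqAlignment):
            return [rec.id for rec in msa], [str(rec.seq).upper() for rec in msa]
    except ImportError:  # pragma: no cover
        pass
    labels, rows = [], []
    for i, item in enumerate(msa):
        if isinstance(item, str):
            labels.append(f"seq_{i + 1}")
            rows.append(item.upper())
        else:
            label, seq = item
            labels.append(str(label))
            rows.append(str(seq).upper())
    return labels, rows


def identity_matrix(msa) -> pd.DataFrame:
    """Pairwise percent identity over alignment columns, excluding columns
    where both sequences have a gap; symmetric with a 100 diagonal."""
    labels, rows = _msa_rows(msa)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences have different lengths")
    n = len(rows)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            cols = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
            if not cols:
                ident = 0.0
            else:
                same = sum(1 for x, y in cols if x == y and x != "-")
                ident = 100.0 * same / len(cols)
            values[i, j] = values[j, i] = ident
    return pd.DataFrame(values, index=labels, columns=labels)


def conservation_map(msa, reference_row: int = 0, structure=None) -> pd.DataFrame:
    """Per-position conservation of the reference sequence within an MSA.

    For every non-gap reference position: the percentage of rows sharing the
    reference letter, and a 1-9 grade from linear binning of that percentage.
    With *structure* given, positions are projected onto the residues of its
    first protein chain (length mismatch is an error naming the offset).
    """
    labels, rows = _msa_rows(msa)
    ref = rows[reference_row]
    columns = []
    for col, letter in enumerate(ref):
        if letter == "-":
            continue
        pct = 100.0 * sum(1 for r in rows if r[col] == letter) / len(rows)
        columns.append((col, letter, pct))
    grade = [min(9, max(1, int(np.ceil(pct / 100.0 * 9)))) for _, _, pct in columns]
    out = pd.DataFrame({
        "position": np.arange(1, len(columns) + 1),
        "letter": [c[1] for c in columns],
        "conservation_pct": [c[2] for c in columns],
        "grade": grade,
    })
    if structure is not None:
        protein_chains = [c for c in structure.chains if c.polymer == "protein"]
        residues = protein_chains[0].residues
        if len(residues) != len(out):
            raise ValueError(
                f"structure/sequence mismatch: first offset at position "
                f"{min(len(residues), len(out)) + 1} "
                f"({len(residues)} residues vs {len(out)} reference positions)")
        out["residue_number"] = [r.number for r in residues]
    return out


def ptm_meta_score(table: pd.DataFrame, include_zero: bool = False) -> pd.DataFrame:
    """Consensus PTM score per (site, modification class).

    A program predicts a site iff its raw score strictly exceeds its cutoff;
    the meta-score is predicting programs / programs registered for that
    class, so a site predicted by every program scores 1.  Sites with no
    predicting program are omitted unless ``include_zero``.
    """
    required = {"site", "class", "program", "score", "cutoff"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    if table["cutoff"].isna().any():
        bad = table.loc[table["cutoff"].isna(), "program"].iloc[0]
        raise ValueError(f"program {bad!r} has no cutoff")
    totals = table.groupby("class")["program"].nunique()
    predicted = table[table["score"] > table["cutoff"]]
    counts = predicted.groupby(["site", "class"])["program"].nunique()
    rows = []
    for (site, mod_class), group in table.groupby(["site", "class"]):
        n_pred = int(counts.get((site, mod_class), 0))
        total = int(totals[mod_class])
        rows.append((site, mod_class, n_pred, total, n_pred / total))
    out = pd.DataFrame(rows, columns=["site", "class", "n_predicting", "n_programs", "score"])
    if not include_zero:
        out = out[out["n_predicting"] > 0].reset_index(drop=True)
    return out
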