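# Methods

`hlhkit` analyses small helix-loop-helix (HLH) DNA-binding chromatin
proteins of the kind typified by nuclear protein 1 (NUPR1) and the
AT-hook-containing HMGA family: largely disordered polypeptides of ~80-100
residues that populate three transient helices, carry a G/R/K-rich
minor-groove binding motif plus a basic C-terminal cluster, and are
regulated through trafficking signals and dense posttranslational
modification. Because such proteins resist conventional structure
determination, their characterization rests on consensus analysis of
predicted models, geometric interface criteria, ensemble statistics and
sequence-level meta-prediction — the stages this package implements.

## Structure model and I/O

Structures are a plain chain/residue/atom hierarchy (Angstrom coordinates,
1-based residue numbers, inclusive spans). PDB parsing and writing go
through gemmi; a pre-scan of ATOM/HETATM coordinate columns turns malformed
fixed-width records into errors that name the offending line. Phosphate
oxygens are normalized to the `OP1`/`OP2` dialect (`O1P -> OP1`,
`O2P -> OP2`); the mapping is idempotent and touches nothing else.
Insertion codes are ignored with a warning and only the first altloc of a
disordered atom is kept — the intended inputs (predicted models, sampled
conformations, fiber-model DNA) do not use them. Hydrogens are ordinary
atoms: nothing at the I/O layer invents or strips them.

Interface reports use the compact `chain:ResnameNumber:atomname` notation
(`A:Arg60:NH2`, `C:A7:OP2`); parsing splits the middle field at its first
digit and formatting is the exact inverse, so specs round-trip verbatim
(DNA residues may be written in their one-letter table style).

## Synthetic generators

The generators produce every input the pipeline consumes, so all stages are
testable without downloads.

* **Peptide builder.** Backbones (N, CA, C, O, CB except Gly) are grown by
  NeRF extension with ideal bond lengths (N-CA 1.458, CA-C 1.525, C-N
  1.329 A) and angles; phi/psi are (-57, -47) degrees inside helical spans
  and (-120, +120) elsewhere; omega is 180. Only dihedral-level realism is
  needed by the downstream rules, so side chains beyond CB, rotamers and
  nonbonded packing are deliberately absent. Optional seeded Gaussian
  positional noise models coordinate error.
* **Side chains.** Where charge-bearing termini matter (docking peptides,
  charge-reversal mutation) side chains for Ala/Asp/Glu/Lys/Arg are grown
  as idealized straight chains along CA->CB (1.52 A spacing, symmetric
  terminal branch pairs). Geometry is schematic; atom names and formal
  charges are exact, which is what the distance-cutoff detectors consume.
* **B-DNA.** A rigid fiber model: 36 degrees twist and 3.38 A rise per
  base pair, the given strand as chain C (residues 1..n) and its reverse
  complement as antiparallel chain D (n+1..2n). Each nucleotide carries P,
  OP1, OP2, O5', C1' and planar base-ring atoms; paired C1' atoms subtend
  120 degrees on the minor-groove side, phosphates sit just outside the
  glycosidic positions, all at one cylinder radius. No sequence-dependent
  geometry and no bending — DNA deformation is out of scope throughout.
* **Ensembles.** A helix schedule assigns each span an order probability.
  Per frame, each span is rebuilt helical with its probability and
  otherwise re-dihedralized to random coil (phi ~ U(-160, -75), psi ~
  U(95, 175): generously allowed, unambiguously non-helical); residues
  outside every span keep the base dihedrals; small positional noise
  (default 0.05 A) is added. Frames share one topology. Span-wise helix
  persistence therefore converges to the schedule, which is the module's
  parameter-recovery surface.
* **Predictor tables and sequences.** Site-prediction tables draw, per
  site and program, a score above the program cutoff with a configurable
  agreement probability. Motif-embedding backgrounds exclude K/R/G/L so a
  planted motif is the only match its scanner can find.

## Model evaluation

Pairs of models are superposed by least-squares rigid-body fitting on
matched C-alpha atoms (Kabsch via quaternion alignment; reflections
excluded), giving all-against-all RMSD matrices. Alignment significance is
scored against a shuffle null: the statistic is the number of matched
C-alpha pairs within 4 A after superposition (fraction matched times
alignment length), and the null re-threads one structure's residue order on
its own backbone trace with 200 seeded shuffles;
z = (S_obs - mean_null) / sd_null. The shuffle null destroys chain
continuity, so genuinely chain-like decoys can sit slightly above it; the
calibration tests therefore use exchangeable random point clouds, for which
the null is exact. A degenerate (zero-variance) null is reported as an
error suggesting a larger null size.

Consensus statistics per candidate: mean and population SD of RMSD over the
other candidates (self and negative control excluded), and a Z aggregate
taken as the quadratic mean (root mean square) over the other candidates
plus the control — the quadratic form rewards consistently significant
alignments and is the combination under which the published aggregate rows
we checked reproduce exactly. Pearson r between a model's off-diagonal
RMSD and Z entries is computed descriptively only. Ranking sorts ascending
by mean RMSD with ties broken by descending Z aggregate, then label; the
negative control is never ranked.

Ramachandran regions use a three-level rectangular basin map: favored
covers the alpha, beta and left-handed-alpha cores; allowed is a generous
envelope around each (including the classic gamma-turn center near
(75, -64)); everything else is disallowed. The map is deliberately coarse —
region topology (helical core favored, origin disallowed), not a
particular published grid, is what downstream consumers rely on.

## Secondary structure and accessibility

A residue is helical when its (phi, psi) lie within +/-35 degrees of
(-57, -47); maximal runs of at least four helical residues become spans, so
a span from 20 to 33 has length 14. The dihedral window was chosen over an
H-bond (DSSP-style) assignment because the inputs are dihedral-built and
the reported quantities are residue spans. Beta turns are four consecutive
non-helical residues with CA(i)-CA(i+3) strictly below 7 A; gamma turns are
three consecutive residues with an O(i)...N(i+2) hydrogen bond
(H...acceptor <= 2.5 A when hydrogens exist, heavy-atom <= 3.5 A
otherwise), flagged classic when the central residue is within 30 degrees
of (75, -64). Turn scans report maximal non-overlapping windows N-to-C.

Solvent accessibility is Shrake-Rupley sampling: 960 golden-spiral points
per atom on the probe-expanded sphere (probe 1.4 A), vdW radii C 1.70,
N 1.55, O 1.52, S 1.80, P 1.80, H 1.20. Relative accessibility divides by
Gly-X-Gly reference maxima (Tien et al. theoretical values); residues with
relative ASA strictly below 0.25 are labeled buried ("b"), others exposed
("e"). The 0.25 threshold is this package's declared choice.

## Interface geometry

All cutoffs are inclusive (a contact at exactly the cutoff is reported;
0.01 A beyond never is):

| category | rule | cutoff (A) |
|---|---|---|
| salt bridge | charged N (Lys NZ; Arg NH1/NH2/NE; His ND1/NE2) to charged O (Asp/Glu carboxylate, DNA OP1/OP2, OXT), atom-pairwise | 5.0 |
| hydrogen bond | polar H (on N/O) to O/N acceptor | 2.5 |
| attractive charge | opposite formal charges, atom-pairwise | 5.6 |
| pi-pi stacking | aromatic ring centroid to ring centroid | 5.5 |
| alkyl | aliphatic carbon group to aliphatic group, closest approach | 5.5 |
| pi-alkyl | ring centroid to aliphatic group, closest approach | 6.0 |

Salt-bridge and attractive-charge distances are measured between the named
atoms, not group centroids, matching how interface tables are reported.
The electrostatic/hydrophobic cutoffs are this package's calibration,
chosen to bracket the distances such reports print. Histidine counts as
positive by default (configurable). Reports across a receptor/ligand chain
partition or intramolecularly are the union of the detectors, deduplicated
(a pair already reported as a salt bridge is not repeated as attractive
charge) and sorted by category then distance. When a structure carries no
hydrogens at all, hydrogen-bond detection falls back to donor-heavy-atom
distances at 3.5 A.

Charge-reversal mutation keeps the backbone and rebuilds the side chain
with the idealized straight-chain geometry along CA->CB; supported targets
are Glu/Asp/Lys/Arg/Ala, and glycine positions are rejected (no CB to
orient the new chain). Mutant side-chain geometry is an idealization:
numeric distances in relaxed mutant complexes are not reproduced, only the
presence/absence logic that the rewiring report consumes. Rewiring diffs
two record sets at the (category, residue-pair) level into lost, gained and
conserved keys.

## Docking and groove assignment

Rigid docking samples seeded random orientations of the protein placed in a
shell around the duplex axis and scores each pose as
`w_attr * (attractive-charge pairs <= 5.6 A) - w_clash * (heavy-atom pairs
< 2.5 A)` with unit weights by default. Poses are greedily clustered at
3 A RMSD on placed protein coordinates (best scores first); clusters are
ranked by their best member. This is an enrichment screen, not a physical
energy model: its contract is that a cationic-patch protein robustly
outranks an uncharged control, and that an uncharged protein can never
score above zero.

Groove assignment classifies a point relative to a builder duplex: distal
when more than 10 A from the nearest DNA atom, backbone when the nearest
atom is a phosphate/sugar atom within 4 A, otherwise by angular sector
around the helical axis — the minor-groove direction at each base-pair
level is the bisector of the two glycosidic (axis -> C1') directions
(within 70 degrees: minor; beyond 110: major; between: backbone ridge).
The axis is recovered from the coordinates by a least-squares cylinder fit
to the C1' atoms; a plain principal-component line fit is biased toward the
helix for short duplexes, which the cylinder fit avoids.

## Ensemble analytics

Frame subsampling is evenly spaced including both endpoints (a 120-frame
ensemble sampled at 6 gives frames {0, 24, 48, 72, 96, 119}) or a seeded
uniform draw, order preserved. RMSF superposes every frame onto an
iteratively refined mean C-alpha structure (two refinement passes — the
mean, not frame 1, to avoid reference bias) and reports per-residue
root-mean-square deviation from that mean. Pairwise frame RMSD uses the
same rigid fit per pair. Helix persistence counts the fraction of frames
in which an assigned helix covers at least 75% of a span's residues
(the 75% coverage rule is this package's definition of "helix present in a
frame", exposed in configuration). Disorder consensus calls a residue
disordered per predictor iff its probability strictly exceeds 0.5 (exactly
0.5 is ordered), with majority voting and the agreement fraction reported.

Because the synthetic frames are ideal dihedral chains without tertiary
packing, re-dihedralized spans swing on long lever arms and global
superposition distributes part of that motion onto rigid regions. The
robust, tested consequence of an order/disorder schedule is therefore that
the persistently folded span fluctuates less than the rest of the chain,
and that a fully disordered ensemble is less self-similar (higher pairwise
RMSD) than a fully ordered one — not a literal per-residue reproduction of
an MD fluctuation profile. Passing tests show parameter recovery and these
orderings; they do not show force-field-level realism.

## Sequence analyses

* **NLS**: all matches of the basic core K(K/R)X(K/R); a bipartite signal
  is reported when a second basic cluster (>= 2 K/R in a 4-residue window)
  starts 8-14 residues downstream of the core start, the hit extending to
  the end of the cluster's contiguous basic stretch. The spacer bounds are
  configurable; defaults were fixed so a core at 82 with a cluster at
  93-96 yields the canonical 82-96 bipartite span.
* **NES**: the leucine-spaced pattern L-x(3)-L-x(2)-L-x-L with strict
  leucine anchors; an option widens anchors to {L, I, V, F, M} (off by
  default), the score being the leucine fraction of the anchors.
* **DNA-binding core**: sliding windows (default 7) whose G/R/K fraction
  reaches 0.7; overlapping qualifying windows merge and report their
  best-scoring window (leftmost on ties), so RKGRTKR and KKRGARR each
  score 6/7. Two cores separated by 10-40 residues pair into a bipartite
  domain hit.
* **Physicochemistry**: Kyte-Doolittle hydropathy as a centered
  sliding-window mean (ends truncated); molecular weight as residue-mass
  sum plus one water (Biopython masses); isoelectric point by bisection of
  the Henderson-Hasselbalch net charge with an EMBOSS-style pKa set, to a
  charge tolerance of 1e-6.
* **Alignment statistics**: percent identity over columns excluding
  gap-gap pairs; conservation as the percentage of rows sharing the
  reference letter per reference position, graded 1-9 by linear binning,
  optionally projected onto a structure's residues.
* **PTM meta-score**: a program predicts a site iff its raw score strictly
  exceeds its program-specific cutoff; the score is predicting programs
  over programs registered for that modification class (per-class totals),
  so unanimous prediction scores 1 and a site predicted by half the
  programs scores 0.5. Per-program weighting is deliberately rejected for
  reproducibility. Zero-prediction sites are omitted from reports but
  retrievable.

## Numerical choices and degenerate inputs

Distance cutoffs are inclusive; boundary behavior is tested at +/-0.01 A.
Rigid fits on coordinates far from the origin are accurate to ~1e-5 A
RMSD. Pearson r is reported as missing when either vector is constant;
a zero-variance shuffle null raises instead of returning an infinite z.
Probabilities outside [0, 1], overlapping spans or motif placements, ragged
alignments, unknown elements and unknown residue letters are rejected with
messages naming the offender. All stochastic steps take explicit seeds and
are bit-reproducible under a fixed seed, including the command-line
pipeline (byte-identical reports).

## Problem sizes

Defaults were sized for interactive desk use: 400-frame ensembles for
parameter recovery, 300 docking poses per run across 20 seeds for the
enrichment contract, 200-sample shuffle nulls, 960 sphere points per atom.
All are parameters, not constants.

## Known limitations

No physical energetics anywhere (docking scores count contacts; no
electrostatic potentials or volumes are computed). DNA is rigid and
sequence-independent. Mutant side chains are idealized, so mutant contact
distances are qualitative. The Ramachandran map is rectangular, not a
published density grid. The helix assigner is dihedral-only and will not
recognize distorted helices an H-bond-based assigner would. Sequence scans
are pattern-based and do not re-implement machine-learning predictors;
their inputs (probability and score tables) are consumed, not produced.
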