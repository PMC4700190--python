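# Methods

`spiralscan` models the quaternary structure and solution behaviour of
spiral-forming nitrilases, using *Bacillus pumilus* cyanide dihydratase
(CynD) as its reference system.  CynD dimers stack along a screw axis into a
self-terminating 18-mer spiral; the dimer–dimer interface (the C-surface)
is carried by two sequence insertions absent from non-spiral members of the
superfamily.  The package provides the computational side of probing that
surface: screw geometry, contact mapping, insertion-region detection,
size-exclusion (SEC) oligomer-state calling, and integration of a
per-position cysteine-scan survey.

## Screw geometry

A spiral is parameterised by a per-step rise Δz (nm), a twist ΔΦ magnitude
(deg) and a handedness.  Conventions, fixed once and asserted in tests:

* the screw axis is the +z axis through the origin; callers pre-orient
  structures (the synthetic generators emit them pre-oriented);
* left-handed = negative rotation about +z per positive rise, so the signed
  twist used internally is −ΔΦ for a left-handed spiral;
* the repeating unit is the dimer: the CynD values (Δz = 1.62 nm,
  ΔΦ = 77° left) are treated as per-dimer quantities, because the dimer is
  the spiral's building block.  The engine itself is agnostic — any
  protomer model can be stepped;
* lengths are Å internally (PDB convention) and nm at the user surface,
  with a fixed factor of 10 Å/nm.

`build_helical_assembly` places copy *k* at `Rz(kθ)·x + k·(0,0,Δz)`.
`estimate_screw_parameters` inverts this from coordinates alone: each
consecutive copy pair is superposed by least squares (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`, which excludes
reflections by construction), the relative transform is decomposed into
axis–angle form, the axis is oriented so the rise (translation component
along the axis) is positive, and the handedness is read from the sign of
the rotation about that axis.  Estimates are averaged over pairs; the
maximum per-pair deviation is reported as a diagnostic, and an assembly is
rejected as "not helical" when the axes deviate by more than 1° or the
rises by more than 1% (both configurable).  A relative rotation below
1e-6° is a degenerate (no-screw) error.  Twists very near 180° make the
axis sign ill-conditioned; the tested range is (5°, 175°).

Reference parameter sets are shipped as constants: CynD (1.62 nm / 77°
left), the *Drosophila* beta-alanine synthase crystal spiral (1.41 nm /
83.1° left) and the *Synechocystis* oxy-nitrilase helix (2.68 nm / 60.0°
left, exactly six dimers per turn).

## Interfaces

Contacts are heavy-atom pairs from distinct copies within a cutoff,
default 4.5 Å — the common structural-biology convention; the underlying
survey names interaction types but no cutoff, so the value is explicit and
tunable.  Hydrogens and HETATM records are excluded.  The implementation
uses a k-d tree and is tested against an all-pairs brute-force oracle.

Copy pairs are labelled by the surface they can form: pairs inside one
declared dimer → A; consecutive copies → C; pairs whose cumulative
rotation differs from a full turn by at most a groove tolerance (default
30°) → cross-groove.  With 77° per step no pair lands exactly on 360°
(copies k and k+5 differ by 385°), hence the tolerance.  The D and E
surfaces of the EM literature are distinguished experimentally by outcome
(stabilisation vs termination), not geometry, so both map to the single
cross-groove label; no termination predictor is implemented because no
geometric rule for E-surface closure is available.  Residue-level
interface membership is "at least one atomic contact".

## Insertion regions

An insertion is defined pairwise: columns where a named non-spiral
reference is gapped and the query holds residues.  Runs separated by fewer
than `gap_merge` (default 2) intervening columns are merged; merged runs
with at least `min_length` (default 4) query residues are reported in the
query's ungapped 1-based coordinates.  The defaults are chosen so each of
the two CynD regions (55–72, length 18; 222–235, length 14) comes out as a
single run on plausible alignments.  Region mapping projects a region's
column span onto another sequence and reports the length difference (the
beta-alanine-synthase-like homolog's region 1 is 8 residues shorter).
Residue ranges throughout the package are 1-based and inclusive at both
ends, so 55–72 counts 18 residues.  Real homolog sequences are not
bundled; the packaged fixture is a synthetic alignment engineered to
reproduce the CynD region coordinates exactly, and only CynD numbering is
pinned.

## SEC analysis

Calibration fits log10(mass/Da) against the partition coefficient
Kav = (Ve − V0)/(Vt − V0) (standard SEC practice; a raw-Ve mode exists).
A non-negative slope is rejected: larger species must elute earlier.  V0
and Vt are run parameters, defaulting to the synthetic column's truth
(8.0 / 24.0 ml, a 10/300-format geometry).  Peak detection smooths with an
edge-padded moving average (default 5 points), finds local maxima above a
prominence threshold (default 1% of the trace maximum) and assigns areas
by watershed at the smoothed minima between apexes, normalised to total
trace area.  An apex within 0.2 ml of V0 is flagged in-void (excluded
species have no defined mass).

Oligomer assignment rounds mass/monomer to the nearest stoichiometry,
resolving odd candidates to the nearest even one by default because the
dimer is the assembly unit.  The default monomer mass is 37 kDa, the value
implied by the internally consistent oligomer ladder (decamer 370 kDa,
hexamer 222 kDa, dimer 74 kDa); denaturing gels read the monomer nearer
40 kDa, and the knob is configurable.

Elution patterns are classified against measured 18-mer and 14-mer
reference volumes (run parameters, not constants) with a ±0.3 ml
tolerance: void-dominant → extended/aggregated; two or more peaks of ≥15%
area with at least one beyond the 14-mer → multiple smaller species;
otherwise the dominant apex decides 18-mer / 14-mer / intermediate ~16-mer.
The original mutant survey classified traces by visual inspection, so every
threshold here is explicit and tunable rather than implicit.
Re-chromatography stability is the rerun area inside the original
collection window over total rerun area, "stable" at ≥ 0.5.

## Activity and the scan summary

The picric-acid endpoint assay reads remaining cyanide as A520, so
consumed cyanide is proportional to (blank − sample) and

relative activity = 100 × (mean_blank − mean_sample) / (mean_blank − mean_wt),

clamped below at 0, with the sd propagated from replicate sds by the delta
method.  The buffer-only blank anchors 0% and wild type anchors 100%; the
formula is the package's explicit rendering of "activity relative to wild
type", which the source survey plots without printing.  Activity classes:
below 10% → minimal (strict), at or below 50% → reduced (inclusive),
else normal; a secondary 60% cut is available through the configurable
threshold.  The scan summary joins elution classes with activity classes
per region; "wild-type pattern" means the 18-mer elution class.

The packaged fixture encodes the 32-construct survey (18 positions in
region 1, 14 in region 2, native C225 scanned as C225A) with threshold-level
activity classes only — per-mutant percentages were never published, so
activity-dependent counts beyond the threshold statements require user
data.  Two rendering ambiguities in the source table are resolved in the
package's favour of the running text: F69C (not F59C) is the intermediate
~16-mer in region 1, and position 230 is Q230C; the R67C row follows the
fraction-level description (14-mer dominant, decamer/hexamer shoulder,
dimer peak → multiple smaller).

## Synthetic data

The generators define the study conditions and are first-class, tested
code.  They are deliberately coarse-grained; none of the following is a
physical protein model.

* **Toy protomer** — Cα pseudo-atoms on one hexagonal lattice layer (5.5 Å
  spacing) at z = +5 Å, farthest atom rescaled to sit exactly at the
  stated radius (default 55 Å, giving the 11 nm assembly diameter seen in
  micrographs).  Interface residues carry one protruding pseudo-sidechain
  atom placed 3 Å short (along −z) of that residue's image under the
  screw.  This guarantees inter-copy contacts at exactly the planted
  residues and nowhere else at the 4.5 Å cutoff: the nearest non-partner
  atom is at least √(s² + 9) ≈ 6 Å away for lattice spacing s.  A lattice,
  not a smooth backbone, is what makes this guarantee provable; the
  fixtures therefore test contact bookkeeping, not fold realism.
* **C2 dimer** — the protomer plus its 180° rotation about an in-plane
  dyad through the origin; with the protomer at z ≥ +5 the chains cannot
  clash, the dimer centroid lies on the dyad, and the dimer (height ~10 Å
  plus protrusions) fits inside one 16.2 Å screw step.  In an assembled
  spiral the B-chain contacts mirror the A-chain contacts onto the
  previous copy, reproducing the twofold symmetry of a C2 C-surface.
* **Assemblies** — built exactly, then optionally perturbed with isotropic
  Gaussian coordinate noise (0.5 Å is the tested level; the estimator
  recovers the twist to well under 0.5° there because the error averages
  over hundreds of atoms at large radius).
* **Chromatograms** — Gaussian mixtures on a truth calibration line
  log10(M/Da) = 6 − 2.3·Kav (exclusion limit 1 MDa), peak sd 0.15 ml,
  additive baseline noise sd 0.002 AU, grid 0.02 ml over 7–25 ml.  With a
  37 kDa monomer this places the 18-mer at 9.23 ml and the 14-mer at
  9.99 ml — resolved at 5 sd, comfortably classifiable at the 0.3 ml
  tolerance.  Species above the exclusion limit pile up at V0.
* **Assay plates** — sample means interpolated between blank (1.10 AU) and
  wild-type (0.15 AU) anchors with multiplicative noise (default CV 5%,
  3 replicates); recovery error on a 20-mutant plate averages under
  5 percentage points.
* **Alignments** — conserved random core with insertion blocks present
  only in the named spiral members; per-member length overrides produce
  the 8-residue-shorter homolog.  Planted (position, length) truths are
  returned for recovery tests.

All generators are deterministic given a seed and return truth records.
Passing tests therefore demonstrate correctness of the algorithms under
idealised geometry and noise models — not performance on real electron
micrographs, real chromatograms with drifting baselines, or real
alignments with ambiguous gap placement.

## Numerical and design notes

* PDB I/O is delegated to gemmi; coordinates round-trip exactly at the
  format's 3-decimal precision.  Insertion codes are rejected (scan
  constructs have none; silent renumbering would corrupt author
  numbering); altloc duplicates keep the first copy; HETATM records are
  retained but excluded from contact and selection defaults.
* Assembly output relabels chains deterministically through A–Z, a–z, 0–9;
  beyond 62 chains single-column PDB chain IDs are exhausted and the
  writer raises rather than emitting a file that cannot round-trip.
* Tie-breaks: even-preferred oligomer assignment resolves an exact odd tie
  to the smaller even stoichiometry; classification rules are ordered
  (void first, multi-peak second) so a 14-mer-dominant multi-species trace
  is called "multiple smaller", matching the biology of a partial assembly
  defect.
* The demo pipeline and all tests use problem sizes of a few thousand
  atoms and ~900-point traces; the full suite runs in a few seconds.

## Known limitations

* No D/E disambiguation, no termination-count prediction from geometry,
  no buried-surface-area or energy scoring.
* Single-screw helices only: no point-group builders, no axis fitting for
  arbitrarily oriented assemblies (structures must be pre-oriented on +z).
* SEC peak areas use watershed partitioning, not Gaussian deconvolution;
  strongly overlapping species bias area fractions.
* The F-surface named in the EM literature has no geometric definition
  here and is not classified; whether the A-surface dyad coincides with
  the spiral dyad is left open, and nothing in the package assumes it.
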