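# Methods

This note records the models, conventions and numerical choices behind
`fivetm`, in the spirit of a package methods appendix: what is computed,
under which assumptions, which knobs matter, and what the synthetic
validation does and does not establish.

## Coordinate model and numbering

Structures are read and written through gemmi (PDB and mmCIF) into a
column-wise atom table per model. Author (PDB) residue numbering is the
only numbering used anywhere: the residues users care about (W118, Y184,
C245, E123/V274, …) are author numbers, and unmodelled stretches are simply
absent residues — no renumbering, no gap filling. Alternate locations are
resolved at read time to the highest-occupancy conformer, ties broken by
file order, which makes parsing deterministic. Hydrogens, waters and
non-protein heteroatoms are retained on read but excluded from every
geometric analysis unless selected explicitly; this keeps glycans and
solvent from polluting surface and contact measurements by default.

The default segment table divides the receptor into linker 114–120,
helix I 121–140, helix II 160–178, ECL1 179–185, helix III 186–207,
helix IV 224–242, ECL2 243–250 and helix V 251–278; the intracellular
loops fall in the unnamed gaps. Segment maps are user-replaceable.

## Membrane frame and ECD tilt

The membrane frame is defined entirely by the coordinates: origin at the
center of mass of the backbone atoms (N, Cα, C, O) of the five helix
segments, membrane normal along their first principal axis. The principal
axis was chosen over any membrane-insertion heuristic because it is
parameter-free and deterministic for a near-vertical bundle; its sign is
fixed by requiring z(Cα E123) > z(Cα V274), the extracellular and
intracellular boundary references. The ECD tilt is the angle in [0°, 90°]
between the vector from the origin to the center of mass of Cα 32–36 (the
β-hairpin tip of the domain) and the plane z = 0. Both the frame and the
tilt are equivariant/invariant under rigid motions of the input, which the
test suite checks with randomized rotations.

## Static anatomy

* **Contacts**: heavy-atom pairs across different named segments within a
  cutoff (default 3.5 Å, sensible over 3–5 Å), excluding bonded neighbours
  (|Δres| ≤ 1 within a chain). Verified against an O(n²) exhaustive scan.
* **Hydrogen bonds**: heavy-atom donor–acceptor pairs at 2.2–3.5 Å, typed
  by a residue dictionary (backbone N except proline and side-chain N/O
  donors; backbone O/OXT and side-chain O/N acceptors). No angular
  criterion is applied because the intended inputs are crystal structures
  without hydrogens; distances are what such structures support. One
  consequence worth knowing: idealized synthetic helices also produce
  backbone pairs inside the window, so analyses assert specific planted
  bonds rather than totals.
* **Salt bridges**: minimal carboxylate-O (Asp/Glu) to amine/guanidinium/
  imidazolium-N (Lys/Arg/His) distance ≤ 4 Å per residue pair.
* **Intracellular polar network**: side-chain–side-chain polar contacts
  among a configurable member set (default 141, 145, 206, 227, 264),
  reported with its connected components; absent members warn and are
  skipped rather than aborting, since partially modelled intracellular
  regions are the norm.
* **Hydrophobic layers**: a residue (Ala/Val/Leu/Ile/Met/Phe/Trp/Pro) is
  core-facing when its side-chain center of mass is radially nearer the
  bundle axis than its Cα; core-facing residues are clustered along z by
  single linkage with a 3 Å gap and numbered from the extracellular side.
  All modelled residues participate, not only helix residues — the
  outermost layer genuinely includes loop residues. The classification rule
  is a documented convention; absolute layer-membership counts depend on it
  and should be read accordingly.
* **Span and kinks**: the span is z(Cα E123) − z(Cα V274) along the
  membrane normal. Kink angles compare the principal axes of the Cα sets
  on either side of a pivot (≥ 4 residues per arm); each arm is first
  averaged over a four-residue window (one helical turn) so the spiral of
  short arms does not bias the axis. Straight traces are unaffected.

## Surface areas

SASA is Shrake–Rupley with a golden-section-spiral point set, so results
are bit-stable across runs for a fixed point count (default 960; probe
1.4 Å). Radii are per element: C 1.70, N 1.55, O 1.52, S/P 1.80, Se 1.90,
H 1.20 Å. Published implementations differ by a few percent through their
radius tables alone, so buried-area comparisons across programs warrant a
~10% tolerance. Buried area of an atom set is SASA of the set extracted
alone minus SASA of the same atoms inside the full context, computed with
identical parameters; a side-chain-only mode restricts the selection to
non-backbone atoms. Default sampling agrees with a 20,000-point reference
within 2% per atom on a realistically spaced pentapeptide, and with an
independent SASA implementation within the radius-table margin.

## Aromatic ring geometry

Ring planes are least-squares fits: all nine indole ring atoms for
tryptophan, the six ring carbons for phenylalanine/tyrosine, five for
histidine. The reported angle is the interplanar angle folded into
[0°, 90°] — chosen over normal-to-centroid-vector variants as the single
documented convention; at the ~5° level the choice is immaterial for an
edge-to-face pair — plus the centroid–centroid distance.

## Trajectory analysis

Tilt series come either from multi-model structures (each frame's TM
backbone superposed on the reference before measuring, so global drift
never masquerades as domain motion) or from plain `time_ns`/`value` tables,
and both routes are checked to agree. Deviation is θ_ref − θ(t): positive
values mean the domain leans further toward the membrane than in the
reference, so the second macrostate sits at larger deviation.

Macrostates are a Gaussian mixture on the deviation series — EM with
k-means initialisation, 50 restarts, a fixed configurable seed, states
reported by ascending mean with mixture weights as occupancies. A mixture
replaces reading peaks off a histogram with a deterministic, documented
estimator; `n_states="auto"` chooses between one and two components by
BIC. The transition time is the first time the 1-ns-smoothed series enters
within one SD of the upper state's mean and stays for ≥ 10 ns. Event
detectors (side-chain switch, salt-bridge formation) are min-distance
thresholds (3.5 Å / 4.0 Å) with a 5 ns dwell. The dwell times are package
choices, exposed in the API, to keep single-frame excursions from counting
as transitions; detectors are monotone in their cutoffs. Smoothing is a
centered mean over ± window/2 with truncated edge windows.

## HDX uptake

The maximum number of exchangeable backbone amides of a peptide of length
L is L − 2 − #Pro(positions 3..L): the two N-terminal residues back-
exchange too fast to retain label and prolines have no amide hydrogen.
Percent uptake is 100 · Δm / (N_ex · f_D₂O) with f_D₂O = 0.917 by default
(configurable). No back-exchange correction is applied — values are
relative uptake, the standard convention when fully deuterated controls
are not measured. Replicates are summarised as mean ± sample SD (n−1);
single-replicate cells are flagged. Differential tables join wild type and
mutant on (start, end, sequence, timepoint), so a peptide whose sequence
the mutation changed cannot join; such peptides are listed in a separate
uncomparable table, and a fully disjoint pair of peptide sets yields an
explicitly empty comparison rather than an error.

## Conservation

Absolute conservation of a reference position within a clade requires the
identical character in every clade member, with gaps counting as
mismatches ("absolutely conserved" implies a residue is present). Counting
uses MSA columns, not pairwise alignments — the simpler semantics, stated
here because both readings exist in the wild. The 1–9 profile is
identity-fraction binning, bin = ⌈9f⌉ clipped to [1, 9]: a transparent
stand-in for evolutionary-rate estimators that reproduces identity-count
statements exactly and keeps the familiar painting scale, but does not
model substitution rates or phylogeny — scores from rate-based tools will
differ in the middle of the scale. Pairwise global alignment is
Needleman–Wunsch with affine gaps (gap of length k costs
open + (k−1)·extend; BLOSUM62, open 10, extend 1) via Biopython's
PairwiseAligner, cross-checked against exhaustive enumeration on short
sequences.

## Synthetic data: what it shows and what it does not

The generators produce every input class with planted truth:

* **Toy receptor** — five ideal α-helices (1.5 Å rise, 100° twist,
  radius 2.3 Å) on a pentagonal cross-section with the default residue
  numbering, helix z-centers balanced so the bundle's principal axis stays
  near vertical while E123 and V274 sit 32 Å apart. A rigid Cα-only
  pseudo-ECD is *placed in the measured frame* so the tilt metric equals
  the requested angle exactly by construction; the loop cluster likewise
  plants a Trp/Phe ring pair at a chosen interplanar angle (default 45°),
  a tyrosine hydroxyl at 2.9/3.0 Å from a backbone carbonyl and amide, a
  Glu/Lys salt bridge at 3.0 Å, and an outermost hydrophobic layer
  {127, 179, 192, 238, 253}. Optional Gaussian coordinate jitter (0.05 Å
  in the validation runs) exercises noise robustness.
* **Two-state series** — Gaussian noise about a pre-transition mean and a
  post-transition mean on a regular grid; the defaults are deviation means
  (17°, 40°), SDs (6°, 3°), transition at 300 ns, 10,000 frames at 0.1 ns
  spacing (1 μs). Distance traces for events reuse the same process.
* **Uptake tables** — mass shifts back-computed from planted uptake
  through the inverse of the uptake formula plus per-replicate Gaussian
  noise (0.05 Da default, duplicates); constructs carry planted extra
  uptake on linker-region peptides, and mutated positions carry the
  wild-type letters their names imply so mutation-covering peptides
  genuinely drop out of differential joins.
* **Alignments** — a reference plus derived sequences mutated everywhere
  outside a planted conserved set (mutations always change the character);
  the multi-clade design plants 62/305 conserved for a 71-member clade,
  17 for a 59-member clade, and 55/7 for near/far 12+10-member clades.

Passing these suites establishes that the estimators recover known truth
under the stated noise — correct frames, metrics, counting rules and
detectors. It does not establish realism: the toy receptor has no loops
between helices, no physical side-chain rotamers and no membrane; the
time series are independent Gaussian draws with a hard transition, not
autocorrelated dynamics; uptake noise is Gaussian and timepoint-
independent; alignments have no gaps or phylogenetic structure. Numbers
measured on real structures will additionally reflect modelling quality,
radius tables and chain/segment choices.

## Problem sizes and determinism

The validation runs use 10,000-frame series (ten seeds), 350-record uptake
tables, 143-sequence alignments of width 305, and a ~500-atom toy
receptor; the whole test suite completes in well under a minute on one
CPU, and the acceptance script in seconds. Every stochastic component
(generators, jitter, mixture initialisation) takes an explicit seed, and
reports log each scalar with the parameters that produced it.

## Known limitations

* Chain identifiers are never guessed; analyses of deposited entries need
  the user to name the receptor chain.
* The hydrogen-bond model is distance-only; with hydrogens present it will
  overcount relative to angular criteria.
* Layer membership and core-facing classification are convention-bound;
  absolute counts (e.g. "n side chains in the core") carry that caveat.
* The conservation bins are identity fractions, not evolutionary rates.
* No electrostatics, no interface/epitope analysis between chains, no MD
  engine or free-energy machinery: the trajectory module analyses supplied
  frames or observable tables only.
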