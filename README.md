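# fivetm

Structural analysis toolkit for membrane receptors whose extracellular
domain (ECD) rides on a transmembrane (TM) helix bundle — the archetype
being the five-TM immune receptor CD47, whose IgV-like ECD is tethered to
the bundle by a short linker and held upright by an extracellular loop
region. The package is for structural biologists and simulation analysts
who need reproducible, scriptable versions of the measurements usually done
ad hoc across several GUIs: receptor anatomy on coordinates, tilt-state
analysis of trajectories, peptide-level hydrogen/deuterium-exchange (HDX)
uptake, and sequence-conservation mapping.

## What it computes

**Membrane frame and ECD tilt.** The TM-bundle backbone defines a frame:
origin at its center of mass, membrane normal **ẑ** along its first
principal axis (sign fixed so the extracellular boundary reference residue,
E123, sits above the intracellular one, V274). The ECD tilt is

&nbsp;&nbsp;&nbsp;&nbsp;θ = 90° − ∠(**v**, **ẑ**),&nbsp;&nbsp;
**v** = COM(Cα 32–36) − origin,

i.e. the angle between the domain-tip vector and the membrane plane z = 0.
For trajectories, each frame's TM backbone is superposed onto the
reference, and the *deviation* Δθ(t) = θ_ref − θ(t) is analysed: a
two-component Gaussian mixture (EM, k-means initialisation, 50 restarts,
fixed seed) yields the macrostate means/occupancies, and threshold+dwell
detectors time side-chain switches and salt-bridge formation.

**Anatomy.** Inter-segment contacts at a 3.5 Å heavy-atom cutoff (bonded
neighbours excluded), hydrogen bonds as heavy-atom donor–acceptor pairs in
the 2.2–3.5 Å window (no angular term: crystal structures carry no
hydrogens), salt bridges as carboxylate-O/amine-N pairs ≤ 4 Å, hydrophobic
core layers from core-facing side chains clustered along **ẑ**, helix span,
and kink angles. Solvent-accessible surface area is Shrake–Rupley on a
deterministic golden-spiral point set (960 points, 1.4 Å probe; C 1.70,
N 1.55, O 1.52, S 1.80 Å radii); buried area is SASA(atoms alone) −
SASA(same atoms in context).

**HDX.** Percent deuterium uptake per peptide:
%D = 100 · Δm / (N_ex · f_D₂O) with N_ex = L − 2 − #Pro(positions 3..L)
and f_D₂O = 0.917; replicate mean ± sample SD; mutant-vs-wild-type
differential tables joined on (start, end, sequence, timepoint) so peptides
altered by the mutation drop out explicitly rather than silently.

**Conservation.** Absolute conservation counts per clade (a reference
position counts only if every clade member matches it; gaps are
mismatches), identity-fraction profiles binned to the familiar 1–9 scale
(bin = ⌈9f⌉), global Needleman–Wunsch alignment with affine gaps
(BLOSUM62, open 10, extend 1), and painting of bins or uptake onto
structure B-factors.

**Synthetic data.** Every input class can be generated with planted ground
truth: a toy five-helix receptor with prescribed tilt, ring-pair angle,
hydrogen-bond distances, span and layer membership; two-state noisy time
series; replicate uptake tables; multi-clade alignments with planted
conserved sets. All generators are bit-reproducible under a fixed seed.

## Worked example

```python
from fivetm import anatomy, synthetic, trajectory
from fivetm.structure import default_segment_map

structure, truth = synthetic.make_toy_receptor(jitter_sd=0.05, seed=0)
model, seg = structure.first, default_segment_map()
frame = anatomy.build_frame(model, seg)
print(anatomy.ecd_tilt(model, frame), anatomy.helix_span(model, frame))

table, planted, theta_ref = synthetic.make_tilt_trajectory(seed=0)
series = trajectory.tilt_series(table, theta_ref=theta_ref)
print(trajectory.find_macrostates(series, seed=0).state_means)
```

Running `python examples/01_receptor_anatomy.py` prints:

```
extracellular domain tilt :  79.99 deg   (planted 80.0)
membrane span (E123-V274) :  32.17 A     (planted 32.0)
W118/F119 ring angle      :  46.58 deg   (planted 45.0)
Y184 hydroxyl contacts    : {(184, 242): 2.94, (244, 184): 3.06}
outermost hydrophobic layer: [127, 179, 192, 238, 253]
```

— the domain stands ~80° to the membrane, the bundle spans ~32 Å between
its boundary residues, the linker's aromatic pair sits edge-to-face at
~45°, the switch tyrosine hydrogen-bonds the loop backbone at 2.9/3.0 Å,
and the five planted side chains form the outermost core layer. And
`python examples/02_trajectory_macrostates.py` recovers the two tilt
macrostates (deviations ≈ 17° and 40°), the s2 entry at ≈ 300 ns, the
switch at ≈ 300 ns and the salt-bridge formation at ≈ 200 ns from the
generated time series.

Each example script under `examples/` covers one capability;
`examples/05_analyze_deposited_structure.py` runs the same static battery
on any locally available coordinate file (chain supplied by the user, since
deposited entries name chains differently). A thin CLI mirrors the library:
`fivetm anatomy|traj|hdx|conserve|simulate|demo`.

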