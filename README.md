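# bivalens

Valency classification of homodimeric receptor conformations by
template-based rigid docking and buried-surface-area analysis.

## The problem

Some immunoglobulin-superfamily receptors are expressed as homodimers with
two intact ligand-binding sites and yet engage their ligand only
monovalently.  The canonical example is the T-cell costimulatory receptor
CD28: although each subunit carries a functional site for the elongated
two-domain ligand CD80, the compact orientation of the subunits within the
dimer places the two binding sites so close together that two docked
ligands would collide sterically at their membrane-proximal
(carboxy-terminal) domains.  The inhibitory homologue CTLA-4 has a more
open dimer interface, the sites are farther apart, and it binds ligand
bivalently — a large avidity advantage.  Whether a given dimer *conformer*
is monovalent-only or bivalent-competent is therefore a purely geometric
question, and it can be asked frame by frame over a conformational
ensemble (e.g. an MD trajectory).

`bivalens` implements that analysis as a reusable pipeline:

1. **Template docking.**  A binding-mode template — a PDB complex of one
   receptor monomer plus one ligand, e.g. the CTLA-4:CD80 mode applied to
   CD28 — is superposed onto each subunit of a dimer frame by least-squares
   (Kabsch) fitting of a declared atom selection, and the template ligand
   is carried along by the same rigid transform.  No receptor atom moves;
   the fit RMSD is reported per dock as a quality control.
2. **Buried surface.**  The surface area buried between the two docked
   ligands (by default restricted to their carboxy-terminal domains) is

   `BSA = [SASA(A) + SASA(B) − SASA(A ∪ B)] / 2`

   with SASA computed by the Shrake–Rupley method on a deterministic
   golden-spiral point set (960 points/atom, probe 1.4 Å by default).
3. **Classification and aggregation.**  A frame is *bivalent-competent*
   iff its buried area is ≤ a small zero tolerance (1 Å² by default): zero
   buried surface means the ligands do not touch, so both sites could be
   occupied.  Per-trajectory bivalent fractions are averaged across
   trajectories with equal weight per trajectory.

The package also provides dimer-geometry tools (opening/twist angles,
binding-site separation, rigid subunit reorientation under an
interface-preservation constraint, grafting a monomer onto another dimer's
subunit arrangement) for constructing alternative starting conformations,
plus RMSD-versus-initial trajectory analysis, and a synthetic toy-system
generator that produces dimer ensembles with closed-form ground-truth
valency so every stage is testable without MD trajectories.

## Worked example

Generate a synthetic 30-frame ensemble programmed to be 40 %
bivalent-competent, then run the pipeline on the written files:

```sh
printf 'n_frames = 30\nbivalent_fraction_target = 0.4\nseed = 17\n' > spec.txt
bivalens synth --spec spec.txt --out bundle
bivalens run --ensemble bundle/ensemble.pdb --template bundle/template.pdb \
             --config bundle/config.txt --out results
```

stderr reports progress and timings:

```
INFO bivalens: wrote 30 frames (12 bivalent by construction) to bundle in 0.02 s
INFO bivalens: trajectory ensemble: 30 frames classified in 0.70 s
INFO bivalens: mean bivalent fraction 0.4000 over 1 trajectories (total 0.70 s)
```

`results/records.csv` holds one row per frame:

```
trajectory_id,frame_index,time_ns,buried_area_A2,bivalent_competent,fit_rmsd_1_A,fit_rmsd_2_A,dock_quality_ok
ensemble,0,0.000000,156.551387,False,0.092636,0.098901,True
ensemble,1,1.000000,130.889287,False,0.071601,0.076800,True
ensemble,2,2.000000,0.000000,True,0.090704,0.081913,True
```

Frames 0 and 1 are compact conformers: the docked ligands' C-terminal
domains bury 130–160 Å² against each other, so only one ligand could bind.
Frame 2 is an open conformer with exactly zero buried surface —
bivalent-competent.  The small fit RMSDs (< 0.1 Å) confirm the docking
superpositions are clean.  `results/summary.json` aggregates:

```json
{
  "mean_fraction": 0.4,
  "per_trajectory_fraction": { "ensemble": 0.4 },
  "weighted_mean_fraction": 0.4,
  "n_frames_per_trajectory": { "ensemble": 30 },
  "zero_tolerance_A2": 1.0,
  "n_dock_quality_flagged": 0,
  "config": { "...": "echo of the run parameters" }
}
```

The recovered bivalent fraction (0.4) equals the generator's programmed
ground truth exactly, because the synthetic regimes keep every frame far
from the contact boundary.  The same library API is available from Python
(`make_toy_system`, `dock_dimer`, `buried_surface`, `classify_frame`,
`analyze_ensemble`, `summarize`, `rmsd_vs_initial`, `describe_dimer`,
`reorient_dimer`, `graft_onto_dimer_template`).

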