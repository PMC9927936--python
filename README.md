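# gpcrtraj

Trajectory analysis of class-A GPCR activation observables, built around the
structural readouts used to characterise gain-of-function endothelin
receptor A (ET_A_R) mutants: generic-numbering-anchored distances, hydrogen-
bond and ionic-contact occupancies, Na⁺/water-pocket zoning with per-frame
water counting, conditional distribution analysis, and PCA of helix-segment
conformations. It is aimed at structural bioinformaticians who have an
ensemble of receptor snapshots (multi-model PDB) and want reproducible,
machine-readable versions of the standard activation-state panels.

## What it computes

**Generic numbering.** Ballesteros–Weinstein positions `h.xx` resolve to
author residue numbers through a per-receptor anchor table:
`residue(h.xx) = anchor_h + (xx − 50)`. A table for mouse ET_A_R is bundled
(2.50 → D126, 3.50 → R183, 6.36 → T307, 7.56 → V372, …).

**Activation-state distances.** The intracellular TM6–TM7 Cα gap
(`TMin`, positions 6.36–7.56) separates receptor states: crystal-structure
surveys place active structures at long (7.7–11.5 Å) and inactive ones at
short (5.5–6.7 Å) distances; values in the gap or outside are left
unclassified. Companion observables are the extracellular TM2–TM6 gap
(`TMex`, 2.65–6.58) and the Na⁺/water-pocket width (`TMpkt`, 2.57–6.48).

**Occupancy.** A hydrogen bond is geometric: donor–acceptor ≤ 3.0 Å and
D–H–A within 20° of linear (or a 3.5 Å heavy-atom cutoff when no hydrogens
are present; the mode is explicit). Occupancy is the percent of snapshots
in which *any* donor–acceptor pair between two residue groups satisfies the
criterion — e.g. the nonclassical TM6–H8 ionic lock E303(6.32)–S373/K374.

**Pocket hydration.** The interhelical space below the ligand-binding site
is split into three stacked 8 Å slabs along the membrane normal (G-protein
area / D2.50 area / Y2.53 area) bounded by a lateral cylinder, and water
oxygens are counted per frame and slab.

**Conformational PCA.** After Kabsch superposition, PCA of the flattened
Cα coordinates of the extracellular halves of TM2/6/7 places apo,
Na⁺-bound and agonist-bound ensembles into one shared component space.

Because no public trajectory accessions exist for the motivating system,
the package ships a seeded synthetic helix-bundle generator
(`gpcrtraj.synthetic`) that plants a two-state ionic-lock Markov chain,
state-coupled TMin/TMex emissions, a wide/narrow pocket state with Poisson
water counts, lock-bond geometry and Na⁺ coordination — with full
per-frame ground truth, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from gpcrtraj import *

for name in ("WT-like", "E303K-like", "Y129F-like"):
    traj, gt = simulate_runs(preset(name, seed=1), RunPlan(3, 1000.0, 1.0))
    lock = hbond_series(traj, [303], [373, 374],
                        criterion=HBCriterion(mode="heavy_only"))
    tmin = generic_ca_distance(traj, MOUSE_ETAR_BW, "6.36", "7.56")
    wc = count_waters(traj, ZonePartition(anchor_z=6.0), (0.0, 0.0))
    print(f"{name:12s} lock={occupancy_percent(lock):5.1f}%  "
          f"TMin>7A={100*np.mean(tmin.values>7):5.1f}%  "
          f"area3 waters={wc.counts[:,2].mean():5.2f}")
```

prints

```
WT-like      lock=100.0%  TMin>7A=  0.0%  area3 waters=10.05
E303K-like   lock=  0.0%  TMin>7A= 40.8%  area3 waters=10.05
Y129F-like   lock= 91.2%  TMin>7A=  9.0%  area3 waters= 7.31
```

Reading: in the wild-type-like ensemble the TM6–H8 lock is always formed
and the intracellular gap never opens past 7 Å (unimodal inactive-state
distribution); breaking the lock (E303K-like) leaves ~41% of snapshots in
the open state; the Y129F-like ensemble keeps the lock but dwells in a
narrow, water-depleted pocket (mean area-3 count drops from ~10 to ~7.3).
Each preset pools three independent 1000-snapshot runs, i.e. 3,000
snapshots per system.

## Command line

```bash
gpcrtraj simulate --preset E303K-like --seed 1 -o out/      # PDB + ground truth + BW table
gpcrtraj analyze config.yaml -o reports/                     # full TSV/JSON report bundle
gpcrtraj survey structure1.pdb structure2.pdb                # TMin state table
gpcrtraj identity receptorA.fasta receptorB.fasta            # percent identity
```

`analyze` takes one declarative YAML config naming trajectories, the BW
table, observables, H-bond group pairs, zone parameters, threshold
conditions and the PCA fit/project plan; see `tests/test_pipeline.py` for
a complete schema example.

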