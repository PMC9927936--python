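# Methods

## Scope and model

`gpcrtraj` analyses ordered coordinate ensembles ("trajectories") over a
fixed atom topology. The required interchange format is the multi-model
PDB dialect (one `MODEL`/`ENDMDL` block per snapshot); binary trajectory
formats are deliberately out of scope so that every fixture in the test
suite can be plain text. Residue numbering always follows the file
(author numbering); internal 0-based atom indices never appear in
reports. Alternate locations other than blank/"A" are dropped; insertion
codes are rejected rather than silently folded into residue ids, because
silent handling corrupts generic-numbering arithmetic.

Generic positions use the Ballesteros–Weinstein scheme: each helix h of a
class-A receptor has one maximally conserved residue labelled h.50, and
h.xx resolves to `anchor_h + (xx − 50)`. Tables are user-supplied
configuration (one anchor and one residue interval per helix), not
computed by alignment — automated generic-numbering annotation is a
separate problem with its own error modes. A resolution landing outside
the helix interval is an error, never clamped.

## Activation-state classification

The intracellular TM6–TM7 Cα distance (positions 6.36–7.56) is classified
against two closed bands: long / active 7.7–11.5 Å, short / inactive
5.5–6.7 Å. Both boundaries are inclusive (the most conservative reading
of printed closed intervals), and distances in the gap (6.7, 7.7) Å or
outside either band return `unclassified`: the published bands do not
assign them, and coercion would manufacture state labels.

## Hydrogen bonds, occupancy, and coordination

With hydrogens present, a bond requires donor–acceptor heavy-atom
distance ≤ 3.0 Å and the donor–H–acceptor angle within 20° of linear —
the convention popularised by the common MD visualisation tools. Without
hydrogens, a single heavy-atom cutoff of 3.5 Å applies. The mode is an
explicit field of `HBCriterion`; requesting the hydrogen-aware mode on a
hydrogen-free topology is an error, never a silent fallback. All cutoffs
are configuration.

Occupancy of a group pair (e.g. "cytoplasmic half of TM6 vs the TM7–H8
junction") is defined per snapshot: the frame counts if *any* enumerated
donor–acceptor pair across the groups satisfies the criterion. This OR
convention matches a per-snapshot probability ("fraction of snapshots
having the bond") rather than a per-pair sum, and the test suite verifies
the group series equals the OR-decomposition over constituent pairs.
Donor/acceptor atoms are enumerated from a bundled static table of the
twenty standard amino acids (side chains plus backbone N/O) intersected
with the atoms actually present; ligand atoms require explicit
annotation.

Cation coordination (the pocket Na⁺ against the D2.50 carboxylate and
the S7.46/T3.39 hydroxyls) counts partner oxygens within 3.0 Å per frame.
The cutoff is unsettled in the literature and therefore exposed.

## Pocket zoning and water counting

The interhelical space below the orthosteric site is partitioned into
`n_zones = 3` stacked slabs of 8 Å each along the membrane normal
(+z extracellular), ordered intracellular → extracellular: the G-protein
area, the D2.50 level (the middle slab is centred on the mean axial
coordinate of the D2.50 Cα) and the Y2.53 level. Laterally the zones are
bounded by a cylinder of default radius 8 Å around the bundle axis — a
declared approximation of the "interhelical space" that avoids a
cavity-detection dependency; radius, width, count and axis are all
configuration. Zone intervals are half-open `[lower, upper)` with
boundary points assigned upward, so no oxygen is ever double-counted;
water oxygens are identified by residue name (HOH/TIP3/SOL/WAT).

## Distributions

Histograms are probability-normalised (bin counts / n_samples).
Distances default to 0.2 Å bins aligned to multiples of the width;
integer data (water counts) use unit bins centred on the integers. Bin
widths are not prescribed by any source and distribution *shapes*, not
bar heights, are the reproducible object. A conditional overlay keeps
the unconditional binning and denominator: overlay mass per bin is
`count(in bin AND condition)/n`, so it is bin-wise comparable to (and
never exceeds) the unconditional histogram, and its total equals the
fraction of frames satisfying the condition. Frames from independent
runs of one system are concatenated before histogramming (three pooled
runs, 3,000 snapshots per system, is the canonical layout).
`histogram_modes` reports contiguous runs of bins above a small noise
floor (default 0.2% of samples) so that modality statements reflect the
bulk of the distribution rather than single stray frames.

## Superposition and PCA

Frames are rigid-body fitted (Kabsch least squares, implemented via
`scipy`'s rotation alignment) onto a reference over a fit set —
defaulting to all receptor Cα — before any conformational statistics;
the analysis selection (extracellular halves of TM2/6/7) is separate
from the fit set so that global-motion removal and the analysed subspace
do not interact. "Extracellular half" defaults to the helix-range
midpoint cut toward the extracellular terminus, with a per-helix
override; the bundled ET_A_R table pins the TM6 cut at 6.47 so the
halves are complementary to the conventional cytoplasmic segment
6.25–6.47. Covariance uses the unbiased (n−1) denominator; components
are sign-pinned (first nonzero coordinate positive) because eigenvector
sign is otherwise arbitrary and would make projections irreproducible.
Ensembles other than the fitting ensemble can be projected into the same
component space, which is how apo / Na⁺-bound / agonist-bound
comparisons are made; which ensembles to pool for fitting is left as
explicit configuration.

## Synthetic generator

The generator emulates the statistical structure of pooled microsecond
MD ensembles with a kinematic model — rigid helix-segment displacements
plus isotropic Gaussian jitter — not physics. Its purpose is analysis
validation: every emitted quantity has a planted per-frame ground truth.

* **Scaffold.** Ideal straight Cα traces (1.5 Å rise/residue) for TM1–7
  on a 12 Å ring plus a horizontal intracellular H8 stub; marker
  residues carry the side-chain pseudo-atoms the analyses need (CZ/CH2,
  lock carboxylate and donor atoms, pocket oxygens). Side-chain
  placement is schematic, positioned to realise the planted geometry
  exactly rather than to be stereochemically correct.
* **Lock chain.** A two-state (locked/unlocked) Markov chain — the
  minimal generator of the unimodal vs multimodal contrast — drives the
  TM6–TM7 gap, the coupled TM2–TM6 gap, and the lock-bond geometry
  (bond formed iff locked and the preset says the lock exists). The
  default chain has stationary locked mass 0.7 with strong persistence,
  comparable to the state dwell behaviour the analyses must cope with.
* **Exact channels.** TM7 translates along a fixed direction so the
  TM6–TM7 gap equals its per-frame draw exactly (pre-jitter); TM2 is
  modelled as three rigid segments (static base, mid segment carrying
  2.53/2.57, tip carrying 2.65) so the TM2–TM6 and pocket-width channels
  are independently controllable — a single rigid TM2 cannot realise
  both distances because their difference is bounded by fixed
  intra-helix offsets.
* **Pocket state.** An independent per-frame wide/narrow Bernoulli state
  sets the pocket width draw and the area-3 water Poisson mean (10 wide,
  5 narrow; the flanking zones use a state-independent mean of 8). The
  pocket state is independent of the lock chain because pocket narrowing
  and intracellular opening are distinct phenotypes: one preset has a
  broken lock with a normal pocket, another a held lock with a
  water-poor pocket.
* **Waters.** A fixed pool of 60 water molecules keeps the topology
  constant across frames; per frame, the drawn number are placed
  uniformly inside their zone with a 0.9 Å margin from every zone and
  cylinder boundary (so 6-sigma jitter excursions cannot cross a
  boundary and planted counts stay exact), and unused pool members are
  parked far outside the analysis cylinder.
* **Jitter.** Isotropic Gaussian noise, default sd 0.15 Å, applied to
  every atom as the last draw. Planted distances are recorded
  pre-jitter; measured distances therefore scatter around them with
  sd ≈ 0.21 Å (two jittered endpoints), and tests check stochastic
  bounds (95th percentile within 3×sd, max < 1 Å), not a hard per-frame
  cap, which Gaussian tails would violate over thousands of frames.
  Post-jitter geometric truths (lock bond, Na⁺ coordination) are
  recorded by direct distance predicates coded independently of the
  analysis modules.
* **Determinism.** One seeded generator drives every draw in a fixed
  order; identical seeds give byte-identical PDB output. Pooled-run
  simulation derives child seeds from the spec seed.

**Presets.** `WT-like`: fully locked chain, lock geometry on, locked gap
draw N(6.0, 0.2 Å) — the tighter sd (vs the generic 0.4 Å default) is
chosen analytically so that all 3,000 snapshots of the planted unimodal
state fall inside the published 5–7 Å band once jitter is added.
`E303K-like`: lock geometry off, mixed chain (stationary unlocked mass
0.43), state-coupled TM2–TM6 emissions N(23.5, 0.7)/N(21.0, 0.7) Å so
conditioning on an open intracellular gap concentrates extracellular
mass in the shifted component. `Y129F-like`: lock held (stationary
locked 0.94), pocket narrow 55% of frames with correspondingly reduced
area-3 water counts and pocket width.

What passing tests on this generator shows: the analysis pipeline
recovers planted occupancies, state masses, counts, eigenvalues and
conditional structure from data with realistic sampling noise and
autocorrelation. What it does not show: force-field realism, membrane
or solvent physics, side-chain stereochemistry, or ligand-binding
energetics — none of which the analyses depend on.

## Statistical tolerances

Occupancy and state-mass recovery is tested within 3 autocorrelation-
corrected standard errors: for a two-state chain the indicator
autocorrelation decays as ρ^k with ρ = 1 − p01 − p10, inflating the
binomial variance by (1+ρ)/(1−ρ). PCA recovery on a 3,000-frame planted
two-motion ensemble (variances 4.0 and 1.0 Ų) is tested within 5% on
eigenvalues and |cosine| > 0.99 on directions, consistent with the
sampling error of a variance estimate at that n. Exact-agreement checks
(water counts vs exhaustive enumeration, per-frame bond detection vs a
brute-force predicate, conditional overlay vs filter-then-bin) use
equality, not tolerances.

## Sequence identity

Global Needleman–Wunsch alignment (BLOSUM62, gap open 10, extend 0.5 by
default); identity = identical pairs / aligned columns with residues in
both sequences (gap columns excluded from both numerator and
denominator), optionally restricted to a residue interval of the first
sequence — the helix-domain region of a receptor model, for instance.
Published identity percentages depend on the aligner and its parameters,
so cross-tool agreement is approximate by nature; the denominator
convention is recorded with the output.

## Problem sizes

Test and acceptance runs use the canonical pooled ensemble size of
3 × 1,000 = 3,000 snapshots per system for statistical checks, and
40–200-frame ensembles for exact-agreement and geometry checks; these
sizes make every statistical tolerance meaningful while keeping the
whole suite fast to run routinely.

## Known limitations

* mmCIF, DCD/XTC, periodic-boundary unwrapping and bond perception are
  out of scope; convert upstream.
* The cylinder pocket delimitation is an approximation; cavity-volume
  methods would give different absolute water counts (the comparative
  statements between systems are the robust object).
* The generator's helices do not twist and its side chains are
  pseudo-atoms; do not use it as structural prior for anything but
  analysis validation.
* Hydrogen-aware bond detection requires hydrogens in the input; the
  heavy-atom fallback is coarser and slightly more permissive by
  construction.
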