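# Methods

`rpfold` assesses how robust a protein backbone (scaffold) is to packing
perturbations. The probe is the *random permutant* (RP): the wild-type
(WT) sequence is randomly shuffled and repacked onto the unchanged WT
backbone. Shuffling conserves amino-acid composition — and therefore the
average side-chain size and chain volume — but relocates large and small
side chains, so the set of inter-residue contacts in the folded structure
changes. Folding simulations of coarse-grained structure-based models of
the WT and several RPs then reveal whether those contact-map changes
disturb folding. A scaffold whose permutants keep the WT's folded and
unfolded basins, barrier, and folding route is called robust; one whose
permutants shift basins, change barriers, populate intermediates, or
reroute folding has regions that depend on a specific pattern of
side-chain sizes.

RPs are theoretical constructs: a randomly permuted sequence would not
fold (or likely even stay soluble) in an experiment. The models used here
encode only native interactions, so the method probes the geometry of
packing, not sequence chemistry.

## Pipeline

1. **Permute** — a uniform shuffle of the WT sequence, driven only by a
   seed. The first `n_rps` permutants from sequential seeds are used, no
   cherry-picking (default `n_rps = 5`: permutant contact patterns
   stabilize after a handful of maps, and a scaffold for redesign should
   tolerate at least the handful of sequences a design campaign will
   actually test).
2. **Repack** — side chains of the permuted sequence are rebuilt on the
   fixed backbone (below).
3. **Contacts** — residues i, j are in contact when any heavy atom of i
   is strictly within 4.5 Å of any heavy atom of j and j − i ≥ 3. One
   contact per residue pair regardless of atomic multiplicity; this
   deliberately mutes over-packing, so only the strongest packing
   perturbations survive into the model. Each contact carries the native
   Cα–Cα distance d_ij (stored in nm, the simulation length unit).
   Cutoffs of 5.5/6 Å are supported but blunt the method's sensitivity
   (more contacts, smaller relative perturbations). The min-sep rule
   "separated by at least three residues" is read as j − i ≥ 3; the
   stricter reading (j − i ≥ 4) is available as a parameter.
4. **Model** — a Cα structure-based (Gō-type) model per construct
   (below).
5. **Folding temperature** — located per construct (below); production
   sampling near T_f.
6. **Landscape** — Q histograms reweighted to T_f, free-energy profiles,
   basins/barrier/intermediates, Q-resolved average contact maps
   (routes).
7. **Verdict** — three criteria per RP (below).

## Side-chain repacking

The built-in placer grows side chains from internal-coordinate
templates (Z-matrix rooted at Cβ, heavy atoms only, standard bond
lengths/angles; rings closed to within a few hundredths of an Å). χ1 and
χ2 are sampled from {−60°, +60°, 180°}; deeper torsions are fixed
extended; proline uses a fixed ring, glycine has no side chain. Residues
are placed greedily in descending side-chain-size order; each takes the
rotamer with the fewest steric clashes (heavy-atom pairs closer than
2.5 Å, excluding intra-residue pairs and the covalent/1-3 neighborhood
across the peptide bond, including the proline ring closure onto the
preceding carbonyl), ties broken by rotamer index; `max_sweeps` (default
2) refinement passes re-optimize every residue against the full
environment. Only repulsive sterics are scored — no attractive or
electrostatic terms — so chemically incompatible neighborhoods are still
packed at full density, which is exactly what the RP construction
requires. This is a deliberately simple analogue of a steric-only
side-chain predictor; it has no backbone-dependent rotamer priors and a
coarse χ grid, a fidelity gap that matters most for fitting bulky
aromatics into tight cavities (the placer will choose an outward rotamer
over a strained inward one more often than a fine-grained predictor
would). An external SCWRL4-compatible executable can be plugged in via
`RepackSettings.external_tool`; its output is validated for backbone
preservation and sequence identity on read-back. Whether built-in vs
external repacking changes a robustness verdict is left as an empirical
question the hook exposes. The same machinery repairs incomplete input
models: `complete_missing_side_chains` rebuilds only residues with
missing heavy atoms, constrained to the structure's own sequence, and
leaves every complete residue untouched.

## The Cα structure-based model

One bead per residue at the Cα position; units: energy ε (nominally
1 kJ/mol), length nm, k_B = 1, temperature in ε/k_B.

- bonds: ½·k_b (r − r₀)², k_b = 20000 ε/nm²
- angles: ½·k_θ (θ − θ₀)², k_θ = 40 ε/rad²
- dihedrals: k_d [(1 − cos(φ − φ₀)) + ½(1 − cos 3(φ − φ₀))], k_d = 1 ε
- native contacts: ε_C [5 (d_ij/r)¹² − 6 (d_ij/r)¹⁰], minimum exactly at
  r = d_ij with depth −ε_C = −1 ε
- all other pairs: ε_nc (σ/r)¹², σ = 0.4 nm, cutoff 3.0 nm, with pairs
  within 3 bonds and all contact pairs excluded

All equilibrium values (r₀, θ₀, φ₀, d_ij) come from the native
coordinates, so the native state is a stationary point with zero bonded
energy. The force-constant ratios follow the common Cα convention
(backbone terms far stiffer than the unit contact scale); absolute
values are configurable in `SBMParameters` because only the dimensionless
landscape shape matters for the comparisons made here. Topologies
export/import as GROMACS-dialect `.top`/`.gro` text (10–12 contacts as
C10/C12 pair coefficients; 9-decimal coordinates so energies round-trip
to ~1e-6) for cross-checking against external MD engines.

## Sampling and the folding temperature

Langevin dynamics with BAOAB splitting (exact Ornstein–Uhlenbeck
velocity refresh), dt = 0.0005 ps, friction 1/ps, unit bead masses —
kinetics are never interpreted, only equilibrium populations.
Trajectories record (step, Q, E) at a fixed stride and are bit
reproducible for a given seed.

Q is the fraction of native contacts: a contact is formed in a snapshot
when its Cα distance is strictly below 1.2·d_ij. Folded/unfolded states
are assigned by a hysteresis automaton (folded at Q ≥ 0.8, unfolded at
Q ≤ 0.3, both configurable); a transition is a flip between assignments.

T_f is the temperature at which folded and unfolded ensembles are
equally populated. The search runs a coarse temperature scan to bracket
the transition, then refines: each run's (Q, E) samples are reweighted
(single-histogram) to predict the equal-population temperature, and the
process repeats until the populations balance within `balance_tol`
(natural-log units) with enough observed transitions. Production
sampling then runs near that temperature: at least two independent runs
are pooled (more until `min_transitions` transitions are banked; a run
that never visits one ensemble nudges the temperature 5% toward it and
restarts the pool). On the pooled ensemble the reported T_f is fixed in
two stages — first the temperature balancing the folded/unfolded wing
populations, then, with basins located on that profile, the temperature
at which the two basin neighborhoods carry equal reweighted mass. The
final free-energy profile −ln P(Q) (uniform bins on [0,1], minimum
shifted to zero, empty bins flagged not interpolated) is built at that
T_f.

Basins and intermediates: on the 3-bin-smoothed profile, the unfolded
basin is the lowest-Q local minimum, the folded basin the highest-Q one;
the barrier is the maximum in between, measured from each basin;
interior minima with prominence ≥ 0.5 k_BT_f count as intermediates
("a dip in the barrier"). Routes: within a Q bin (default: the WT's
barrier-top bin), C_ij is each contact's formation frequency over the
bin's snapshots; two constructs' routes are compared by Pearson
correlation over the union of their contact sets (absent contacts
contribute 0).

## Robustness criteria

Per RP, relative to the WT:

1. **Basins** — fail if either basin's Q moves by more than 0.1.
2. **Barrier/intermediates** — fail if the folding barrier differs by
   more than 2 k_BT_f, or the number of detected intermediates differs.
3. **Route** — a route correlation below 0.75 is always annotated, but
   flags non-robustness only when it co-occurs with a criterion-1 or -2
   failure (an RP may fold by a different route and still fold well).

The 2 k_BT_f barrier window is the method's empirical significance
threshold; the 0.1 basin tolerance and 0.75 route floor are this
package's numeric pinning of the qualitative "similar" — both
configurable, and test fixtures are designed to sit far from the
boundaries. The verdict is robust iff every RP passes everything.

Rescue contacts: when some RP folds with a higher barrier than the WT,
the contacts it gained (absent in the WT) that touch a sensitive region
are ranked by how many RP maps contain them. These are candidate
interactions whose addition would suppress a WT intermediate; choosing
actual mutations to realize them is left to the user.

## Synthetic study systems

The toy builder produces idealized structures from internal coordinates
(helix φ/ψ = −57°/−47°, strand −139°/+135°, standard peptide geometry,
tuned two-residue turns for hairpins) with side chains added by the
repacker. Packed assemblies place segment groups by a seeded random
search over connecting-loop torsions that maximizes the inter-group
Cα-contact window (4.2–7 Å) under a chain-collision penalty; an optional
gap keeps groups at a minimum separation so that only long side chains
can bridge.

Two 39-residue three-helix bundles are the study fixtures:

- **balanced** — leucine-rich faces everywhere (M ≈ 100 contacts);
  every interface is sustained by many interchangeable medium/large
  residues, so permutation leaves the map nearly invariant (interface
  contact counts stay within a few of the wild type's across
  permutants).
- **bulky_core** — two small-residue (Ala/Ser/Val/Thr) helices pack a
  robust subcore while the third helix docks across a 5.5 Å gap that
  only its concentrated Leu/Phe can span (M ≈ 83, docking interface
  ≈ 10 contacts). Permutation dilutes the larges over the chain: the
  docking interface loses 30-70% of its contacts while the subcore
  gains — the miniature of a natural fold whose core packs several
  large aromatics against each other.

Three-helix bundles were chosen because they are the smallest
architecture that folds two-state in a Cα model at this scale
(hairpin+helix and β-sandwich toys of ≤ 40 residues melt continuously —
their landscapes have no barrier to compare). Even the bundles' barriers
are fractions of k_BT_f, far below a real protein's, so the fixtures
exercise the classification logic and its failure modes, not the
magnitude of real folding barriers. What passing tests show is that the
pipeline detects engineered packing imbalance and leaves balanced
packing alone; they do not show that the verdicts match any
experimental folding data, and the toys lack everything real structures
have beyond ideal geometry (loops with structure, β-bulges, kinks,
cavities, variable secondary-structure content).

## Problem sizes and profiles

The "test" profile (default) uses the 39-residue toys, a 5-point
temperature scan of 8×10⁴ steps, search runs of 7×10⁵ steps, at least
two pooled production runs of ~10⁶ steps each, a 5-transition floor and
25 Q bins — sized so the full two-fixture study runs on one CPU in
minutes. The profile also moves the hysteresis window to 0.4/0.75:
in these small bundles the helices stay formed when tertiary structure
melts, so the unfolded basin sits near Q ≈ 0.5 and the default 0.3/0.8
window would almost never register state assignments. The "full" profile (2×10⁶-step scans, 2×10⁷-step runs,
15-transition floor) mirrors production conditions for real proteins.
Numerical choices worth noting: strict inequalities at the contact
cutoff and the 1.2·d_ij formation criterion (determinism at exact
boundaries); highest-occupancy-then-alphabetical altloc resolution;
sequential renumbering of author residue numbers with the original kept
as metadata; contacts attributed to a region only when both partners are
inside it, contacts straddling two named regions go to an "interface"
bucket; region gain/loss normalized by max(1, WT contacts in region) so
gains in WT-empty regions stay reportable.

## Known limitations

- The built-in repacker's coarse χ grid under-places bulky aromatics in
  tight cavities (see above); the SCWRL4 hook exists for exactly that
  reason.
- Only native interactions are modeled: non-native trapping, which can
  dominate the folding of poorly designed sequences, is invisible here.
- Toy landscapes are weakly cooperative; barrier-height comparisons on
  them operate near the detection floor, which is why the fixtures are
  engineered to fail (or pass) by large margins in basin position and
  intermediate count rather than by barrier height alone.
- Single-histogram reweighting is reliable only near the sampling
  temperature; the T_f search keeps every reweighting step inside the
  scan bracket.
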