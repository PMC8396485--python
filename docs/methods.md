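# Methods

## Scope and model

`dynopharm` turns an aligned protein–ligand complex trajectory into a
screening-ready pharmacophore model and validates it by retrieval
statistics. The pipeline assumes:

* atom ordering is identical across frames and atom identity is
  (chain, residue id, atom name); coordinates are Å;
* the ligand is a single residue selected by residue name, with bonded
  topology supplied either by an attached template molecule or inferred
  from frame-0 geometry via covalent radii (fallback only);
* protein residues use standard names and atom nomenclature; hydrogens are
  optional — when a donor hydrogen is absent, the H-bond angle criterion is
  skipped and detection is distance-only.

## Feature and interaction rules

Ligand features: aromatic rings (AR, centroid + ring normal), hydrophobic
fragments (H; connected subgraphs of ≥ 2 carbon/halogen heavy atoms none
bonded to N/O/S, one feature per fragment at its centroid), positive
ionizable (PI; N with formal charge +1, or — as a fallback for
un-protonated input — a neutral sp3 amine with ≥ 1 H and no adjacent
carbonyl), N–H/O–H donors (HBD), N/O acceptors excluding amide N and
pyrrole-type aromatic N–H (HBA), and C–Cl/Br/I halogen-bond donors (XBD; F
excluded, since fluorine is a poor σ-hole donor). Default tolerance radii:
1.5 Å for point features, 1.1 Å for AR. Protein groups are read from
residue templates: Phe/Tyr/Trp/His rings; Ser/Thr/Tyr hydroxyls as
donor+acceptor; backbone C=O acceptors and N–H donors; Lys/Arg positive and
Asp/Glu negative groups; apolar side-chain carbons as hydrophobic contact
atoms (ring-substituted carbons bonded to the hydroxyl are excluded for
Tyr).

Interaction thresholds (`GeometricRules`) default to standard
interaction-geometry survey values: H-bond donor–acceptor ≤ 3.5 Å with
D–H···A ≥ 130° when the hydrogen is present; hydrophobic feature centroid
to protein apolar atom ≤ 4.5 Å; ring-centroid distance ≤ 5.5 Å with
interplanar angle ≤ 30° (parallel/parallel-displaced) or ≥ 60° (T-shaped);
cation-π ≤ 6.0 Å; halogen X···A ≤ 3.8 Å with C–X···A ≥ 140°; ionic ≤ 5.5 Å.
Cation-π and ionic contacts are reported under the PI class, matching the
occurrence-table conventions of commercial perception tools. All values are
configurable; the 5.5 Å stacking bound comfortably contains the ~5 Å
parallel-displaced geometry typical of pore aromatic networks.

## Occurrence statistics and model selection

The occurrence table reports, per (residue, interaction type),
`100 × (#frames in window with ≥ 1 such record) / (#frames in window)`.
The analysis window defaults to the trailing 20% of the analyzed frames
(the "last 20 ns" of a 100 ns run analyzed at 500 evenly distributed
frames); it is exposed as `window`/`window_frac` because tools differ on
whether equilibration is included. Model uniqueness is defined by the
canonical signature — the sorted set of (type, chain, resid) — not by
feature coordinates, since coordinate jitter would make every frame unique.
The k (default 4) most frequent signatures are selected with deterministic
tie-breaking (higher count, then more features, then lexicographic
signature), and each selected model's geometry is the per-feature centroid
over its supporting frames.

## Merging, alignment, flags, exclusion volumes

Merging interpolates overlapping same-type features by single-linkage
clustering of centers at tolerance 1.5 Å (the default feature radius; no
canonical value exists, so it is configuration): each cluster becomes one
feature at the centroid with radius `max(member radii, spread)`, so every
member center stays inside the merged sphere. Cross-ligand alignment seeds
on type-compatible feature triplets (required to include the PI feature
when both models have one — the cationic center is the anchor of this
ligand class), superposes by a Kabsch fit, greedily extends with
mutually-nearest same-type pairs within tolerance, and accepts when
≥ `min_pairs` (default 3) pairs align with RMSD ≤ 1.5 Å. Alignment failure
is an explicit result carrying the pair count and RMSD; the final-model
builder excludes such models and reports them, making the exclusion
criterion reproducible rather than a matter of inspection.

Flags default to: PI essential; the hydrophobic feature nearest the PI
essential; the next two hydrophobic features an either/or pair (exactly one
must match — covering ligands that do or do not reach a hydrophobic side
pocket); everything else optional. The either/or semantics at match time
are: the chosen member must match and the unchosen member is withheld from
optional matching, so exactly one member of the pair appears in the matched
set. Exclusion volumes are spheres (default radius 1.2 Å) on every protein
heavy atom whose window-mean position lies within 8 Å of the ligand's mean
position, skipping atoms within 2 Å of a model feature center.

## Screening and retrieval metrics

A conformer matches when a rigid placement puts a same-type conformer
feature inside every essential model feature's sphere (zero omitted
features), with no conformer heavy atom inside an exclusion sphere. The
search enumerates seed triplets of required features (padded with optional
features, with a degenerate 1–2-point fit as a fallback for conformers
lacking optional feature types), prunes by pairwise-distance compatibility,
fits by Kabsch, assigns required features optimally per type (Hungarian
algorithm), and extends greedily with optional pairs. The pharmacophore-fit
score is `S = 10·M − 3·RMSD_feat`; no published formula exists for the
commercial score, so only the relative ranking is the validated contract.
Unmatched molecules rank after matched ones in stable input order, giving a
full ROC curve under retrieved/not-retrieved semantics. The AUC is
accumulated along the ranked list (equal to the normalized Mann–Whitney
U statistic for tie-free scores, which the tests verify), and
`EF_f = (a_f/n_f)/(A/N)` with `n_f = max(1, floor(f·N))` — the bin
convention under which a 463-compound library with 15 actives and 2 actives
in the top 4 yields the printed 15.4.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *statistical structure* of a pore-blocker MD
analysis, not its physics. The pocket is a C4-symmetric arrangement of
serine (hydroxyl), tyrosine (ring), alanine (CB) and phenylalanine (ring)
sites; the ligand is five feature-bearing fragments (trans-amide donor,
quaternary ammonium, benzene, ethyl, chloromethyl). Per frame, each
scheduled interaction is an independent Bernoulli draw; the corresponding
fragment is placed in an "on" pose satisfying exactly that interaction
under the geometric rules (H-bond at 3.0 Å/180°, stacking at 5.0 Å/0°,
hydrophobic at 3.5 Å, cation-π at 4.5 Å, halogen bond at 3.2 Å/180°) or
parked ~17 Å outside every cutoff. Isotropic Gaussian jitter (default
σ = 0.15 Å) is added to all atoms; a frame whose jitter flips any
interaction — judged by the generator's internal geometric check, written
independently of the detector module — is resampled (up to 100 times), and
schedule feasibility is proven up front by checking all 2^k on/off
combinations in the jitter-free geometry. Default occupancies (0.95 H-bond,
0.90 hydrophobic, 0.50 cation-π, 0.25 aromatic, 0.15 halogen over 500
frames) mirror the occurrence-table shape of a persistent pore blocker.

Deliberate idealizations: the ligand fragments are topologically
disconnected so interactions toggle independently (a rigid connected
ligand could not realize all 2^k states); the protein is static apart from
jitter; there is no solvent, no correlated motion, no force field.
Consequently, passing tests demonstrate the correctness of the
*measurement and model-building machinery* — detection, counting, merging,
alignment, matching, ranking — not the realism of any MD ensemble.
Generated library conformers are likewise geometric scaffolds (fragments
placed at feature centers, joined by ether-oxygen linkers with idealized
local geometry), not energy-minimized structures.

Decoys keep the parent active's formal charge and ring count exactly and
its heavy-atom/HBD/HBA counts within ±2/±1/±1, but every carbon outside the
charged core is bonded to an oxygen or sulfur, so no conformer of a decoy
carries a hydrophobic feature and any model with an essential hydrophobic
feature can never retrieve it; the bond graph therefore always differs from
the parent's (the property-matched/dissimilar-topology contract). Sulfur
thioethers pad heavy-atom counts without altering the counted 1D properties.
This construction requires an essential hydrophobic feature and ring-free
active parents — both true under the default flag spec; models violating it
raise `decoy-generation-failed` rather than emit weakly broken decoys.
"Bulky" feature-matching decoys (retrieved only without exclusion volumes)
are built by placing an extra linker-borne carbon where every
essential-exact placement maps it into an exclusion sphere; with only two
essential features that point must lie on the essential axis, and when that
axis misses all spheres (as in the default pocket) the generator warns and
skips them.

## Numerical choices and degenerate inputs

* Kabsch superposition rejects < 3 or collinear points
  (`degenerate-fit`) except where a degenerate fit is explicitly wanted
  (feature-triplet seeding, 1–2-point fallbacks); rotations are proper
  (det = +1).
* Single-linkage clustering inputs are sorted by rounded coordinates, and
  alignment/matching enumerations are ordered, so merging, alignment and
  screening are deterministic and input-order invariant.
* Pairwise ligand RMSD uses the Gram-matrix identity in the common
  frame-0-aligned coordinates with no per-pair re-superposition, so the
  matrix is a true (scaled Euclidean) metric and preserves binding-mode
  drift; RMSF is computed on Cα atoms only, with residues lacking a Cα
  omitted and warned.
* Downsampling keeps indices `floor(i·(F−1)/(n−1))`, always retaining the
  first and last frame.
* Empty frame windows, missing ligands, inconsistent multi-model PDB atom
  ordering, schema-violating model files and degenerate screening labels
  raise typed errors with stable codes (`empty-window`, `ligand-not-found`,
  `frame-mismatch`, `bad-model-file`, `degenerate-labels`).
* Problem sizes used by the test suite: 500-frame trajectories for
  exactness and occupancy statistics (100 seeded replicates for the
  recovery study), 120–150-frame trajectories for the five per-ligand
  model builds, 5000 frames for the RMSF calibration check, libraries of
  up to 15 actives × 50 decoys.

## Known limitations

* Feature perception is a fixed open rule set; proprietary perception
  engines differ in detail (e.g. charged-group and tautomer handling), so
  absolute occurrence values are comparable only under identical rules.
* The H-bond acceptor check against protein donors is distance-only when
  donor hydrogens are absent from the structure.
* Matching enumerates feature correspondences; it is exact for the model
  sizes produced here (≤ ~20 features) but not engineered for models an
  order of magnitude larger.
* The occupancy-recovery study inherits the generator's Bernoulli sampling
  noise: a 3σ band around the planted probability covers a 500-frame
  replicate with probability ≈ 99.77%, so a small number of replicates per
  hundred can fall outside the band even though the detector reproduces
  the planted per-frame sets exactly.
* Water-mediated interactions, protein flexibility beyond positional
  jitter, and conformer generation (embedding) are out of scope; libraries
  must arrive with 3D conformers.
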