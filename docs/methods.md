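# Methods

This note documents the models, rules and numerical choices behind
`protacsar`, and what the synthetic-data experiments do and do not
demonstrate.

## Scope and data model

The package analyses degradation tables: one row per degrader with its
SMILES, the recruited E3-ligase class (VHL or CRBN) and percent target
degradation at 0.1 µM and 1 µM. Degradation percentages outside [0, 100]
are rejected rather than clipped; SMILES must parse to a single connected
molecule. Activity is binarized at a cutoff of 75% (inclusive for active) —
a pragmatic early-discovery convention, configurable everywhere it is used.
Train/test splits are plain uniform draws without stratification; the
training size is n·ratio rounded half-up, which reproduces the familiar
74/18, 42/11 and 31/8 partitions of 92-, 53- and 39-compound sets at 80:20.

## Frameworks and the sphere fingerprint

Murcko scaffolds (ring systems plus inter-ring connections, labels and
stereo kept) and skeletons (labels and bond orders erased) are delegated to
RDKit's scaffold machinery; the common convention that an exocyclic
double-bonded atom is kept only when its anchor atom is retained applies.

Similarity uses a hashed sphere-count fingerprint defined in this package
because the skeleton-sphere descriptors of interactive desktop tools are
proprietary and unpublished. For each atom, a Morgan-style iteration builds
a canonical invariant of its r-sphere for r = 0..5; at every (atom, radius)
the invariant is hashed (stable 64-bit blake2b) into a 1024-bin count
vector twice — once from full atom/bond labels (element, degree, charge,
aromaticity, H count; bond type) and once skeleton-abstracted (degree only,
all bonds single-equivalent). The total count is exactly
2·A·(radius+1) for A heavy atoms, and the vector is byte-identical across
runs and platforms. Similarity is the count (min/max) Tanimoto. This is an
approximation with the same *shape* as the descriptor it stands in for, not
a bit-exact reproduction; every similarity threshold in this package (the
0.9 cliff threshold in particular) is defined against this fingerprint.

## Matched molecular pairs and clustering

Two molecules are an MMP when single cuts of one acyclic single bond in
each expose an identical canonical core (attachment point labeled) with two
different substituents. Only single cuts are considered; the substituent is
capped at 8 heavy atoms — on 700–1200 Da degraders this keeps the exchanged
fragment a genuinely localized change — and the core must be at least as
large as the substituent. Clusters are connected components over the union
of scaffold-identity edges and MMP edges; a flag restricts merging to
ring-bearing substituent swaps for the strictest "ring-system substitution"
reading (off by default, since chain swaps are equally localized).

## Degradation cliffs

A cliff candidate is an unordered pair at Tanimoto ≥ 0.9. It passes when
its absolute degradation difference reaches the delta cutoff at both
concentrations; requiring consistency across the two doses filters
single-point assay artefacts. The delta cutoff defaults to 40 percentage
points — a value chosen here as "clearly beyond replicate noise on a 0–100
scale" and reported in every output header, since no canonical value
exists. All candidates are also emitted unfiltered, and curated pairs below
the similarity threshold can be appended with a `manual` provenance tag
(ring-size analogs, for example, fall below 0.9 on this fingerprint even
when chemists would call them near-duplicates).

## Tripartite decomposition and LDR

Anchor SMARTS patterns identify the warhead and E3-ligand blocks; the best
disjoint pair of matches (largest match, then lowest canonical atom rank)
is selected, the linker is the complement, and exactly two attachment bonds
must remain. A junction carbonyl/amide therefore belongs to the linker
exactly when it lies between the two anchors. Linker metrics: n_carbon
counts all linker carbons including ring carbons (so rigid series sit on
the same axis as flexible ones), and the class is alkyl (acyclic C only),
ether (acyclic C/O), rigid (any ring atom) or mixed.

Matched series group records that share warhead fragment, E3 fragment,
attachment points and linker class, differing only in linker length. Series
need at least 4 members and 4 distinct lengths before a quadratic is fitted
(3 points fit any parabola exactly). The fit is ordinary least squares;
vertex = −b/2a estimates the optimal carbon count; fits with a ≥ 0 or
|a| < 10⁻⁶ are flagged degenerate rather than reported as optima. Clipped
observations (0% or 100%) are not special-cased; heavily clipped series
show up as degenerate or low-r² fits, which the reports expose.

## Descriptors

Seven 2D permeability-related descriptors: MW, carbon count, aromatic ring
count, nHAcc, nHDon, TPSA and PHI. TPSA is Ertl's fragment-additive N/O
variant (RDKit implementation). The H-bond counting rules are frozen here
because commercial descriptor suites do not publish theirs: donors are N/O
atoms bearing ≥ 1 H; acceptors are N/O atoms minus pyrrole-type aromatic
nitrogens (lone pair in the ring) and amide/imide nitrogens; fluorine and
sulfur never count. PHI is computed from Kier's alpha-modified kappa shape
indices, κ1α·κ2α/A, with the alpha table built from Kier's covalent-radius
ratios (sp³ carbon reference; aromatic atoms treated as sp²). For an
unbranched alkane of A atoms PHI is exactly A−1, which the tests pin for
A = 3..20. log P is deliberately excluded: no available calculator is
trustworthy for beyond-rule-of-five molecules of this size. 3D/conformer
descriptors are out of scope for the same reason.

## Classification harness

Estimator internals are delegated to scikit-learn (RF with 100 trees, a
single random-split tree, Gaussian NB, 5-NN, linear-kernel SVM with C = 1);
everything the validation semantics depend on is implemented natively so
it is seeded and bit-reproducible: unstratified folds whose sizes differ by
at most one, pooled out-of-fold confusion counts, TPR/TNR/MCC (MCC defined
as 0 on an empty marginal), the rank-based ROC area with half-credit ties,
Y-randomization (label permutations preserving class counts, full CV per
permutation) and the attribute evaluators. Continuous attributes are
discretized for InfoGain and OneR with the single binary cut maximizing the
criterion — simpler than MDL multi-way discretization and sufficient to
rank a planted signal; CFS uses the standard merit
k·r̄_cf / √(k + k(k−1)·r̄_ff) with absolute Pearson correlations and greedy
forward search. MCC > 0.4 marks a robust model in the reports.

## Synthetic generator

The generator defines the study conditions the recovery experiments run
under. Compounds are assembled from attachment-labeled blocks: an
aryl-nitrile/cyclohexyl-amine warhead family (with two dead analogs: a
cyano→ethynyl single-atom edit and a ring-size edit), an unrelated
benzoxazole warhead, hydroxyproline-amide VHL-like and
glutarimide/phthalimide CRBN-like E3 ligands in four decoration variants,
and alkyl (4–14 C), PEG-ether (4–6 C) and rigid (piperidine–arylene)
linkers. Degradation follows an additive model with clipping:

    deg_low  = clip(Dmax − a(L − L*)² − p_w − γ·max(0, TPSA − τ) + ε, 0, 100)
    deg_high = clip(deg_low + δ(100 − deg_low)/100 + ε′, 0, 100)

Defaults: n = 200 compounds at the 53:39 VHL:CRBN balance of curated AR
degrader sets; L* = 10 C (VHL) and 6 C (CRBN), encoding the qualitative
field observation that cereblon degraders optimize at shorter linkers;
curvature a = 2%/C² (0.1 for rigid linkers, which degrade well almost
independently of length); Dmax = 95%; dead-warhead penalty 90 points;
cliff_fraction 0.15; polarity rule τ = 135 Å², γ = 2.5%/Å²; noise sd 3%;
concentration gain δ = 20. Linker lengths are drawn within ±4 C of each
class's optimum, as a linker-optimization campaign would explore. The
polarity decorations are acceptor-rich (methoxy, nitrile, nitro; the top
variant carries one primary amide so donors also track polarity), which
makes TPSA and nHAcc the planted activity determinants. τ and γ were fixed
once against the shipped block library so that undecorated and
singly-decorated compounds stay below the penalty threshold and the planted
dead-analog pairs separate by ≥ 70 points at both concentrations.

Planted cliff pairs use the single-atom (cyano→ethynyl) dead analog, whose
fingerprint similarity to its parent is 0.93 (VHL) / 0.92 (CRBN) — above
the 0.9 threshold; the ring-size analog lands near 0.80 and models the kind
of pair a similarity search misses and a chemist flags manually. A
signal-free configuration (all structural effects off, readouts drawn wide
around the cutoff) provides the null for chance-level checks.

What the generator does *not* emulate: real AR pharmacophores,
synthesizability, dose–response (Hill) behaviour, assay batch effects, or
correlated measurement error between the two concentrations. Passing
recovery tests therefore shows the pipeline's statistical machinery is
correct and well-calibrated under its stated assumptions — not that real
degradation data satisfies those assumptions.

## Problem sizes and determinism

The validation suite uses: 50 replicates (×2 classes) for linker-vertex
recovery on matched series of 27 points (9 lengths × 3); 20 replicates of
200 compounds for cliff sensitivity; 5 seeds for classifier robustness and
attribute ranking (the InfoGain check ranks mean scores over the seeds);
20 permutations for Y-randomization; 20 seeds for the signal-free null; one
timed 200-compound end-to-end run. All randomness flows through explicit
integer seeds: one stream per generated dataset, per split and per CV run,
so every reported number is exactly reproducible.

## Known limitations

* The sphere fingerprint is a declared stand-in; absolute similarity values
  are not comparable with other fingerprints, only the relative structure
  (thresholds were chosen against this one).
* Double-cut MMPs (linker replacements) are not enumerated; a linker swap
  appears as two single-cut relations only when one side is small enough.
* The cliff delta cutoff and the 75% activity cutoff are conventions, not
  fitted quantities; both are configurable and logged.
* With n ≈ 50–100 per class, external-test metrics have wide sampling
  variance; the reports carry the exact split and seed so those error bars
  can be probed by rerunning under other seeds.
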