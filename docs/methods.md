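# Methods

## Contact network

A chain is treated as a self-contained system; inter-chain contacts are
never considered. Two residues are connected iff the distance between
any pair of their atoms is *strictly* smaller than the sum of the atoms'
van der Waals radii plus an extra threshold (default 2.0 Å). The radii
are Bondi values pinned in `catres.config` (C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80, H 1.20 Å; unknown elements fall back to 1.70 with a
warning) and are configurable. All parsed atoms enter the distance test;
X-ray structures rarely contain hydrogens, so in practice this is a
heavy-atom rule. Sequence-adjacent residues receive no automatic edge —
they pass or fail the same geometric test. Edges are unweighted and all
distances downstream are hop counts.

PDB input keeps ATOM records of the first model only; HETATM records
(ligands, waters) are excluded, except selenomethionine (MSE), which is
mapped to MET. For alternate locations the highest-occupancy atom wins,
with ties keeping the first record seen. Author residue numbering and
insertion codes are preserved verbatim so annotated residues stay
addressable. Other nonstandard residues are parsed but flagged, and the
encoder skips them with a warning.

## Network parameters

Eight per-residue measures are computed on the contact network. The
conventions below are pinned because keyAA selection and the feature
encoding depend on them:

* **closeness** = (r − 1) / Σ d over reachable vertices only, with r the
  size of the residue's reachable component (including itself); isolated
  vertices score 0. Bounded in [0, 1].
* **betweenness**: raw Brandes pair counts (unordered pairs once),
  unnormalized — any constant factor would be absorbed by feature
  scaling.
* **hub score**: on an undirected graph HITS hub and authority vectors
  coincide with the Perron eigenvector of the adjacency matrix. Computed
  by power iteration on A + I (tolerance 1e−10, ≤1000 iterations) — the
  shift preserves eigenvectors but makes the Perron root strictly
  dominant, so the iteration also converges on bipartite graphs, where
  iterating A² collapses to the uniform vector. Scores are rescaled so
  the per-chain maximum is 1, for cross-protein comparability.
* **cocitation** is a matrix quantity (shared-neighbor counts per vertex
  pair); it is scalarized as the row sum over all other vertices.
* **clustering coefficient** is defined as 0 for degree < 2 so feature
  vectors stay numeric; **coreness** is the largest k with the vertex in
  the k-core; **constraint** is Burt's measure with transition weights
  1/degree, 0 for isolated vertices.

## DNSC

Residues are ranked by closeness, descending, with ties broken by
sequence position (ascending) for reproducibility; the top k = 5 are the
keyAAs. When a chain has fewer residues than k, all are used and the
remaining descriptor slots read 0. Signal intensity from a keyAA at hop
distance d is g_s·d^(−a) for 1 ≤ d ≤ cutoff, 0 beyond the cutoff or when
unreachable, and g_s when d = 0 — the power law is undefined at 0, and a
residue that *is* a keyAA is treated like a direct contact. Defaults
a = 1, g_s = 1, cutoff = 5 hops; all three are configurable.

## Layered environment

Layer m (m = 1, 2, 3) is the set of residues at hop distance exactly m
from the target. Each layer is summarized by the arithmetic mean of 14
per-residue features: conservation, polarity, hydrophobicity, volume,
ASA, rASA and the eight network parameters. Identity and
secondary-structure one-hots are excluded from averaging (a mean of
one-hots is not a code of the same kind, and the layer vector is
specified as 14-dimensional). An empty layer contributes 14 zeros and an
empty flag rather than missing values.

## Sequence features

Conservation is the Shannon entropy −Σ p ln p (nats) of the weighted
observed frequencies at a position, so lower values mean stronger
conservation; the log base is configurable in principle but nats are
used throughout. All-zero frequency rows (PSI-BLAST emits these for
gappy columns) score 0 and are flagged rather than imputed. Profiles are
matched to chain residues by position order; a length mismatch drops the
profile with a warning, and missing profiles zero-fill the
conservation/PSSM/frequency blocks.

The three physicochemical scales are pinned (Grantham polarity,
Kyte–Doolittle hydropathy, Zamyatnin volumes) and replaceable. The
2-bit class code follows charged (DEKHR) → (0,0), polar (CNQSTY) →
(0,1), hydrophobic (AFGILMPVW) → (1,0).

Accessible surface area comes from either a DSSP file (format-faithful
to the classic tool output) or the internal Shrake–Rupley implementation
(probe 1.4 Å, 960 golden-spiral sphere points per atom, same radii table
as the contact rule, chain computed in isolation). Relative ASA divides
by theoretical Gly-X-Gly maxima; values above 1 (possible for exposed
termini, and common on toy structures) are reported as-is with a
warning. Without DSSP the secondary structure defaults to coil, which is
encoded as all-zeros in the 7-dim one-hot over H, G, I, E, B, T, S.

## Encoding and model

The 130 components concatenate in fixed block order: conservation (1),
identity (20), class code (2), physicochemical (3), ASA+rASA (2),
secondary structure (7), PSSM (20), frequencies (20), network (8), DNSC
(5), layered environment (42). The layered block therefore starts at
column 89 (1-indexed).

Training scales features to [−1, 1] with min/max fit on the training
data only (stored with the model) and fits an SVM with RBF kernel,
C = 8, gamma = 'scale' by default; `tune=True` replaces the fixed pair
with a 3-fold grid search over a coarse C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}
grid. Cross-validation splits proteins, not residues, into k = 10 folds;
each training fold is re-balanced to 1:1 by drawing negatives without
replacement per protein with a per-fold seeded generator, while test
folds keep their natural skew so precision and recall-at-precision are
meaningful. Sensitivity, specificity, accuracy and precision are
reported in percent at decision threshold 0; AUC is the rank-statistic
ROC area. Feature ranking fits a linear-kernel SVM on balanced, scaled
data and orders features by weight², ties broken by feature index.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
protein physics. Each protein is an idealized α-helix CA trace (rise
1.5 Å, radius 2.3 Å, 100°/residue — consecutive CA ≈ 3.8 Å apart) with
one jittered pseudo side-chain atom per residue; this guarantees a
connected contact network with sequence-local contacts, so keyAAs and
layers are well defined. Per protein, 2–4 catalytic residues are drawn;
with probability `enrichment` each is placed within one hop of a
top-5-closeness residue, otherwise uniformly. Profile rows mix a delta
at the position's own amino acid with a noisy Dirichlet background,
with mixture weight `enrichment · exp(−d/1.5)` where d is the hop
distance to the nearest catalytic residue — catalytic positions are
strongly conserved, their spatial neighborhood more weakly so, matching
the observation that conservation falls off with distance from active
sites. At `enrichment = 0` both signals vanish and the dataset is an
exact null. Everything is deterministic given the seed, and datasets can
be written through the real PDB/TSV/PSSM readers.

What passing tests on these fixtures shows: the pipeline recovers
planted keyAA-proximity and conservation signals, keeps protein-level
folds leak-free, and orders layer informativeness inner > outer. What it
does not show: performance on real enzymes, where conservation comes
from actual alignments, contact networks are irregular, and the
catalytic signal is far weaker than a near-delta profile column.

## Problem sizes and determinism

The shipped verification runs use 200 proteins × 60 residues (12,000
residues, ~600 catalytic) for the cross-validation properties, 50-graph
oracle sweeps at n ≤ 10 for the centrality checks, and 960-point spheres
for ASA; these sizes give stable statistics while keeping a full run in
the minutes range on one CPU. All stochastic steps (placement, profiles,
fold shuffling, negative sampling) flow from explicit seeds; repeated
runs with the same seed are identical.

## Known limitations

* One chain at a time; inter-chain contacts and biological assemblies
  are out of scope, as are mmCIF input and NMR multi-model handling.
* Shortest paths are unweighted and unique-length only; when several
  shortest paths connect two residues the signal model still counts a
  single geodesic distance.
* PSI-BLAST and DSSP are parsed, never executed; without their files the
  profile blocks are zero-filled and secondary structure is coil.
* The cocitation scalarization (row sum) and the closeness
  normalization are pinned conventions; other choices exist and would
  change keyAA selection.
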