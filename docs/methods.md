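# Methods

This note documents the models, conventions and numerical choices
behind `omegafeat`, the defaults that matter, and what the synthetic
fixtures do and do not exercise.

## Data model and I/O

Sequences are validated against canonical alphabets (20 amino acids,
ACGT, ACGU).  By default ambiguity codes (X/B/Z/U/J/O for protein, N
and IUPAC degenerates for nucleic acids) are rejected with the
offending position, because every composition formula here is defined
over the canonical alphabet; a permissive flag instead drops those
characters so composition denominators count canonical residues only.
FASTA headers use the `id|label` dialect: the token up to the first
whitespace is the id, an optional pipe-separated suffix is a class
label.  RNA input containing T (and DNA containing U) is
transliterated on read.

Feature matrices export to CSV/TSV (header row, first column sample
id, label column when present), SVM-light (`label index:value`,
1-based indices, zeros omitted) and ARFF (numeric attribute per
feature, nominal class attribute last, only when labels exist;
relation name = output file stem).

## The descriptor manifest

The registry pins 189 descriptor sets: 71 protein, 49 DNA, 37 RNA, 14
structure, 18 ligand.  Within the protein roster, the 16 PseKRAAC
reduction families expand to 19 registry entries (families 3 and 6
carry lettered sub-variants).  The RNA roster is the DNA roster minus
twelve DNA-only sets: everything built on the trinucleotide property
panel (TAC/TCC/TACC, TPCP type 1/2, PC-PseTNC, SC-PseTNC), the
double-strand propensity PSTNPds, the EIIP pair, and the two Z-curve
variants conditioned on dinucleotide prefixes (48/144-bit), which are
tied to the DNA property set here.  The protein nearest-neighbour
(KNN) descriptor is provided as an operation but is not a registry
entry; the DNA/RNA KNN is registered.

"Type 1" composition variants are frequencies (each normalization
block sums to 1); "type 2" variants are their raw-count companions
(for DPCP/TPCP, the standardized-property companions).  Sum-to-1
invariants therefore apply to type-1/frequency sets.

## Bundled tables

All numeric tables live in `tables.py` with provenance in the module
docstring: classic per-residue scales (Kyte–Doolittle, Hopp–Woods,
Grantham polarity/volume/composition, isoelectric point, residue mass,
polarizability, accessible surface), the PseAAC property triple,
Sandberg Z-scales, the seven 3-group CTD attribute partitions, Taylor
overlapping-property classes, conjoint-triad classes, Dayhoff exchange
groups and the standard genetic-code codon counts (for DDE).

Three tables are constructed rather than transcribed, since their
original numeric files are not reproducible from first principles:

- **Grantham distances** are computed from Grantham's published
  formula and c/p/v tables, rescaled to mean off-diagonal distance
  100.
- **The Schneider–Wrede-form matrix** is the Euclidean distance over
  the standardized hydrophobicity/hydrophilicity/side-chain-mass
  triple, scaled to maximum 1 — the functional form of that distance,
  with side-chain mass standing in for side-chain volume.
- **AESNN3** is a 3-D residue embedding taken as the first three
  principal components of the standardized bundled property panel
  (signs fixed on alanine), replacing the original learned embedding.

Nucleotide property panels are the unified nearest-neighbour
thermodynamics (enthalpy, entropy, free energy) for DNA and the
Watson–Crick nearest-neighbour parameters for RNA; trinucleotide
values follow by nearest-neighbour additivity.  Panels are
standardized (mean 0, population sd 1 over the 4^k k-mers) before any
correlation use.  EIIP constants: A 0.1260, C 0.1340, G 0.0806, T/U
0.1335.

PseKRAAC reductions are version-controlled data computed at import:
each scheme family ranks the 20 residues along a fixed linear
combination of the standardized property panel and splits the ordering
into contiguous near-equal groups; `cluster_count = 20` is the
identity.  Valid cluster counts are {2, 3, 4, 5, 8, 10, 15, 20}.

## Sequence-descriptor conventions

- **Autocorrelation** (Moran, Geary, Moreau–Broto; protein and
  di-/tri-nucleotide versions) follows the formulas quoted in the
  README.  A property that is constant on the given sequence would
  make Moran/Geary denominators 0; the descriptor value is then
  defined as 0 (constant signal carries no autocorrelation), keeping
  matrices dense.  The constant-signal test uses a small absolute
  tolerance (1e-10 on the deviation sum of squares) so that rounding
  in the mean of identical floats cannot leak spurious values.
- **Pseudo compositions**: PAAC/APAAC use λ default `min(30, L−1)` and
  w = 0.05; the correlation function is the mean squared difference of
  the three standardized PAAC properties (APAAC keeps per-property
  products).  The six pseudo k-nucleotide compositions default to
  λ = 2, w = 0.1, k = 3; "parallel" variants average property
  differences and sum to 1, "series" variants keep per-property
  product terms.
- **Quasi-sequence-order** reports both bundled distance matrices side
  by side; each matrix block of QSOrder sums to 1.
- **MMI** uses single-term entropies `H(·) = −p log p` of unordered
  adjacent pair/triple frequencies, with the fixed ordering of the 10
  pairs then 20 triples.
- **KNN** ranks training sequences by normalized global alignment
  score, `2·S(a,b)/(S(a,a)+S(b,b))`, with BLOSUM62 and gap open/extend
  −10/−1 for protein, +2/−1 match/mismatch with −5/−1 gaps for
  nucleic acids; ties break by training-set order; k-fractions default
  to 1%..30% rounded up to ≥1.
- **PSTNP** computes positional trinucleotide propensities from the
  two label classes of the input set itself; double-strand mode merges
  each trinucleotide with its reverse complement.
- Default lags: nlag = 5 (protein), 3 (nucleic); gaps: CKSAAP/CKSNAP 3,
  KSCTriad 2; sliding window 5.  These are compact defaults chosen for
  well-conditioned output on short sequences and are freely
  configurable.

## Structure layer

Parsing (gemmi) keeps the first model, resolves alternate locations to
the highest occupancy (ties prefer altloc A), excludes waters and
hetero groups from the residue list while retaining their atoms for
site centering, and synthesizes an ideal tetrahedral Cβ for glycine
(flagged per residue).

Shells are half-open, `[r₀+(s−1)Δ, r₀+sΔ)`, default r₀ = 0, Δ = 2 Å,
n = 15 (covering 0–30 Å).  The target residue is excluded from its own
shells; empty shells produce zero blocks.  Cumulative ("type 2")
compositions are computed from cumulated counts, which are monotone by
construction.

Secondary structure is assigned internally (no external binary): amide
H positions are rebuilt from the preceding carbonyl, hydrogen bonds
follow the electrostatic model with the −0.5 kcal/mol threshold,
n-turn patterns give H/G/I (4-turn priority first), bridge patterns
give B and ladders E, turns T, bends S (Cα virtual angle > 70°), and
everything else "−".  Residues with missing backbone atoms are
labelled "−".  The 3-state collapse is H,G,I→helix, E,B→strand,
rest→coil.  This is a deliberately self-contained assignment: it
reproduces ideal helices and strands exactly and agrees with the usual
pattern rules on well-formed backbones, but it is not a byte-for-byte
re-implementation of any external tool; a pre-computed assignment can
be substituted by calling `ss_shell_composition` with labels of your
own.

Half-sphere exposure counts Cα neighbours within 13 Å, split by the
sign of the dot product against the side-chain direction — observed
(or synthesized) Cβ in variant 1, an ideal backbone-derived pseudo-Cβ
for every residue in variant 2.  up + down equals the plain neighbour
count by construction.

Residue depth approximates the solvent-accessible surface by
Fibonacci-lattice points on each heavy atom's van-der-Waals sphere
expanded by the probe radius (default 1.4 Å, 960 points/atom), with
points buried inside any other expanded sphere removed.  An atom's
depth is the distance to the nearest accessible point minus its own
expanded radius, clamped at 0 (so an isolated atom has depth exactly
0), and residue depth averages over the residue's atoms.  Because the
sphere lattice has a fixed global orientation, depth is
rotation-equivariant only up to the sampling resolution: at the
default density, rigid motions move depths by well under 0.1 Å on the
bundled fixture, and halving the density changes them by < 0.2 Å.
All other structure descriptors are exactly invariant under rigid
motion (asserted at 1e-9).

The contact network joins residues whose Cα atoms lie within 8 Å
(configurable).  Degree centrality is degree/(n−1); betweenness is
normalized by (n−1)(n−2)/2; closeness uses per-component
Wasserman–Faust scaling; the sixth metric ("centrality") is
interpreted as eigenvector centrality of the adjacency matrix
(unit-norm principal eigenvector, absolute values).  Metric
computation delegates to networkx; tests verify it against an
independent BFS/path-counting oracle.

## Ligand layer

Molecule perception (aromaticity, rings, Gasteiger charges, distance
matrices) and the standard index implementations delegate to RDKit;
unparseable entries are reported by input index and skipped.  Blocks
authored in-repo on top of atomic tables: the topological
autocorrelations (ordered-pair convention — (i,j) and (j,i) both
counted — lags 1..8 over mass, electronegativity, vdW volume and
polarizability), Burden-matrix eigenvalues (properties on the
diagonal, bond-order-scaled 0.1·order couplings, 0.001 elsewhere,
+0.01 for terminal bonds), Basak information content (Shannon entropy
of neighbourhood equivalence classes at radii 0–2, with SIC/CIC at
radius 1), and pharmacophore counts from bundled SMARTS definitions.
Indices that degenerate on single-atom molecules are defined as 0.
Fingerprints: MACCS 166 keys, Morgan radius 2 / 2048 bits, E-state
79 atom-type counts, topological (path-hashed) 2048 bits.

## Analysis and plots

z-score normalization uses the population standard deviation so that
applying it twice is exactly idempotent; min–max maps columns onto
[0, 1]; constant columns map to zeros under both (no division by
zero).  The ten clustering algorithms and three reductions run behind
one seeded interface; Markov clustering is implemented in-repo
(column-normalize → expand (power 2) → inflate (power 2.0,
renormalize) → prune 1e-5 until convergence; attractor rows define
clusters), since it is absent from the installed libraries.  Spectral
and Markov clustering build an RBF affinity with γ = 1/#features by
default.  t-SNE clamps perplexity to (n−1)/3 for small sample sets.
LDA requires labels and at most classes−1 components.

Plots: Freedman–Diaconis histogram bins with a floor of 10; Gaussian
KDE with Scott's rule; histogram/KDE overlay by label when labels
exist; the circular plot links samples whose Pearson correlation (or
cosine / 1/(1+d) Euclidean similarity) reaches the threshold (default
0.75); `structure3d` is a static backbone-trace projection and
`ligand2d` a static 2-D depiction, so all nine plot kinds exist in the
standalone artifact.  Rendering never mutates its input.

## Synthetic fixtures and their limits

`generate_fixtures(seed)` produces uniform random sequences (default
six 50-mers per kind, labels alternating 1/0), a 16-residue ideal
α-helix with varied residue types (including CYS/HIS/ASP/GLU) and full
backbone + Cβ, and a small SMILES list (methane, benzene, pyridine and
a few small organics).  All randomness flows through one seeded
generator; identical seeds give byte-identical files.  These fixtures
exercise every code path and every registered descriptor, but they are
not realistic data: uniform sequences carry no compositional bias or
motif structure, the helix has no packing environment or side chains
beyond Cβ, and the ligand list spans only small rigid molecules.
Passing tests therefore demonstrate formula correctness, invariants
and end-to-end plumbing — not biological discrimination power.

The test suite and the acceptance script use deliberately small
problem sizes (50 sequences for oracle sweeps, 6–16 samples for
matrices, ≤ 12-atom molecules), chosen so the whole verification run
completes in seconds while still covering ≥ 50 seeded inputs per
oracle comparison.

## Known limitations

- The secondary-structure assignment and the sampled-surface depth are
  self-contained approximations (see above), not drop-in replacements
  for external assignment/surface tools.
- PseKRAAC group tables and the three constructed residue tables are
  the package's own documented choices; descriptor *values* for those
  sets are reproducible but not numerically interchangeable with other
  software.
- PSSM/evolutionary-profile descriptors are out of scope (they require
  external sequence searches), as are 3-D ligand conformers, web/GUI
  interactivity and network fetching of structures.
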