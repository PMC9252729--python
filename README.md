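# omegafeat

Feature engineering, analysis and visualization for biological and
chemical molecules.  `omegafeat` turns protein, DNA and RNA sequences
(FASTA), protein structures (PDB/mmCIF) and small-molecule ligands
(SMILES/SDF) into numeric descriptor matrices suitable for machine
learning, then clusters, reduces, normalizes and plots them — all from
one library and one JSON-driven command line.

It is aimed at bioinformaticians and cheminformaticians who need a
single, reproducible path from raw molecules to a samples × features
table: 189 descriptor sets in total (71 protein, 49 DNA, 37 RNA, 14
structure, 18 ligand), 15 analysis algorithms (10 clustering, 3
dimensionality reduction, 2 normalization), 9 plot kinds and 4 export
formats (CSV, TSV, SVM-light, ARFF).

## The descriptors in brief

**Sequences.** Compositions count residues, k-mers and gapped pairs:
the amino-acid composition is `f(a) = n_a / N`, the k-spaced pair
composition counts pairs `(s_i, s_{i+g+1})` per gap block.
Autocorrelations trace a physicochemical property `P` along the chain,
e.g. Moran's index at lag *d*:

    I(d) = [ Σ_{i≤N−d} (P_i − P̄)(P_{i+d} − P̄) / (N−d) ] / [ Σ_i (P_i − P̄)² / N ]

with Geary's *c*, Moreau–Broto sums and auto-/cross-covariances as
companions.  Pseudo compositions (PseAAC, APAAC, the six pseudo
k-nucleotide compositions) append λ sequence-order correlation factors
to the composition block and renormalize by `Σf + w·Σθ`.
Quasi-sequence-order couples residues through squared physicochemical
distances `τ_d = Σ d(R_i, R_{i+d})²`.  Per-residue encodings (one-hot,
Z-scales, BLOSUM62 rows, AAindex panels), reduced-alphabet k-tuple
compositions (PseKRAAC, 16 scheme families), Z-curve transforms,
electron–ion pseudopotentials, multivariate mutual information over
base pairs/triples, and nearest-neighbour similarity profiles complete
the sequence layer.

**Structures.** Around every target site, concentric shells
`[r₀+(s−1)Δ, r₀+sΔ)` collect residue, residue-group, secondary-structure
and atom-type compositions, per shell ("type 1") or cumulatively
("type 2").  Secondary structure is assigned internally from the
classic hydrogen-bond electrostatic energy
`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` (bond if
E < −0.5 kcal/mol).  Half-sphere exposure splits the Cα neighbours
within 13 Å by the side-chain direction; residue depth measures the
mean atom distance to a sampled solvent-accessible surface; and a Cα
contact network (8 Å cutoff) yields degree, centralities, clustering
and closeness per residue.

**Ligands.** Fourteen descriptor blocks (constitution, topological
indices such as the Wiener index `W = Σ_{i<j} d_topo(i,j)`,
connectivity χ, kappa shape, E-state, Basak information content,
Burden eigenvalues, pharmacophore counts, Moran/Geary/Moreau–Broto
autocorrelations over atomic properties, charge, bulk properties and
MOE-type surface bins) plus MACCS, Morgan, E-state and topological
fingerprints.

## Worked example

```python
from omegafeat import read_fasta
from omegafeat import nucleic, analysis
from omegafeat.fixtures import write_fixtures

paths = write_fixtures("demo", seed=1)          # seeded synthetic inputs
seqs = read_fasta(paths["dna"], "dna")          # 6 labelled 50-mers
fm = nucleic.compute(seqs, "PseDNC", lam=2, w=0.1)
print(fm.shape)                                  # (6, 18)
print(fm.df.iloc[0].head(4).round(4).to_dict())
# {'PseDNC.AA': 0.0301, 'PseDNC.AC': 0.0151,
#  'PseDNC.AG': 0.0151, 'PseDNC.AT': 0.0753}

res = analysis.cluster(analysis.normalize(fm, "zscore"),
                       "kmeans", {"n_clusters": 2}, seed=1)
print(list(res.cluster_ids))                     # [0, 0, 0, 0, 1, 1]

red = analysis.reduce(fm, "pca", 2, seed=1)
print(red.params["explained_variance_ratio"])    # [0.442, 0.270]
```

The 18 PseDNC features are the 16 dinucleotide frequencies plus two
sequence-order correlation factors (λ = 2), jointly normalized so the
vector sums to 1; k-means then partitions the six samples and PCA's
first two components carry 71% of the variance.

The same run from the shell:

```bash
omegafeat fixtures --seed 1 --out demo
cat > config.json <<'JSON'
{"scheme": "iDNA", "input": "demo/dna.fasta",
 "descriptors": ["PseDNC"], "parameters": {"PseDNC": {"lam": 2, "w": 0.1}},
 "output": "features.csv", "format": "csv", "seed": 1}
JSON
omegafeat run -c config.json
omegafeat list --kind dna        # the 49 DNA descriptor sets
```

## Layout

- `src/omegafeat/records.py` — sequence and feature-matrix containers
- `src/omegafeat/tables.py`, `reduced.py` — bundled property tables and
  reduced alphabets (provenance in the module docstrings)
- `src/omegafeat/protein.py`, `nucleic.py`, `structure.py`, `ligand.py`
  — the descriptor layers
- `src/omegafeat/analysis.py`, `plots.py` — feature analysis and plotting
- `src/omegafeat/registry.py` — the descriptor manifest
- `src/omegafeat/io.py`, `cli.py`, `fixtures.py` — I/O, command line,
  seeded synthetic inputs
- `docs/methods.md` — models, conventions and numerical choices
- `examples/` — case-study-style workflows on the bundled fixtures
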