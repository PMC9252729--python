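"""Three case-study-style workflows on the bundled synthetic fixtures.

Each mirrors a typical application of the toolkit: (1) structural
microenvironments around candidate functional-site residues, (2)
separating two classes of nucleotide sequences from composition
features, and (3) profiling a small ligand set and visualizing its
similarity structure.  Run from the repository root:

    python examples/case_studies.py --seed 1 --out scratch/examples
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np


def structural_microenvironments(out: Path, seed: int) -> None:
    """Shell compositions + exposure around CYS/HIS/ASP/GLU residues,
    the residue types that typically coordinate metal sites."""
    from omegafeat import hstack, structure, write_feature_matrix
    from omegafeat.fixtures import toy_structure_pdb

    model = structure.parse_structure(toy_structure_pdb())
    targets = [
        r.key for r in model.residues
        if r.name in ("CYS", "HIS", "ASP", "GLU")
    ]
    scheme = structure.ShellScheme(r0=0.0, delta=2.0, n=8)
    fm = hstack([
        structure.shell_residue_composition(model, targets, scheme, "type2"),
        structure.ss_shell_composition(model, targets, scheme, states=3),
    ])
    hse = structure.half_sphere_exposure(model)
    write_feature_matrix(fm, str(out / "site_microenvironments.csv"))
    print(f"[1] {len(targets)} candidate sites x {fm.shape[1]} shell features")
    up, down = hse.values.sum(axis=0)
    print(f"    total HSE neighbours: up={up:.0f} down={down:.0f}")


def sequence_class_separation(out: Path, seed: int) -> None:
    """k-mer + pseudo compositions for two labelled sequence classes,
    z-scored, clustered and embedded."""
    from omegafeat import analysis, hstack, nucleic, write_feature_matrix
    from omegafeat.fixtures import generate_fixtures
    from omegafeat.plots import render

    seqs = generate_fixtures(seed, n_seq=10, seq_len=60)["dna"]
    fm = hstack([
        nucleic.compute(seqs, "Kmer", k=3),
        nucleic.compute(seqs, "PseDNC", lam=3, w=0.1),
        nucleic.compute(seqs, "Z_curve_9bit"),
    ])
    z = analysis.normalize(fm, "zscore")
    ids = analysis.cluster(z, "kmeans", {"n_clusters": 2}, seed=seed).cluster_ids
    emb = analysis.reduce(z, "pca", 2, seed=seed).embedding
    write_feature_matrix(z, str(out / "dna_features.csv"))
    render(emb, "scatter", str(out / "dna_pca.png"),
           {"cluster_ids": ids.tolist()})
    print(f"[2] {fm.shape[0]} sequences x {fm.shape[1]} features; "
          f"clusters: {ids.tolist()}")


def ligand_profiling(out: Path, seed: int) -> None:
    """Constitution + Geary autocorrelation blocks for the SMILES set,
    with a circular similarity plot."""
    from omegafeat import analysis, hstack, ligand, write_feature_matrix
    from omegafeat.fixtures import TOY_SMILES
    from omegafeat.plots import correlation_edges, render

    parsed = ligand.parse_molecules(TOY_SMILES)
    fm = hstack([
        ligand.compute(parsed, "constitution"),
        ligand.compute(parsed, "geary"),
    ])
    z = analysis.normalize(fm, "minmax")
    edges = correlation_edges(z, "pearson", 0.75)
    render(z, "circular", str(out / "ligand_similarity.png"),
           {"threshold": 0.75})
    render(z, "heatmap", str(out / "ligand_heatmap.png"))
    write_feature_matrix(fm, str(out / "ligand_features.csv"))
    print(f"[3] {fm.shape[0]} molecules x {fm.shape[1]} features; "
          f"{len(edges)} similarity edges at r >= 0.75")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("scratch/examples"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    structural_microenvironments(args.out, args.seed)
    sequence_class_separation(args.out, args.seed)
    ligand_profiling(args.out, args.seed)


if __name__ == "__main__":
    main()
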