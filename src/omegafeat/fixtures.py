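"""Seeded synthetic inputs: sequence sets, a toy structure, SMILES.

Everything a run needs can be generated here: labelled random
protein/DNA/RNA sequence sets, a small single-chain peptide structure
built from ideal backbone geometry at chosen phi/psi angles, and a
short SMILES list.  All randomness flows through one seeded generator;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .records import DNA_ALPHABET, PROTEIN_ALPHABET, RNA_ALPHABET, SequenceRecord, SequenceSet

# --------------------------------------------------------------------------
# ideal-geometry peptide builder
# --------------------------------------------------------------------------

_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom d with given internal coordinates w.r.t. a-b-c."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + np.column_stack([bc, m, n]) @ d2


def _cb_from_backbone(n, ca, c) -> np.ndarray:
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return ca - 0.58273431 * a + 0.56802827 * b - 0.54067466 * cc


def build_peptide(
    sequence: str,
    phi: float = -57.0,
    psi: float = -47.0,
) -> list[dict]:
    """Backbone (+Cbeta, +O) coordinates for a chain at fixed phi/psi.

    Defaults build an ideal alpha-helix; phi=-139, psi=135 gives an
    extended (beta) strand.  Returns one dict per residue with keys
    ``name`` (one-letter) and ``atoms`` (atom name -> xyz).
    """
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    t = math.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([math.cos(t), math.sin(t), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, len(sequence)):
        prev = coords[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca = _place(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, 180.0)
        c = _place(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        coords.append({"N": n, "CA": ca, "C": c})
    residues = []
    for i, (aa, at) in enumerate(zip(sequence, coords)):
        at["O"] = _place(at["N"], at["CA"], at["C"], _B_C_O, _A_CA_C_O,
                         psi + 180.0)
        if aa != "G":
            at["CB"] = _cb_from_backbone(at["N"], at["CA"], at["C"])
        residues.append({"name": aa, "atoms": at})
    return residues


def peptide_to_pdb(residues: list[dict], chain: str = "A") -> str:
    """Serialize builder output as minimal PDB text."""
    from .tables import AA1TO3

    lines = []
    serial = 1
    for i, res in enumerate(residues, start=1):
        res3 = AA1TO3[res["name"]]
        for atom in ("N", "CA", "C", "O", "CB"):
            if atom not in res["atoms"]:
                continue
            x, y, z = res["atoms"][atom]
            el = atom[0]
            lines.append(
                f"ATOM  {serial:5d}  {atom:<3s}{res3:>4s} {chain}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


#: toy structure sequence: varied types incl. CYS/HIS/ASP/GLU
TOY_STRUCTURE_SEQUENCE = "ACDEFGHIKLMNPQRS"

#: default SMILES fixture: methane, benzene, a heteroaromatic ring, and
#: a few small organics
TOY_SMILES = [
    "C",
    "c1ccccc1",
    "c1ccncc1",
    "CCO",
    "CC(=O)O",
    "C1CCCCC1",
    "CC(N)C(=O)O",
    "c1ccc2ccccc2c1",
]


def toy_structure_pdb() -> str:
    """A 16-residue ideal alpha-helix with full backbone and Cbeta."""
    return peptide_to_pdb(build_peptide(TOY_STRUCTURE_SEQUENCE))


def _random_set(
    rng: np.random.Generator, kind: str, alphabet: str, n_seq: int, seq_len: int
) -> SequenceSet:
    records = []
    for i in range(n_seq):
        seq = "".join(rng.choice(list(alphabet), size=seq_len))
        label = "1" if i % 2 == 0 else "0"
        records.append(SequenceRecord(f"{kind[0]}{i + 1}", kind, seq, label))
    return SequenceSet(records, kind)


def generate_fixtures(seed: int, n_seq: int = 6, seq_len: int = 50) -> dict:
    """Reproducible fixture bundle for every molecule kind.

    Returns labelled protein/dna/rna sequence sets, the toy structure
    as PDB text, and the SMILES list.  Labels alternate "1"/"0" so
    label-dependent descriptors (KNN, PSTNP, LDA) can run.
    """
    if n_seq < 1:
        raise ValueError("n_seq must be >= 1")
    if seq_len < 3:
        raise ValueError("seq_len must be >= 3")
    rng = np.random.default_rng(seed)
    return {
        "protein": _random_set(rng, "protein", PROTEIN_ALPHABET, n_seq, seq_len),
        "dna": _random_set(rng, "dna", DNA_ALPHABET, n_seq, seq_len),
        "rna": _random_set(rng, "rna", RNA_ALPHABET, n_seq, seq_len),
        "structure_pdb": toy_structure_pdb(),
        "smiles": list(TOY_SMILES),
    }


def write_fixtures(out_dir: str, seed: int, n_seq: int = 6, seq_len: int = 50) -> dict:
    """Write the fixture bundle to ``out_dir``; returns the file paths."""
    from .io import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = generate_fixtures(seed, n_seq, seq_len)
    paths = {}
    for kind in ("protein", "dna", "rna"):
        p = out / f"{kind}.fasta"
        write_fasta(fx[kind], str(p))
        paths[kind] = str(p)
    p = out / "toy.pdb"
    p.write_text(fx["structure_pdb"])
    paths["structure"] = str(p)
    p = out / "ligands.smi"
    p.write_text("\n".join(fx["smiles"]) + "\n")
    paths["ligand"] = str(p)
    return paths
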