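"""Ligand descriptor sets.

Fourteen named descriptor blocks (constitution, topology, connectivity,
kappa shape, E-state, Basak information indices, Burden eigenvalues,
pharmacophore counts, Moran/Geary/Moreau-Broto autocorrelations, charge,
bulk molecular properties, MOE-type surface bins) plus four fingerprint
families (MACCS, Morgan, E-state, topological).  Ring/aromaticity
perception, atomic property tables and the individual index
implementations delegate to RDKit; the block -> index roster is pinned
here so output dimensions stay stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from rdkit import Chem, RDLogger
from rdkit.Chem import (
    AllChem,
    Crippen,
    Descriptors,
    GraphDescriptors,
    Lipinski,
    MACCSkeys,
    rdMolDescriptors,
)
from rdkit.Chem.EState import EState, Fingerprinter as EStateFingerprinter

from .records import FeatureMatrix

RDLogger.DisableLog("rdApp.*")

Vector = tuple[list[str], np.ndarray]


@dataclass
class ParsedMolecules:
    mols: list[Chem.Mol]
    ids: list[str]
    labels: list[str] | None
    invalid: list[tuple[int, str]]  # (input index, raw entry)


def parse_molecules(source, fmt: str = "smiles") -> ParsedMolecules:
    """Parse SMILES (path, text, or list of strings) or an SDF path.

    Unparseable entries are recorded by input index and skipped; if
    every entry fails, an error is raised.  SMILES lines may carry an
    optional whitespace-separated id.
    """
    mols: list[Chem.Mol] = []
    ids: list[str] = []
    labels: list[str] | None = None
    invalid: list[tuple[int, str]] = []
    if fmt == "smiles":
        if isinstance(source, str):
            try:
                with open(source) as fh:
                    lines = fh.read().splitlines()
            except OSError:
                lines = source.splitlines()
        else:
            lines = list(source)
        entries = [l.strip() for l in lines if l.strip()]
        for i, entry in enumerate(entries):
            parts = entry.split()
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                invalid.append((i, entry))
                continue
            mols.append(mol)
            ids.append(parts[1] if len(parts) > 1 else f"mol{i + 1}")
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(source, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                invalid.append((i, f"sdf entry {i}"))
                continue
            mols.append(mol)
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            ids.append(name or f"mol{i + 1}")
    else:
        raise ValueError(f"unknown molecule format {fmt!r}")
    if not mols:
        raise ValueError("no parseable molecules in input")
    # de-duplicate ids deterministically
    seen: dict[str, int] = {}
    for j, name in enumerate(ids):
        if name in seen:
            seen[name] += 1
            ids[j] = f"{name}_{seen[name]}"
        else:
            seen[name] = 0
    return ParsedMolecules(mols, ids, labels, invalid)


# --------------------------------------------------------------------------
# atomic property tables for the autocorrelation blocks
# --------------------------------------------------------------------------

#: Pauling electronegativity, Bondi vdW radius (A) and atomic
#: polarizability (A^3) for common organic elements
_ELEMENT_PROPS: dict[str, tuple[float, float, float]] = {
    "H": (2.20, 1.20, 0.667), "B": (2.04, 1.92, 3.03),
    "C": (2.55, 1.70, 1.76), "N": (3.04, 1.55, 1.10),
    "O": (3.44, 1.52, 0.802), "F": (3.98, 1.47, 0.557),
    "P": (2.19, 1.80, 3.63), "S": (2.58, 1.80, 2.90),
    "Cl": (3.16, 1.75, 2.18), "Br": (2.96, 1.85, 3.05),
    "I": (2.66, 1.98, 5.35),
}


def _atomic_property(atom: Chem.Atom, prop: str) -> float:
    sym = atom.GetSymbol()
    en, rv, pol = _ELEMENT_PROPS.get(sym, (2.50, 1.70, 1.76))
    if prop == "mass":
        return atom.GetMass()
    if prop == "electronegativity":
        return en
    if prop == "vdw_volume":
        return 4.0 / 3.0 * math.pi * rv ** 3
    if prop == "polarizability":
        return pol
    raise ValueError(prop)


_AUTOCORR_PROPS = ["mass", "electronegativity", "vdw_volume", "polarizability"]
_AUTOCORR_NLAG = 8


def _topological_autocorrelation(mol: Chem.Mol, variant: str) -> Vector:
    """Moreau-Broto / Moran / Geary over topological distances 1..8.

    Pair convention: ordered pairs, i.e. (i,j) and (j,i) both counted.
    Degenerate denominators (constant property or no pairs) yield 0.
    """
    dm = Chem.GetDistanceMatrix(mol)
    n = mol.GetNumAtoms()
    names, vals = [], []
    for prop in _AUTOCORR_PROPS:
        p = np.array([_atomic_property(a, prop) for a in mol.GetAtoms()])
        pbar = p.mean()
        dev = p - pbar
        ss = float(np.dot(dev, dev))
        for d in range(1, _AUTOCORR_NLAG + 1):
            pairs = [
                (i, j) for i in range(n) for j in range(n)
                if i != j and dm[i, j] == d
            ]
            names.append(f"{variant}.{prop}.d{d}")
            if not pairs:
                vals.append(0.0)
                continue
            if variant == "moreau_broto":
                vals.append(sum(p[i] * p[j] for i, j in pairs))
            elif variant == "moran":
                if ss == 0:
                    vals.append(0.0)
                else:
                    num = sum(dev[i] * dev[j] for i, j in pairs) / len(pairs)
                    vals.append(num / (ss / n))
            else:  # geary
                if ss == 0 or n < 2:
                    vals.append(0.0)
                else:
                    num = sum((p[i] - p[j]) ** 2 for i, j in pairs) / (
                        2 * len(pairs)
                    )
                    vals.append(num / (ss / (n - 1)))
    return names, np.array(vals)


# --------------------------------------------------------------------------
# descriptor blocks
# --------------------------------------------------------------------------

def _constitution(mol: Chem.Mol) -> Vector:
    counts = {el: 0 for el in ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")}
    for a in mol.GetAtoms():
        if a.GetSymbol() in counts:
            counts[a.GetSymbol()] += 1
    bonds = {"single": 0, "double": 0, "triple": 0, "aromatic": 0}
    for b in mol.GetBonds():
        if b.GetIsAromatic():
            bonds["aromatic"] += 1
        elif b.GetBondType() == Chem.BondType.SINGLE:
            bonds["single"] += 1
        elif b.GetBondType() == Chem.BondType.DOUBLE:
            bonds["double"] += 1
        elif b.GetBondType() == Chem.BondType.TRIPLE:
            bonds["triple"] += 1
    names = (
        ["heavy_atoms", "total_atoms_with_h"]
        + [f"n_{el}" for el in counts]
        + ["n_H"]
        + [f"bonds_{k}" for k in bonds]
        + ["rings", "aromatic_rings", "rotatable_bonds", "hbd", "hba",
           "path_length_2", "path_length_3"]
    )
    molh = Chem.AddHs(mol)
    n_h = sum(1 for a in molh.GetAtoms() if a.GetSymbol() == "H")
    vals = (
        [mol.GetNumHeavyAtoms(), molh.GetNumAtoms()]
        + list(counts.values())
        + [n_h]
        + list(bonds.values())
        + [
            rdMolDescriptors.CalcNumRings(mol),
            rdMolDescriptors.CalcNumAromaticRings(mol),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
            Lipinski.NumHDonors(mol),
            Lipinski.NumHAcceptors(mol),
            len(Chem.FindAllPathsOfLengthN(mol, 2, useBonds=True)),
            len(Chem.FindAllPathsOfLengthN(mol, 3, useBonds=True)),
        ]
    )
    return [f"constitution.{n}" for n in names], np.array(vals, dtype=float)


def wiener_index(mol: Chem.Mol) -> float:
    """Sum of topological distances over unordered heavy-atom pairs."""
    dm = Chem.GetDistanceMatrix(mol)
    return float(np.triu(dm, k=1).sum())


def _topology(mol: Chem.Mol) -> Vector:
    dm = Chem.GetDistanceMatrix(mol)
    n = mol.GetNumAtoms()
    ecc = dm.max(axis=1) if n > 1 else np.zeros(1)
    degs = np.array([a.GetDegree() for a in mol.GetAtoms()], dtype=float)
    names = [
        "wiener", "balaban_j", "bertz_ct", "diameter", "radius",
        "zagreb_m1", "zagreb_m2", "platt", "ipc",
    ]
    m2 = sum(
        b.GetBeginAtom().GetDegree() * b.GetEndAtom().GetDegree()
        for b in mol.GetBonds()
    )
    platt = sum(
        b.GetBeginAtom().GetDegree() + b.GetEndAtom().GetDegree() - 2
        for b in mol.GetBonds()
    )
    vals = [
        wiener_index(mol),
        GraphDescriptors.BalabanJ(mol),
        GraphDescriptors.BertzCT(mol),
        float(ecc.max()),
        float(ecc.min()),
        float((degs ** 2).sum()),
        float(m2),
        float(platt),
        GraphDescriptors.Ipc(mol, avg=True),
    ]
    return [f"topology.{n}" for n in names], np.array(vals, dtype=float)


def _connectivity(mol: Chem.Mol) -> Vector:
    fns = {
        "chi0": GraphDescriptors.Chi0,
        "chi1": GraphDescriptors.Chi1,
        "chi0n": GraphDescriptors.Chi0n,
        "chi1n": GraphDescriptors.Chi1n,
        "chi2n": GraphDescriptors.Chi2n,
        "chi3n": GraphDescriptors.Chi3n,
        "chi4n": GraphDescriptors.Chi4n,
        "chi0v": GraphDescriptors.Chi0v,
        "chi1v": GraphDescriptors.Chi1v,
        "chi2v": GraphDescriptors.Chi2v,
        "chi3v": GraphDescriptors.Chi3v,
        "chi4v": GraphDescriptors.Chi4v,
    }
    return (
        [f"connectivity.{n}" for n in fns],
        np.array([f(mol) for f in fns.values()], dtype=float),
    )


def _kappa(mol: Chem.Mol) -> Vector:
    names = ["kappa1", "kappa2", "kappa3", "hall_kier_alpha", "phi"]
    k1 = GraphDescriptors.Kappa1(mol)
    k2 = GraphDescriptors.Kappa2(mol)
    k3 = GraphDescriptors.Kappa3(mol)
    alpha = GraphDescriptors.HallKierAlpha(mol)
    n = mol.GetNumHeavyAtoms()
    phi = k1 * k2 / n if n else 0.0  # Kier molecular flexibility
    return (
        [f"kappa.{n_}" for n_ in names],
        np.array([k1, k2, k3, alpha, phi], dtype=float),
    )


def _estate(mol: Chem.Mol) -> Vector:
    es = EState.EStateIndices(mol)
    arr = np.asarray(es, dtype=float)
    names = ["sum", "max", "min", "mean", "abs_sum"]
    if arr.size == 0:
        vals = np.zeros(5)
    else:
        vals = np.array([
            arr.sum(), arr.max(), arr.min(), arr.mean(), np.abs(arr).sum()
        ])
    return [f"estate.{n}" for n in names], vals


def _shannon(counts: list[int]) -> float:
    total = sum(counts)
    if total == 0:
        return 0.0
    return -sum(
        c / total * math.log2(c / total) for c in counts if c > 0
    )


def _basak(mol: Chem.Mol) -> Vector:
    """Basak-style neighbourhood information content.

    IC_r partitions atoms (with hydrogens) into equivalence classes by
    element and by Morgan-style neighbourhood identity out to radius r;
    SIC/CIC are the size-normalized and complementary variants at r=1.
    """
    molh = Chem.AddHs(mol)
    n = molh.GetNumAtoms()
    names, vals = [], []
    classes: dict[int, tuple] = {
        a.GetIdx(): (a.GetAtomicNum(),) for a in molh.GetAtoms()
    }
    for r in range(3):
        groups: dict[tuple, int] = {}
        for key in classes.values():
            groups[key] = groups.get(key, 0) + 1
        ic = _shannon(list(groups.values()))
        names.append(f"ic{r}")
        vals.append(ic)
        if r == 1:
            maxent = math.log2(n) if n > 1 else 1.0
            names += ["sic1", "cic1"]
            vals += [ic / maxent if maxent else 0.0, maxent - ic]
        # refine classes by sorted neighbour classes
        new = {}
        for a in molh.GetAtoms():
            neigh = sorted(classes[b.GetIdx()] for b in a.GetNeighbors())
            new[a.GetIdx()] = (classes[a.GetIdx()], tuple(neigh))
        classes = new
    return [f"basak.{n_}" for n_ in names], np.array(vals, dtype=float)


def _burden(mol: Chem.Mol) -> Vector:
    """Burden-matrix eigenvalue descriptors.

    The Burden matrix has atomic properties on the diagonal and
    bond-order-scaled couplings off-diagonal; the two largest and two
    smallest eigenvalues are reported for mass- and
    electronegativity-weighted variants.
    """
    n = mol.GetNumAtoms()
    names, vals = [], []
    for prop in ("mass", "electronegativity"):
        b = np.full((n, n), 0.001)
        for i, a in enumerate(mol.GetAtoms()):
            b[i, i] = _atomic_property(a, prop)
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            order = bond.GetBondTypeAsDouble()
            v = order * 0.1
            if bond.GetBeginAtom().GetDegree() == 1 or bond.GetEndAtom().GetDegree() == 1:
                v += 0.01
            b[i, j] = b[j, i] = v
        w = np.sort(np.linalg.eigvalsh(b))
        lo = [w[0], w[1] if n > 1 else w[0]]
        hi = [w[-1], w[-2] if n > 1 else w[-1]]
        names += [f"{prop}_low1", f"{prop}_low2", f"{prop}_high1", f"{prop}_high2"]
        vals += [lo[0], lo[1], hi[0], hi[1]]
    return [f"burden.{n_}" for n_ in names], np.array(vals, dtype=float)


#: pharmacophore atom typings (SMARTS definitions, bundled as data)
_PHARMACOPHORE_SMARTS = {
    "donor": "[$([N;!H0;v3,v4&+1]),$([O,S;H1;+0]),n&H1&+0]",
    "acceptor": (
        "[$([O,S;H1;v2;!$(*-*=[O,N,P,S])]),$([O,S;H0;v2]),"
        "$([O,S;-]),$([N;v3;!$(N-*=[O,N,P,S])]),n&H0&+0]"
    ),
    "aromatic": "a",
    "hydrophobe": "[C;D3,D4;!$(C=*)]",
    "positive": "[+,$([N;H2&+0][C;!$(C=*)]),$([N;H1&+0]([C;!$(C=*)])[C;!$(C=*)])]",
    "negative": "[-,$([C,S](=[O,S,P])-[O;H1])]",
}


def _pharmacophore(mol: Chem.Mol) -> Vector:
    names, vals = [], []
    for tag, smarts in _PHARMACOPHORE_SMARTS.items():
        patt = Chem.MolFromSmarts(smarts)
        names.append(f"pharmacophore.{tag}")
        vals.append(len(mol.GetSubstructMatches(patt)))
    return names, np.array(vals, dtype=float)


def _charge(mol: Chem.Mol) -> Vector:
    m = Chem.AddHs(mol)
    AllChem.ComputeGasteigerCharges(m)
    q = np.array([
        float(a.GetProp("_GasteigerCharge")) for a in m.GetAtoms()
    ])
    q = np.nan_to_num(q)
    pos = q[q > 0]
    neg = q[q < 0]
    names = [
        "total_pos", "total_neg", "max", "min", "abs_sum", "mean_abs",
        "rel_pos", "rel_neg",
    ]
    abs_sum = float(np.abs(q).sum())
    vals = [
        float(pos.sum()), float(neg.sum()),
        float(q.max()) if q.size else 0.0,
        float(q.min()) if q.size else 0.0,
        abs_sum, abs_sum / len(q) if len(q) else 0.0,
        float(q.max()) / abs_sum if abs_sum else 0.0,
        abs(float(q.min())) / abs_sum if abs_sum else 0.0,
    ]
    return [f"charge.{n}" for n in names], np.array(vals, dtype=float)


def _property(mol: Chem.Mol) -> Vector:
    names = ["logp", "mr", "tpsa", "mw", "labute_asa", "fraction_csp3",
             "qed_like_hbd", "qed_like_hba"]
    vals = [
        Crippen.MolLogP(mol),
        Crippen.MolMR(mol),
        rdMolDescriptors.CalcTPSA(mol),
        Descriptors.MolWt(mol),
        rdMolDescriptors.CalcLabuteASA(mol),
        rdMolDescriptors.CalcFractionCSP3(mol),
        Lipinski.NumHDonors(mol),
        Lipinski.NumHAcceptors(mol),
    ]
    return [f"property.{n}" for n in names], np.array(vals, dtype=float)


def _moe(mol: Chem.Mol) -> Vector:
    """MOE-type surface bins: SlogP_VSA, SMR_VSA, PEOE_VSA and
    EState_VSA atomic-contribution partitions of the vdW surface area."""
    names, vals = [], []
    for tag, arr in (
        ("slogp_vsa", rdMolDescriptors.SlogP_VSA_(mol)),
        ("smr_vsa", rdMolDescriptors.SMR_VSA_(mol)),
        ("peoe_vsa", rdMolDescriptors.PEOE_VSA_(mol)),
    ):
        for i, v in enumerate(arr, start=1):
            names.append(f"{tag}{i}")
            vals.append(v)
    from rdkit.Chem.EState import EState_VSA

    for i, v in enumerate(EState_VSA.EState_VSA_(mol), start=1):
        names.append(f"estate_vsa{i}")
        vals.append(v)
    return [f"moe.{n}" for n in names], np.array(vals, dtype=float)


_BLOCKS = {
    "constitution": _constitution,
    "topology": _topology,
    "connectivity": _connectivity,
    "kappa": _kappa,
    "estate": _estate,
    "basak": _basak,
    "burden": _burden,
    "pharmacophore": _pharmacophore,
    "moran": lambda m: _topological_autocorrelation(m, "moran"),
    "geary": lambda m: _topological_autocorrelation(m, "geary"),
    "moreau_broto": lambda m: _topological_autocorrelation(m, "moreau_broto"),
    "charge": _charge,
    "property": _property,
    "moe": _moe,
}


def descriptor_block(mol: Chem.Mol, block: str) -> Vector:
    """Compute one named descriptor block for a molecule."""
    try:
        fn = _BLOCKS[block]
    except KeyError:
        raise ValueError(f"unknown descriptor block {block!r}") from None
    return fn(mol)


# --------------------------------------------------------------------------
# fingerprints
# --------------------------------------------------------------------------

def fingerprint(mol: Chem.Mol, family: str, **params) -> Vector:
    """Bit/count fingerprint vectors.

    maccs: 166 structural keys (key 0 of the 167-bit RDKit vector is
    unused and dropped); morgan: 2048-bit circular hashing, radius 2;
    estate_fp: 79 atom-type counts; topological_fp: 2048-bit hashed
    path fingerprint.
    """
    if family == "maccs":
        bv = MACCSkeys.GenMACCSKeys(mol)
        arr = np.array([bv.GetBit(i) for i in range(1, 167)], dtype=float)
        return [f"maccs.k{i}" for i in range(1, 167)], arr
    if family == "morgan":
        radius = int(params.get("radius", 2))
        n_bits = int(params.get("n_bits", 2048))
        gen = AllChem.GetMorganGenerator(radius=radius, fpSize=n_bits)
        bv = gen.GetFingerprint(mol)
        arr = np.zeros(n_bits)
        for i in bv.GetOnBits():
            arr[i] = 1.0
        return [f"morgan.b{i}" for i in range(n_bits)], arr
    if family == "estate_fp":
        counts, _sums = EStateFingerprinter.FingerprintMol(mol)
        arr = np.asarray(counts, dtype=float)
        return [f"estate_fp.t{i + 1}" for i in range(arr.size)], arr
    if family == "topological_fp":
        n_bits = int(params.get("n_bits", 2048))
        bv = Chem.RDKFingerprint(mol, fpSize=n_bits)
        arr = np.zeros(n_bits)
        for i in bv.GetOnBits():
            arr[i] = 1.0
        return [f"topological_fp.b{i}" for i in range(n_bits)], arr
    raise ValueError(f"unknown fingerprint family {family!r}")


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity over binarized vectors."""
    x = a > 0
    y = b > 0
    union = np.logical_or(x, y).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(x, y).sum() / union)


# --------------------------------------------------------------------------
# dispatcher
# --------------------------------------------------------------------------

FINGERPRINT_FAMILIES = ["maccs", "morgan", "estate_fp", "topological_fp"]
LIGAND_DESCRIPTORS = list(_BLOCKS) + FINGERPRINT_FAMILIES


def compute(parsed: ParsedMolecules, descriptor: str, **params) -> FeatureMatrix:
    """Compute a descriptor block or fingerprint family for a molecule set."""
    rows = []
    names: list[str] | None = None
    for mol in parsed.mols:
        if descriptor in _BLOCKS:
            n, v = descriptor_block(mol, descriptor)
        elif descriptor in FINGERPRINT_FAMILIES:
            n, v = fingerprint(mol, descriptor, **params)
        else:
            raise ValueError(f"unknown ligand descriptor {descriptor!r}")
        if names is None:
            names = n
        rows.append(v)
    assert names is not None
    return FeatureMatrix(np.array(rows), parsed.ids, names, parsed.labels)
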