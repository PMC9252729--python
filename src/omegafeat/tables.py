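"""Bundled amino-acid and nucleotide property tables.

Every numeric table used by the sequence descriptors lives here so that
descriptor values are reproducible across library versions.  Provenance:

* Kyte-Doolittle hydropathy, Hopp-Woods hydrophilicity, Grantham polarity
  and volume, isoelectric points, residue molecular weights,
  polarizability and accessible surface area are the classic published
  per-residue scales.
* The PAAC property triple (hydrophobicity, hydrophilicity, side-chain
  mass) is the standard pseudo-amino-acid-composition panel.
* Z-scales are the five Sandberg descriptor variables.
* The composition/transition/distribution (CTD) attribute groups are the
  classic seven three-group physicochemical partitions.
* DNA dinucleotide thermodynamics are the unified nearest-neighbour
  enthalpy/entropy/free-energy parameters (SantaLucia); RNA dinucleotide
  parameters are the Watson-Crick nearest-neighbour values (Xia et al.).
  Trinucleotide properties are derived from dinucleotides by
  nearest-neighbour additivity.
* EIIP constants are the electron-ion interaction pseudopotentials of
  the four nucleobases.
"""

from __future__ import annotations

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1TO3 = {v: k for k, v in AA3TO1.items()}


def _scale(d: dict[str, float]) -> dict[str, float]:
    assert sorted(d) == sorted(AA)
    return d


# --------------------------------------------------------------------------
# per-residue scales (AAindex-style panel)
# --------------------------------------------------------------------------

HYDROPATHY_KD = _scale({  # Kyte-Doolittle
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
})

HYDROPHILICITY_HW = _scale({  # Hopp-Woods
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2,
    "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0,
    "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4,
    "Y": -2.3, "V": -1.5,
})

# standard PAAC hydrophobicity panel
HYDROPHOBICITY_PAAC = _scale({
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
})

SIDE_CHAIN_MASS = _scale({
    "A": 15.0, "R": 101.0, "N": 58.0, "D": 59.0, "C": 47.0, "Q": 72.0,
    "E": 73.0, "G": 1.0, "H": 82.0, "I": 57.0, "L": 57.0, "K": 73.0,
    "M": 75.0, "F": 91.0, "P": 42.0, "S": 31.0, "T": 45.0, "W": 130.0,
    "Y": 107.0, "V": 43.0,
})

GRANTHAM_POLARITY = _scale({
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
})

GRANTHAM_VOLUME = _scale({
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0, "Q": 85.0,
    "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0, "L": 111.0, "K": 119.0,
    "M": 105.0, "F": 132.0, "P": 32.5, "S": 32.0, "T": 61.0, "W": 170.0,
    "Y": 136.0, "V": 84.0,
})

GRANTHAM_COMPOSITION = _scale({
    "A": 0.0, "R": 0.65, "N": 1.33, "D": 1.38, "C": 2.75, "Q": 0.89,
    "E": 0.92, "G": 0.74, "H": 0.58, "I": 0.0, "L": 0.0, "K": 0.33,
    "M": 0.0, "F": 0.0, "P": 0.39, "S": 1.42, "T": 0.71, "W": 0.13,
    "Y": 0.20, "V": 0.0,
})

ISOELECTRIC_POINT = _scale({
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.05, "Q": 5.65,
    "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
    "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.66, "W": 5.89,
    "Y": 5.66, "V": 5.96,
})

RESIDUE_MW = _scale({
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.15,
    "Q": 146.15, "E": 147.13, "G": 75.07, "H": 155.16, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "W": 204.24, "Y": 181.19, "V": 117.15,
})

POLARIZABILITY = _scale({
    "A": 0.046, "R": 0.291, "N": 0.134, "D": 0.105, "C": 0.128,
    "Q": 0.180, "E": 0.151, "G": 0.000, "H": 0.230, "I": 0.186,
    "L": 0.186, "K": 0.219, "M": 0.221, "F": 0.290, "P": 0.131,
    "S": 0.062, "T": 0.108, "W": 0.409, "Y": 0.298, "V": 0.140,
})

ACCESSIBLE_SURFACE = _scale({
    "A": 115.0, "R": 225.0, "N": 160.0, "D": 150.0, "C": 135.0,
    "Q": 180.0, "E": 190.0, "G": 75.0, "H": 195.0, "I": 175.0,
    "L": 170.0, "K": 200.0, "M": 185.0, "F": 210.0, "P": 145.0,
    "S": 115.0, "T": 140.0, "W": 255.0, "Y": 230.0, "V": 155.0,
})

#: default AAindex-style panel exposed by the AAIndex residue encoding
AAINDEX_PANEL: dict[str, dict[str, float]] = {
    "HYDROPATHY_KD": HYDROPATHY_KD,
    "HYDROPHILICITY_HW": HYDROPHILICITY_HW,
    "POLARITY_GRANTHAM": GRANTHAM_POLARITY,
    "VOLUME_GRANTHAM": GRANTHAM_VOLUME,
    "ISOELECTRIC_POINT": ISOELECTRIC_POINT,
    "RESIDUE_MW": RESIDUE_MW,
    "POLARIZABILITY": POLARIZABILITY,
    "ACCESSIBLE_SURFACE": ACCESSIBLE_SURFACE,
}


def standardize(scale: dict[str, float]) -> dict[str, float]:
    """Standardize a 20-residue scale to mean 0, population sd 1."""
    v = np.array([scale[a] for a in AA], dtype=float)
    sd = v.std()  # population sd over the 20 amino acids
    if sd == 0:
        raise ValueError("constant property scale")
    z = (v - v.mean()) / sd
    return {a: float(z[i]) for i, a in enumerate(AA)}


# Z-scales (Sandberg et al.): five descriptor variables per residue.
ZSCALES: dict[str, tuple[float, float, float, float, float]] = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}

# --------------------------------------------------------------------------
# group partitions
# --------------------------------------------------------------------------

#: five physicochemical groups (hydrophobicity, charge, molecular size)
FIVE_GROUPS: dict[str, str] = {
    "aliphatic": "GAVLMI",
    "aromatic": "FYW",
    "positive": "KRH",
    "negative": "DE",
    "uncharged": "STCPNQ",
}
FIVE_GROUP_NAMES = list(FIVE_GROUPS)
AA_TO_FIVE_GROUP = {
    a: name for name, members in FIVE_GROUPS.items() for a in members
}

#: classic CTD attributes: 7 properties x 3 groups
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MPSTHY"),
}
CTD_PROPERTIES = list(CTD_GROUPS)

#: conjoint-triad classification into 7 classes
CTRIAD_GROUPS: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

#: six-letter exchange groups (Dayhoff) for the 6-bit binary encoding
SIX_GROUPS: tuple[str, ...] = ("AGPST", "C", "DENQ", "FWY", "HKR", "ILMV")

#: Taylor overlapping property classes for the 10-bit one-hot encoding
OPF_10 = {
    "hydrophobic": "ACFGHIKLMTVWY",
    "polar": "CDEHKNQRSTWY",
    "small": "ACDGNPSTV",
    "proline": "P",
    "tiny": "ACGS",
    "aliphatic": "ILV",
    "aromatic": "FHWY",
    "positive": "HKR",
    "negative": "DE",
    "charged": "DEHKR",
}
OPF_10_NAMES = list(OPF_10)

#: number of codons per amino acid (standard genetic code), used by DDE
CODON_COUNT = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3,
    "K": 2, "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6,
    "T": 4, "V": 4, "W": 1, "Y": 2,
}

# --------------------------------------------------------------------------
# amino-acid distance matrices (quasi-sequence-order)
# --------------------------------------------------------------------------


def _grantham_matrix() -> dict[tuple[str, str], float]:
    """Grantham chemical distance from composition, polarity and volume.

    D(i,j) = [a*(c_i-c_j)^2 + b*(p_i-p_j)^2 + g*(v_i-v_j)^2]^(1/2)
    with the published constants a=1.833, b=0.1018, g=0.000399 and a
    global factor scaling the mean distance to 100.
    """
    a, b, g = 1.833, 0.1018, 0.000399
    raw = {}
    for x in AA:
        for y in AA:
            d2 = (
                a * (GRANTHAM_COMPOSITION[x] - GRANTHAM_COMPOSITION[y]) ** 2
                + b * (GRANTHAM_POLARITY[x] - GRANTHAM_POLARITY[y]) ** 2
                + g * (GRANTHAM_VOLUME[x] - GRANTHAM_VOLUME[y]) ** 2
            )
            raw[(x, y)] = float(np.sqrt(d2))
    off = [v for (x, y), v in raw.items() if x != y]
    factor = 100.0 / float(np.mean(off))
    return {k: v * factor for k, v in raw.items()}


def _physchem_distance_matrix() -> dict[tuple[str, str], float]:
    """Schneider-Wrede-form physicochemical distance.

    Euclidean distance over the standardized hydrophobicity,
    hydrophilicity and side-chain mass scales, scaled so the largest
    pair distance is 1 (the form used for quasi-sequence-order
    coupling numbers).
    """
    props = [
        standardize(HYDROPHOBICITY_PAAC),
        standardize(HYDROPHILICITY_HW),
        standardize(SIDE_CHAIN_MASS),
    ]
    raw = {}
    for x in AA:
        for y in AA:
            raw[(x, y)] = float(
                np.sqrt(sum((p[x] - p[y]) ** 2 for p in props))
            )
    m = max(raw.values())
    return {k: v / m for k, v in raw.items()}


GRANTHAM_DISTANCE = _grantham_matrix()
SCHNEIDER_WREDE_DISTANCE = _physchem_distance_matrix()

QSO_MATRICES = {
    "SchneiderWrede": SCHNEIDER_WREDE_DISTANCE,
    "Grantham": GRANTHAM_DISTANCE,
}

# --------------------------------------------------------------------------
# nucleotide tables
# --------------------------------------------------------------------------

#: electron-ion interaction pseudopotential of the nucleobases
EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335, "U": 0.1335}

#: nucleotide chemical-property code (ring number, H-bond strength, amino/keto)
NCP_CODE = {
    "A": (1, 1, 1),
    "C": (0, 1, 0),
    "G": (1, 0, 0),
    "T": (0, 0, 1),
    "U": (0, 0, 1),
}

_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_RNA_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def complement(base: str, kind: str) -> str:
    return (_DNA_COMP if kind == "dna" else _RNA_COMP)[base]


def reverse_complement(kmer: str, kind: str) -> str:
    comp = _DNA_COMP if kind == "dna" else _RNA_COMP
    return "".join(comp[b] for b in reversed(kmer))


def _nn_table(pairs: dict[str, float], kind: str) -> dict[str, float]:
    """Expand a 10-entry nearest-neighbour table to all 16 dinucleotides
    using reverse-complement symmetry."""
    out: dict[str, float] = {}
    alphabet = "ACGT" if kind == "dna" else "ACGU"
    for x in alphabet:
        for y in alphabet:
            dn = x + y
            if dn in pairs:
                out[dn] = pairs[dn]
            else:
                out[dn] = pairs[reverse_complement(dn, kind)]
    return out


# unified DNA nearest-neighbour thermodynamics (kcal/mol, cal/mol/K)
_DNA_DG = {"AA": -1.00, "AT": -0.88, "TA": -0.58, "CA": -1.45, "GT": -1.44,
           "CT": -1.28, "GA": -1.30, "CG": -2.17, "GC": -2.24, "GG": -1.84}
_DNA_DH = {"AA": -7.9, "AT": -7.2, "TA": -7.2, "CA": -8.5, "GT": -8.4,
           "CT": -7.8, "GA": -8.2, "CG": -10.6, "GC": -9.8, "GG": -8.0}
_DNA_DS = {"AA": -22.2, "AT": -20.4, "TA": -21.3, "CA": -22.7, "GT": -22.4,
           "CT": -21.0, "GA": -22.2, "CG": -27.2, "GC": -24.4, "GG": -19.9}

DNA_DINUC_PROPERTIES: dict[str, dict[str, float]] = {
    "free_energy": _nn_table(_DNA_DG, "dna"),
    "enthalpy": _nn_table(_DNA_DH, "dna"),
    "entropy": _nn_table(_DNA_DS, "dna"),
}

# RNA Watson-Crick nearest-neighbour parameters
_RNA_DG = {"AA": -0.93, "AU": -1.10, "UA": -1.33, "CU": -2.08, "CA": -2.11,
           "GU": -2.24, "GA": -2.35, "CG": -2.36, "GG": -3.26, "GC": -3.42}
_RNA_DH = {"AA": -6.82, "AU": -9.38, "UA": -7.69, "CU": -10.48, "CA": -10.44,
           "GU": -11.40, "GA": -12.44, "CG": -10.64, "GG": -13.39,
           "GC": -14.88}

RNA_DINUC_PROPERTIES: dict[str, dict[str, float]] = {
    "free_energy": _nn_table(_RNA_DG, "rna"),
    "enthalpy": _nn_table(_RNA_DH, "rna"),
    "entropy": {
        dn: (h - g) / 310.15 * 1000.0
        for (dn, g), h in zip(
            _nn_table(_RNA_DG, "rna").items(),
            _nn_table(_RNA_DH, "rna").values(),
        )
    },
}


def _tri_from_di(di: dict[str, dict[str, float]], kind: str) -> dict[str, dict[str, float]]:
    """Trinucleotide property panel by nearest-neighbour additivity."""
    alphabet = "ACGT" if kind == "dna" else "ACGU"
    out: dict[str, dict[str, float]] = {}
    for name, table in di.items():
        out[name] = {
            x + y + z: table[x + y] + table[y + z]
            for x in alphabet for y in alphabet for z in alphabet
        }
    return out


DNA_TRINUC_PROPERTIES = _tri_from_di(DNA_DINUC_PROPERTIES, "dna")
RNA_TRINUC_PROPERTIES = _tri_from_di(RNA_DINUC_PROPERTIES, "rna")


def standardize_kmer_table(table: dict[str, float]) -> dict[str, float]:
    """Standardize a k-mer property table (population sd over all 4^k)."""
    keys = sorted(table)
    v = np.array([table[k] for k in keys], dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("constant k-mer property")
    z = (v - v.mean()) / sd
    return {k: float(z[i]) for i, k in enumerate(keys)}


def dinuc_panel(kind: str, standardized: bool = True) -> dict[str, dict[str, float]]:
    src = DNA_DINUC_PROPERTIES if kind == "dna" else RNA_DINUC_PROPERTIES
    if not standardized:
        return {n: dict(t) for n, t in src.items()}
    return {n: standardize_kmer_table(t) for n, t in src.items()}


def trinuc_panel(kind: str, standardized: bool = True) -> dict[str, dict[str, float]]:
    src = DNA_TRINUC_PROPERTIES if kind == "dna" else RNA_TRINUC_PROPERTIES
    if not standardized:
        return {n: dict(t) for n, t in src.items()}
    return {n: standardize_kmer_table(t) for n, t in src.items()}


# --------------------------------------------------------------------------
# structure tables
# --------------------------------------------------------------------------

#: van der Waals radii (A) by element, used by the sampled-surface depth
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
VDW_DEFAULT = 1.70
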