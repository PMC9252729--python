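"""Protein-sequence descriptor sets.

Ten categories: plain and grouped compositions, autocorrelation /
covariance measures, quasi-sequence-order, pseudo amino-acid
compositions, reduced-alphabet (PseKRAAC) k-tuple compositions,
per-residue encodings (one-hot and property-based), AAindex / BLOSUM62 /
Z-scale representations, and a nearest-neighbour similarity descriptor.

Single-sequence descriptors are exposed as functions returning
``(feature_names, vector)``; window/per-residue encodings operate on a
whole equal-length :class:`~omegafeat.records.SequenceSet`.  The
:func:`compute` dispatcher turns any registered descriptor name into a
:class:`~omegafeat.records.FeatureMatrix`.
"""

from __future__ import annotations

import itertools
import math
from typing import Callable, Iterable, Sequence

import numpy as np

from .records import FeatureMatrix, SequenceSet
from .reduced import SCHEME_TAGS, reduced_alphabet
from .tables import (
    AA,
    AAINDEX_PANEL,
    ACCESSIBLE_SURFACE,
    AA_TO_FIVE_GROUP,
    CODON_COUNT,
    CTD_GROUPS,
    CTD_PROPERTIES,
    CTRIAD_GROUPS,
    FIVE_GROUPS,
    FIVE_GROUP_NAMES,
    HYDROPHILICITY_HW,
    HYDROPHOBICITY_PAAC,
    OPF_10,
    OPF_10_NAMES,
    QSO_MATRICES,
    SIDE_CHAIN_MASS,
    SIX_GROUPS,
    ZSCALES,
    standardize,
)

Vector = tuple[list[str], np.ndarray]

_DIPEPTIDES = [a + b for a in AA for b in AA]
_TRIPEPTIDES = [a + b + c for a in AA for b in AA for c in AA]

#: default standardized property panel for autocorrelation descriptors
DEFAULT_PROPERTIES: dict[str, dict[str, float]] = {
    name: standardize(scale) for name, scale in AAINDEX_PANEL.items()
}

DEFAULT_NLAG = 5


def _check_protein(seq: str) -> str:
    bad = set(seq) - set(AA)
    if bad:
        raise ValueError(f"non-canonical residue(s) {sorted(bad)} in sequence")
    return seq


# --------------------------------------------------------------------------
# compositions
# --------------------------------------------------------------------------

def aac(seq: str) -> Vector:
    """Amino-acid composition: 20 frequencies summing to 1."""
    _check_protein(seq)
    counts = np.array([seq.count(a) for a in AA], dtype=float)
    return [f"AAC.{a}" for a in AA], counts / len(seq)


def dpc(seq: str, counts: bool = False, tag: str = "DPC") -> Vector:
    """Dipeptide composition (400); ``counts=True`` gives raw counts."""
    _check_protein(seq)
    if len(seq) < 2:
        raise ValueError("DPC needs length >= 2")
    c = np.zeros(400)
    for i in range(len(seq) - 1):
        c[20 * AA.index(seq[i]) + AA.index(seq[i + 1])] += 1
    names = [f"{tag}.{d}" for d in _DIPEPTIDES]
    return names, c if counts else c / (len(seq) - 1)


def tpc(seq: str, counts: bool = False, tag: str = "TPC") -> Vector:
    """Tripeptide composition (8000)."""
    _check_protein(seq)
    if len(seq) < 3:
        raise ValueError("TPC needs length >= 3")
    c = np.zeros(8000)
    for i in range(len(seq) - 2):
        c[400 * AA.index(seq[i]) + 20 * AA.index(seq[i + 1]) + AA.index(seq[i + 2])] += 1
    names = [f"{tag}.{t}" for t in _TRIPEPTIDES]
    return names, c if counts else c / (len(seq) - 2)


def cksaap(seq: str, gap: int = 3, counts: bool = False, tag: str = "CKSAAP") -> Vector:
    """Composition of k-spaced amino-acid pairs for gaps 0..``gap``.

    Each gap block holds the 400 pair frequencies at that spacing and
    (in frequency mode) sums to 1.
    """
    _check_protein(seq)
    if len(seq) < gap + 2:
        raise ValueError(f"CKSAAP gap={gap} needs length >= {gap + 2}")
    names: list[str] = []
    out: list[np.ndarray] = []
    for g in range(gap + 1):
        c = np.zeros(400)
        for i in range(len(seq) - g - 1):
            c[20 * AA.index(seq[i]) + AA.index(seq[i + g + 1])] += 1
        if not counts:
            c = c / (len(seq) - g - 1)
        names.extend(f"{tag}.g{g}.{d}" for d in _DIPEPTIDES)
        out.append(c)
    return names, np.concatenate(out)


def dde(seq: str) -> Vector:
    """Dipeptide deviation from expected mean.

    DDE(ij) = (Dc - Tm) / sqrt(Tv) with Tm the codon-background
    expectation (C_i/61)(C_j/61) and Tv = Tm (1-Tm)/(N-1).
    """
    _check_protein(seq)
    n = len(seq) - 1
    if n < 1:
        raise ValueError("DDE needs length >= 2")
    _, dc = dpc(seq)
    out = np.zeros(400)
    for idx, (a, b) in enumerate(itertools.product(AA, AA)):
        tm = (CODON_COUNT[a] / 61.0) * (CODON_COUNT[b] / 61.0)
        tv = tm * (1 - tm) / n
        out[idx] = (dc[idx] - tm) / math.sqrt(tv)
    return [f"DDE.{d}" for d in _DIPEPTIDES], out


def asdc(seq: str) -> Vector:
    """Adaptive skip dipeptide composition: all ordered residue pairs
    (i < j) regardless of distance, normalized to sum 1 (400)."""
    _check_protein(seq)
    if len(seq) < 2:
        raise ValueError("ASDC needs length >= 2")
    c = np.zeros(400)
    for i in range(len(seq) - 1):
        for j in range(i + 1, len(seq)):
            c[20 * AA.index(seq[i]) + AA.index(seq[j])] += 1
    return [f"ASDC.{d}" for d in _DIPEPTIDES], c / c.sum()


def eaac(seqs: SequenceSet, window: int = 5) -> FeatureMatrix:
    """Enhanced AAC: sliding-window composition over equal-length input."""
    L = _equal_length(seqs, window)
    names = [
        f"EAAC.w{p + 1}.{a}" for p in range(L - window + 1) for a in AA
    ]
    rows = []
    for rec in seqs:
        row = []
        for p in range(L - window + 1):
            sub = rec.residues[p:p + window]
            row.extend(sub.count(a) / window for a in AA)
        rows.append(row)
    return FeatureMatrix(np.array(rows), seqs.ids, names, seqs.labels)


# --------------------------------------------------------------------------
# CTD: composition / transition / distribution
# --------------------------------------------------------------------------

def _group_of(prop: str, residue: str) -> int:
    for g, members in enumerate(CTD_GROUPS[prop]):
        if residue in members:
            return g
    raise ValueError(f"residue {residue!r} unassigned for {prop}")


def ctdc(seq: str) -> Vector:
    _check_protein(seq)
    names, vals = [], []
    for prop in CTD_PROPERTIES:
        gs = [_group_of(prop, r) for r in seq]
        for g in range(3):
            names.append(f"CTDC.{prop}.g{g + 1}")
            vals.append(gs.count(g) / len(seq))
    return names, np.array(vals)


def ctdt(seq: str) -> Vector:
    """Transition frequencies between the three groups of each attribute."""
    _check_protein(seq)
    if len(seq) < 2:
        raise ValueError("CTDT needs length >= 2")
    names, vals = [], []
    for prop in CTD_PROPERTIES:
        gs = [_group_of(prop, r) for r in seq]
        pairs = list(zip(gs, gs[1:]))
        for a, b in ((0, 1), (0, 2), (1, 2)):
            n = sum(1 for x, y in pairs if {x, y} == {a, b})
            names.append(f"CTDT.{prop}.g{a + 1}{b + 1}")
            vals.append(n / (len(seq) - 1))
    return names, np.array(vals)


def ctdd(seq: str) -> Vector:
    """Distribution: relative position (%) of the 1st/25/50/75/100-th
    percentile occurrence of each group of each attribute."""
    _check_protein(seq)
    names, vals = [], []
    for prop in CTD_PROPERTIES:
        gs = [_group_of(prop, r) for r in seq]
        for g in range(3):
            pos = [i + 1 for i, x in enumerate(gs) if x == g]
            for frac, tag in ((0.0, "first"), (0.25, "25"), (0.5, "50"),
                              (0.75, "75"), (1.0, "100")):
                names.append(f"CTDD.{prop}.g{g + 1}.{tag}")
                if not pos:
                    vals.append(0.0)
                else:
                    k = max(1, math.ceil(frac * len(pos))) if frac > 0 else 1
                    vals.append(pos[k - 1] / len(seq) * 100.0)
    return names, np.array(vals)


# --------------------------------------------------------------------------
# conjoint triads
# --------------------------------------------------------------------------

_CTRIAD_OF = {a: g for g, members in enumerate(CTRIAD_GROUPS) for a in members}


def ctriad(seq: str) -> Vector:
    """Conjoint triad: 343 class-triple frequencies (sum 1)."""
    return _ksctriad_block(seq, 0, "CTriad")


def _ksctriad_block(seq: str, g: int, prefix: str) -> Vector:
    _check_protein(seq)
    span = 2 * (g + 1)
    if len(seq) <= span:
        raise ValueError(f"{prefix} gap={g} needs length > {span}")
    c = np.zeros(343)
    for i in range(len(seq) - span):
        t = (
            49 * _CTRIAD_OF[seq[i]]
            + 7 * _CTRIAD_OF[seq[i + g + 1]]
            + _CTRIAD_OF[seq[i + span]]
        )
        c[t] += 1
    names = [
        f"{prefix}.{'g%d.' % g if prefix == 'KSCTriad' else ''}c{i}.c{j}.c{k}"
        for i in range(7) for j in range(7) for k in range(7)
    ]
    return names, c / c.sum()


def ksctriad(seq: str, gap: int = 2) -> Vector:
    """k-spaced conjoint triads for spacings 0..``gap``; each 343-block
    is frequency-normalized."""
    names: list[str] = []
    blocks = []
    for g in range(gap + 1):
        n, v = _ksctriad_block(seq, g, "KSCTriad")
        names.extend(n)
        blocks.append(v)
    return names, np.concatenate(blocks)


# --------------------------------------------------------------------------
# grouped compositions (five physicochemical groups)
# --------------------------------------------------------------------------

_G5 = FIVE_GROUP_NAMES
_G5_PAIRS = [(a, b) for a in _G5 for b in _G5]
_G5_TRIPLES = [(a, b, c) for a in _G5 for b in _G5 for c in _G5]


def gaac(seq: str) -> Vector:
    _check_protein(seq)
    gs = [AA_TO_FIVE_GROUP[r] for r in seq]
    return (
        [f"GAAC.{g}" for g in _G5],
        np.array([gs.count(g) / len(seq) for g in _G5]),
    )


def gdpc(seq: str, counts: bool = False, tag: str = "GDPC") -> Vector:
    _check_protein(seq)
    if len(seq) < 2:
        raise ValueError("GDPC needs length >= 2")
    gs = [AA_TO_FIVE_GROUP[r] for r in seq]
    c = np.zeros(25)
    for i in range(len(gs) - 1):
        c[5 * _G5.index(gs[i]) + _G5.index(gs[i + 1])] += 1
    names = [f"{tag}.{a}.{b}" for a, b in _G5_PAIRS]
    return names, c if counts else c / (len(seq) - 1)


def gtpc(seq: str, counts: bool = False, tag: str = "GTPC") -> Vector:
    _check_protein(seq)
    if len(seq) < 3:
        raise ValueError("GTPC needs length >= 3")
    gs = [AA_TO_FIVE_GROUP[r] for r in seq]
    c = np.zeros(125)
    for i in range(len(gs) - 2):
        c[25 * _G5.index(gs[i]) + 5 * _G5.index(gs[i + 1]) + _G5.index(gs[i + 2])] += 1
    names = [f"{tag}.{a}.{b}.{c_}" for a, b, c_ in _G5_TRIPLES]
    return names, c if counts else c / (len(seq) - 2)


def cksaagp(seq: str, gap: int = 3, counts: bool = False, tag: str = "CKSAAGP") -> Vector:
    """k-spaced grouped pairs (25 per gap block)."""
    _check_protein(seq)
    if len(seq) < gap + 2:
        raise ValueError(f"CKSAAGP gap={gap} needs length >= {gap + 2}")
    gs = [AA_TO_FIVE_GROUP[r] for r in seq]
    names: list[str] = []
    out = []
    for g in range(gap + 1):
        c = np.zeros(25)
        for i in range(len(gs) - g - 1):
            c[5 * _G5.index(gs[i]) + _G5.index(gs[i + g + 1])] += 1
        if not counts:
            c = c / (len(seq) - g - 1)
        names.extend(f"{tag}.g{g}.{a}.{b}" for a, b in _G5_PAIRS)
        out.append(c)
    return names, np.concatenate(out)


def egaac(seqs: SequenceSet, window: int = 5) -> FeatureMatrix:
    """Enhanced grouped AAC over sliding windows (equal-length input)."""
    L = _equal_length(seqs, window)
    names = [f"EGAAC.w{p + 1}.{g}" for p in range(L - window + 1) for g in _G5]
    rows = []
    for rec in seqs:
        gs = [AA_TO_FIVE_GROUP[r] for r in rec.residues]
        row = []
        for p in range(L - window + 1):
            sub = gs[p:p + window]
            row.extend(sub.count(g) / window for g in _G5)
        rows.append(row)
    return FeatureMatrix(np.array(rows), seqs.ids, names, seqs.labels)


# --------------------------------------------------------------------------
# autocorrelation / covariance
# --------------------------------------------------------------------------

def autocorrelation(
    seq: str,
    variant: str,
    properties: dict[str, dict[str, float]] | None = None,
    nlag: int = DEFAULT_NLAG,
) -> Vector:
    """Moran / Geary / normalized Moreau-Broto autocorrelation.

    Properties must be standardized scales (mean 0, sd 1 over the 20
    amino acids).  A property that is constant on the given sequence
    yields 0 for every lag (zero-variance rule) rather than NaN.
    """
    _check_protein(seq)
    if variant not in {"Moran", "Geary", "NMBroto"}:
        raise ValueError(f"unknown autocorrelation variant {variant!r}")
    props = properties or DEFAULT_PROPERTIES
    N = len(seq)
    if nlag < 1 or nlag >= N:
        raise ValueError(f"nlag={nlag} invalid for sequence of length {N}")
    names, vals = [], []
    for pname, scale in props.items():
        p = np.array([scale[r] for r in seq])
        pbar = p.mean()
        dev = p - pbar
        ss = float(np.dot(dev, dev))
        if ss < 1e-10:  # constant signal up to rounding
            ss = 0.0
        for d in range(1, nlag + 1):
            names.append(f"{variant}.{pname}.d{d}")
            if variant == "Moran":
                if ss == 0:
                    vals.append(0.0)
                else:
                    num = float(np.dot(dev[:-d], dev[d:])) / (N - d)
                    vals.append(num / (ss / N))
            elif variant == "Geary":
                if ss == 0:
                    vals.append(0.0)
                else:
                    num = float(((p[:-d] - p[d:]) ** 2).sum()) / (2 * (N - d))
                    vals.append(num / (ss / (N - 1)))
            else:  # NMBroto
                vals.append(float(np.dot(p[:-d], p[d:])) / (N - d))
    return names, np.array(vals)


def auto_covariance(
    seq: str,
    variant: str,
    properties: dict[str, dict[str, float]] | None = None,
    nlag: int = DEFAULT_NLAG,
) -> Vector:
    """AC / CC / ACC auto- and cross-covariance descriptors.

    AC(u,d) = sum_i (P_u(i)-mean_u)(P_u(i+d)-mean_u) / (N-d); CC pairs
    two distinct properties; ACC concatenates both.
    """
    _check_protein(seq)
    if variant not in {"AC", "CC", "ACC"}:
        raise ValueError(f"unknown covariance variant {variant!r}")
    props = properties or DEFAULT_PROPERTIES
    N = len(seq)
    if nlag < 1 or nlag >= N:
        raise ValueError(f"nlag={nlag} invalid for sequence of length {N}")
    series = {
        name: np.array([scale[r] for r in seq]) for name, scale in props.items()
    }
    dev = {name: s - s.mean() for name, s in series.items()}
    names, vals = [], []
    pre = "ACC." if variant == "ACC" else ""
    if variant in {"AC", "ACC"}:
        for pname, d1 in dev.items():
            for d in range(1, nlag + 1):
                names.append(f"{pre}AC.{pname}.d{d}")
                vals.append(float(np.dot(d1[:-d], d1[d:])) / (N - d))
    if variant in {"CC", "ACC"}:
        for p1, p2 in itertools.permutations(dev, 2):
            for d in range(1, nlag + 1):
                names.append(f"{pre}CC.{p1}.{p2}.d{d}")
                vals.append(float(np.dot(dev[p1][:-d], dev[p2][d:])) / (N - d))
    return names, np.array(vals)


# --------------------------------------------------------------------------
# quasi-sequence-order
# --------------------------------------------------------------------------

def _tau(seq: str, matrix: dict[tuple[str, str], float], nlag: int) -> np.ndarray:
    N = len(seq)
    taus = np.zeros(nlag)
    for d in range(1, nlag + 1):
        taus[d - 1] = sum(
            matrix[(seq[i], seq[i + d])] ** 2 for i in range(N - d)
        )
    return taus


def socnumber(seq: str, nlag: int = DEFAULT_NLAG) -> Vector:
    """Sequence-order coupling numbers tau_1..tau_nlag for both bundled
    distance matrices."""
    _check_protein(seq)
    if nlag >= len(seq):
        raise ValueError(f"nlag={nlag} must be < sequence length {len(seq)}")
    names, vals = [], []
    for mname, matrix in QSO_MATRICES.items():
        taus = _tau(seq, matrix, nlag)
        names.extend(f"SOCNumber.{mname}.d{d}" for d in range(1, nlag + 1))
        vals.extend(taus)
    return names, np.array(vals)


def qsorder(seq: str, nlag: int = DEFAULT_NLAG, w: float = 0.1) -> Vector:
    """Quasi-sequence-order: 20 composition terms and nlag order terms
    per distance matrix, each matrix block summing to 1."""
    _check_protein(seq)
    if nlag >= len(seq):
        raise ValueError(f"nlag={nlag} must be < sequence length {len(seq)}")
    counts = np.array([seq.count(a) for a in AA], dtype=float)
    names, vals = [], []
    for mname, matrix in QSO_MATRICES.items():
        taus = _tau(seq, matrix, nlag)
        denom = counts.sum() + w * taus.sum()
        names.extend(f"QSOrder.{mname}.{a}" for a in AA)
        vals.extend(counts / denom)
        names.extend(f"QSOrder.{mname}.d{d}" for d in range(1, nlag + 1))
        vals.extend(w * taus / denom)
    return names, np.array(vals)


# --------------------------------------------------------------------------
# pseudo amino-acid composition
# --------------------------------------------------------------------------

_PAAC_PROPS = [
    standardize(HYDROPHOBICITY_PAAC),
    standardize(HYDROPHILICITY_HW),
    standardize(SIDE_CHAIN_MASS),
]


def _resolve_lam(seq: str, lam: int | None) -> int:
    if lam is None:
        lam = min(30, len(seq) - 1)
    if lam < 0 or lam >= len(seq):
        raise ValueError(f"lambda={lam} invalid for length {len(seq)}")
    return lam


def paac(seq: str, lam: int | None = None, w: float = 0.05) -> Vector:
    """Pseudo amino-acid composition (20 + lambda terms, summing to 1).

    The correlation function Theta is the mean squared difference of the
    three standardized PAAC properties; lambda defaults to
    min(30, L-1).
    """
    _check_protein(seq)
    lam = _resolve_lam(seq, lam)
    N = len(seq)
    thetas = np.zeros(lam)
    for j in range(1, lam + 1):
        s = 0.0
        for i in range(N - j):
            s += np.mean(
                [(p[seq[i]] - p[seq[i + j]]) ** 2 for p in _PAAC_PROPS]
            )
        thetas[j - 1] = s / (N - j)
    counts = np.array([seq.count(a) for a in AA], dtype=float)
    freqs = counts / N
    denom = freqs.sum() + w * thetas.sum()
    names = [f"PAAC.{a}" for a in AA] + [f"PAAC.lam{j}" for j in range(1, lam + 1)]
    return names, np.concatenate([freqs / denom, w * thetas / denom])


def apaac(seq: str, lam: int | None = None, w: float = 0.05) -> Vector:
    """Amphiphilic PAAC: per-property correlation terms (20 + 2*lambda)."""
    _check_protein(seq)
    lam = _resolve_lam(seq, lam)
    N = len(seq)
    props = _PAAC_PROPS[:2]  # hydrophobicity and hydrophilicity
    taus = np.zeros(2 * lam)
    for j in range(1, lam + 1):
        for u, p in enumerate(props):
            s = sum(p[seq[i]] * p[seq[i + j]] for i in range(N - j))
            taus[2 * (j - 1) + u] = s / (N - j)
    counts = np.array([seq.count(a) for a in AA], dtype=float)
    freqs = counts / N
    denom = freqs.sum() + w * np.abs(taus).sum()
    names = [f"APAAC.{a}" for a in AA] + [
        f"APAAC.lam{j}.p{u + 1}" for j in range(1, lam + 1) for u in range(2)
    ]
    return names, np.concatenate([freqs / denom, w * taus / denom])


# --------------------------------------------------------------------------
# PseKRAAC
# --------------------------------------------------------------------------

def psekraac(
    seq: str,
    scheme: str,
    cluster_count: int = 5,
    k: int = 2,
    mode: str = "ktuple",
    gap: int = 0,
    lam: int = 1,
) -> Vector:
    """Pseudo K-tuple reduced amino-acid composition.

    The sequence is mapped through the scheme's reduced alphabet, then a
    k-tuple composition is taken over the reduced alphabet.  In
    ``ktuple`` mode tuple positions are spaced ``gap+1`` apart; in
    ``lambda`` mode they are spaced ``lam`` apart.  Output dimension is
    ``cluster_count ** k`` and sums to 1.
    """
    _check_protein(seq)
    if mode not in {"ktuple", "lambda"}:
        raise ValueError(f"unknown PseKRAAC mode {mode!r}")
    step = (gap + 1) if mode == "ktuple" else lam
    if step < 1:
        raise ValueError("tuple spacing must be >= 1")
    alpha = reduced_alphabet(scheme, cluster_count)
    mapped = [alpha.mapping[r] for r in seq]
    span = (k - 1) * step
    if len(seq) <= span:
        raise ValueError(
            f"sequence too short for k={k}, spacing={step} tuples"
        )
    c = np.zeros(cluster_count ** k)
    for i in range(len(seq) - span):
        idx = 0
        for j in range(k):
            idx = idx * cluster_count + mapped[i + j * step]
        c[idx] += 1
    names = [
        f"PseKRAAC_{scheme}.{'.'.join(f'g{g}' for g in tup)}"
        for tup in itertools.product(range(cluster_count), repeat=k)
    ]
    return names, c / c.sum()


# --------------------------------------------------------------------------
# per-residue encodings
# --------------------------------------------------------------------------

def _equal_length(seqs: SequenceSet, minimum: int = 1) -> int:
    if len(seqs) == 0:
        raise ValueError("empty sequence set")
    if not seqs.equal_length():
        raise ValueError("this descriptor requires equal-length sequences")
    L = len(seqs[0])
    if L < minimum:
        raise ValueError(f"sequences must be at least {minimum} long")
    return L


def _five_bit_codes() -> dict[str, tuple[int, ...]]:
    """20 distinct 5-bit patterns: the ten 2-of-5 codes then the first
    ten 3-of-5 codes, assigned to residues alphabetically."""
    patterns = [p for p in itertools.product((0, 1), repeat=5) if sum(p) == 2]
    patterns += [p for p in itertools.product((0, 1), repeat=5) if sum(p) == 3][:10]
    return {a: patterns[i] for i, a in enumerate(sorted(AA))}


_FIVE_BIT = _five_bit_codes()


def _aesnn3_table() -> dict[str, tuple[float, float, float]]:
    """Three-dimensional residue embedding: the first three principal
    components of the standardized bundled property panel (signs fixed
    so each component's loading on alanine is non-negative)."""
    mat = np.array(
        [[standardize(AAINDEX_PANEL[p])[a] for p in AAINDEX_PANEL] for a in AA]
    )
    mat = mat - mat.mean(axis=0)
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    comp = u[:, :3] * s[:3]
    for j in range(3):
        if comp[0, j] < 0:
            comp[:, j] = -comp[:, j]
    return {a: tuple(float(x) for x in comp[i]) for i, a in enumerate(AA)}


_AESNN3 = _aesnn3_table()


def _blosum62_rows() -> dict[str, tuple[float, ...]]:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    return {a: tuple(float(m[a][b]) for b in AA) for a in AA}


_BLOSUM62 = _blosum62_rows()

#: per-residue encoders: variant -> (width, residue -> values)
_RESIDUE_CODERS: dict[str, tuple[int, Callable[[str], Sequence[float]]]] = {}


def _register_coder(name: str, width: int, fn: Callable[[str], Sequence[float]]) -> None:
    _RESIDUE_CODERS[name] = (width, fn)


_register_coder("binary", 20, lambda r: [1.0 if a == r else 0.0 for a in AA])
_register_coder(
    "binary_6bit", 6,
    lambda r: [1.0 if r in grp else 0.0 for grp in SIX_GROUPS],
)
_register_coder(
    "binary_5bit_type1", 5,
    lambda r: [1.0 if r in FIVE_GROUPS[g] else 0.0 for g in _G5],
)
_register_coder("binary_5bit_type2", 5, lambda r: [float(b) for b in _FIVE_BIT[r]])
for _t, _prop in enumerate(CTD_PROPERTIES, start=1):
    _register_coder(
        f"binary_3bit_type{_t}", 3,
        (lambda prop: lambda r: [
            1.0 if r in CTD_GROUPS[prop][g] else 0.0 for g in range(3)
        ])(_prop),
    )
_register_coder("AESNN3", 3, lambda r: list(_AESNN3[r]))
_register_coder(
    "OPF_10bit", 10,
    lambda r: [1.0 if r in OPF_10[c] else 0.0 for c in OPF_10_NAMES],
)
for _t in (1, 2, 3):
    _register_coder(
        f"OPF_7bit_type{_t}", 7,
        (lambda g: lambda r: [
            1.0 if r in CTD_GROUPS[p][g] else 0.0 for p in CTD_PROPERTIES
        ])(_t - 1),
    )
_register_coder("ZScale", 5, lambda r: list(ZSCALES[r]))
_register_coder("BLOSUM62", 20, lambda r: list(_BLOSUM62[r]))
_register_coder(
    "AAIndex", len(AAINDEX_PANEL),
    lambda r: [DEFAULT_PROPERTIES[p][r] for p in AAINDEX_PANEL],
)

RESIDUE_ENCODINGS = list(_RESIDUE_CODERS)


def residue_encoding(seqs: SequenceSet, variant: str) -> FeatureMatrix:
    """Concatenated per-residue vectors for an equal-length sequence set."""
    if variant not in _RESIDUE_CODERS:
        raise ValueError(f"unknown residue encoding {variant!r}")
    width, coder = _RESIDUE_CODERS[variant]
    L = _equal_length(seqs)
    names = [
        f"{variant}.p{p + 1}.b{b + 1}" for p in range(L) for b in range(width)
    ]
    rows = []
    for rec in seqs:
        _check_protein(rec.residues)
        row: list[float] = []
        for r in rec.residues:
            row.extend(coder(r))
        rows.append(row)
    return FeatureMatrix(np.array(rows), seqs.ids, names, seqs.labels)


def encoding_width(variant: str) -> int:
    return _RESIDUE_CODERS[variant][0]


# --------------------------------------------------------------------------
# nearest-neighbour similarity descriptor
# --------------------------------------------------------------------------

def _protein_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -1.0
    return al


def _knn_matrix(
    query: SequenceSet,
    train: SequenceSet,
    k_fractions: Sequence[float],
    similarity: Callable[[str, str], float],
    prefix: str,
) -> FeatureMatrix:
    labels = train.labels
    if labels is None:
        raise ValueError("KNN descriptor needs a labelled training set")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("KNN descriptor needs >= 2 classes")
    n_train = len(train)
    ks = []
    for f in k_fractions:
        k = max(1, math.ceil(f * n_train))
        if k > n_train:
            raise ValueError(f"k fraction {f} exceeds training size")
        ks.append(k)
    names = [
        f"{prefix}.k{int(round(f * 100))}pct.class_{c}"
        for f in k_fractions for c in classes
    ]
    rows = []
    for q in query:
        sims = np.array([similarity(q.residues, t.residues) for t in train])
        # descending similarity, ties broken by training-set order
        order = sorted(range(n_train), key=lambda i: (-sims[i], i))
        row: list[float] = []
        for k in ks:
            top = [labels[i] for i in order[:k]]
            row.extend(top.count(c) / k for c in classes)
        rows.append(row)
    return FeatureMatrix(np.array(rows), query.ids, names, query.labels)


DEFAULT_K_FRACTIONS = tuple(round(0.01 * i, 2) for i in range(1, 31))


def knn_descriptor(
    query: SequenceSet,
    train: SequenceSet,
    k_fractions: Sequence[float] = DEFAULT_K_FRACTIONS,
) -> FeatureMatrix:
    """Per-class proportions among the k nearest training sequences,
    ranked by normalized global BLOSUM62 alignment score."""
    al = _protein_aligner()
    self_score: dict[str, float] = {}

    def sim(a: str, b: str) -> float:
        for s in (a, b):
            if s not in self_score:
                self_score[s] = float(al.score(s, s))
        return 2.0 * float(al.score(a, b)) / (self_score[a] + self_score[b])

    return _knn_matrix(query, train, k_fractions, sim, "KNN")


# --------------------------------------------------------------------------
# dispatcher
# --------------------------------------------------------------------------

def _per_seq(fn: Callable[..., Vector]) -> Callable[..., FeatureMatrix]:
    def run(seqs: SequenceSet, **params) -> FeatureMatrix:
        names: list[str] | None = None
        rows = []
        for rec in seqs:
            n, v = fn(rec.residues, **params)
            if names is None:
                names = n
            elif n != names:
                raise ValueError(
                    "descriptor dimensionality varies across sequences; "
                    "use equal-length input or fix the lag/lambda parameter"
                )
            rows.append(v)
        assert names is not None
        return FeatureMatrix(np.array(rows), seqs.ids, names, seqs.labels)

    return run


def _fixed_lam_wrapper(fn, seqs: SequenceSet, **params):
    # resolve the default lambda against the shortest sequence so every
    # row has the same dimension
    if params.get("lam") is None:
        params["lam"] = min(30, seqs.min_length() - 1)
    return _per_seq(fn)(seqs, **params)


_DISPATCH: dict[str, Callable[..., FeatureMatrix]] = {
    "AAC": _per_seq(aac),
    "EAAC": eaac,
    "CKSAAP_type1": _per_seq(cksaap),
    "CKSAAP_type2": lambda seqs, **p: _per_seq(cksaap)(seqs, counts=True, tag="CKSAAP2", **p),
    "DPC_type1": _per_seq(dpc),
    "DPC_type2": lambda seqs, **p: _per_seq(dpc)(seqs, counts=True, tag="DPC2", **p),
    "DDE": _per_seq(dde),
    "TPC_type1": _per_seq(tpc),
    "TPC_type2": lambda seqs, **p: _per_seq(tpc)(seqs, counts=True, tag="TPC2", **p),
    "CTDC": _per_seq(ctdc),
    "CTDT": _per_seq(ctdt),
    "CTDD": _per_seq(ctdd),
    "CTriad": _per_seq(ctriad),
    "KSCTriad": _per_seq(ksctriad),
    "ASDC": _per_seq(asdc),
    "GAAC": _per_seq(gaac),
    "EGAAC": egaac,
    "CKSAAGP_type1": _per_seq(cksaagp),
    "CKSAAGP_type2": lambda seqs, **p: _per_seq(cksaagp)(seqs, counts=True, tag="CKSAAGP2", **p),
    "GDPC_type1": _per_seq(gdpc),
    "GDPC_type2": lambda seqs, **p: _per_seq(gdpc)(seqs, counts=True, tag="GDPC2", **p),
    "GTPC_type1": _per_seq(gtpc),
    "GTPC_type2": lambda seqs, **p: _per_seq(gtpc)(seqs, counts=True, tag="GTPC2", **p),
    "Moran": lambda seqs, **p: _per_seq(autocorrelation)(seqs, variant="Moran", **p),
    "Geary": lambda seqs, **p: _per_seq(autocorrelation)(seqs, variant="Geary", **p),
    "NMBroto": lambda seqs, **p: _per_seq(autocorrelation)(seqs, variant="NMBroto", **p),
    "AC": lambda seqs, **p: _per_seq(auto_covariance)(seqs, variant="AC", **p),
    "CC": lambda seqs, **p: _per_seq(auto_covariance)(seqs, variant="CC", **p),
    "ACC": lambda seqs, **p: _per_seq(auto_covariance)(seqs, variant="ACC", **p),
    "SOCNumber": _per_seq(socnumber),
    "QSOrder": _per_seq(qsorder),
    "PAAC": lambda seqs, **p: _fixed_lam_wrapper(paac, seqs, **p),
    "APAAC": lambda seqs, **p: _fixed_lam_wrapper(apaac, seqs, **p),
    "KNN": lambda seqs, train=None, **p: knn_descriptor(
        seqs, train if train is not None else seqs, **p
    ),
}
for _tag in SCHEME_TAGS:
    _DISPATCH[f"PseKRAAC_{_tag}"] = (
        lambda seqs, _tag=_tag, **p: _per_seq(psekraac)(seqs, scheme=_tag, **p)
    )
for _enc in RESIDUE_ENCODINGS:
    _DISPATCH[_enc] = (
        lambda seqs, _enc=_enc, **p: residue_encoding(seqs, _enc, **p)
    )

PROTEIN_DESCRIPTORS = list(_DISPATCH)


def compute(seqs: SequenceSet, descriptor: str, **params) -> FeatureMatrix:
    """Compute any registered protein descriptor for a sequence set."""
    if seqs.kind != "protein":
        raise ValueError(f"protein descriptor on {seqs.kind!r} sequences")
    try:
        fn = _DISPATCH[descriptor]
    except KeyError:
        raise ValueError(f"unknown protein descriptor {descriptor!r}") from None
    return fn(seqs, **params)
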