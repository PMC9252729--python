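"""DNA and RNA sequence descriptor sets.

Eight categories: nucleotide/k-mer compositions, position-specific
encodings, electron-ion interaction pseudopotentials, autocorrelation
and covariance over di-/tri-nucleotide physicochemical properties,
property-weighted compositions, multivariate mutual information, pseudo
nucleotide compositions, Z-curve transforms, and a nearest-neighbour
similarity descriptor.  DNA and RNA share all code paths; the RNA
registry simply excludes the DNA-only sets (trinucleotide-property,
double-strand, EIIP and the two long Z-curve variants).
"""

from __future__ import annotations

import itertools
import math
from typing import Callable, Sequence

import numpy as np

from .records import FeatureMatrix, SequenceSet
from .tables import (
    EIIP,
    NCP_CODE,
    dinuc_panel,
    reverse_complement,
    trinuc_panel,
)

Vector = tuple[list[str], np.ndarray]


def f_kmer_tag(k: int) -> str:
    return f"Kmer{k}"

DEFAULT_NLAG = 3


def _alphabet(kind: str) -> str:
    if kind == "dna":
        return "ACGT"
    if kind == "rna":
        return "ACGU"
    raise ValueError(f"not a nucleic kind: {kind!r}")


def _check(seq: str, kind: str) -> str:
    bad = set(seq) - set(_alphabet(kind))
    if bad:
        raise ValueError(f"non-canonical base(s) {sorted(bad)} in sequence")
    return seq


def _kmers(kind: str, k: int) -> list[str]:
    return ["".join(t) for t in itertools.product(_alphabet(kind), repeat=k)]


# --------------------------------------------------------------------------
# k-mer compositions
# --------------------------------------------------------------------------

def kmer(seq: str, kind: str, k: int = 3, counts: bool = False, tag: str | None = None) -> Vector:
    """Normalized k-mer composition (4^k entries)."""
    _check(seq, kind)
    if not 1 <= k <= 6:
        raise ValueError("k must be in 1..6")
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    kk = _kmers(kind, k)
    idx = {m: i for i, m in enumerate(kk)}
    c = np.zeros(len(kk))
    for i in range(len(seq) - k + 1):
        c[idx[seq[i:i + k]]] += 1
    names = [f"{tag or f_kmer_tag(k)}.{m}" for m in kk]
    return names, c if counts else c / c.sum()


def rckmer(seq: str, kind: str, k: int = 3) -> Vector:
    """Reverse-complement-collapsed k-mer composition.

    Each k-mer and its reverse complement (A<->T for DNA, A<->U for RNA)
    share the lexicographically smaller canonical key.
    """
    _check(seq, kind)
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    canon: dict[str, str] = {}
    for m in _kmers(kind, k):
        canon[m] = min(m, reverse_complement(m, kind))
    classes = sorted(set(canon.values()))
    idx = {c: i for i, c in enumerate(classes)}
    v = np.zeros(len(classes))
    for i in range(len(seq) - k + 1):
        v[idx[canon[seq[i:i + k]]]] += 1
    return [f"RCKmer{k}.{c}" for c in classes], v / v.sum()


def mismatch_profile(seq: str, kind: str, k: int = 3, m: int = 1) -> Vector:
    """k-mer profile counting occurrences within ``m`` substitutions."""
    _check(seq, kind)
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    if not 0 <= m < k:
        raise ValueError("mismatch count must satisfy 0 <= m < k")
    kk = _kmers(kind, k)
    windows = [seq[i:i + k] for i in range(len(seq) - k + 1)]
    c = np.zeros(len(kk))
    for j, t in enumerate(kk):
        c[j] = sum(
            1 for w in windows
            if sum(a != b for a, b in zip(w, t)) <= m
        )
    return [f"Mismatch{k}m{m}.{t}" for t in kk], c / c.sum()


def subsequence_profile(
    seq: str, kind: str, k: int = 2, delta: float = 1.0
) -> Vector:
    """(Optionally gap-penalized) subsequence composition.

    Every not-necessarily-contiguous length-k subsequence contributes
    ``delta ** (span - k)`` to its k-mer bin; delta=1 gives plain
    subsequence counts.  Normalized to sum 1.
    """
    _check(seq, kind)
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    if k != 2:
        raise ValueError("subsequence profile implemented for k=2")
    kk = _kmers(kind, 2)
    idx = {m_: i for i, m_ in enumerate(kk)}
    c = np.zeros(len(kk))
    for i in range(len(seq) - 1):
        for j in range(i + 1, len(seq)):
            c[idx[seq[i] + seq[j]]] += delta ** (j - i - 1)
    return [f"Subsequence.{t}" for t in kk], c / c.sum()


def cksnap(seq: str, kind: str, gap: int = 3, counts: bool = False, tag: str = "CKSNAP") -> Vector:
    """Composition of k-spaced nucleotide pairs (16 per gap block)."""
    _check(seq, kind)
    if len(seq) < gap + 2:
        raise ValueError(f"CKSNAP gap={gap} needs length >= {gap + 2}")
    alpha = _alphabet(kind)
    pairs = _kmers(kind, 2)
    names: list[str] = []
    out = []
    for g in range(gap + 1):
        c = np.zeros(16)
        for i in range(len(seq) - g - 1):
            c[4 * alpha.index(seq[i]) + alpha.index(seq[i + g + 1])] += 1
        if not counts:
            c = c / (len(seq) - g - 1)
        names.extend(f"{tag}.g{g}.{p}" for p in pairs)
        out.append(c)
    return names, np.concatenate(out)


def asdc(seq: str, kind: str) -> Vector:
    """Adaptive skip dinucleotide composition (16, sum 1)."""
    _check(seq, kind)
    if len(seq) < 2:
        raise ValueError("ASDC needs length >= 2")
    alpha = _alphabet(kind)
    c = np.zeros(16)
    for i in range(len(seq) - 1):
        for j in range(i + 1, len(seq)):
            c[4 * alpha.index(seq[i]) + alpha.index(seq[j])] += 1
    return [f"ASDC.{p}" for p in _kmers(kind, 2)], c / c.sum()


# --------------------------------------------------------------------------
# position-specific encodings (equal-length sets)
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


def _onehot_windows(seqs: SequenceSet, k: int, tag: str) -> FeatureMatrix:
    kind = seqs.kind
    L = _equal_length(seqs, k)
    kk = _kmers(kind, k)
    idx = {m: i for i, m in enumerate(kk)}
    width = len(kk)
    names = [
        f"{tag}.p{p + 1}.{m}" for p in range(L - k + 1) for m in kk
    ]
    rows = []
    for rec in seqs:
        _check(rec.residues, kind)
        row = np.zeros((L - k + 1) * width)
        for p in range(L - k + 1):
            row[p * width + idx[rec.residues[p:p + k]]] = 1.0
        rows.append(row)
    return FeatureMatrix(np.array(rows), seqs.ids, names, seqs.labels)


def binary(seqs: SequenceSet) -> FeatureMatrix:
    """Per-position one-hot over the four bases (4L)."""
    return _onehot_windows(seqs, 1, "binary")


def ps2(seqs: SequenceSet) -> FeatureMatrix:
    return _onehot_windows(seqs, 2, "PS2")


def ps3(seqs: SequenceSet) -> FeatureMatrix:
    return _onehot_windows(seqs, 3, "PS3")


def ps4(seqs: SequenceSet) -> FeatureMatrix:
    return _onehot_windows(seqs, 4, "PS4")


def ncp(seqs: SequenceSet) -> FeatureMatrix:
    """Nucleotide chemical property codes (ring/H-bond/amino-keto), 3L."""
    L = _equal_length(seqs)
    names = [f"NCP.p{p + 1}.b{b + 1}" for p in range(L) for b in range(3)]
    rows = []
    for rec in seqs:
        _check(rec.residues, seqs.kind)
        rows.append([float(x) for r in rec.residues for x in NCP_CODE[r]])
    return FeatureMatrix(np.array(rows), seqs.ids, names, seqs.labels)


def anf(seqs: SequenceSet) -> FeatureMatrix:
    """Accumulated nucleotide frequency: at position i, frequency of the
    base seq[i] within the prefix seq[1..i]."""
    L = _equal_length(seqs)
    names = [f"ANF.p{p + 1}" for p in range(L)]
    rows = []
    for rec in seqs:
        _check(rec.residues, seqs.kind)
        row = []
        for i in range(L):
            prefix = rec.residues[: i + 1]
            row.append(prefix.count(rec.residues[i]) / (i + 1))
        rows.append(row)
    return FeatureMatrix(np.array(rows), seqs.ids, names, seqs.labels)


def lpdf(seqs: SequenceSet) -> FeatureMatrix:
    """Local position-specific dinucleotide frequency: at position i>=2,
    the frequency of the dinucleotide ending at i within the prefix."""
    L = _equal_length(seqs, 2)
    names = [f"LPDF.p{p + 2}" for p in range(L - 1)]
    rows = []
    for rec in seqs:
        _check(rec.residues, seqs.kind)
        s = rec.residues
        row = []
        for i in range(1, L):
            dn = s[i - 1:i + 1]
            n = sum(1 for j in range(i) if s[j:j + 2] == dn)
            row.append(n / i)
        rows.append(row)
    return FeatureMatrix(np.array(rows), seqs.ids, names, seqs.labels)


_TWO_BIT = {"A": (0, 0), "C": (0, 1), "G": (1, 0), "T": (1, 1), "U": (1, 1)}


def dbe(seqs: SequenceSet) -> FeatureMatrix:
    """Dinucleotide binary encoding: each of the L-1 dinucleotides as the
    4-bit concatenation of its bases' 2-bit codes."""
    L = _equal_length(seqs, 2)
    names = [
        f"DBE.p{p + 1}.b{b + 1}" for p in range(L - 1) for b in range(4)
    ]
    rows = []
    for rec in seqs:
        _check(rec.residues, seqs.kind)
        s = rec.residues
        row: list[float] = []
        for i in range(L - 1):
            row.extend(float(b) for b in _TWO_BIT[s[i]] + _TWO_BIT[s[i + 1]])
        rows.append(row)
    return FeatureMatrix(np.array(rows), seqs.ids, names, seqs.labels)


# --------------------------------------------------------------------------
# EIIP
# --------------------------------------------------------------------------

def eiip(seqs: SequenceSet) -> FeatureMatrix:
    """Per-position electron-ion interaction pseudopotential values."""
    L = _equal_length(seqs)
    names = [f"EIIP.p{p + 1}" for p in range(L)]
    rows = []
    for rec in seqs:
        _check(rec.residues, seqs.kind)
        rows.append([EIIP[r] for r in rec.residues])
    return FeatureMatrix(np.array(rows), seqs.ids, names, seqs.labels)


def pse_eiip(seq: str, kind: str) -> Vector:
    """Trinucleotide-frequency-weighted EIIP: f(xyz) * (E_x+E_y+E_z)."""
    _check(seq, kind)
    if len(seq) < 3:
        raise ValueError("PseEIIP needs length >= 3")
    names, freqs = kmer(seq, kind, k=3)
    tri = _kmers(kind, 3)
    vals = freqs * np.array([sum(EIIP[b] for b in t) for t in tri])
    return [f"PseEIIP.{t}" for t in tri], vals


# --------------------------------------------------------------------------
# autocorrelation / covariance over k-nucleotide properties
# --------------------------------------------------------------------------

def _property_series(
    seq: str, table: dict[str, float], k: int
) -> np.ndarray:
    return np.array(
        [table[seq[i:i + k]] for i in range(len(seq) - k + 1)], dtype=float
    )


def _panel(kind: str, order: int) -> dict[str, dict[str, float]]:
    if order == 2:
        return dinuc_panel(kind)
    if order == 3:
        if kind == "rna":
            raise ValueError("trinucleotide property panel is DNA-only")
        return trinuc_panel(kind)
    raise ValueError("property order must be 2 or 3")


def nuc_autocorrelation(
    seq: str,
    kind: str,
    variant: str,
    order: int = 2,
    properties: dict[str, dict[str, float]] | None = None,
    nlag: int = DEFAULT_NLAG,
) -> Vector:
    """Moran / Geary / NMBroto over k-nucleotide property series.

    Same algebra as the protein autocorrelations but the signal is the
    standardized property of the di-/tri-nucleotide starting at each
    position.  Constant signal yields 0 (zero-variance rule).
    """
    _check(seq, kind)
    if variant not in {"Moran", "Geary", "NMBroto"}:
        raise ValueError(f"unknown autocorrelation variant {variant!r}")
    props = properties or _panel(kind, order)
    k = order
    N = len(seq) - k + 1  # number of k-nucleotide positions
    if N - nlag < 1 or nlag < 1:
        raise ValueError(f"nlag={nlag} invalid for {N} {k}-mer positions")
    names, vals = [], []
    for pname, table in props.items():
        p = _property_series(seq, table, k)
        dev = p - p.mean()
        ss = float(np.dot(dev, dev))
        if ss < 1e-10:  # constant signal up to rounding
            ss = 0.0
        for d in range(1, nlag + 1):
            names.append(f"{variant}{k}.{pname}.d{d}")
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
            else:
                vals.append(float(np.dot(p[:-d], p[d:])) / (N - d))
    return names, np.array(vals)


def nuc_covariance(
    seq: str,
    kind: str,
    variant: str,
    order: int = 2,
    properties: dict[str, dict[str, float]] | None = None,
    nlag: int = DEFAULT_NLAG,
) -> Vector:
    """DAC/DCC/DACC (order 2) and TAC/TCC/TACC (order 3)."""
    _check(seq, kind)
    if variant not in {"AC", "CC", "ACC"}:
        raise ValueError(f"unknown covariance variant {variant!r}")
    props = properties or _panel(kind, order)
    k = order
    N = len(seq) - k + 1
    if N - nlag < 1 or nlag < 1:
        raise ValueError(f"nlag={nlag} invalid for {N} {k}-mer positions")
    tag = {2: "D", 3: "T"}[k]
    dev = {
        name: (lambda p: p - p.mean())(_property_series(seq, t, k))
        for name, t in props.items()
    }
    names, vals = [], []
    pre = f"{tag}ACC." if variant == "ACC" else ""
    if variant in {"AC", "ACC"}:
        for pname, d1 in dev.items():
            for d in range(1, nlag + 1):
                names.append(f"{pre}{tag}AC.{pname}.d{d}")
                vals.append(float(np.dot(d1[:-d], d1[d:])) / (N - d))
    if variant in {"CC", "ACC"}:
        for p1, p2 in itertools.permutations(dev, 2):
            for d in range(1, nlag + 1):
                names.append(f"{pre}{tag}CC.{p1}.{p2}.d{d}")
                vals.append(float(np.dot(dev[p1][:-d], dev[p2][d:])) / (N - d))
    return names, np.array(vals)


# --------------------------------------------------------------------------
# property-weighted compositions
# --------------------------------------------------------------------------

def kmer_property_composition(
    seq: str, kind: str, order: int = 2, standardized: bool = False
) -> Vector:
    """Di-/tri-nucleotide physicochemical property composition:
    f(kmer) * P_u(kmer) for every k-mer and property."""
    _check(seq, kind)
    if order == 2:
        panel = dinuc_panel(kind, standardized=standardized)
    else:
        if kind == "rna":
            raise ValueError("trinucleotide property panel is DNA-only")
        panel = trinuc_panel(kind, standardized=standardized)
    _, freqs = kmer(seq, kind, k=order)
    kk = _kmers(kind, order)
    tag = {2: "DPCP", 3: "TPCP"}[order] + ("_std" if standardized else "")
    names, vals = [], []
    for pname, table in panel.items():
        names.extend(f"{tag}.{pname}.{m}" for m in kk)
        vals.extend(freqs[i] * table[m] for i, m in enumerate(kk))
    return names, np.array(vals)


# --------------------------------------------------------------------------
# multivariate mutual information
# --------------------------------------------------------------------------

def _plogp(p: float) -> float:
    return -p * math.log(p) if p > 0 else 0.0


def mmi(seq: str, kind: str) -> Vector:
    """Multivariate mutual information over unordered base pairs/triples.

    Single-base frequencies come from the sequence, unordered pair
    frequencies from adjacent dinucleotides, unordered triple
    frequencies from adjacent trinucleotides.  For a pair (x,y):
    I(x;y) = H(x) + H(y) - H(x,y); for a triple:
    I(x;y;z) = I(x;y) - [H(x,z) + H(y,z) - H(z) - H(x,y,z)], where every
    H(.) is the single-term entropy -p log p of the corresponding
    frequency.
    """
    _check(seq, kind)
    if len(seq) < 3:
        raise ValueError("MMI needs length >= 3")
    alpha = _alphabet(kind)
    f1 = {a: seq.count(a) / len(seq) for a in alpha}
    pair_n = len(seq) - 1
    f2: dict[str, float] = {}
    for a, b in itertools.combinations_with_replacement(alpha, 2):
        n = sum(
            1 for i in range(pair_n)
            if "".join(sorted(seq[i:i + 2])) == a + b
        )
        f2[a + b] = n / pair_n
    tri_n = len(seq) - 2
    f3: dict[str, float] = {}
    for a, b, c in itertools.combinations_with_replacement(alpha, 3):
        n = sum(
            1 for i in range(tri_n)
            if "".join(sorted(seq[i:i + 3])) == a + b + c
        )
        f3[a + b + c] = n / tri_n

    def h1(x: str) -> float:
        return _plogp(f1[x])

    def h2(x: str, y: str) -> float:
        return _plogp(f2["".join(sorted(x + y))])

    def i2(x: str, y: str) -> float:
        return h1(x) + h1(y) - h2(x, y)

    names, vals = [], []
    for a, b in itertools.combinations_with_replacement(alpha, 2):
        names.append(f"MMI.{a}{b}")
        vals.append(i2(a, b))
    for a, b, c in itertools.combinations_with_replacement(alpha, 3):
        names.append(f"MMI.{a}{b}{c}")
        cond = h2(a, c) + h2(b, c) - h1(c) - _plogp(f3[a + b + c])
        vals.append(i2(a, b) - cond)
    return names, np.array(vals)


# --------------------------------------------------------------------------
# pseudo k-nucleotide compositions
# --------------------------------------------------------------------------

def _theta_parallel(
    seq: str, panel: dict[str, dict[str, float]], order: int, lam: int
) -> np.ndarray:
    """Parallel correlation factors: mean over properties of the squared
    difference between k-mer property values at separation j."""
    N = len(seq) - order + 1
    tables = list(panel.values())
    thetas = np.zeros(lam)
    for j in range(1, lam + 1):
        s = 0.0
        for i in range(N - j):
            a, b = seq[i:i + order], seq[i + j:i + j + order]
            s += np.mean([(t[a] - t[b]) ** 2 for t in tables])
        thetas[j - 1] = s / (N - j)
    return thetas


def _tau_series(
    seq: str, panel: dict[str, dict[str, float]], order: int, lam: int
) -> tuple[list[str], np.ndarray]:
    """Series correlation factors: per-property products at separation j."""
    N = len(seq) - order + 1
    names, vals = [], []
    for j in range(1, lam + 1):
        for pname, t in panel.items():
            s = sum(
                t[seq[i:i + order]] * t[seq[i + j:i + j + order]]
                for i in range(N - j)
            )
            names.append(f"lam{j}.{pname}")
            vals.append(s / (N - j))
    return names, np.array(vals)


def pseudo_knc(
    seq: str,
    kind: str,
    variant: str,
    lam: int = 2,
    w: float = 0.1,
    k: int = 3,
) -> Vector:
    """The six pseudo nucleotide compositions.

    ``PseDNC``/``PC-PseDNC``/``PC-PseTNC`` use parallel (averaged)
    correlation factors; ``SC-PseDNC``/``SC-PseTNC`` keep per-property
    series terms; ``PseKNC`` combines a 4^k k-mer block with
    dinucleotide parallel correlations.  Parallel variants sum to 1.
    """
    _check(seq, kind)
    variants = {
        "PseDNC": (2, 2, "parallel"),
        "PC-PseDNC": (2, 2, "parallel"),
        "PC-PseTNC": (3, 3, "parallel"),
        "SC-PseDNC": (2, 2, "series"),
        "SC-PseTNC": (3, 3, "series"),
        "PseKNC": (k, 2, "parallel"),
    }
    if variant not in variants:
        raise ValueError(f"unknown pseudo composition {variant!r}")
    comp_k, corr_order, mode = variants[variant]
    panel = _panel(kind, corr_order)
    n_pos = len(seq) - corr_order + 1
    if lam < 0 or lam >= n_pos:
        raise ValueError(f"lambda={lam} too large for sequence")
    _, freqs = kmer(seq, kind, k=comp_k)
    kk = _kmers(kind, comp_k)
    if mode == "parallel":
        thetas = _theta_parallel(seq, panel, corr_order, lam)
        denom = freqs.sum() + w * thetas.sum()
        names = [f"{variant}.{m}" for m in kk] + [
            f"{variant}.lam{j}" for j in range(1, lam + 1)
        ]
        return names, np.concatenate([freqs / denom, w * thetas / denom])
    tau_names, taus = _tau_series(seq, panel, corr_order, lam)
    denom = freqs.sum() + w * np.abs(taus).sum()
    names = [f"{variant}.{m}" for m in kk] + [
        f"{variant}.{n}" for n in tau_names
    ]
    return names, np.concatenate([freqs / denom, w * taus / denom])


# --------------------------------------------------------------------------
# position-specific trinucleotide propensity (needs labelled sets)
# --------------------------------------------------------------------------

def pstnp(seqs: SequenceSet, double_strand: bool = False) -> FeatureMatrix:
    """Position-specific trinucleotide propensity.

    The propensity of trinucleotide t at position j is the difference of
    its positional frequencies between the two label classes of the
    input set itself; each sequence is then encoded by the propensity of
    its observed trinucleotide at every position (L-2 features).  In
    double-strand mode a trinucleotide and its reverse complement share
    a canonical class.
    """
    L = _equal_length(seqs, 3)
    labels = seqs.labels
    if labels is None:
        raise ValueError("PSTNP needs a labelled sequence set")
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError("PSTNP needs exactly 2 classes")
    kind = seqs.kind
    if double_strand and kind != "dna":
        raise ValueError("double-strand PSTNP is DNA-only")

    def canon(t: str) -> str:
        return min(t, reverse_complement(t, kind)) if double_strand else t

    pos_counts = {c: [dict() for _ in range(L - 2)] for c in classes}
    n_by_class = {c: labels.count(c) for c in classes}
    for rec, lab in zip(seqs, labels):
        _check(rec.residues, kind)
        for j in range(L - 2):
            t = canon(rec.residues[j:j + 3])
            d = pos_counts[lab][j]
            d[t] = d.get(t, 0) + 1
    tag = "PSTNPds" if double_strand else "PSTNPss"
    names = [f"{tag}.p{j + 1}" for j in range(L - 2)]
    rows = []
    for rec in seqs:
        row = []
        for j in range(L - 2):
            t = canon(rec.residues[j:j + 3])
            f_pos = pos_counts[classes[1]][j].get(t, 0) / n_by_class[classes[1]]
            f_neg = pos_counts[classes[0]][j].get(t, 0) / n_by_class[classes[0]]
            row.append(f_pos - f_neg)
        rows.append(row)
    return FeatureMatrix(np.array(rows), seqs.ids, names, seqs.labels)


# --------------------------------------------------------------------------
# Z-curve transforms
# --------------------------------------------------------------------------

def _zxyz(counts: dict[str, float], kind: str) -> tuple[float, float, float]:
    t = "T" if kind == "dna" else "U"
    n = sum(counts.values())
    if n == 0:
        return 0.0, 0.0, 0.0
    x = (counts["A"] + counts["G"] - counts["C"] - counts[t]) / n
    y = (counts["A"] + counts["C"] - counts["G"] - counts[t]) / n
    z = (counts["A"] + counts[t] - counts["C"] - counts["G"]) / n
    return x, y, z


def zcurve(seq: str, kind: str, variant: str) -> Vector:
    """Z-curve transforms of cumulative base counts.

    9-bit: phase-specific mononucleotide x/y/z; 12-bit: x/y/z of the
    base following each of the 4 bases; 36-bit: the 12-bit transform per
    codon phase; 48-bit: x/y/z following each of the 16 dinucleotides;
    144-bit: the 48-bit transform per phase.
    """
    _check(seq, kind)
    alpha = _alphabet(kind)
    dims = {"9bit": 9, "12bit": 12, "36bit": 36, "48bit": 48, "144bit": 144}
    if variant not in dims:
        raise ValueError(f"unknown Z-curve variant {variant!r}")
    names: list[str] = []
    vals: list[float] = []

    def counts_for(prefix: str, phase: int | None) -> dict[str, float]:
        lp = len(prefix)
        c = {a: 0.0 for a in alpha}
        for i in range(len(seq) - lp):
            if seq[i:i + lp] == prefix and (phase is None or i % 3 == phase):
                c[seq[i + lp]] += 1
        return c

    if variant == "9bit":
        if len(seq) < 1:
            raise ValueError("empty sequence")
        for phase in range(3):
            sub = seq[phase::3]
            c = {a: float(sub.count(a)) for a in alpha}
            x, y, z = _zxyz(c, kind)
            names += [f"Zcurve9.ph{phase + 1}.{ax}" for ax in "xyz"]
            vals += [x, y, z]
        return names, np.array(vals)

    prefix_len = 1 if variant in {"12bit", "36bit"} else 2
    phased = variant in {"36bit", "144bit"}
    if len(seq) < prefix_len + 1:
        raise ValueError("sequence too short for this Z-curve variant")
    prefixes = _kmers(kind, prefix_len)
    tag = f"Zcurve{dims[variant] // (3 if phased else 1) * (3 if phased else 1)}"
    for phase in (range(3) if phased else [None]):
        for pre in prefixes:
            x, y, z = _zxyz(counts_for(pre, phase), kind)
            ph = f"ph{phase + 1}." if phase is not None else ""
            names += [f"{tag}.{ph}{pre}.{ax}" for ax in "xyz"]
            vals += [x, y, z]
    return names, np.array(vals)


# --------------------------------------------------------------------------
# nearest-neighbour descriptor
# --------------------------------------------------------------------------

def knn_descriptor(
    query: SequenceSet,
    train: SequenceSet,
    k_fractions: Sequence[float] | None = None,
) -> FeatureMatrix:
    """Per-class proportions among the k nearest training sequences,
    ranked by normalized +2/-1 match/mismatch global alignment score."""
    from Bio import Align

    from .protein import DEFAULT_K_FRACTIONS, _knn_matrix

    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 2.0
    al.mismatch_score = -1.0
    al.open_gap_score = -5.0
    al.extend_gap_score = -1.0
    self_score: dict[str, float] = {}

    def sim(a: str, b: str) -> float:
        for s in (a, b):
            if s not in self_score:
                self_score[s] = float(al.score(s, s))
        return 2.0 * float(al.score(a, b)) / (self_score[a] + self_score[b])

    return _knn_matrix(
        query, train, k_fractions or DEFAULT_K_FRACTIONS, sim, "KNN"
    )


# --------------------------------------------------------------------------
# dispatcher
# --------------------------------------------------------------------------

def _per_seq(fn: Callable[..., Vector]) -> Callable[..., FeatureMatrix]:
    def run(seqs: SequenceSet, **params) -> FeatureMatrix:
        names: list[str] | None = None
        rows = []
        for rec in seqs:
            n, v = fn(rec.residues, seqs.kind, **params)
            if names is None:
                names = n
            elif n != names:
                raise ValueError(
                    "descriptor dimensionality varies across sequences"
                )
            rows.append(v)
        assert names is not None
        return FeatureMatrix(np.array(rows), seqs.ids, names, seqs.labels)

    return run


_DISPATCH: dict[str, Callable[..., FeatureMatrix]] = {
    "NAC": lambda seqs, **p: _per_seq(kmer)(seqs, k=1, tag="NAC", **p),
    "DNC": lambda seqs, **p: _per_seq(kmer)(seqs, k=2, tag="DNC", **p),
    "TNC": lambda seqs, **p: _per_seq(kmer)(seqs, k=3, tag="TNC", **p),
    "Kmer": _per_seq(kmer),
    "RCKmer": _per_seq(rckmer),
    "Mismatch": _per_seq(mismatch_profile),
    "Subsequence": _per_seq(subsequence_profile),
    "CKSNAP_type1": _per_seq(cksnap),
    "CKSNAP_type2": lambda seqs, **p: _per_seq(cksnap)(seqs, counts=True, tag="CKSNAP2", **p),
    "ASDC": _per_seq(asdc),
    "ENAC": lambda seqs, window=5: _enac(seqs, window),
    "binary": binary,
    "PS2": ps2,
    "PS3": ps3,
    "PS4": ps4,
    "NCP": ncp,
    "ANF": anf,
    "LPDF": lpdf,
    "DBE": dbe,
    "EIIP": eiip,
    "PseEIIP": _per_seq(pse_eiip),
    "PSTNPss": lambda seqs, **p: pstnp(seqs, double_strand=False, **p),
    "PSTNPds": lambda seqs, **p: pstnp(seqs, double_strand=True, **p),
    "MMI": _per_seq(mmi),
    "Moran": lambda seqs, **p: _per_seq(nuc_autocorrelation)(seqs, variant="Moran", **p),
    "Geary": lambda seqs, **p: _per_seq(nuc_autocorrelation)(seqs, variant="Geary", **p),
    "NMBroto": lambda seqs, **p: _per_seq(nuc_autocorrelation)(seqs, variant="NMBroto", **p),
    "DAC": lambda seqs, **p: _per_seq(nuc_covariance)(seqs, variant="AC", order=2, **p),
    "DCC": lambda seqs, **p: _per_seq(nuc_covariance)(seqs, variant="CC", order=2, **p),
    "DACC": lambda seqs, **p: _per_seq(nuc_covariance)(seqs, variant="ACC", order=2, **p),
    "TAC": lambda seqs, **p: _per_seq(nuc_covariance)(seqs, variant="AC", order=3, **p),
    "TCC": lambda seqs, **p: _per_seq(nuc_covariance)(seqs, variant="CC", order=3, **p),
    "TACC": lambda seqs, **p: _per_seq(nuc_covariance)(seqs, variant="ACC", order=3, **p),
    "DPCP_type1": lambda seqs, **p: _per_seq(kmer_property_composition)(
        seqs, order=2, standardized=False, **p),
    "DPCP_type2": lambda seqs, **p: _per_seq(kmer_property_composition)(
        seqs, order=2, standardized=True, **p),
    "TPCP_type1": lambda seqs, **p: _per_seq(kmer_property_composition)(
        seqs, order=3, standardized=False, **p),
    "TPCP_type2": lambda seqs, **p: _per_seq(kmer_property_composition)(
        seqs, order=3, standardized=True, **p),
    "PseDNC": lambda seqs, **p: _per_seq(pseudo_knc)(seqs, variant="PseDNC", **p),
    "PseKNC": lambda seqs, **p: _per_seq(pseudo_knc)(seqs, variant="PseKNC", **p),
    "PC-PseDNC": lambda seqs, **p: _per_seq(pseudo_knc)(seqs, variant="PC-PseDNC", **p),
    "PC-PseTNC": lambda seqs, **p: _per_seq(pseudo_knc)(seqs, variant="PC-PseTNC", **p),
    "SC-PseDNC": lambda seqs, **p: _per_seq(pseudo_knc)(seqs, variant="SC-PseDNC", **p),
    "SC-PseTNC": lambda seqs, **p: _per_seq(pseudo_knc)(seqs, variant="SC-PseTNC", **p),
    "Z_curve_9bit": lambda seqs, **p: _per_seq(zcurve)(seqs, variant="9bit", **p),
    "Z_curve_12bit": lambda seqs, **p: _per_seq(zcurve)(seqs, variant="12bit", **p),
    "Z_curve_36bit": lambda seqs, **p: _per_seq(zcurve)(seqs, variant="36bit", **p),
    "Z_curve_48bit": lambda seqs, **p: _per_seq(zcurve)(seqs, variant="48bit", **p),
    "Z_curve_144bit": lambda seqs, **p: _per_seq(zcurve)(seqs, variant="144bit", **p),
    "KNN": lambda seqs, train=None, **p: knn_descriptor(
        seqs, train if train is not None else seqs, **p
    ),
}


def _enac(seqs: SequenceSet, window: int = 5) -> FeatureMatrix:
    """Enhanced NAC: sliding-window base composition."""
    L = _equal_length(seqs, window)
    alpha = _alphabet(seqs.kind)
    names = [
        f"ENAC.w{p + 1}.{a}" for p in range(L - window + 1) for a in alpha
    ]
    rows = []
    for rec in seqs:
        _check(rec.residues, seqs.kind)
        row = []
        for p in range(L - window + 1):
            sub = rec.residues[p:p + window]
            row.extend(sub.count(a) / window for a in alpha)
        rows.append(row)
    return FeatureMatrix(np.array(rows), seqs.ids, names, seqs.labels)


#: sets that are meaningful for DNA only
DNA_ONLY = [
    "EIIP", "PseEIIP", "PSTNPds", "TAC", "TCC", "TACC",
    "TPCP_type1", "TPCP_type2", "PC-PseTNC", "SC-PseTNC",
    "Z_curve_48bit", "Z_curve_144bit",
]

DNA_DESCRIPTORS = list(_DISPATCH)
RNA_DESCRIPTORS = [d for d in DNA_DESCRIPTORS if d not in DNA_ONLY]


def compute(seqs: SequenceSet, descriptor: str, **params) -> FeatureMatrix:
    """Compute any registered DNA/RNA descriptor for a sequence set."""
    if seqs.kind not in {"dna", "rna"}:
        raise ValueError(f"nucleic descriptor on {seqs.kind!r} sequences")
    roster = DNA_DESCRIPTORS if seqs.kind == "dna" else RNA_DESCRIPTORS
    if descriptor not in roster:
        raise ValueError(
            f"descriptor {descriptor!r} is not available for {seqs.kind}"
        )
    return _DISPATCH[descriptor](seqs, **params)
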