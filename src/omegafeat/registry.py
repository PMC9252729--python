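"""Descriptor registry: the manifest of every descriptor set.

The roster is version-controlled data: 71 protein, 49 DNA, 37 RNA,
14 structure and 18 ligand descriptor sets (189 in total).  Each entry
records the molecule kind, a category tag, the tunable parameters with
defaults, and (where it is closed-form) the output dimensionality as a
function of parameters and input length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from . import ligand, nucleic, protein, structure
from .reduced import SCHEME_FAMILIES, SCHEME_TAGS

KINDS = ["protein", "dna", "rna", "structure", "ligand"]


@dataclass(frozen=True)
class DescriptorSpec:
    """Manifest entry for one descriptor set."""

    name: str
    kind: str
    category: str
    params: dict = field(default_factory=dict)  # name -> (type, default)
    dim_fn: Callable[[dict, int | None], int | None] | None = None

    def dimension(self, params: dict | None = None, length: int | None = None):
        if self.dim_fn is None:
            return None
        return self.dim_fn({**self.default_params(), **(params or {})}, length)

    def default_params(self) -> dict:
        return {k: v[1] for k, v in self.params.items()}


def _const(n: int):
    return lambda p, L: n


def _specs() -> list[DescriptorSpec]:
    out: list[DescriptorSpec] = []

    def add(name, kind, category, params=None, dim=None):
        out.append(DescriptorSpec(name, kind, category, params or {}, dim))

    gap = {"gap": (int, 3)}
    win = {"window": (int, 5)}
    lagp = {"nlag": (int, protein.DEFAULT_NLAG)}
    nprops = len(protein.DEFAULT_PROPERTIES)

    # ---- protein (71) ----------------------------------------------------
    add("AAC", "protein", "composition", None, _const(20))
    add("EAAC", "protein", "composition", win,
        lambda p, L: None if L is None else 20 * (L - p["window"] + 1))
    for t in ("type1", "type2"):
        add(f"CKSAAP_{t}", "protein", "composition", gap,
            lambda p, L: 400 * (p["gap"] + 1))
        add(f"DPC_{t}", "protein", "composition", None, _const(400))
        add(f"TPC_{t}", "protein", "composition", None, _const(8000))
    add("DDE", "protein", "composition", None, _const(400))
    add("CTDC", "protein", "composition", None, _const(21))
    add("CTDT", "protein", "composition", None, _const(21))
    add("CTDD", "protein", "composition", None, _const(105))
    add("CTriad", "protein", "composition", None, _const(343))
    add("KSCTriad", "protein", "composition", {"gap": (int, 2)},
        lambda p, L: 343 * (p["gap"] + 1))
    add("ASDC", "protein", "composition", None, _const(400))
    add("GAAC", "protein", "grouped_composition", None, _const(5))
    add("EGAAC", "protein", "grouped_composition", win,
        lambda p, L: None if L is None else 5 * (L - p["window"] + 1))
    for t in ("type1", "type2"):
        add(f"CKSAAGP_{t}", "protein", "grouped_composition", gap,
            lambda p, L: 25 * (p["gap"] + 1))
        add(f"GDPC_{t}", "protein", "grouped_composition", None, _const(25))
        add(f"GTPC_{t}", "protein", "grouped_composition", None, _const(125))
    for v in ("Moran", "Geary", "NMBroto"):
        add(v, "protein", "autocorrelation", lagp,
            lambda p, L: nprops * p["nlag"])
    add("AC", "protein", "autocorrelation", lagp,
        lambda p, L: nprops * p["nlag"])
    add("CC", "protein", "autocorrelation", lagp,
        lambda p, L: nprops * (nprops - 1) * p["nlag"])
    add("ACC", "protein", "autocorrelation", lagp,
        lambda p, L: nprops * nprops * p["nlag"])
    add("SOCNumber", "protein", "quasi_sequence_order", lagp,
        lambda p, L: 2 * p["nlag"])
    add("QSOrder", "protein", "quasi_sequence_order",
        {"nlag": (int, protein.DEFAULT_NLAG), "w": (float, 0.1)},
        lambda p, L: 2 * (20 + p["nlag"]))
    add("PAAC", "protein", "pseudo_composition",
        {"lam": (int, None), "w": (float, 0.05)},
        lambda p, L: None if p["lam"] is None else 20 + p["lam"])
    add("APAAC", "protein", "pseudo_composition",
        {"lam": (int, None), "w": (float, 0.05)},
        lambda p, L: None if p["lam"] is None else 20 + 2 * p["lam"])
    for tag in SCHEME_TAGS:
        add(f"PseKRAAC_{tag}", "protein", "psekraac",
            {"cluster_count": (int, 5), "k": (int, 2), "gap": (int, 0)},
            lambda p, L: p["cluster_count"] ** p["k"])
    for enc in protein.RESIDUE_ENCODINGS:
        width = protein.encoding_width(enc)
        add(enc, "protein", "residue_encoding", None,
            (lambda w: lambda p, L: None if L is None else w * L)(width))

    # ---- dna (49) / rna (37) --------------------------------------------
    def add_nuc(name, category, params=None, dim=None):
        add(name, "dna", category, params, dim)
        if name not in nucleic.DNA_ONLY:
            add(name, "rna", category, params, dim)

    lagn = {"nlag": (int, nucleic.DEFAULT_NLAG)}
    add_nuc("NAC", "composition", None, _const(4))
    add_nuc("DNC", "composition", None, _const(16))
    add_nuc("TNC", "composition", None, _const(64))
    add_nuc("Kmer", "composition", {"k": (int, 3)},
            lambda p, L: 4 ** p["k"])
    add_nuc("RCKmer", "composition", {"k": (int, 3)}, None)
    add_nuc("Mismatch", "composition", {"k": (int, 3), "m": (int, 1)},
            lambda p, L: 4 ** p["k"])
    add_nuc("Subsequence", "composition", {"k": (int, 2), "delta": (float, 1.0)},
            _const(16))
    add_nuc("CKSNAP_type1", "composition", gap,
            lambda p, L: 16 * (p["gap"] + 1))
    add_nuc("CKSNAP_type2", "composition", gap,
            lambda p, L: 16 * (p["gap"] + 1))
    add_nuc("ASDC", "composition", None, _const(16))
    add_nuc("ENAC", "composition", win,
            lambda p, L: None if L is None else 4 * (L - p["window"] + 1))
    add_nuc("binary", "position_encoding", None,
            lambda p, L: None if L is None else 4 * L)
    add_nuc("PS2", "position_encoding", None,
            lambda p, L: None if L is None else 16 * (L - 1))
    add_nuc("PS3", "position_encoding", None,
            lambda p, L: None if L is None else 64 * (L - 2))
    add_nuc("PS4", "position_encoding", None,
            lambda p, L: None if L is None else 256 * (L - 3))
    add_nuc("NCP", "position_encoding", None,
            lambda p, L: None if L is None else 3 * L)
    add_nuc("ANF", "position_encoding", None, lambda p, L: L)
    add_nuc("LPDF", "position_encoding", None,
            lambda p, L: None if L is None else L - 1)
    add_nuc("DBE", "position_encoding", None,
            lambda p, L: None if L is None else 4 * (L - 1))
    add_nuc("EIIP", "eiip", None, lambda p, L: L)
    add_nuc("PseEIIP", "eiip", None, _const(64))
    add_nuc("PSTNPss", "propensity", None,
            lambda p, L: None if L is None else L - 2)
    add_nuc("PSTNPds", "propensity", None,
            lambda p, L: None if L is None else L - 2)
    add_nuc("MMI", "mutual_information", None, _const(30))
    for v in ("Moran", "Geary", "NMBroto"):
        add_nuc(v, "autocorrelation", lagn, lambda p, L: 3 * p["nlag"])
    add_nuc("DAC", "autocorrelation", lagn, lambda p, L: 3 * p["nlag"])
    add_nuc("DCC", "autocorrelation", lagn, lambda p, L: 6 * p["nlag"])
    add_nuc("DACC", "autocorrelation", lagn, lambda p, L: 9 * p["nlag"])
    add_nuc("TAC", "autocorrelation", lagn, lambda p, L: 3 * p["nlag"])
    add_nuc("TCC", "autocorrelation", lagn, lambda p, L: 6 * p["nlag"])
    add_nuc("TACC", "autocorrelation", lagn, lambda p, L: 9 * p["nlag"])
    add_nuc("DPCP_type1", "physicochemical", None, _const(48))
    add_nuc("DPCP_type2", "physicochemical", None, _const(48))
    add_nuc("TPCP_type1", "physicochemical", None, _const(192))
    add_nuc("TPCP_type2", "physicochemical", None, _const(192))
    pse = {"lam": (int, 2), "w": (float, 0.1)}
    add_nuc("PseDNC", "pseudo_composition", pse, lambda p, L: 16 + p["lam"])
    add_nuc("PseKNC", "pseudo_composition", {**pse, "k": (int, 3)},
            lambda p, L: 4 ** p["k"] + p["lam"])
    add_nuc("PC-PseDNC", "pseudo_composition", pse, lambda p, L: 16 + p["lam"])
    add_nuc("PC-PseTNC", "pseudo_composition", pse, lambda p, L: 64 + p["lam"])
    add_nuc("SC-PseDNC", "pseudo_composition", pse,
            lambda p, L: 16 + 3 * p["lam"])
    add_nuc("SC-PseTNC", "pseudo_composition", pse,
            lambda p, L: 64 + 3 * p["lam"])
    for v in ("9bit", "12bit", "36bit", "48bit", "144bit"):
        add_nuc(f"Z_curve_{v}", "zcurve", None, _const(int(v[:-3])))
    add_nuc("KNN", "similarity", None, None)

    # ---- structure (14) --------------------------------------------------
    shell_dim = lambda cats: (
        lambda p, L: cats * structure.ShellScheme().n
    )
    for t in ("type1", "type2"):
        add(f"AAC_{t}", "structure", "shell_composition", None, shell_dim(20))
        add(f"GAAC_{t}", "structure", "shell_composition", None, shell_dim(5))
        add(f"SS3_{t}", "structure", "secondary_structure", None, shell_dim(3))
        add(f"SS8_{t}", "structure", "secondary_structure", None, shell_dim(8))
        add(f"AC_{t}", "structure", "atom_composition", None, shell_dim(5))
    add("HSE_CB", "structure", "exposure", {"radius": (float, 13.0)}, _const(2))
    add("HSE_PseudoCB", "structure", "exposure", {"radius": (float, 13.0)},
        _const(2))
    add("ResidueDepth", "structure", "depth",
        {"probe_radius": (float, 1.4), "n_points": (int, 960)}, _const(1))
    add("NetworkIndex", "structure", "network", {"cutoff": (float, 8.0)},
        _const(6))

    # ---- ligand (18) -----------------------------------------------------
    block_dims = {
        "constitution": 23, "topology": 9, "connectivity": 12, "kappa": 5,
        "estate": 5, "basak": 5, "burden": 8, "pharmacophore": 6,
        "moran": 32, "geary": 32, "moreau_broto": 32, "charge": 8,
        "property": 8, "moe": 47,
    }
    for name, dim in block_dims.items():
        add(name, "ligand", "descriptor_block", None, _const(dim))
    add("maccs", "ligand", "fingerprint", None, _const(166))
    add("morgan", "ligand", "fingerprint",
        {"radius": (int, 2), "n_bits": (int, 2048)},
        lambda p, L: p["n_bits"])
    add("estate_fp", "ligand", "fingerprint", None, _const(79))
    add("topological_fp", "ligand", "fingerprint", {"n_bits": (int, 2048)},
        lambda p, L: p["n_bits"])
    return out


_REGISTRY: list[DescriptorSpec] = _specs()

_EXPECTED = {"protein": 71, "dna": 49, "rna": 37, "structure": 14, "ligand": 18}
for _k, _n in _EXPECTED.items():
    _got = sum(1 for s in _REGISTRY if s.kind == _k)
    if _got != _n:  # pragma: no cover - manifest self-check
        raise RuntimeError(f"manifest mismatch for {_k}: {_got} != {_n}")

#: number of PseKRAAC reduction families exposed
N_PSEKRAAC_FAMILIES = len(SCHEME_FAMILIES)


def registry_list(kind: str | None = None) -> list[DescriptorSpec]:
    """All descriptor specs, optionally filtered by kind, in manifest order."""
    if kind is None:
        return list(_REGISTRY)
    if kind not in KINDS:
        raise ValueError(f"unknown kind {kind!r}")
    return [s for s in _REGISTRY if s.kind == kind]


def registry_counts() -> dict[str, int]:
    counts = {k: len(registry_list(k)) for k in KINDS}
    counts["total"] = len(_REGISTRY)
    return counts


def get_spec(name: str, kind: str) -> DescriptorSpec:
    for s in _REGISTRY:
        if s.name == name and s.kind == kind:
            return s
    raise KeyError(f"no descriptor {name!r} for kind {kind!r}")
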