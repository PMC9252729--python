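"""Protein-structure descriptor sets.

Fourteen descriptor sets over a parsed 3-D model: residue and grouped
residue compositions in concentric shells around each target site
(per-shell "type1" and cumulative "type2"), secondary-structure shell
compositions (3- and 8-state), half-sphere exposure in two side-chain
conventions, residue depth from a sampled solvent-accessible surface,
atom-type shell compositions, and residue contact-network indices.

Secondary structure is assigned internally with the classic
hydrogen-bond electrostatic model (no external binary); the
solvent-accessible surface is a sampled-sphere (Shrake-Rupley style)
approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .records import FeatureMatrix
from .tables import (
    AA3TO1,
    AA,
    AA_TO_FIVE_GROUP,
    FIVE_GROUP_NAMES,
    VDW_DEFAULT,
    VDW_RADII,
)

# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------


@dataclass
class Residue:
    chain: str
    seqnum: int
    icode: str
    name: str  # 3-letter
    atoms: dict[str, tuple[str, np.ndarray]] = field(default_factory=dict)
    cb_synthesized: bool = False

    @property
    def one_letter(self) -> str:
        return AA3TO1.get(self.name, "X")

    @property
    def key(self) -> str:
        ic = self.icode.strip()
        return f"{self.chain}{self.seqnum}{ic}"

    def coord(self, atom: str) -> np.ndarray | None:
        entry = self.atoms.get(atom)
        return None if entry is None else entry[1]

    @property
    def ca(self) -> np.ndarray | None:
        return self.coord("CA")

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C", "O"))


@dataclass
class StructureModel:
    """First-model, altloc-resolved view of a PDB/mmCIF structure."""

    residues: list[Residue]
    het_atoms: list[tuple[str, str, np.ndarray]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def keys(self) -> list[str]:
        return [r.key for r in self.residues]

    def ca_coords(self) -> np.ndarray:
        return np.array(
            [r.ca if r.ca is not None else [np.nan] * 3 for r in self.residues]
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-motion copy (used to verify descriptor invariance)."""
        res = []
        for r in self.residues:
            rr = Residue(r.chain, r.seqnum, r.icode, r.name, {}, r.cb_synthesized)
            for name, (el, xyz) in r.atoms.items():
                rr.atoms[name] = (el, rotation @ xyz + translation)
            res.append(rr)
        het = [
            (n, el, rotation @ xyz + translation)
            for n, el, xyz in self.het_atoms
        ]
        return StructureModel(res, het)


def _pseudo_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral Cbeta from backbone N, CA, C."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return ca - 0.58273431 * a + 0.56802827 * b - 0.54067466 * cc


def parse_structure(source: str) -> StructureModel:
    """Parse PDB or mmCIF content into a :class:`StructureModel`.

    ``source`` is a file path, or raw PDB text (detected by a newline).
    Only the first model is kept; alternate locations resolve to the
    highest occupancy (ties prefer altloc 'A'); waters and hetero
    residues are excluded from the residue list but their atoms are
    retained for site centering.
    """
    import gemmi

    if "\n" in source:
        st = gemmi.read_pdb_string(source)
    else:
        st = gemmi.read_structure(source)
    if len(st) == 0:
        raise ValueError("structure contains no models")
    model = st[0]
    residues: list[Residue] = []
    het: list[tuple[str, str, np.ndarray]] = []
    for chain in model:
        for res in chain:
            is_aa = res.name in AA3TO1
            if res.is_water():
                continue
            target = None
            if is_aa:
                target = Residue(
                    chain.name, res.seqid.num, res.seqid.icode or " ", res.name
                )
            # altloc resolution: per atom name keep highest occupancy,
            # ties prefer 'A' (then first seen)
            best: dict[str, tuple[float, str, "gemmi.Atom"]] = {}
            for atom in res:
                alt = atom.altloc or ""
                rank = (atom.occ, "A" if alt in ("", "A") else "")
                cur = best.get(atom.name)
                if cur is None or rank > (cur[0], cur[1]):
                    best[atom.name] = (rank[0], rank[1], atom)
            for name, (_, _, atom) in best.items():
                xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                el = atom.element.name.upper()
                if target is not None:
                    target.atoms[name] = (el, xyz)
                else:
                    het.append((name, el, xyz))
            if target is not None:
                if not np.isfinite(
                    np.concatenate([v for _, v in target.atoms.values()])
                ).all():
                    raise ValueError(f"non-finite coordinates in {target.key}")
                if "CB" not in target.atoms and all(
                    a in target.atoms for a in ("N", "CA", "C")
                ):
                    cb = _pseudo_cb(
                        target.coord("N"), target.coord("CA"), target.coord("C")
                    )
                    target.atoms["CB"] = ("C", cb)
                    target.cb_synthesized = True
                residues.append(target)
    if not residues:
        raise ValueError("no protein residues in structure")
    return StructureModel(residues, het)


# --------------------------------------------------------------------------
# shells
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ShellScheme:
    """Concentric half-open shells [r0+(s-1)*delta, r0+s*delta)."""

    r0: float = 0.0
    delta: float = 2.0
    n: int = 15

    def __post_init__(self) -> None:
        if self.r0 < 0 or self.delta <= 0 or self.n < 1:
            raise ValueError("invalid shell scheme")

    def shell_of(self, d: float) -> int | None:
        """0-based shell index of distance d, or None if outside."""
        if d < self.r0:
            return None
        s = int(math.floor((d - self.r0) / self.delta))
        return s if s < self.n else None


def resolve_targets(
    model: StructureModel, targets
) -> list[tuple[str, np.ndarray, int | None]]:
    """Normalize target specs to (label, site, excluded-residue-index).

    Accepted: None (all residues, Calpha centers), residue key strings
    like ``A12``/``chain:resnum``, or explicit (x, y, z) triples.
    """
    if targets is None:
        out = []
        for i, r in enumerate(model.residues):
            if r.ca is None:
                continue
            out.append((r.key, r.ca, i))
        if not out:
            raise ValueError("no Calpha atoms in model")
        return out
    keys = {r.key: i for i, r in enumerate(model.residues)}
    out = []
    for t in targets:
        if isinstance(t, str):
            k = t.replace(":", "")
            if k not in keys:
                raise ValueError(f"target residue {t!r} not in model")
            i = keys[k]
            ca = model.residues[i].ca
            if ca is None:
                raise ValueError(f"target residue {t!r} has no Calpha")
            out.append((k, ca, i))
        else:
            xyz = np.asarray(t, dtype=float)
            if xyz.shape != (3,):
                raise ValueError(f"bad target site {t!r}")
            out.append((f"site({xyz[0]:g},{xyz[1]:g},{xyz[2]:g})", xyz, None))
    return out


def _shell_category_counts(
    model: StructureModel,
    site: np.ndarray,
    exclude: int | None,
    scheme: ShellScheme,
    categories: list[str],
    cat_of: list[str | None],
) -> np.ndarray:
    """(n_shells x n_categories) counts of residues by Calpha shell."""
    counts = np.zeros((scheme.n, len(categories)))
    idx = {c: j for j, c in enumerate(categories)}
    for i, r in enumerate(model.residues):
        if i == exclude or r.ca is None or cat_of[i] is None:
            continue
        s = scheme.shell_of(float(np.linalg.norm(r.ca - site)))
        if s is not None:
            counts[s, idx[cat_of[i]]] += 1
    return counts


def _counts_to_features(
    counts: np.ndarray, categories: list[str], mode: str, tag: str
) -> tuple[list[str], np.ndarray]:
    if mode == "type2":
        counts = np.cumsum(counts, axis=0)
    names, vals = [], []
    for s in range(counts.shape[0]):
        total = counts[s].sum()
        block = counts[s] / total if total > 0 else np.zeros(len(categories))
        names.extend(f"{tag}.s{s + 1}.{c}" for c in categories)
        vals.extend(block)
    return names, np.array(vals)


def shell_residue_composition(
    model: StructureModel,
    targets=None,
    scheme: ShellScheme = ShellScheme(),
    mode: str = "type1",
    grouping: str = "aa",
) -> FeatureMatrix:
    """Residue-type composition per shell (type1) or cumulative shell
    (type2), over the 20 amino acids or the five physicochemical groups.
    The target residue itself is excluded; empty shells give zero blocks."""
    if mode not in {"type1", "type2"}:
        raise ValueError(f"unknown shell mode {mode!r}")
    if grouping == "aa":
        categories = list(AA)
        cat_of = [
            r.one_letter if r.one_letter in AA else None for r in model.residues
        ]
        tag = f"AAC_{mode}"
    elif grouping == "group5":
        categories = FIVE_GROUP_NAMES
        cat_of = [
            AA_TO_FIVE_GROUP.get(r.one_letter) for r in model.residues
        ]
        tag = f"GAAC_{mode}"
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rows, ids = [], []
    names: list[str] | None = None
    for label, site, exclude in resolve_targets(model, targets):
        counts = _shell_category_counts(
            model, site, exclude, scheme, categories, cat_of
        )
        names, vals = _counts_to_features(counts, categories, mode, tag)
        rows.append(vals)
        ids.append(label)
    assert names is not None
    return FeatureMatrix(np.array(rows), ids, names)


# --------------------------------------------------------------------------
# secondary structure (hydrogen-bond electrostatic model)
# --------------------------------------------------------------------------

_HB_CUTOFF = -0.5  # kcal/mol


def _hbond_energy(
    n: np.ndarray, h: np.ndarray, c: np.ndarray, o: np.ndarray
) -> float:
    """E = 0.084 * 332 * (1/rON + 1/rCH - 1/rOH - 1/rCN) kcal/mol."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing placement
        return -9.9
    return 0.084 * 332.0 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)


def assign_secondary_structure(
    model: StructureModel,
) -> tuple[list[str], list[str]]:
    """Per-residue 8-state and 3-state secondary structure labels.

    Hydrogen bonds follow the classic electrostatic model (bond if
    E < -0.5 kcal/mol); n-turn patterns yield G/H/I helices, bridge
    patterns yield B/E strands, turns T, bends S (kappa > 70 deg),
    otherwise '-'.  Residues with missing backbone atoms are labelled
    '-'.  The 3-state collapse is H,G,I -> H; E,B -> E; rest -> C.
    """
    res = model.residues
    n = len(res)
    ok = [r.has_backbone() for r in res]
    # amide H estimated from the previous residue's C=O direction
    h_pos: list[np.ndarray | None] = [None] * n
    for i in range(n):
        if not ok[i]:
            continue
        if i > 0 and ok[i - 1] and res[i - 1].chain == res[i].chain:
            co = res[i - 1].coord("C") - res[i - 1].coord("O")
            h_pos[i] = res[i].coord("N") + co / np.linalg.norm(co)

    def hbond(donor: int, acceptor: int) -> bool:
        """N-H of *donor* to C=O of *acceptor*."""
        if not (0 <= donor < n and 0 <= acceptor < n):
            return False
        if not (ok[donor] and ok[acceptor]) or h_pos[donor] is None:
            return False
        if abs(donor - acceptor) < 2 and res[donor].chain == res[acceptor].chain:
            return False
        e = _hbond_energy(
            res[donor].coord("N"), h_pos[donor],
            res[acceptor].coord("C"), res[acceptor].coord("O"),
        )
        return e < _HB_CUTOFF

    turn = {k: [False] * n for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(n - k):
            turn[k][i] = hbond(i + k, i)

    def helix_at(k: int, i: int) -> bool:
        return i >= 1 and turn[k][i - 1] and turn[k][i]

    bridge = [False] * n
    strand = [False] * n
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hbond(i, j - 1) and hbond(j + 1, i)) or (
                hbond(j, i - 1) and hbond(i + 1, j)
            )
            anti = (hbond(i, j) and hbond(j, i)) or (
                hbond(i + 1, j - 1) and hbond(j + 1, i - 1)
            )
            if para or anti:
                bridge[i] = bridge[j] = True
    for i in range(n):
        if bridge[i] and (
            (i > 0 and bridge[i - 1]) or (i + 1 < n and bridge[i + 1])
        ):
            strand[i] = True

    in_turn = [False] * n
    for k in (3, 4, 5):
        for i in range(n - k):
            if turn[k][i]:
                for j in range(i + 1, i + k):
                    in_turn[j] = True

    eight: list[str] = []
    for i in range(n):
        if not ok[i]:
            eight.append("-")
            continue
        if helix_at(4, i):
            eight.append("H")
        elif strand[i]:
            eight.append("E")
        elif bridge[i]:
            eight.append("B")
        elif helix_at(3, i):
            eight.append("G")
        elif helix_at(5, i):
            eight.append("I")
        elif in_turn[i]:
            eight.append("T")
        else:
            # bend: kappa angle CA(i-2), CA(i), CA(i+2) > 70 degrees
            bend = False
            if 2 <= i < n - 2 and all(
                res[j].ca is not None for j in (i - 2, i, i + 2)
            ):
                v1 = res[i].ca - res[i - 2].ca
                v2 = res[i + 2].ca - res[i].ca
                cosang = np.dot(v1, v2) / (
                    np.linalg.norm(v1) * np.linalg.norm(v2)
                )
                bend = math.degrees(math.acos(np.clip(cosang, -1, 1))) > 70
            eight.append("S" if bend else "-")
    three = [
        "H" if s in "HGI" else "E" if s in "EB" else "C" for s in eight
    ]
    return eight, three


SS8_STATES = list("HBEGITS-")
SS3_STATES = list("HEC")


def ss_shell_composition(
    model: StructureModel,
    targets=None,
    scheme: ShellScheme = ShellScheme(),
    states: int = 3,
    mode: str = "type1",
) -> FeatureMatrix:
    """Secondary-structure-state composition per (cumulative) shell."""
    if states not in {3, 8}:
        raise ValueError("states must be 3 or 8")
    eight, three = assign_secondary_structure(model)
    labels = three if states == 3 else eight
    categories = SS3_STATES if states == 3 else SS8_STATES
    tag = f"SS{states}_{mode}"
    rows, ids = [], []
    names: list[str] | None = None
    for label, site, exclude in resolve_targets(model, targets):
        counts = _shell_category_counts(
            model, site, exclude, scheme, categories, list(labels)
        )
        names, vals = _counts_to_features(counts, categories, mode, tag)
        rows.append(vals)
        ids.append(label)
    assert names is not None
    return FeatureMatrix(np.array(rows), ids, names)


# --------------------------------------------------------------------------
# half-sphere exposure
# --------------------------------------------------------------------------

def half_sphere_exposure(
    model: StructureModel, radius: float = 13.0, variant: str = "CB"
) -> FeatureMatrix:
    """(HSE_up, HSE_down) neighbour counts within ``radius`` angstroms.

    ``CB`` uses the observed (or glycine-synthesized) Cbeta direction;
    ``PseudoCB`` rebuilds an ideal Cbeta from backbone geometry for
    every residue.  up + down equals the plain neighbour count.
    """
    if variant not in {"CB", "PseudoCB"}:
        raise ValueError(f"unknown HSE variant {variant!r}")
    res = [r for r in model.residues if r.ca is not None]
    cas = np.array([r.ca for r in res])
    rows, ids = [], []
    for i, r in enumerate(res):
        if variant == "CB":
            cb = r.coord("CB")
        else:
            if all(a in r.atoms for a in ("N", "CA", "C")):
                cb = _pseudo_cb(r.coord("N"), r.coord("CA"), r.coord("C"))
            else:
                cb = None
        up = down = 0
        if cb is not None:
            direction = cb - r.ca
            d = np.linalg.norm(cas - r.ca, axis=1)
            for j in np.nonzero((d <= radius) & (d > 0))[0]:
                if np.dot(cas[j] - r.ca, direction) > 0:
                    up += 1
                else:
                    down += 1
        rows.append([float(up), float(down)])
        ids.append(r.key)
    tag = f"HSE_{variant}"
    return FeatureMatrix(np.array(rows), ids, [f"{tag}.up", f"{tag}.down"])


# --------------------------------------------------------------------------
# residue depth
# --------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic Fibonacci-lattice unit sphere points."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0, 1))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def residue_depth(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> FeatureMatrix:
    """Mean atom distance to the sampled solvent-accessible surface.

    The surface is approximated by points on each atom's van-der-Waals
    sphere expanded by the probe radius, with points buried inside any
    other expanded sphere removed.  An atom's depth is the distance to
    the nearest accessible point minus its own expanded radius, clamped
    at 0; residue depth averages over the residue's atoms.
    """
    atoms: list[tuple[int, np.ndarray, float]] = []
    for i, r in enumerate(model.residues):
        for name, (el, xyz) in r.atoms.items():
            if el == "H":
                continue
            atoms.append((i, xyz, VDW_RADII.get(el, VDW_DEFAULT)))
    if not atoms:
        raise ValueError("no atoms in model")
    coords = np.array([a[1] for a in atoms])
    radii = np.array([a[2] for a in atoms]) + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    surface: list[np.ndarray] = []
    for k in range(len(atoms)):
        pts = coords[k] + radii[k] * unit
        neigh = [
            j for j in tree.query_ball_point(coords[k], radii[k] + radii.max())
            if j != k
        ]
        if neigh:
            d = np.linalg.norm(
                pts[:, None, :] - coords[neigh][None, :, :], axis=2
            )
            keep = (d >= radii[neigh][None, :] - 1e-9).all(axis=1)
            pts = pts[keep]
        if len(pts):
            surface.append(pts)
    if not surface:  # fully buried pathological case
        surf = coords
    else:
        surf = np.vstack(surface)
    stree = cKDTree(surf)
    dmin, _ = stree.query(coords)
    depth_atom = np.clip(dmin - radii, 0.0, None)
    rows, ids = [], []
    for i, r in enumerate(model.residues):
        mine = [d for (ri, _, _), d in zip(atoms, depth_atom) if ri == i]
        rows.append([float(np.mean(mine))] if mine else [0.0])
        ids.append(r.key)
    return FeatureMatrix(np.array(rows), ids, ["ResidueDepth.depth"])


# --------------------------------------------------------------------------
# atom shell composition
# --------------------------------------------------------------------------

ATOM_TYPES = ["C", "N", "O", "S", "other"]


def atom_shell_composition(
    model: StructureModel,
    targets=None,
    scheme: ShellScheme = ShellScheme(),
    mode: str = "type1",
) -> FeatureMatrix:
    """Element-type composition ({C,N,O,S,other}) per (cumulative) shell
    around each target site.  Default targets: every residue's Calpha."""
    if mode not in {"type1", "type2"}:
        raise ValueError(f"unknown shell mode {mode!r}")
    all_atoms: list[tuple[np.ndarray, str]] = []
    for r in model.residues:
        for name, (el, xyz) in r.atoms.items():
            if el == "H":
                continue
            t = el if el in ATOM_TYPES else "other"
            all_atoms.append((xyz, t))
    tag = f"AC_{mode}"
    rows, ids = [], []
    names: list[str] | None = None
    for label, site, _ in resolve_targets(model, targets):
        counts = np.zeros((scheme.n, len(ATOM_TYPES)))
        for xyz, t in all_atoms:
            d = float(np.linalg.norm(xyz - site))
            if d == 0.0:
                continue  # the target atom itself
            s = scheme.shell_of(d)
            if s is not None:
                counts[s, ATOM_TYPES.index(t)] += 1
        names, vals = _counts_to_features(counts, ATOM_TYPES, mode, tag)
        rows.append(vals)
        ids.append(label)
    assert names is not None
    return FeatureMatrix(np.array(rows), ids, names)


# --------------------------------------------------------------------------
# residue contact network
# --------------------------------------------------------------------------

NETWORK_METRICS = [
    "degree", "degree_centrality", "betweenness",
    "clustering_coefficient", "closeness", "eigenvector_centrality",
]


def network_indices(model: StructureModel, cutoff: float = 8.0) -> FeatureMatrix:
    """Per-residue graph metrics of the Calpha contact network.

    Nodes are residues; an edge joins residues whose Calpha atoms lie
    within ``cutoff`` angstroms.  The sixth metric ("centrality") is
    eigenvector centrality of the adjacency matrix.
    """
    import networkx as nx

    res = [r for r in model.residues if r.ca is not None]
    n = len(res)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    cas = np.array([r.ca for r in res])
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(cas[i] - cas[j]) <= cutoff:
                g.add_edge(i, j)
    if n == 1 or g.number_of_edges() == 0:
        vals = np.zeros((n, 6))
    else:
        deg = dict(g.degree())
        degc = nx.degree_centrality(g)
        btw = nx.betweenness_centrality(g, normalized=True)
        clus = nx.clustering(g)
        clo = nx.closeness_centrality(g)
        adj = nx.to_numpy_array(g, nodelist=range(n))
        w, v = np.linalg.eigh(adj)
        ev = np.abs(v[:, int(np.argmax(w))])
        ev = ev / np.linalg.norm(ev)
        vals = np.array([
            [deg[i], degc[i], btw[i], clus[i], clo[i], ev[i]]
            for i in range(n)
        ])
    names = [f"NetworkIndex.{m}" for m in NETWORK_METRICS]
    return FeatureMatrix(vals, [r.key for r in res], names)


# --------------------------------------------------------------------------
# dispatcher
# --------------------------------------------------------------------------

_DISPATCH = {
    "AAC_type1": lambda m, **p: shell_residue_composition(m, mode="type1", grouping="aa", **p),
    "AAC_type2": lambda m, **p: shell_residue_composition(m, mode="type2", grouping="aa", **p),
    "GAAC_type1": lambda m, **p: shell_residue_composition(m, mode="type1", grouping="group5", **p),
    "GAAC_type2": lambda m, **p: shell_residue_composition(m, mode="type2", grouping="group5", **p),
    "SS3_type1": lambda m, **p: ss_shell_composition(m, states=3, mode="type1", **p),
    "SS3_type2": lambda m, **p: ss_shell_composition(m, states=3, mode="type2", **p),
    "SS8_type1": lambda m, **p: ss_shell_composition(m, states=8, mode="type1", **p),
    "SS8_type2": lambda m, **p: ss_shell_composition(m, states=8, mode="type2", **p),
    "HSE_CB": lambda m, **p: half_sphere_exposure(m, variant="CB", **p),
    "HSE_PseudoCB": lambda m, **p: half_sphere_exposure(m, variant="PseudoCB", **p),
    "ResidueDepth": residue_depth,
    "AC_type1": lambda m, **p: atom_shell_composition(m, mode="type1", **p),
    "AC_type2": lambda m, **p: atom_shell_composition(m, mode="type2", **p),
    "NetworkIndex": network_indices,
}

STRUCTURE_DESCRIPTORS = list(_DISPATCH)


def compute(model: StructureModel, descriptor: str, **params) -> FeatureMatrix:
    """Compute any registered structure descriptor."""
    try:
        fn = _DISPATCH[descriptor]
    except KeyError:
        raise ValueError(f"unknown structure descriptor {descriptor!r}") from None
    return fn(model, **params)
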