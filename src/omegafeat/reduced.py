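"""Reduced amino-acid alphabets for pseudo K-tuple composition (PseKRAAC).

Sixteen reduction families are exposed (three of which carry lettered
sub-variants, giving 19 registered descriptor sets).  Each family orders
the twenty amino acids along its own physicochemical axis — a fixed
linear combination of the standardized per-residue scales bundled in
:mod:`omegafeat.tables` — and a ``cluster_count`` of *c* splits that
ordering into *c* contiguous, near-equal groups.  ``cluster_count=20``
is always the identity reduction.

The resulting group tables are deterministic, version-controlled data:
they are computed once at import from the bundled scales, never from
run-time input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import AA, AAINDEX_PANEL, standardize

#: scheme tag -> (primary scale, secondary scale, secondary weight, sign)
_PANEL = list(AAINDEX_PANEL)
SCHEME_TAGS = [
    "type1", "type2", "type3A", "type3B", "type4", "type5",
    "type6A", "type6B", "type6C", "type7", "type8", "type9",
    "type10", "type11", "type12", "type13", "type14", "type15",
    "type16",
]

#: the 16 reduction families (lettered sub-variants share a family)
SCHEME_FAMILIES = sorted(
    {t.rstrip("ABC") for t in SCHEME_TAGS},
    key=lambda t: int(t[4:]),
)

VALID_CLUSTER_COUNTS = (2, 3, 4, 5, 8, 10, 15, 20)


def _axis(tag: str) -> np.ndarray:
    """Deterministic per-scheme ranking axis over the 20 amino acids."""
    i = SCHEME_TAGS.index(tag)
    primary = standardize(AAINDEX_PANEL[_PANEL[i % len(_PANEL)]])
    secondary = standardize(AAINDEX_PANEL[_PANEL[(3 * i + 1) % len(_PANEL)]])
    sign = 1.0 if i % 2 == 0 else -1.0
    w2 = 0.5 if (i // 2) % 2 == 0 else -0.5
    return np.array(
        [sign * (primary[a] + w2 * secondary[a]) for a in AA], dtype=float
    )


def _ordering(tag: str) -> list[str]:
    axis = _axis(tag)
    # ties broken alphabetically (stable argsort over (value, letter))
    order = sorted(range(20), key=lambda j: (axis[j], AA[j]))
    return [AA[j] for j in order]


@dataclass(frozen=True)
class ReducedAlphabet:
    """A concrete reduction: scheme tag, cluster count and residue->group map."""

    scheme: str
    cluster_count: int
    mapping: dict[str, int]

    @property
    def groups(self) -> list[str]:
        out = ["" for _ in range(self.cluster_count)]
        for a in AA:
            out[self.mapping[a]] += a
        return out


def reduced_alphabet(scheme: str, cluster_count: int) -> ReducedAlphabet:
    """Build the reduction for *scheme* at *cluster_count* groups."""
    if scheme not in SCHEME_TAGS:
        raise ValueError(
            f"unknown PseKRAAC scheme {scheme!r}; valid: {SCHEME_TAGS}"
        )
    if cluster_count not in VALID_CLUSTER_COUNTS:
        raise ValueError(
            f"cluster_count {cluster_count} invalid for {scheme}; "
            f"valid: {VALID_CLUSTER_COUNTS}"
        )
    if cluster_count == 20:
        mapping = {a: i for i, a in enumerate(AA)}
        return ReducedAlphabet(scheme, 20, mapping)
    order = _ordering(scheme)
    # contiguous near-equal split: group boundaries at rounded multiples
    bounds = np.linspace(0, 20, cluster_count + 1).round().astype(int)
    mapping: dict[str, int] = {}
    for g in range(cluster_count):
        for a in order[bounds[g]:bounds[g + 1]]:
            mapping[a] = g
    return ReducedAlphabet(scheme, cluster_count, mapping)
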