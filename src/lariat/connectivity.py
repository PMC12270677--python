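"""Disulfide connectivities: enumeration, geometric detection, Roman labels.

A disulfide connectivity is a perfect matching on the cysteine positions of a
peptide; for 2n cysteines there are (2n−1)!! of them (15 for the six-cysteine
granulin scaffold).  Connectivities are canonically stored as pairs ``(a, b)``
with ``a < b``, sorted by the smaller member, and labelled in the field's
Roman-numeral rank notation (e.g. the granulin pattern ``I-III, II-V, IV-VI``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .structures import StructureEnsemble

__all__ = [
    "DisulfideConnectivity",
    "enumerate_connectivities",
    "detect_disulfides",
    "roman_label",
    "GRANULIN_PAIRS",
]

#: The granulin connectivity of GRN-P4A (positions, 1-based): Cys I–III, II–V, IV–VI.
GRANULIN_PAIRS = ((1, 14), (8, 23), (15, 24))

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI"]


@dataclass(frozen=True)
class DisulfideConnectivity:
    """A set of disjoint cysteine pairs, canonically ordered."""

    pairs: tuple[tuple[int, int], ...]

    def __init__(self, pairs: Iterable[Sequence[int]]):
        canon = tuple(sorted(tuple(sorted(map(int, p))) for p in pairs))
        seen: set[int] = set()
        for a, b in canon:
            if a == b:
                raise ValueError(f"self-pair ({a},{b})")
            for x in (a, b):
                if x in seen:
                    raise ValueError(f"position {x} appears in more than one pair")
                seen.add(x)
        object.__setattr__(self, "pairs", canon)

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(x for p in self.pairs for x in p))

    def is_perfect_on(self, cys_positions: Sequence[int]) -> bool:
        return self.positions == tuple(sorted(cys_positions))


def enumerate_connectivities(cys_positions: Sequence[int]) -> list[DisulfideConnectivity]:
    """All perfect matchings of an even-sized cysteine set.

    Deterministic order: the first (lowest) free position is paired with each
    later position in turn, recursively; yields (2n−1)!! matchings.
    """
    pos = sorted(int(p) for p in cys_positions)
    if len(set(pos)) != len(pos):
        raise ValueError("duplicate cysteine positions")
    if len(pos) < 2 or len(pos) % 2:
        raise ValueError(f"need an even number (≥2) of cysteines, got {len(pos)}")

    def rec(rest: tuple[int, ...]):
        if not rest:
            yield ()
            return
        first, tail = rest[0], rest[1:]
        for i, partner in enumerate(tail):
            remaining = tail[:i] + tail[i + 1:]
            for sub in rec(remaining):
                yield ((first, partner),) + sub

    return [DisulfideConnectivity(m) for m in rec(tuple(pos))]


def detect_disulfides(
    structure: StructureEnsemble,
    model: int = 0,
    sg_cutoff: float = 2.5,
) -> DisulfideConnectivity:
    """Detect disulfide bonds geometrically from Sγ positions.

    Pairs are mutually nearest Sγ atoms within ``sg_cutoff`` Å, assigned
    greedily shortest-first so each cysteine joins at most one bond.  If some
    cysteines remain unpaired a warning is emitted and the partial matching
    is returned.
    """
    cys_res = np.unique(structure.res_num[structure.res_name == "CYS"])
    if cys_res.size == 0:
        raise ValueError("structure contains no cysteine residues")
    sg_idx = []
    missing = []
    for r in cys_res:
        try:
            sg_idx.append(structure.atom_index(int(r), "SG"))
        except KeyError:
            missing.append(int(r))
    if missing:
        raise ValueError(f"missing SG atoms for cysteine residues {missing}")
    xyz = structure.coords[model, sg_idx]
    n = len(cys_res)
    d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    # greedy shortest-first over mutually-nearest candidates
    pairs = []
    used: set[int] = set()
    order = np.argsort(d, axis=None)
    for flat in order:
        i, j = divmod(int(flat), n)
        if i >= j or i in used or j in used:
            continue
        if d[i, j] > sg_cutoff:
            break
        # mutual nearest among unused partners
        avail = [k for k in range(n) if k not in used]
        di = min(avail, key=lambda k: d[i, k] if k != i else np.inf)
        dj = min(avail, key=lambda k: d[j, k] if k != j else np.inf)
        if di == j and dj == i:
            pairs.append((int(cys_res[i]), int(cys_res[j])))
            used.update((i, j))
    if len(used) < n and pairs:
        warnings.warn(
            f"partial matching: {n - len(used)} cysteine(s) unpaired "
            f"within {sg_cutoff} Å",
            stacklevel=2,
        )
    return DisulfideConnectivity(pairs)


def roman_label(conn: DisulfideConnectivity, cys_positions: Sequence[int]) -> str:
    """Label a connectivity by cysteine rank order, e.g. ``I-III, II-V, IV-VI``."""
    pos = sorted(int(p) for p in cys_positions)
    rank = {p: i for i, p in enumerate(pos)}
    parts = []
    for a, b in conn.pairs:
        if a not in rank or b not in rank:
            raise ValueError(f"pair ({a},{b}) not within cysteine positions {pos}")
        parts.append((rank[a], rank[b]))
    parts.sort()
    return ", ".join(f"{_ROMAN[a]}-{_ROMAN[b]}" for a, b in parts)
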