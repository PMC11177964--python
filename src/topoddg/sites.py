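"""Element/site-specific atom subsets and modified distance matrices.

The featurization works on four atom subsets of a complex: the mutated
residue's heavy atoms (the mutation site), its r-neighborhood, and each
binding partner's atoms within r of the other partner (the interface). These
are intersected with element groups (C, N, O by default) and turned into
pairwise distance matrices. The *modified* distance assigns +inf to pairs
from the same group — same side of the interface, or both mutation-site /
both neighborhood atoms — so that only cross-group interactions create
topology during filtration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import AA1_TO_3, Atom, MutationSpec, Structure

__all__ = [
    "SiteSubsets",
    "DistanceMatrix",
    "select_mutation_site",
    "select_neighborhood",
    "select_binding_site",
    "filter_by_element",
    "pairwise_distances",
    "build_site_subsets",
    "DEFAULT_NEIGHBORHOOD_RADIUS",
    "DEFAULT_BINDING_RADIUS",
]

#: Default cutoff (Å) for the mutation-neighborhood subset.
DEFAULT_NEIGHBORHOOD_RADIUS = 10.0
#: Default cutoff (Å) for the binding-site subsets.
DEFAULT_BINDING_RADIUS = 12.0


@dataclass(frozen=True)
class SiteSubsets:
    """The four atom subsets driving feature generation, at one radius r."""

    a_m: tuple[Atom, ...]
    a_mn: tuple[Atom, ...]
    a_p1: tuple[Atom, ...]
    a_p2: tuple[Atom, ...]
    r_neighborhood: float
    r_binding: float


@dataclass
class DistanceMatrix:
    """Pairwise atom distances in Å; entries may be +inf in ``mod`` mode."""

    entries: np.ndarray
    row_atoms: tuple[Atom, ...]
    col_atoms: tuple[Atom, ...]
    mode: str  # "euclidean" | "mod"

    def __post_init__(self) -> None:
        finite = self.entries[np.isfinite(self.entries)]
        if finite.size and finite.min() < 0:
            raise ValueError("negative distance entry")

    @property
    def is_square(self) -> bool:
        return self.row_atoms == self.col_atoms


def _coords(atoms: Sequence[Atom]) -> np.ndarray:
    return np.array([a.coords for a in atoms]).reshape(-1, 3)


def select_mutation_site(structure: Structure, mut: MutationSpec) -> list[Atom]:
    """All heavy atoms of the mutated residue (author numbering)."""
    atoms = structure.residue_atoms(mut.chain, mut.res_seq)
    expected = AA1_TO_3.get(mut.wt_aa)
    found = atoms[0].res_name
    if expected and found != expected:
        warnings.warn(
            f"{structure.id} {mut.chain}:{mut.res_seq} is {found}, "
            f"mutation code says {expected}"
        )
    return atoms


def select_neighborhood(structure: Structure, mut: MutationSpec, r: float) -> list[Atom]:
    """Atoms within r Å (minimum distance) of any mutation-site atom.

    The mutation-site atoms themselves are always included.
    """
    if r <= 0:
        raise ValueError("neighborhood radius must be positive")
    site = select_mutation_site(structure, mut)
    d = cdist(_coords(structure.atoms), _coords(site)).min(axis=1)
    return [a for a, di in zip(structure.atoms, d) if di <= r]


def select_binding_site(structure: Structure, partner: str, r: float) -> list[Atom]:
    """Atoms of one partner within r Å of any atom of the other partner."""
    if partner not in ("P1", "P2"):
        raise ValueError("partner must be 'P1' or 'P2'")
    if not structure.partition:
        raise ValueError(f"{structure.id}: no chain partition attached")
    own = [a for a in structure.atoms if structure.partner_of(a) == partner]
    other = [a for a in structure.atoms if structure.partner_of(a) != partner]
    if not own or not other:
        raise ValueError(f"{structure.id}: both partners must be non-empty")
    d = cdist(_coords(own), _coords(other)).min(axis=1)
    return [a for a, di in zip(own, d) if di <= r]


def filter_by_element(atoms: Iterable[Atom], elements: Iterable[str]) -> list[Atom]:
    """Subset with element symbols in ``elements`` (case-insensitive)."""
    wanted = {e.upper() for e in elements}
    if not wanted:
        raise ValueError("element set must be non-empty")
    return [a for a in atoms if a.element.upper() in wanted]


def pairwise_distances(
    set_a: Sequence[Atom],
    set_b: Sequence[Atom],
    mode: str = "euclidean",
    grouping: Callable[[Atom], str] | None = None,
) -> DistanceMatrix:
    """Distance matrix between two atom sets.

    In ``mod`` mode, pairs whose ``grouping`` labels coincide get +inf
    (interactions within one side are excluded from the topology); cross-group
    pairs keep their Euclidean distance. Every atom must then carry a label.
    """
    set_a, set_b = tuple(set_a), tuple(set_b)
    d = cdist(_coords(set_a), _coords(set_b))
    if mode == "euclidean":
        return DistanceMatrix(d, set_a, set_b, "euclidean")
    if mode != "mod":
        raise ValueError(f"unknown distance mode {mode!r}")
    if grouping is None:
        raise ValueError("mod mode requires a grouping function")
    ga = [grouping(a) for a in set_a]
    gb = [grouping(b) for b in set_b]
    if any(g is None for g in ga + gb):
        raise ValueError("mod mode: every atom needs a group label")
    same = np.array([[x == y for y in gb] for x in ga], dtype=bool)
    d = d.copy()
    d[same] = np.inf
    return DistanceMatrix(d, set_a, set_b, "mod")


def build_site_subsets(
    structure: Structure,
    mut: MutationSpec,
    r_neighborhood: float = DEFAULT_NEIGHBORHOOD_RADIUS,
    r_binding: float = DEFAULT_BINDING_RADIUS,
) -> SiteSubsets:
    """Assemble the four canonical subsets for one mutation."""
    return SiteSubsets(
        a_m=tuple(select_mutation_site(structure, mut)),
        a_mn=tuple(select_neighborhood(structure, mut, r_neighborhood)),
        a_p1=tuple(select_binding_site(structure, "P1", r_binding)),
        a_p2=tuple(select_binding_site(structure, "P2", r_binding)),
        r_neighborhood=r_neighborhood,
        r_binding=r_binding,
    )
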