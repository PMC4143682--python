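"""Pedigree structure: persons, nuclear-family decomposition, Mendel checks, kinship.

A :class:`PedigreeSet` holds the people of one or more pedigrees with parent
links.  The family-based tests operate on nuclear families (two parents plus
their common offspring); an individual in an extended pedigree may appear as
offspring in one nuclear family and as parent in another.  Kinship
coefficients are computed by the standard recursive algorithm (founders
unrelated, non-inbred diagonal 1/2) and feed both the trait simulator and the
variance-component machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MALE, FEMALE, UNKNOWN_SEX = 1, 2, 0


class PedigreeError(ValueError):
    """Structural problem in a pedigree (dangling parent, cycle, duplicate id)."""


@dataclass(frozen=True)
class Person:
    fid: str
    iid: str
    father: str | None = None
    mother: str | None = None
    sex: int = UNKNOWN_SEX

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class NuclearFamily:
    """Two parents and their common offspring within one pedigree."""

    pedigree_id: str
    father: str
    mother: str
    offspring: list[str]

    def __post_init__(self) -> None:
        if self.father == self.mother:
            raise PedigreeError(f"father and mother identical: {self.father}")
        if not self.offspring:
            raise PedigreeError("nuclear family with no offspring")


class PedigreeSet:
    """A validated collection of pedigrees keyed by individual id.

    Individual ids must be unique across the whole set (they are the join key
    to genotype samples).  Parent references must resolve within the same
    pedigree and the parent graph must be acyclic.
    """

    def __init__(self, persons: list[Person]):
        self.persons: dict[str, Person] = {}
        for p in persons:
            if p.iid in self.persons:
                raise PedigreeError(f"duplicate individual id {p.iid!r}")
            self.persons[p.iid] = p
        self.pedigrees: dict[str, list[str]] = {}
        for p in persons:
            self.pedigrees.setdefault(p.fid, []).append(p.iid)
        self._validate()

    def _validate(self) -> None:
        for p in self.persons.values():
            for ref in (p.father, p.mother):
                if ref is None:
                    continue
                if ref == p.iid:
                    raise PedigreeError(f"{p.iid} is its own parent")
                q = self.persons.get(ref)
                if q is None:
                    raise PedigreeError(f"parent {ref!r} of {p.iid!r} not in file")
                if q.fid != p.fid:
                    raise PedigreeError(
                        f"parent {ref!r} of {p.iid!r} is in pedigree {q.fid!r}, not {p.fid!r}"
                    )
        # cycle check doubles as topological sort
        self.topological_order()

    # -- structure ---------------------------------------------------------

    def topological_order(self) -> list[str]:
        """Individual ids ordered parents-before-children; raises on cycles."""
        order: list[str] = []
        state: dict[str, int] = {}  # 0 unvisited / 1 on stack / 2 done

        def visit(iid: str) -> None:
            st = state.get(iid, 0)
            if st == 2:
                return
            if st == 1:
                raise PedigreeError(f"pedigree cycle involving {iid!r}")
            state[iid] = 1
            p = self.persons[iid]
            for ref in (p.father, p.mother):
                if ref is not None:
                    visit(ref)
            state[iid] = 2
            order.append(iid)

        for iid in self.persons:
            visit(iid)
        return order

    @property
    def founders(self) -> list[str]:
        return [iid for iid, p in self.persons.items() if p.is_founder]

    @property
    def nonfounders(self) -> list[str]:
        return [iid for iid, p in self.persons.items() if not p.is_founder]

    def __len__(self) -> int:
        return len(self.persons)


def decompose_nuclear(pedset: PedigreeSet) -> list[NuclearFamily]:
    """Split every pedigree into nuclear families.

    Offspring are grouped by their (father, mother) pair, so each nonfounder
    appears as offspring in exactly one family regardless of input order.
    Individuals with only one recorded parent are not assigned to a nuclear
    family (both parents are required for the conditional tests).
    """
    groups: dict[tuple[str, str, str], list[str]] = {}
    for iid in sorted(pedset.persons):
        p = pedset.persons[iid]
        if p.father is not None and p.mother is not None:
            groups.setdefault((p.fid, p.father, p.mother), []).append(iid)
    return [
        NuclearFamily(pedigree_id=fid, father=fa, mother=mo, offspring=kids)
        for (fid, fa, mo), kids in sorted(groups.items())
    ]


def mendel_check(
    family: NuclearFamily,
    dosages: dict[str, float],
) -> list[tuple[str, str]]:
    """Flag offspring whose dosage is impossible given parental dosages.

    ``dosages`` maps iid -> minor-allele count at one marker (NaN = missing).
    With parental dosages f, m the offspring count must lie in
    [(f==2)+(m==2), (f>0)+(m>0)].  Missing parent or offspring genotype means
    no check.  Returns (offspring_iid, reason) pairs.
    """
    f = dosages.get(family.father, np.nan)
    m = dosages.get(family.mother, np.nan)
    if not (np.isfinite(f) and np.isfinite(m)):
        return []
    lo = int(f == 2) + int(m == 2)
    hi = int(f > 0) + int(m > 0)
    out = []
    for kid in family.offspring:
        x = dosages.get(kid, np.nan)
        if np.isfinite(x) and not (lo <= x <= hi):
            out.append((kid, f"offspring dosage {x:g} outside [{lo},{hi}] for parents ({f:g},{m:g})"))
    return out


@dataclass
class KinshipMatrix:
    ids: list[str]
    phi: np.ndarray
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {iid: k for k, iid in enumerate(self.ids)}

    def coeff(self, a: str, b: str) -> float:
        return float(self.phi[self.index[a], self.index[b]])


def kinship(pedset: PedigreeSet) -> KinshipMatrix:
    """Kinship coefficients by the recursive founder-based algorithm.

    phi(i,i) = (1 + phi(f_i, m_i)) / 2 and, for i added after j in
    parents-first order, phi(i,j) = (phi(f_i,j) + phi(m_i,j)) / 2 with founder
    parents contributing 0.  Different pedigrees are unrelated.  The matrix is
    symmetric and 2*phi is positive semidefinite.
    """
    order = pedset.topological_order()
    n = len(order)
    idx = {iid: k for k, iid in enumerate(order)}
    phi = np.zeros((n, n))
    for iid in order:
        i = idx[iid]
        p = pedset.persons[iid]
        fi = idx[p.father] if p.father is not None else None
        mi = idx[p.mother] if p.mother is not None else None
        if fi is None and mi is None:
            phi[i, i] = 0.5
        else:
            phi[i, i] = 0.5 * (1.0 + (phi[fi, mi] if fi is not None and mi is not None else 0.0))
        for jid in order[:i]:
            j = idx[jid]
            if pedset.persons[jid].fid != p.fid:
                continue
            val = 0.0
            if fi is not None:
                val += 0.5 * phi[fi, j]
            if mi is not None:
                val += 0.5 * phi[mi, j]
            phi[i, j] = phi[j, i] = val
    return KinshipMatrix(ids=order, phi=phi)
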