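"""CIPSI-style selected configuration interaction with Epstein-Nesbet PT2.

Determinants are occupation patterns over spin orbitals (spin orbital
p = 2*orbital + spin) with matrix elements from the Slater-Condon rules
over an :class:`~qmcforces.systems.IntegralTable`.  Starting from a small
space S, determinants outside S connected by singles/doubles are ranked
by their second-order Epstein-Nesbet contribution

    e_gamma = |<gamma|H|Psi>|^2 / (E - <gamma|H|gamma>),

and the largest-|e| candidates are moved into S iteratively; the total
E^(PT2) = sum e_gamma estimates the residual error and reaches zero at
the full-CI limit.  ``match_pt2`` builds expansions at several geometries
sharing a common |E^(PT2)| target, balancing wavefunction quality across
a potential-energy surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .systems import IntegralTable

__all__ = [
    "Determinant",
    "DeterminantSpace",
    "CiWavefunction",
    "Pt2Report",
    "hamiltonian_element",
    "build_hamiltonian",
    "diagonalize",
    "connected_space",
    "pt2_contributions",
    "cipsi_iterate",
    "match_pt2",
    "full_ci_space",
]

#: a determinant is a sorted tuple of occupied spin orbitals
Determinant = tuple[int, ...]


def _spatial(p: int) -> int:
    return p // 2


def _spin(p: int) -> int:
    return p % 2


@dataclass(frozen=True)
class DeterminantSpace:
    determinants: tuple[Determinant, ...]

    def __post_init__(self) -> None:
        dets = tuple(tuple(sorted(int(p) for p in d)) for d in self.determinants)
        object.__setattr__(self, "determinants", dets)
        if len(set(dets)) != len(dets):
            raise ValueError("determinants must be distinct")
        if len(dets) == 0:
            raise ValueError("determinant space must be nonempty")
        n = len(dets[0])
        if any(len(d) != n for d in dets):
            raise ValueError("all determinants must have the same electron count")

    @property
    def n_electrons(self) -> int:
        return len(self.determinants[0])

    def __contains__(self, det: Determinant) -> bool:
        return tuple(det) in set(self.determinants)

    def __len__(self) -> int:
        return len(self.determinants)


@dataclass(frozen=True)
class CiWavefunction:
    space: DeterminantSpace
    coefficients: np.ndarray
    energy: float

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, float)
        object.__setattr__(self, "coefficients", c)
        if c.shape != (len(self.space),):
            raise ValueError("one coefficient per determinant required")


@dataclass(frozen=True)
class Pt2Report:
    contributions: dict
    total: float
    n_external: int
    n_excluded: int = 0


def _phase(det: Determinant, removed: Sequence[int], added: Sequence[int]) -> float:
    """Fermionic sign for exciting ``removed`` -> ``added`` in ``det``."""
    occ = list(det)
    sign = 1
    for r, a in zip(removed, added):
        i = occ.index(r)
        occ.pop(i)
        sign *= (-1) ** i
        j = 0
        while j < len(occ) and occ[j] < a:
            j += 1
        occ.insert(j, a)
        sign *= (-1) ** j
    return float(sign)


def _eri(table: IntegralTable, p: int, q: int, r: int, s: int) -> float:
    """<pq| 1/r12 |rs> over spin orbitals, chemist-stored spatial integrals."""
    if _spin(p) != _spin(r) or _spin(q) != _spin(s):
        return 0.0
    return float(table.eri[_spatial(p), _spatial(r), _spatial(q), _spatial(s)])


def hamiltonian_element(table: IntegralTable, bra: Determinant, ket: Determinant) -> float:
    """Slater-Condon matrix element <bra|H|ket> including the core energy
    on the diagonal; zero beyond double excitations."""
    bra_s, ket_s = set(bra), set(ket)
    diff_b = sorted(bra_s - ket_s)
    diff_k = sorted(ket_s - bra_s)
    n_diff = len(diff_k)
    if n_diff > 2:
        return 0.0
    h1 = table.h1
    if n_diff == 0:
        e = table.core
        for p in ket:
            e += h1[_spatial(p), _spatial(p)]
        for p, q in combinations(ket, 2):
            e += _eri(table, p, q, p, q) - _eri(table, p, q, q, p)
        return float(e)
    if n_diff == 1:
        (p,), (r,) = diff_k, diff_b
        if _spin(p) != _spin(r):
            return 0.0
        e = h1[_spatial(p), _spatial(r)]
        for q in ket_s & bra_s:
            e += _eri(table, p, q, r, q) - _eri(table, p, q, q, r)
        return _phase(ket, [p], [r]) * float(e)
    (p, q), (r, s) = diff_k, diff_b
    e = _eri(table, p, q, r, s) - _eri(table, p, q, s, r)
    return _phase(ket, [p, q], [r, s]) * float(e)


def build_hamiltonian(table: IntegralTable, space: DeterminantSpace) -> np.ndarray:
    dets = space.determinants
    n = len(dets)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            H[i, j] = H[j, i] = hamiltonian_element(table, dets[i], dets[j])
    if not np.allclose(H, H.T, atol=1e-10):
        raise RuntimeError("assembled Hamiltonian is not symmetric")
    return H


def diagonalize(table: IntegralTable, space: DeterminantSpace) -> CiWavefunction:
    """Lowest eigenpair of H restricted to the space (dense solve).

    The coefficient vector is normalized with its largest-magnitude entry
    positive so results are deterministic.
    """
    if len(space) > 4000:
        raise ValueError("dense diagonalization limited to small toy spaces")
    H = build_hamiltonian(table, space)
    w, v = scipy.linalg.eigh(H)
    c = v[:, 0]
    if c[np.argmax(np.abs(c))] < 0:
        c = -c
    return CiWavefunction(space, c, float(w[0]))


def _excitations(det: Determinant, n_spin: int):
    """All distinct single and double excitations of a determinant."""
    occ = list(det)
    occ_set = set(occ)
    virt = [p for p in range(n_spin) if p not in occ_set]
    seen = set()
    for p in occ:
        for a in virt:
            if _spin(p) == _spin(a):
                new = tuple(sorted(occ_set - {p} | {a}))
                if new not in seen:
                    seen.add(new)
                    yield new
    for p, q in combinations(occ, 2):
        for a, b in combinations(virt, 2):
            if _spin(p) + _spin(q) == _spin(a) + _spin(b):
                new = tuple(sorted(occ_set - {p, q} | {a, b}))
                if new not in seen:
                    seen.add(new)
                    yield new


def connected_space(table: IntegralTable, space: DeterminantSpace) -> list[Determinant]:
    """External determinants connected to S by single/double excitation."""
    n_spin = 2 * table.n_orbitals
    inside = set(space.determinants)
    out = set()
    for det in space.determinants:
        for new in _excitations(det, n_spin):
            if new not in inside:
                out.add(new)
    return sorted(out)


def pt2_contributions(wf: CiWavefunction, table: IntegralTable) -> Pt2Report:
    """Epstein-Nesbet second-order contribution of every connected external
    determinant: e_gamma = |<gamma|H|Psi>|^2 / (E - <gamma|H|gamma>)."""
    externals = connected_space(table, wf.space)
    contributions = {}
    excluded = 0
    for gamma in externals:
        num = 0.0
        for det, c in zip(wf.space.determinants, wf.coefficients):
            num += c * hamiltonian_element(table, gamma, det)
        den = wf.energy - hamiltonian_element(table, gamma, gamma)
        if abs(den) < 1e-10:
            if abs(num) > 1e-12:
                warnings.warn(
                    f"vanishing Epstein-Nesbet denominator for {gamma}; "
                    "contribution excluded",
                    stacklevel=2,
                )
                excluded += 1
            continue
        contributions[gamma] = num * num / den
    total = float(sum(contributions.values()))
    return Pt2Report(contributions, total, len(externals), excluded)


def cipsi_iterate(
    table: IntegralTable,
    initial: DeterminantSpace,
    n_select: int = 1,
    max_determinants: Optional[int] = None,
    pt2_target: Optional[float] = None,
) -> list[tuple[CiWavefunction, Pt2Report]]:
    """Iterative determinant selection by PT2 contribution.

    Each iteration moves the ``n_select`` largest-|e_gamma| external
    determinants into S (ties broken by lexicographic determinant order),
    rediagonalizes, and recomputes the PT2 report.  Stops at the optional
    determinant budget, when |E^(PT2)| reaches the optional target, or at
    full CI (no connected externals), whichever comes first.
    """
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    space = initial
    trajectory = []
    while True:
        wf = diagonalize(table, space)
        report = pt2_contributions(wf, table)
        trajectory.append((wf, report))
        if not report.contributions:
            break
        if pt2_target is not None and abs(report.total) <= abs(pt2_target):
            break
        if max_determinants is not None and len(space) >= max_determinants:
            break
        ranked = sorted(
            report.contributions.items(), key=lambda kv: (-abs(kv[1]), kv[0])
        )
        chosen = [det for det, _ in ranked[:n_select]]
        space = DeterminantSpace(space.determinants + tuple(chosen))
    return trajectory


def match_pt2(
    tables: Sequence[IntegralTable],
    initial_spaces: Sequence[DeterminantSpace],
    reference_pt2: float,
    tolerance: float = 0.0,
    n_select: int = 1,
) -> list[tuple[CiWavefunction, Pt2Report]]:
    """Balanced expansions across geometries by matching a PT2 target.

    For each geometry (integral table), returns the smallest CIPSI
    iterate whose |E^(PT2)| <= |reference| * (1 + tolerance).  Expansions
    at different geometries will generally have different lengths.
    """
    if len(tables) != len(initial_spaces):
        raise ValueError("one initial space per integral table required")
    bound = abs(reference_pt2) * (1.0 + tolerance)
    out = []
    for g, (table, space) in enumerate(zip(tables, initial_spaces)):
        traj = cipsi_iterate(table, space, n_select=n_select, pt2_target=bound)
        wf, report = traj[-1]
        if abs(report.total) > bound and report.contributions:
            raise RuntimeError(
                f"geometry {g}: PT2 target {reference_pt2:g} unattainable; "
                f"reached {report.total:g} with {len(wf.space)} determinants"
            )
        out.append((wf, report))
    return out


def full_ci_space(table: IntegralTable, n_electrons: int, sz: Optional[int] = None) -> DeterminantSpace:
    """Every determinant of ``n_electrons`` over the table's spin orbitals,
    optionally restricted to 2*Sz = n_up - n_down."""
    n_spin = 2 * table.n_orbitals
    dets = []
    for occ in combinations(range(n_spin), n_electrons):
        if sz is not None:
            n_up = sum(1 for p in occ if _spin(p) == 0)
            if n_up - (n_electrons - n_up) != sz:
                continue
        dets.append(tuple(occ))
    return DeterminantSpace(tuple(dets))
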