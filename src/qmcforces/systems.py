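"""Analytic model systems with known ground states.

Few-particle Hamiltonians (hydrogenic atoms, a 3D harmonic well, the
one-electron two-center molecule) serve as oracles for every Monte Carlo
estimator in the package: their exact wavefunctions give zero-variance
local energies, and their forces are either zero by symmetry or checkable
against a finite difference of the energy.  The module also generates the
synthetic geometry ensembles and toy CI integral tables that stand in for
room-temperature configuration pools and molecular Hamiltonians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Geometry",
    "CoulombPotential",
    "HarmonicPotential",
    "AnalyticReference",
    "ModelSystem",
    "IntegralTable",
    "SyntheticEnsemble",
    "HarmonicNuclearField",
    "make_hydrogenic_atom",
    "make_harmonic_atom",
    "make_two_center_system",
    "make_toy_integrals",
    "perturb_geometries",
    "fd_force_component",
]


@dataclass(frozen=True, eq=False)
class Geometry:
    """Clamped nuclei: positions (n,3) in bohr, charges, element labels."""

    positions: np.ndarray
    charges: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        chg = np.atleast_1d(np.asarray(self.charges, dtype=float))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", chg)
        object.__setattr__(self, "labels", tuple(self.labels))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if pos.shape[0] < 1:
            raise ValueError("need at least one nucleus")
        if not np.all(np.isfinite(pos)):
            raise ValueError("nuclear positions must be finite")
        if chg.shape != (pos.shape[0],) or np.any(chg <= 0):
            raise ValueError("need one positive charge per nucleus")
        if len(self.labels) != pos.shape[0]:
            raise ValueError("need one label per nucleus")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Geometry)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.charges, other.charges)
            and self.labels == other.labels
        )

    __hash__ = None

    @property
    def n_nuclei(self) -> int:
        return self.positions.shape[0]

    def with_positions(self, positions: np.ndarray) -> "Geometry":
        return Geometry(np.asarray(positions, float), self.charges, self.labels)

    def shifted(self, nucleus: int, axis: int, delta: float) -> "Geometry":
        pos = self.positions.copy()
        pos[nucleus, axis] += delta
        return self.with_positions(pos)


class CoulombPotential:
    """-sum Z/|r-R| attraction, e-e repulsion (>=2 electrons), n-n repulsion."""

    kind = "coulomb"

    def energy(self, electrons: np.ndarray, geometry: Geometry) -> np.ndarray:
        elec = np.atleast_3d(electrons)  # (B, n_e, 3)
        diff = elec[:, :, None, :] - geometry.positions[None, None, :, :]
        s = np.linalg.norm(diff, axis=-1)  # (B, n_e, n_n)
        with np.errstate(divide="ignore"):
            v = -np.sum(geometry.charges[None, None, :] / s, axis=(1, 2))
        n_e = elec.shape[1]
        for i in range(n_e):
            for j in range(i + 1, n_e):
                rij = np.linalg.norm(elec[:, i] - elec[:, j], axis=-1)
                with np.errstate(divide="ignore"):
                    v = v + 1.0 / rij
        return v + self.nuclear_repulsion(geometry)

    @staticmethod
    def nuclear_repulsion(geometry: Geometry) -> float:
        e = 0.0
        pos, chg = geometry.positions, geometry.charges
        for a in range(geometry.n_nuclei):
            for b in range(a + 1, geometry.n_nuclei):
                e += chg[a] * chg[b] / np.linalg.norm(pos[a] - pos[b])
        return e


@dataclass(frozen=True)
class HarmonicPotential:
    """Isotropic 3D harmonic well, V = k/2 |r - R_c|^2, attached to a nucleus.

    The "nuclear force" is the derivative with respect to the well center,
    which vanishes for the ground state by symmetry.
    """

    k: float
    center_index: int = 0
    kind = "harmonic"

    def energy(self, electrons: np.ndarray, geometry: Geometry) -> np.ndarray:
        elec = np.atleast_3d(electrons)
        c = geometry.positions[self.center_index]
        s2 = np.sum((elec - c[None, None, :]) ** 2, axis=-1)  # (B, n_e)
        return 0.5 * self.k * np.sum(s2, axis=1)

    @staticmethod
    def nuclear_repulsion(geometry: Geometry) -> float:
        return 0.0


@dataclass(frozen=True, eq=False)
class AnalyticReference:
    """Exact ground-state data for a model system, when known in closed form.

    ``wavefunction_spec`` is a declarative description consumed by
    :func:`qmcforces.wavefunction.build_wavefunction`.
    """

    energy: float
    forces: np.ndarray
    wavefunction_spec: Optional[dict] = None


@dataclass(frozen=True, eq=False)
class ModelSystem:
    geometry: Geometry
    n_electrons: int
    potential: object
    reference: Optional[AnalyticReference] = None
    name: str = "system"

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise ValueError("electron count must be >= 1")

    def potential_energy(
        self, electrons: np.ndarray, geometry: Optional[Geometry] = None
    ) -> np.ndarray:
        """Potential part of the local energy, vectorized over samples."""
        geo = self.geometry if geometry is None else geometry
        return self.potential.energy(electrons, geo)

    def with_geometry(self, geometry: Geometry) -> "ModelSystem":
        return replace(self, geometry=geometry)


@dataclass(frozen=True, eq=False)
class IntegralTable:
    """One-/two-electron integrals over an orthonormal orbital set.

    ``h1`` is symmetric, ``eri`` is stored in chemist notation (pq|rs)
    with full 8-fold permutational symmetry, ``core`` is a scalar shift.
    """

    n_orbitals: int
    h1: np.ndarray
    eri: np.ndarray
    core: float = 0.0

    def __post_init__(self) -> None:
        n = self.n_orbitals
        if n < 2:
            raise ValueError("orbital count must be >= 2")
        h1 = np.asarray(self.h1, float)
        eri = np.asarray(self.eri, float)
        object.__setattr__(self, "h1", h1)
        object.__setattr__(self, "eri", eri)
        if h1.shape != (n, n) or not np.allclose(h1, h1.T, atol=1e-12):
            raise ValueError("h1 must be a symmetric (n, n) matrix")
        if eri.shape != (n, n, n, n):
            raise ValueError("eri must be a 4-index (n,n,n,n) tensor")
        for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
            if not np.allclose(eri, eri.transpose(perm), atol=1e-12):
                raise ValueError("eri must have 8-fold permutational symmetry")


@dataclass(frozen=True, eq=False)
class SyntheticEnsemble:
    """Geometries with energies (hartree) and forces (hartree/bohr)."""

    configurations: tuple[Geometry, ...]
    energies: np.ndarray
    forces: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "configurations", tuple(self.configurations))
        e = np.asarray(self.energies, float)
        f = np.asarray(self.forces, float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "forces", f)
        n = len(self.configurations)
        if e.shape != (n,) or not np.all(np.isfinite(e)):
            raise ValueError("need one finite energy per configuration")
        if f.shape[0] != n:
            raise ValueError("need one force block per configuration")

    def __len__(self) -> int:
        return len(self.configurations)


@dataclass(frozen=True)
class HarmonicNuclearField:
    """Analytic nuclear potential-energy surface: independent springs.

    E(R) = k/2 sum_a |R_a - R0_a|^2.  Serves as the ground-truth force
    field behind the synthetic ensembles: energies and forces are exact
    and cheap, so machine-learned models can be scored against it.
    """

    reference_positions: np.ndarray
    k: float = 0.2  # hartree/bohr^2

    def energy_forces(self, positions: np.ndarray) -> tuple[float, np.ndarray]:
        d = np.asarray(positions, float) - self.reference_positions
        return 0.5 * self.k * float(np.sum(d * d)), -self.k * d


@dataclass(frozen=True)
class PairSpringField:
    """Analytic nuclear PES of bond springs between every atom pair.

    E(R) = sum_{a<b} k/2 (r_ab - r0_ab)^2 with r0 the reference pair
    distances.  Forces depend on the internal geometry only, which makes
    the surface learnable from distance-based descriptors; this is the
    default ground truth behind the synthetic ensembles.
    """

    reference_positions: np.ndarray
    k: float = 0.2  # hartree/bohr^2

    def energy_forces(self, positions: np.ndarray) -> tuple[float, np.ndarray]:
        pos = np.asarray(positions, float)
        ref = np.asarray(self.reference_positions, float)
        n = pos.shape[0]
        e = 0.0
        f = np.zeros_like(pos)
        for a in range(n):
            for b in range(a + 1, n):
                d = pos[a] - pos[b]
                r = np.linalg.norm(d)
                r0 = np.linalg.norm(ref[a] - ref[b])
                e += 0.5 * self.k * (r - r0) ** 2
                g = self.k * (r - r0) * d / r
                f[a] -= g
                f[b] += g
        return float(e), f


def make_hydrogenic_atom(Z: float) -> ModelSystem:
    """One-electron atom with nuclear charge Z.

    Exact ground state exp(-Z r) with energy -Z^2/2 hartree and zero
    nuclear force by symmetry.
    """
    if Z <= 0:
        raise ValueError("nuclear charge Z must be positive")
    geo = Geometry(np.zeros((1, 3)), np.array([float(Z)]), ("X",))
    ref = AnalyticReference(
        energy=-0.5 * Z**2,
        forces=np.zeros((1, 3)),
        wavefunction_spec={
            "orbitals": [{"kind": "slater", "zeta": float(Z), "center": 0}],
            "determinants": [[0]],
            "coefficients": [1.0],
        },
    )
    return ModelSystem(geo, 1, CoulombPotential(), ref, name=f"hydrogenic(Z={Z:g})")


def make_harmonic_atom(k: float, center: Sequence[float] = (0.0, 0.0, 0.0)) -> ModelSystem:
    """One electron in a 3D isotropic harmonic well of spring constant k.

    Exact ground state exp(-sqrt(k) |r-c|^2 / 2), energy (3/2) sqrt(k).
    """
    if k <= 0:
        raise ValueError("spring constant k must be positive")
    c = np.asarray(center, float).reshape(1, 3)
    geo = Geometry(c, np.array([1.0]), ("X",))
    w = np.sqrt(k)
    ref = AnalyticReference(
        energy=1.5 * w,
        forces=np.zeros((1, 3)),
        wavefunction_spec={
            "orbitals": [{"kind": "gaussian", "zeta": 0.5 * w, "center": 0}],
            "determinants": [[0]],
            "coefficients": [1.0],
        },
    )
    return ModelSystem(geo, 1, HarmonicPotential(k=float(k)), ref, name=f"harmonic(k={k:g})")


def make_two_center_system(separation: float, charges: Sequence[float] = (1.0, 1.0)) -> ModelSystem:
    """One-electron two-nucleus Coulomb system (H2+-like), repulsion included.

    No closed-form reference; the force oracle is a centered finite
    difference of converged energies over the separation.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    z = 0.5 * separation
    geo = Geometry(
        np.array([[0.0, 0.0, -z], [0.0, 0.0, z]]),
        np.asarray(charges, float),
        ("X", "X"),
    )
    return ModelSystem(geo, 1, CoulombPotential(), None, name=f"two-center(R={separation:g})")


def make_toy_integrals(
    n_orbitals: int,
    model: str = "random-hermitian",
    parameters: Optional[dict] = None,
    seed: int = 0,
) -> IntegralTable:
    """Deterministic toy integral tables for the selected-CI module.

    ``two-level``: two orbitals, one electron; the full CI matrix is
    [[0, t], [t, gap]] so the exact ground energy is
    (gap - sqrt(gap^2 + 4 t^2))/2.

    ``random-hermitian``: seeded random symmetric h1 and 8-fold-symmetric
    two-electron tensor of modest magnitude.
    """
    params = dict(parameters or {})
    if n_orbitals < 2:
        raise ValueError("orbital count must be >= 2")
    if model == "two-level":
        t = float(params.pop("t", 0.1))
        gap = float(params.pop("gap", 1.0))
        if params:
            raise ValueError(f"unknown two-level parameters: {sorted(params)}")
        if n_orbitals != 2:
            raise ValueError("two-level model has exactly 2 orbitals")
        h1 = np.array([[0.0, t], [t, gap]])
        eri = np.zeros((2, 2, 2, 2))
        return IntegralTable(2, h1, eri, 0.0)
    if model == "random-hermitian":
        scale1 = float(params.pop("scale1", 1.0))
        scale2 = float(params.pop("scale2", 0.2))
        diag_spread = float(params.pop("diag_spread", 2.0))
        if params:
            raise ValueError(f"unknown random-hermitian parameters: {sorted(params)}")
        rng = np.random.default_rng(seed)
        n = n_orbitals
        a = rng.normal(size=(n, n)) * scale1
        h1 = 0.5 * (a + a.T)
        h1[np.diag_indices(n)] += np.linspace(0.0, diag_spread, n)
        raw = rng.normal(size=(n, n, n, n)) * scale2
        acc = raw.copy()
        for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (1, 0, 3, 2),
                     (2, 3, 0, 1), (3, 2, 0, 1), (2, 3, 1, 0), (3, 2, 1, 0)]:
            acc = acc + raw.transpose(perm)
        acc /= 8.0
        # copy each canonical value to all eight index images so the
        # symmetry holds exactly, not just to rounding
        eri = np.empty_like(acc)
        for p in range(n):
            for q2 in range(n):
                for r in range(n):
                    for s in range(n):
                        key = min(
                            (p, q2, r, s), (q2, p, r, s), (p, q2, s, r), (q2, p, s, r),
                            (r, s, p, q2), (s, r, p, q2), (r, s, q2, p), (s, r, q2, p),
                        )
                        eri[p, q2, r, s] = acc[key]
        return IntegralTable(n, h1, eri, float(rng.normal() * 0.1))
    raise ValueError(f"unknown integral model: {model!r}")


def perturb_geometries(
    reference: Geometry,
    n: int,
    amplitude: float,
    seed: int,
    potential=None,
) -> SyntheticEnsemble:
    """Gaussian-perturbed copies of a reference geometry with exact labels.

    Emulates a room-temperature configuration pool: ``n`` geometries are
    the reference plus zero-mean isotropic Gaussian displacements of the
    stated amplitude (bohr); energies and forces are filled from the
    supplied analytic nuclear potential (default: pair springs between
    all atoms, k = 0.2 hartree/bohr^2, a stiffness giving ~0.1 bohr
    thermal displacements at room temperature).
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    pes = potential or PairSpringField(reference.positions.copy())
    rng = np.random.default_rng(seed)
    shape = reference.positions.shape
    configs, energies, forces = [], [], []
    for _ in range(n):
        pos = reference.positions + amplitude * rng.standard_normal(shape)
        geo = reference.with_positions(pos)
        e, f = pes.energy_forces(pos)
        configs.append(geo)
        energies.append(e)
        forces.append(f)
    return SyntheticEnsemble(tuple(configs), np.array(energies), np.array(forces), seed)


def fd_force_component(
    energy_fn: Callable[[Geometry], tuple[float, float]],
    geometry: Geometry,
    nucleus: int,
    axis: int,
    step: float = 0.01,
) -> tuple[float, float]:
    """Finite-difference force oracle: F = -dE/dR by centered differences.

    ``energy_fn(geometry) -> (energy, statistical error)``; the two runs
    are independent, so their errors combine in quadrature.  Returns
    (force, error) in hartree/bohr.  Independent of any estimator under
    test by construction.
    """
    ep, sp = energy_fn(geometry.shifted(nucleus, axis, +step))
    em, sm = energy_fn(geometry.shifted(nucleus, axis, -step))
    force = -(ep - em) / (2.0 * step)
    err = np.hypot(sp, sm) / (2.0 * step)
    return float(force), float(err)
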