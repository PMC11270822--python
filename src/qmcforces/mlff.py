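"""Machine-learned force-field pipeline downstream of the force engines.

Dataset curation (geometry clustering + per-cluster energy clustering,
and energy-histogram sampling of long trajectories), a kernel ridge
force model on an invariant descriptor, mean-absolute-deviation scoring
against reference forces in kcal/mol/A, Langevin molecular dynamics
(BAOAB splitting), and vibrational power spectra from mass-weighted
velocity autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.kernel_ridge import KernelRidge

from .systems import Geometry
from .units import (
    AU_PER_FS,
    CM1_PER_HARTREE,
    FORCE_AU_TO_KCAL_PER_ANG,
    KB_HARTREE,
    ME_PER_AMU,
)

__all__ = [
    "ConfigurationSet",
    "CurationPlan",
    "ForceFieldModel",
    "MdConfig",
    "Spectrum",
    "geometry_descriptor",
    "curate",
    "split_train_validation",
    "sample_by_energy_histogram",
    "train",
    "mad_forces",
    "run_langevin_md",
    "vacf_spectrum",
]


@dataclass(frozen=True)
class ConfigurationSet:
    """Geometries with energies (hartree) and forces (hartree/bohr)."""

    configurations: tuple[Geometry, ...]
    energies: np.ndarray
    forces: np.ndarray
    label: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "configurations", tuple(self.configurations))
        e = np.asarray(self.energies, float)
        f = np.asarray(self.forces, float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "forces", f)
        n = len(self.configurations)
        if n == 0:
            raise ValueError("configuration set must be nonempty")
        n_at = self.configurations[0].n_nuclei
        if any(g.n_nuclei != n_at for g in self.configurations):
            raise ValueError("all configurations must share the atom count")
        if e.shape != (n,):
            raise ValueError("one energy per configuration required")
        if f.shape != (n, n_at, 3):
            raise ValueError("forces must have shape (n, n_atoms, 3)")

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def n_atoms(self) -> int:
        return self.configurations[0].n_nuclei

    def subset(self, idx: Sequence[int], label: Optional[str] = None) -> "ConfigurationSet":
        idx = list(idx)
        return ConfigurationSet(
            tuple(self.configurations[i] for i in idx),
            self.energies[idx],
            self.forces[idx],
            label or self.label,
        )

    @classmethod
    def from_ensemble(cls, ens, label: str = "synthetic") -> "ConfigurationSet":
        return cls(ens.configurations, ens.energies, ens.forces, label)


@dataclass(frozen=True)
class CurationPlan:
    """Two-stage curation: geometry clusters, then energy sub-clusters."""

    geometry_clusters: int = 40
    energy_clusters: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry_clusters < 1 or self.energy_clusters < 1:
            raise ValueError("cluster counts must be >= 1")

    @property
    def target_size(self) -> int:
        return self.geometry_clusters * self.energy_clusters


def geometry_descriptor(geometry: Geometry) -> np.ndarray:
    """Sorted inverse pairwise distances: rotation/translation/permutation
    invariant and adequate at toy scale."""
    pos = geometry.positions
    n = pos.shape[0]
    if n < 2:
        return np.zeros(1)
    d = []
    for i in range(n):
        for j in range(i + 1, n):
            d.append(1.0 / np.linalg.norm(pos[i] - pos[j]))
    return np.sort(np.asarray(d))[::-1].copy()


def _descriptors(cs: ConfigurationSet) -> np.ndarray:
    return np.stack([geometry_descriptor(g) for g in cs.configurations])


def curate(pool: ConfigurationSet, plan: CurationPlan) -> ConfigurationSet:
    """Cluster a configuration pool down to a diverse representative set.

    Agglomerative (Ward) clustering of geometry descriptors into
    ``geometry_clusters`` groups, k-means on energy into
    ``energy_clusters`` sub-groups within each, then the configuration
    closest to each energy centroid is selected.  The output has exactly
    geometry_clusters * energy_clusters distinct members.
    """
    if len(pool) < plan.target_size:
        raise ValueError("pool smaller than the requested curated size")
    if len(pool) == plan.target_size:
        return replace(pool, label=f"{pool.label}-curated")
    X = _descriptors(pool)
    geo_labels = AgglomerativeClustering(n_clusters=plan.geometry_clusters).fit_predict(X)
    selected: list[int] = []
    for g in range(plan.geometry_clusters):
        members = np.flatnonzero(geo_labels == g)
        if members.size < plan.energy_clusters:
            raise RuntimeError(
                f"geometry cluster {g} has {members.size} members, fewer than "
                f"the {plan.energy_clusters} energy clusters requested"
            )
        e = pool.energies[members].reshape(-1, 1)
        for attempt, seed in enumerate((plan.seed, plan.seed + 7919)):
            km = KMeans(n_clusters=plan.energy_clusters, random_state=seed, n_init=10)
            sub = km.fit_predict(e)
            counts = np.bincount(sub, minlength=plan.energy_clusters)
            if np.all(counts > 0):
                break
        else:
            raise RuntimeError(f"empty energy sub-cluster in geometry cluster {g}")
        for s in range(plan.energy_clusters):
            sub_members = members[sub == s]
            dist = np.abs(pool.energies[sub_members] - km.cluster_centers_[s, 0])
            selected.append(int(sub_members[np.argmin(dist)]))
    assert len(set(selected)) == plan.target_size
    return pool.subset(sorted(selected), label=f"{pool.label}-curated")


def split_train_validation(
    curated: ConfigurationSet, seed: int = 0
) -> tuple[ConfigurationSet, ConfigurationSet]:
    """Random disjoint equal halves (train, validation)."""
    n = len(curated)
    if n % 2:
        raise ValueError("curated set must have even size for a 50/50 split")
    perm = np.random.default_rng(seed).permutation(n)
    return (
        curated.subset(sorted(perm[: n // 2]), "train"),
        curated.subset(sorted(perm[n // 2 :]), "validation"),
    )


def sample_by_energy_histogram(
    trajectory: ConfigurationSet, n: int, bins: int = 25, seed: int = 0
) -> ConfigurationSet:
    """Draw configurations proportionally to the energy-histogram heights.

    Per-bin draw counts are proportional to bin occupancy with
    largest-remainder rounding (summing exactly to n); sampling is
    without replacement within each bin.
    """
    if n > len(trajectory):
        raise ValueError("cannot sample more configurations than available")
    e = trajectory.energies
    counts, edges = np.histogram(e, bins=bins)
    which = np.clip(np.digitize(e, edges) - 1, 0, bins - 1)
    quota = n * counts / counts.sum()
    base = np.floor(quota).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rem]] += 1
    base = np.minimum(base, counts)  # guard against rounding overshoot
    deficit = n - base.sum()
    if deficit > 0:
        room = counts - base
        for b in np.argsort(-room):
            take = min(deficit, room[b])
            base[b] += take
            deficit -= take
            if deficit == 0:
                break
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for b in range(bins):
        members = np.flatnonzero(which == b)
        if base[b] > 0:
            chosen.extend(rng.choice(members, size=base[b], replace=False).tolist())
    return trajectory.subset(sorted(chosen), label=f"{trajectory.label}-histsampled")


@dataclass
class ForceFieldModel:
    """Kernel ridge force (and energy) model on the invariant descriptor.

    A plain RBF kernel ridge regression mapping the sorted
    inverse-distance descriptor to the flattened force vector; in the
    zero-regularization limit it interpolates the training forces.
    """

    length_scale: float
    regularization: float
    training_descriptors: np.ndarray
    dual_coefficients: np.ndarray
    energy_offset: float
    _force_model: KernelRidge
    _energy_model: KernelRidge
    n_atoms: int

    def predict_forces(self, configurations: Sequence[Geometry]) -> np.ndarray:
        X = np.stack([geometry_descriptor(g) for g in configurations])
        out = self._force_model.predict(X)
        return out.reshape(len(configurations), self.n_atoms, 3)

    def predict_energies(self, configurations: Sequence[Geometry]) -> np.ndarray:
        X = np.stack([geometry_descriptor(g) for g in configurations])
        return self._energy_model.predict(X) + self.energy_offset

    def energy_forces(self, positions: np.ndarray) -> tuple[float, np.ndarray]:
        """Single-geometry interface used by the MD driver."""
        geo = Geometry(positions, np.ones(self.n_atoms), ("X",) * self.n_atoms)
        e = float(self.predict_energies([geo])[0])
        f = self.predict_forces([geo])[0]
        return e, f


def train(
    train_set: ConfigurationSet,
    length_scale: Optional[float] = None,
    regularization: float = 1e-8,
) -> ForceFieldModel:
    """Fit the kernel ridge force-field model on energies and forces.

    The RBF length scale defaults to 5x the median pairwise descriptor
    distance: wider than the data spread, so the model starts in the
    smooth near-linear regime appropriate for thermal ensembles.
    """
    if len(train_set) < 2:
        raise ValueError("need at least 2 training configurations")
    X = _descriptors(train_set)
    if length_scale is None:
        from scipy.spatial.distance import pdist

        med = np.median(pdist(X))
        length_scale = 5.0 * float(med) if med > 0 else 1.0
    gamma = 1.0 / (2.0 * length_scale**2)
    y = train_set.forces.reshape(len(train_set), -1)
    fm = KernelRidge(alpha=regularization, kernel="rbf", gamma=gamma)
    try:
        fm.fit(X, y)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "singular kernel matrix; add regularization jitter or deduplicate "
            "training configurations"
        ) from exc
    offset = float(train_set.energies.mean())
    em = KernelRidge(alpha=regularization, kernel="rbf", gamma=gamma)
    em.fit(X, train_set.energies - offset)
    return ForceFieldModel(
        length_scale=float(length_scale),
        regularization=float(regularization),
        training_descriptors=X,
        dual_coefficients=fm.dual_coef_,
        energy_offset=offset,
        _force_model=fm,
        _energy_model=em,
        n_atoms=train_set.n_atoms,
    )


def mad_forces(predicted: np.ndarray, reference: np.ndarray, input_units: str = "hartree/bohr") -> float:
    """Mean absolute deviation of force components, in kcal/mol/A.

    The mean runs over configurations, atoms, and Cartesian components;
    inputs in hartree/bohr are converted at this boundary.
    """
    p = np.asarray(predicted, float)
    r = np.asarray(reference, float)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    mad = float(np.mean(np.abs(p - r)))
    if input_units == "hartree/bohr":
        return mad * FORCE_AU_TO_KCAL_PER_ANG
    if input_units in ("kcal/mol/angstrom", "kcal/mol/A"):
        return mad
    raise ValueError(f"unknown force units {input_units!r}")


@dataclass(frozen=True)
class MdConfig:
    """Langevin MD parameters (file-facing units: fs, K)."""

    time_step_fs: float = 0.2
    temperature_k: float = 300.0
    thermostat_fs: float = 100.0   # time constant; friction gamma = 1/tau
    duration_fs: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.time_step_fs, self.temperature_k, self.thermostat_fs, self.duration_fs) < 0:
            raise ValueError("MD parameters must be positive")
        if self.time_step_fs <= 0 or self.duration_fs <= 0:
            raise ValueError("MD parameters must be positive")


@dataclass
class MdTrajectory:
    positions: np.ndarray    # (T, n_atoms, 3), bohr
    velocities: np.ndarray   # (T, n_atoms, 3), bohr / au-time
    energies: np.ndarray     # (T,), potential, hartree
    kinetic: np.ndarray      # (T,), hartree
    time_step_fs: float
    masses_amu: np.ndarray


def run_langevin_md(
    potential,
    initial: Geometry,
    masses_amu: Sequence[float],
    config: MdConfig,
    initial_velocities: Optional[np.ndarray] = None,
) -> MdTrajectory:
    """BAOAB-discretized Langevin dynamics.

    ``potential`` exposes ``energy_forces(positions) -> (E, F)`` in
    hartree and hartree/bohr (an analytic field or a trained
    :class:`ForceFieldModel`).  The thermostat time constant maps to a
    friction gamma = 1/tau; at gamma = 0 the scheme reduces to velocity
    Verlet and conserves energy to O(dt^2).  Setting temperature to 0
    with zero initial velocities relaxes toward the nearest minimum.
    """
    dt = config.time_step_fs * AU_PER_FS
    gamma = 0.0 if config.thermostat_fs == 0 else 1.0 / (config.thermostat_fs * AU_PER_FS)
    kt = KB_HARTREE * config.temperature_k
    m = np.asarray(masses_amu, float) * ME_PER_AMU
    if m.shape != (initial.n_nuclei,):
        raise ValueError("one mass per atom required")
    n_steps = int(round(config.duration_fs / config.time_step_fs))
    rng = np.random.default_rng(config.seed)

    x = initial.positions.copy()
    if initial_velocities is not None:
        v = np.asarray(initial_velocities, float).copy()
    elif kt > 0:
        v = rng.standard_normal(x.shape) * np.sqrt(kt / m)[:, None]
    else:
        v = np.zeros_like(x)
    e, f = potential.energy_forces(x)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1**2) * kt / m)[:, None] if kt > 0 else 0.0

    pos = np.empty((n_steps, *x.shape))
    vel = np.empty_like(pos)
    epot = np.empty(n_steps)
    ekin = np.empty(n_steps)
    e0 = None
    for i in range(n_steps):
        v = v + 0.5 * dt * f / m[:, None]          # B
        x = x + 0.5 * dt * v                        # A
        if gamma > 0 and kt > 0:
            v = c1 * v + c2 * rng.standard_normal(x.shape)   # O
        elif gamma > 0:
            v = c1 * v
        x = x + 0.5 * dt * v                        # A
        e, f = potential.energy_forces(x)
        v = v + 0.5 * dt * f / m[:, None]          # B
        ke = 0.5 * float(np.sum(m[:, None] * v**2))
        pos[i], vel[i], epot[i], ekin[i] = x, v, e, ke
        tot = e + ke
        if e0 is None:
            e0 = tot
        if not np.isfinite(tot) or abs(tot - e0) > max(1e3 * (abs(e0) + 1), 1e6):
            raise RuntimeError(f"MD unstable at step {i}: total energy {tot:g}")
    return MdTrajectory(pos, vel, epot, ekin, config.time_step_fs, np.asarray(masses_amu, float))


@dataclass(frozen=True)
class Spectrum:
    frequencies_cm1: np.ndarray
    intensity: np.ndarray

    def peak_frequency(self) -> float:
        return float(self.frequencies_cm1[np.argmax(self.intensity)])

    @property
    def grid_spacing(self) -> float:
        return float(self.frequencies_cm1[1] - self.frequencies_cm1[0])


def vacf_spectrum(
    velocities: np.ndarray,
    time_step_fs: float,
    masses_amu: Optional[Sequence[float]] = None,
) -> Spectrum:
    """Vibrational power spectrum from the velocity autocorrelation.

    Mass-weighted Hann-windowed periodogram of the velocities (the
    Wiener-Khinchin transform of the VACF), summed over atoms and
    Cartesian components; frequency axis in cm^-1, intensities >= 0 by
    construction.
    """
    v = np.asarray(velocities, float)
    if v.ndim == 1:
        v = v[:, None, None]
    if v.ndim == 2:
        v = v[:, :, None]
    T = v.shape[0]
    if T < 2:
        raise ValueError("need at least two trajectory frames")
    m = np.ones(v.shape[1]) if masses_amu is None else np.asarray(masses_amu, float)
    window = np.hanning(T)[:, None, None]
    fv = np.fft.rfft(v * window, axis=0)
    power = np.sum((m * ME_PER_AMU)[None, :, None] * np.abs(fv) ** 2, axis=(1, 2))
    dt = time_step_fs * AU_PER_FS
    freq_au = np.fft.rfftfreq(T, d=dt)         # cycles per au-time
    freqs = 2.0 * np.pi * freq_au * CM1_PER_HARTREE
    return Spectrum(freqs, power)
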