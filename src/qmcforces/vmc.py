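"""Variational Monte Carlo: Metropolis sampling of |Psi|^2, energy and
force estimators with node regularization, and stochastic-reconfiguration
energy minimization.

The VMC force estimator is the Hellmann-Feynman + Pulay expansion with
mean-energy subtraction for variance reduction,

    F_alpha = -< dE_L/dR_alpha > - 2 < (E_L - Ebar) dlnPsi/dR_alpha >,

averaged over |Psi|^2 (or a guiding density finite at the nodes, with
ratio reweighting).  Near the nodal surface the estimator's variance
diverges; each sample is damped by the polynomial
f_eps(x) = 9x^2 - 15x^4 + 7x^6 for x = d/eps < 1, where d is the node
distance, which is continuous at x = 1 with f(1) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .stats import blocking_error
from .systems import ModelSystem
from .wavefunction import TrialWavefunction, _core, evaluate

__all__ = [
    "VmcConfig",
    "ForceEstimate",
    "EstimatorSeries",
    "VmcResult",
    "f_eps",
    "regularize",
    "run_vmc",
    "vmc_force",
    "parameter_force_term",
    "optimize_sr",
]


@dataclass(frozen=True)
class VmcConfig:
    steps: int = 1000
    walkers: int = 200
    step_size: float = 1.0           # bohr, adapted during burn-in
    burn_in: int = 200
    seed: int = 0
    eps: float = 0.1                 # node-cutoff for force regularization, bohr
    guiding_offset: float = 0.0      # g in Psi_g = sqrt(Psi^2 + (g Psi_ref)^2)
    record_forces: bool = True
    record_param_grads: bool = False
    adapt_step: bool = True

    def __post_init__(self) -> None:
        if self.steps < 1 or self.walkers < 1:
            raise ValueError("steps and walkers must be >= 1")
        if self.eps <= 0:
            raise ValueError("regularization eps must be positive")
        if self.guiding_offset < 0:
            raise ValueError("guiding offset must be >= 0")


@dataclass
class ForceEstimate:
    """Per-nucleus, per-component force with blocking statistical errors."""

    forces: np.ndarray   # (n_n, 3), hartree/bohr
    errors: np.ndarray   # (n_n, 3)
    n_samples: int

    def total(self) -> np.ndarray:
        return self.forces.sum(axis=0)


@dataclass
class EstimatorSeries:
    """Per-step, per-walker estimator terms collected during sampling."""

    e_loc: np.ndarray                 # (S, W)
    weights: np.ndarray               # (S, W)
    node_dist: np.ndarray             # (S, W)
    dln_dR: Optional[np.ndarray]      # (S, W, n_n, 3)
    deL_dR: Optional[np.ndarray]      # (S, W, n_n, 3)
    dln_dp: Optional[np.ndarray]      # (S, W, P)
    eps: float

    @property
    def n_samples(self) -> int:
        return self.e_loc.size

    def energy(self) -> tuple[float, float]:
        """Weighted mean local energy and its blocking error."""
        w, e = self.weights, self.e_loc
        mean = float(np.sum(w * e) / np.sum(w))
        per_step = np.sum(w * e, axis=1) / np.sum(w, axis=1)
        err = blocking_error(per_step) if per_step.size >= 16 else float("nan")
        return mean, err


@dataclass
class VmcResult:
    series: EstimatorSeries
    energy: float
    error: float
    acceptance: float
    step_size: float
    config: VmcConfig


def f_eps(x: np.ndarray) -> np.ndarray:
    """Node-regularization polynomial: 9x^2 - 15x^4 + 7x^6 for x < 1, else 1."""
    x = np.asarray(x, float)
    x2 = np.minimum(x, 1.0) ** 2
    return np.where(x < 1.0, x2 * (9.0 + x2 * (-15.0 + 7.0 * x2)), 1.0)


def regularize(values: np.ndarray, d: np.ndarray, eps: float) -> np.ndarray:
    """Multiply per-sample estimator values by f_eps(d/eps)."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    d = np.asarray(d, float)
    if np.any(d < 0):
        raise ValueError("node distances must be >= 0")
    values = np.asarray(values, float)
    f = f_eps(d / eps)
    return values * f.reshape(f.shape + (1,) * (values.ndim - f.ndim))


def _log_guiding_sq(wf: TrialWavefunction, elec: np.ndarray, offset: float) -> np.ndarray:
    """2 ln Psi_g with Psi_g = sqrt(Psi^2 + (g Psi_ref)^2); Psi_ref nodeless."""
    core = _core(wf, elec, wf.system.geometry.positions)
    la2 = 2.0 * core["log_abs"]
    if offset <= 0:
        return la2, core
    nuc = wf.system.geometry.positions
    s = np.linalg.norm(elec[:, :, None, :] - nuc[None, None, :, :], axis=-1)
    # log Psi_ref = sum_e log sum_a exp(-s_ea)
    m = (-s).max(axis=2)
    ln_ref = np.sum(m + np.log(np.sum(np.exp(-s - m[:, :, None]), axis=2)), axis=1)
    ref2 = 2.0 * (np.log(offset) + ln_ref)
    return np.logaddexp(np.nan_to_num(la2, nan=-np.inf, neginf=-np.inf), ref2), core


def run_vmc(system: ModelSystem, wf: TrialWavefunction, config: VmcConfig) -> VmcResult:
    """Metropolis chain targeting the guiding density, with estimator recording.

    Isotropic Gaussian single-electron moves; the step size is tuned
    toward ~50% acceptance during burn-in and then frozen so the chain is
    reproducible under the seed.  Energies are ratio-reweighted by
    (Psi/Psi_g)^2 when a guiding offset is used.
    """
    if wf.system is not system:
        wf = replace(wf, system=system)
    rng = np.random.default_rng(config.seed)
    n_e, n_n = system.n_electrons, system.geometry.n_nuclei
    W = config.walkers
    elec = (
        system.geometry.positions[np.arange(n_e) % n_n][None, :, :]
        + rng.standard_normal((W, n_e, 3))
    )
    sigma = float(config.step_size)
    g = config.guiding_offset
    lg, _ = _log_guiding_sq(wf, elec, g)

    S = config.steps
    e_loc = np.empty((S, W))
    weights = np.empty((S, W))
    node_dist = np.empty((S, W))
    dln_dR = np.empty((S, W, n_n, 3)) if config.record_forces else None
    deL_dR = np.empty((S, W, n_n, 3)) if config.record_forces else None
    dln_dp = np.empty((S, W, wf.n_params)) if config.record_param_grads else None

    acc_window: list[float] = []
    n_acc = 0
    n_tot = 0
    burn_acc = 0
    for step in range(config.burn_in + S):
        burn = step < config.burn_in
        for e in range(n_e):
            prop = elec.copy()
            prop[:, e, :] += sigma * rng.standard_normal((W, 3))
            lg_new, _ = _log_guiding_sq(wf, prop, g)
            with np.errstate(invalid="ignore"):
                ratio = np.exp(np.minimum(lg_new - lg, 0.0))
            ratio = np.nan_to_num(ratio, nan=0.0)
            acc = rng.random(W) < ratio
            elec[acc] = prop[acc]
            lg[acc] = lg_new[acc]
            if burn:
                acc_window.append(acc.mean())
                burn_acc += acc.sum()
            else:
                n_acc += acc.sum()
                n_tot += W
        if burn and config.adapt_step and len(acc_window) >= 25:
            rate = float(np.mean(acc_window))
            acc_window.clear()
            sigma *= float(np.clip(np.exp(rate - 0.5), 0.5, 2.0))
        if burn and step == config.burn_in - 1 and burn_acc == 0:
            raise RuntimeError(
                "zero Metropolis acceptance during burn-in; reduce step_size"
            )
        if not burn:
            i = step - config.burn_in
            der = evaluate(
                wf, elec, nuclear=config.record_forces, params=config.record_param_grads
            )
            e_loc[i] = der.local_energy
            node_dist[i] = der.node_distance
            if g > 0:
                weights[i] = np.exp(2.0 * der.log_abs - lg)
            else:
                weights[i] = 1.0
            if config.record_forces:
                dln_dR[i] = der.dln_dR
                deL_dR[i] = der.deL_dR
            if config.record_param_grads:
                dln_dp[i] = der.dln_dp

    series = EstimatorSeries(e_loc, weights, node_dist, dln_dR, deL_dR, dln_dp, config.eps)
    energy, err = series.energy()
    acceptance = n_acc / max(n_tot, 1)
    return VmcResult(series, energy, err, acceptance, sigma, config)


def _force_from_terms(w, f, e_loc, dln_dR, deL_dR, ebar, extra=None):
    """Weighted, regularized force samples and per-step means for blocking."""
    de = (e_loc - ebar)[:, :, None, None]
    samp = -(deL_dR + 2.0 * de * dln_dR)
    if extra is not None:
        samp = samp - (e_loc[:, :, None, None] - ebar) * extra
    samp = samp * f[:, :, None, None]
    wx = w[:, :, None, None]
    force = np.sum(wx * samp, axis=(0, 1)) / np.sum(w)
    per_step = np.sum(wx * samp, axis=1) / np.sum(w, axis=1)[:, None, None]
    return force, per_step


def vmc_force(series: EstimatorSeries, eps: Optional[float] = None) -> ForceEstimate:
    """Regularized VMC force estimate with blocking errors."""
    if series.dln_dR is None or series.deL_dR is None:
        raise ValueError("series was recorded without force terms")
    if series.e_loc.size == 0:
        raise ValueError("empty estimator series")
    eps = series.eps if eps is None else eps
    w = series.weights
    ebar = float(np.sum(w * series.e_loc) / np.sum(w))
    f = f_eps(series.node_dist / eps)
    force, per_step = _force_from_terms(w, f, series.e_loc, series.dln_dR, series.deL_dR, ebar)
    n_n = force.shape[0]
    errors = np.empty_like(force)
    for a in range(n_n):
        for i in range(3):
            s = per_step[:, a, i]
            errors[a, i] = blocking_error(s) if s.size >= 16 else np.nan
    return ForceEstimate(force, errors, series.n_samples)


def parameter_force_term(series: EstimatorSeries) -> tuple[np.ndarray, np.ndarray]:
    """dE/dp_i = 2 <(E_L - Ebar) dlnPsi/dp_i>, with blocking errors.

    After a full energy optimization this term is statistically zero, so
    the parameter contribution to the force vanishes.
    """
    if series.dln_dp is None:
        raise ValueError("series was recorded without parameter gradients")
    w = series.weights
    ebar = float(np.sum(w * series.e_loc) / np.sum(w))
    de = (series.e_loc - ebar)[:, :, None]
    samp = 2.0 * de * series.dln_dp
    wx = w[:, :, None]
    vals = np.sum(wx * samp, axis=(0, 1)) / np.sum(w)
    per_step = np.sum(wx * samp, axis=1) / np.sum(w, axis=1)[:, None]
    errs = np.array(
        [
            blocking_error(per_step[:, p]) if per_step.shape[0] >= 16 else np.nan
            for p in range(per_step.shape[1])
        ]
    )
    return vals, errs


def optimize_sr(
    system: ModelSystem,
    wf: TrialWavefunction,
    config: VmcConfig,
    iterations: int = 40,
    damping: float = 0.05,
    step: float = 0.5,
) -> tuple[TrialWavefunction, np.ndarray, np.ndarray]:
    """Stochastic-reconfiguration energy minimization.

    Each iteration samples |Psi|^2, builds the overlap matrix
    S_ij = <O_i O_j> - <O_i><O_j> of the parameter log-derivatives
    O_i = dlnPsi/dp_i and the energy gradient g_i = 2<(E_L - Ebar) O_i>,
    and updates p <- p - step * (S + damping*diag(S))^-1 g.  Returns the
    optimized wavefunction, the energy trace and the parameter trace.
    """
    if wf.n_params < 1:
        raise ValueError("wavefunction has no optimizable parameters")
    energies = []
    ptrace = [wf.params]
    for it in range(iterations):
        cfg = replace(
            config,
            seed=config.seed + 1000 * it,
            record_forces=False,
            record_param_grads=True,
        )
        res = run_vmc(system, wf, cfg)
        s = res.series
        w = s.weights / np.sum(s.weights)
        O = s.dln_dp.reshape(-1, wf.n_params)
        E = s.e_loc.ravel()
        wv = w.ravel()
        obar = wv @ O
        ebar = wv @ E
        grad = 2.0 * ((wv * E) @ O - ebar * obar)
        smat = (O * wv[:, None]).T @ O - np.outer(obar, obar)
        reg = smat + damping * np.diag(np.diag(smat)) + 1e-10 * np.eye(wf.n_params)
        try:
            dp = np.linalg.solve(reg, grad)
        except np.linalg.LinAlgError:
            dp = np.linalg.lstsq(reg, grad, rcond=None)[0]
        wf = wf.with_params(wf.params - step * dp)
        energies.append(res.energy)
        ptrace.append(wf.params)
    return wf, np.array(energies), np.array(ptrace)
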