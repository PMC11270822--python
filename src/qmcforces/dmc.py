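"""Importance-sampled diffusion Monte Carlo with branching, population
control, time-step extrapolation, and three force estimators.

A walker drifts and diffuses with the short-time Green's function,
accepts or rejects the move against the trial density, and multiplies
its weight by the branching factor exp(S) with the symmetrized

    S(R', R) = tau * { E_T - [E_L(R') + E_L(R)] / 2 }.

Forces on the mixed distribution f = Phi * Psi:

* RE (Reynolds): the VMC force estimator averaged over the DMC
  distribution,
* RE-hybrid: 2 F_RE - F_VMC, cancelling the leading mixed-estimator bias
  at the cost of larger fluctuations,
* VD (variational drift-diffusion): RE plus the covariance of E_L with
  the sum of the branching-factor derivatives dS/dR over a trailing
  window of k_hist steps along each walker's ancestry; the
  drift-diffusion part of the Green's-function derivative is
  approximated by its VMC form.  k_hist must exceed the E_L correlation
  time; at k_hist = 0 the estimator reduces exactly to RE.

Stability near the nodes follows common practice: the drift is smoothly
capped, V_bar = V (-1 + sqrt(1 + 2 tau |V|^2)) / (tau |V|^2) per
electron, and E_L entering S is windowed to E_best +/- 2/sqrt(tau).
Per-sample force terms are damped by f_eps(d/eps) as in VMC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .stats import blocking_error
from .systems import ModelSystem
from .vmc import ForceEstimate, f_eps
from .wavefunction import TrialWavefunction, evaluate

__all__ = [
    "Walker",
    "Population",
    "DmcConfig",
    "DmcResult",
    "propagate",
    "branch",
    "update_trial_energy",
    "run_dmc",
    "force_re",
    "force_vd",
    "force_hybrid",
    "timestep_extrapolate",
]


@dataclass(frozen=True)
class DmcConfig:
    tau: float = 0.005               # au
    target_population: int = 200
    k_hist: int = 900                # branching-derivative history window
    steps: int = 2000                # production steps after equilibration
    equilibration: int = 1000
    et_update_period: int = 1
    et_damping: float = 0.02         # population-control feedback gain * tau
    seed: int = 0
    eps: float = 0.05                # node cutoff for DMC force regularization
    record_k: tuple[int, ...] = ()   # extra history windows to record (0 and k_hist always)
    record_forces: bool = True
    block_length: int = 25
    population_bound: float = 8.0    # fatal if N outside target/bound..target*bound

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("time-step tau must be positive")
        if self.k_hist < 0:
            raise ValueError("k_hist must be >= 0")
        if self.target_population < 2:
            raise ValueError("target population must be >= 2")
        ks = sorted(set((0, self.k_hist) + tuple(int(k) for k in self.record_k)))
        object.__setattr__(self, "record_k", tuple(ks))
        if self.record_forces and self.equilibration < max(ks):
            raise ValueError("equilibration must be >= the largest history window")


@dataclass
class Walker:
    """Single DMC sample: coordinates, weight, local energy, and the rolling
    history of branching-factor derivatives dS/dR (newest last)."""

    coords: np.ndarray
    weight: float
    e_loc: float
    history: np.ndarray      # (n_filled, n_n, 3)
    ancestry: int


class Population:
    """Vectorized walker population with a shared ring-buffer history."""

    def __init__(self, coords: np.ndarray, n_nuclei: int, history_cap: int):
        self.coords = np.asarray(coords, float)       # (W, n_e, 3)
        W = self.coords.shape[0]
        self.weights = np.ones(W)
        self.e_loc = np.zeros(W)
        self.ancestry = np.arange(W)
        self.cap = max(int(history_cap), 1)
        self.hist = np.zeros((W, self.cap, n_nuclei, 3))
        self.hist_ptr = 0
        self.hist_filled = 0
        # running trailing-window sums, keyed by window length
        self.hsums: dict[int, np.ndarray] = {}

    @property
    def size(self) -> int:
        return self.coords.shape[0]

    def total_weight(self) -> float:
        return float(self.weights.sum())

    def init_windows(self, ks: Sequence[int]) -> None:
        n_n = self.hist.shape[2]
        for k in ks:
            if k > 0:
                self.hsums[int(k)] = np.zeros((self.size, n_n, 3))

    def push_history(self, ds: np.ndarray) -> None:
        """Append one per-walker dS/dR entry, maintaining window sums."""
        for k, hs in self.hsums.items():
            if self.hist_filled >= k:
                old = self.hist[:, (self.hist_ptr - k) % self.cap]
                hs += ds - old
            else:
                hs += ds
        self.hist[:, self.hist_ptr] = ds
        self.hist_ptr = (self.hist_ptr + 1) % self.cap
        self.hist_filled = min(self.hist_filled + 1, self.cap)

    def window_sum(self, k: int) -> np.ndarray:
        if k == 0:
            return np.zeros((self.size,) + self.hist.shape[2:])
        if k not in self.hsums:
            raise ValueError(f"history window {k} was not recorded")
        if self.hist_filled < k:
            raise ValueError(f"history window {k} exceeds available history ({self.hist_filled})")
        return self.hsums[k]

    def select(self, idx: np.ndarray) -> "Population":
        """Children inherit coordinates and the full history of the parent."""
        new = Population.__new__(Population)
        new.coords = self.coords[idx].copy()
        new.weights = np.ones(len(idx))
        new.e_loc = self.e_loc[idx].copy()
        new.ancestry = self.ancestry[idx].copy()
        new.cap = self.cap
        new.hist = self.hist[idx].copy()
        new.hist_ptr = self.hist_ptr
        new.hist_filled = self.hist_filled
        new.hsums = {k: v[idx].copy() for k, v in self.hsums.items()}
        return new

    def walker(self, i: int) -> Walker:
        order = (np.arange(self.hist_filled) + self.hist_ptr - self.hist_filled) % self.cap
        return Walker(
            coords=self.coords[i].copy(),
            weight=float(self.weights[i]),
            e_loc=float(self.e_loc[i]),
            history=self.hist[i, order].copy(),
            ancestry=int(self.ancestry[i]),
        )


def _capped_drift(drift: np.ndarray, tau: float) -> np.ndarray:
    v2 = np.sum(drift**2, axis=-1, keepdims=True)
    x = tau * v2
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(x < 1e-8, 1.0 - 0.5 * x, (-1.0 + np.sqrt(1.0 + 2.0 * x)) / np.maximum(x, 1e-300))
    return np.nan_to_num(drift * factor, nan=0.0, posinf=0.0, neginf=0.0)


def _window_e(e: np.ndarray, e_best: float, tau: float) -> tuple[np.ndarray, np.ndarray]:
    cut = 2.0 / np.sqrt(tau)
    d = np.clip(e - e_best, -cut, cut)
    return e_best + d, np.abs(e - e_best) > cut


def propagate(
    pop: Population,
    wf: TrialWavefunction,
    tau: float,
    e_t: float,
    rng: np.random.Generator,
    e_best: Optional[float] = None,
    cur=None,
    record_forces: bool = True,
):
    """One drift-diffusion-branching step for the whole population.

    Proposes R' = R + tau V_bar + sqrt(tau) eta, accepts against the trial
    density with the forward/reverse Green's-function ratio (node
    crossings rejected), multiplies the weight by exp(S) with the
    symmetrized S, and appends dS/dR to each walker's history.  Returns
    (cur, acceptance fraction) where ``cur`` caches the evaluation at the
    new positions.
    """
    if tau <= 0:
        raise ValueError("time-step tau must be positive")
    if cur is None:
        cur = evaluate(wf, pop.coords, nuclear=record_forces, params=False)
    if e_best is None:
        e_best = float(np.average(cur.local_energy, weights=pop.weights))

    vbar = _capped_drift(cur.drift, tau)
    noise = rng.standard_normal(pop.coords.shape)
    prop = pop.coords + tau * vbar + np.sqrt(tau) * noise
    new = evaluate(wf, prop, nuclear=record_forces, params=False)
    vbar_new = _capped_drift(new.drift, tau)

    fwd = prop - pop.coords - tau * vbar
    rev = pop.coords - prop - tau * vbar_new
    ln_t = (np.sum(fwd**2, axis=(1, 2)) - np.sum(rev**2, axis=(1, 2))) / (2.0 * tau)
    with np.errstate(invalid="ignore", over="ignore"):
        ln_ratio = 2.0 * (new.log_abs - cur.log_abs) + ln_t
    ok = np.isfinite(new.log_abs) & (new.sign == cur.sign) & (new.sign != 0)
    accept = ok & (np.log(rng.random(pop.size)) < ln_ratio)

    e_cur_w, cap_cur = _window_e(cur.local_energy, e_best, tau)
    e_new_w, cap_new = _window_e(new.local_energy, e_best, tau)
    e_after = np.where(accept, e_new_w, e_cur_w)
    s = tau * (e_t - 0.5 * (e_cur_w + e_after))
    pop.weights = pop.weights * np.exp(s)

    if record_forces:
        d_cur = np.where(cap_cur[:, None, None], 0.0, cur.deL_dR)
        d_new = np.where(cap_new[:, None, None], 0.0, new.deL_dR)
        ds = np.where(
            accept[:, None, None],
            -0.5 * tau * (d_cur + d_new),
            -tau * d_cur,
        )
        pop.push_history(ds)

    # merge accepted proposals into the cached evaluation
    pop.coords[accept] = prop[accept]
    for name in ("log_abs", "sign", "lap_ratio", "local_energy", "node_distance"):
        getattr(cur, name)[accept] = getattr(new, name)[accept]
    cur.drift[accept] = new.drift[accept]
    if record_forces:
        cur.dln_dR[accept] = new.dln_dR[accept]
        cur.deL_dR[accept] = new.deL_dR[accept]
    pop.e_loc = cur.local_energy.copy()
    return cur, float(accept.mean())


def branch(pop: Population, rng: np.random.Generator) -> tuple[Population, np.ndarray]:
    """Stochastic integer splitting/killing: weight w -> floor(w + u) copies.

    Children inherit the parent's coordinates and full history buffer;
    the expected total walker count equals the total weight.
    """
    if pop.size == 0:
        raise RuntimeError("cannot branch an empty population")
    copies = np.floor(pop.weights + rng.random(pop.size)).astype(int)
    if copies.sum() == 0:
        raise RuntimeError(
            "population extinction during branching "
            f"(total weight {pop.total_weight():.3g})"
        )
    idx = np.repeat(np.arange(pop.size), copies)
    return pop.select(idx), idx


def update_trial_energy(
    e_best: float, population: float, target: int, damping: float, tau: float
) -> float:
    """E_T' = E_best - (damping / tau) ln(N / target); keeps N stationary."""
    if population <= 0:
        raise ValueError("population must be positive")
    return e_best - (damping / tau) * np.log(population / target)


@dataclass
class DmcSamples:
    """Per-block accumulated estimator terms (weighted, regularized)."""

    sw: np.ndarray                    # (B,)
    swe: np.ndarray                   # (B,)
    sw_del: Optional[np.ndarray]      # (B, n_n, 3)
    sw_dln: Optional[np.ndarray]
    swe_dln: Optional[np.ndarray]
    sw_hs: dict                       # k -> (B, n_n, 3)
    swe_hs: dict
    eps: float

    def ebar(self) -> float:
        return float(self.swe.sum() / self.sw.sum())


@dataclass
class DmcResult:
    energy: float
    error: float
    samples: DmcSamples
    population_trace: np.ndarray
    acceptance_trace: np.ndarray
    e_t_trace: np.ndarray
    tau: float
    config: DmcConfig

    @property
    def mean_population(self) -> float:
        return float(self.population_trace.mean())


def run_dmc(system: ModelSystem, wf: TrialWavefunction, config: DmcConfig) -> DmcResult:
    """Importance-sampled DMC with population control.

    The mixed-estimator energy is the weight-averaged local energy over
    all post-equilibration steps; for an exact (nodeless) trial
    wavefunction it equals the exact energy at any time-step with zero
    variance.  Estimator terms for the RE/VD forces are accumulated per
    block for blocking error analysis.
    """
    if wf.system is not system:
        wf = replace(wf, system=system)
    rng = np.random.default_rng(config.seed)
    n_e, n_n = system.n_electrons, system.geometry.n_nuclei
    W = config.target_population
    coords = (
        system.geometry.positions[np.arange(n_e) % n_n][None, :, :]
        + rng.standard_normal((W, n_e, 3))
    )
    # short Metropolis warm-up toward |Psi|^2
    cur = evaluate(wf, coords, nuclear=False, params=False)
    for _ in range(100):
        prop = coords + 0.7 * rng.standard_normal(coords.shape)
        new = evaluate(wf, prop, nuclear=False, params=False)
        with np.errstate(invalid="ignore"):
            r = np.exp(np.minimum(2.0 * (new.log_abs - cur.log_abs), 0.0))
        acc = rng.random(W) < np.nan_to_num(r, nan=0.0)
        coords[acc] = prop[acc]
        cur.log_abs[acc] = new.log_abs[acc]

    pop = Population(coords, n_n, max(config.record_k + (1,)))
    pop.init_windows([k for k in config.record_k if k > 0])

    cur = evaluate(wf, pop.coords, nuclear=config.record_forces, params=False)
    pop.e_loc = cur.local_energy.copy()
    e_best = float(np.average(pop.e_loc, weights=pop.weights))
    e_t = e_best
    n_upd = 0

    total = config.equilibration + config.steps
    n_blocks = max(config.steps // config.block_length, 1)
    blk_len = config.block_length
    sw = np.zeros(n_blocks)
    swe = np.zeros(n_blocks)
    if config.record_forces:
        sw_del = np.zeros((n_blocks, n_n, 3))
        sw_dln = np.zeros((n_blocks, n_n, 3))
        swe_dln = np.zeros((n_blocks, n_n, 3))
        sw_hs = {k: np.zeros((n_blocks, n_n, 3)) for k in config.record_k}
        swe_hs = {k: np.zeros((n_blocks, n_n, 3)) for k in config.record_k}
    else:
        sw_del = sw_dln = swe_dln = None
        sw_hs, swe_hs = {}, {}

    pop_trace = np.empty(total)
    acc_trace = np.empty(total)
    et_trace = np.empty(total)

    for step in range(total):
        cur, acc = propagate(
            pop, wf, config.tau, e_t, rng,
            e_best=e_best, cur=cur, record_forces=config.record_forces,
        )
        # accumulate before branching (weights carry exp(S))
        if step >= config.equilibration:
            b = min((step - config.equilibration) // blk_len, n_blocks - 1)
            w = pop.weights
            e = pop.e_loc
            sw[b] += w.sum()
            swe[b] += (w * e).sum()
            if config.record_forces:
                f = f_eps(cur.node_distance / config.eps)
                wf_ = (w * f)[:, None, None]
                sw_del[b] += (wf_ * cur.deL_dR).sum(axis=0)
                sw_dln[b] += (wf_ * cur.dln_dR).sum(axis=0)
                swe_dln[b] += (wf_ * e[:, None, None] * cur.dln_dR).sum(axis=0)
                for k in config.record_k:
                    hs = pop.window_sum(k)
                    sw_hs[k][b] += (wf_ * hs).sum(axis=0)
                    swe_hs[k][b] += (wf_ * e[:, None, None] * hs).sum(axis=0)

        # population control
        nw = pop.total_weight()
        a = max(config.tau / 10.0, 1.0 / (n_upd + 2))
        e_best = (1 - a) * e_best + a * float(np.average(pop.e_loc, weights=pop.weights))
        n_upd += 1
        if step % config.et_update_period == 0:
            e_t = update_trial_energy(e_best, nw, W, config.et_damping, config.tau)
        pop_trace[step] = nw
        acc_trace[step] = acc
        et_trace[step] = e_t

        pop, idx = branch(pop, rng)
        cur = _reindex_eval(cur, idx, config.record_forces)
        if not (W / config.population_bound <= pop.size <= W * config.population_bound):
            raise RuntimeError(
                f"population {pop.size} left bounds around target {W} at step {step}"
            )

    samples = DmcSamples(sw, swe, sw_del, sw_dln, swe_dln, sw_hs, swe_hs, config.eps)
    energy = samples.ebar()
    per_block = swe / sw
    error = blocking_error(per_block) if per_block.size >= 16 else float(
        np.std(per_block, ddof=1) / np.sqrt(max(per_block.size, 2))
    )
    return DmcResult(energy, error, samples, pop_trace, acc_trace, et_trace, config.tau, config)


def _reindex_eval(cur, idx, record_forces):
    for name in ("log_abs", "sign", "lap_ratio", "local_energy", "node_distance", "drift"):
        setattr(cur, name, getattr(cur, name)[idx].copy())
    if record_forces:
        cur.dln_dR = cur.dln_dR[idx].copy()
        cur.deL_dR = cur.deL_dR[idx].copy()
    return cur


def _force_blocks(samples: DmcSamples, k: Optional[int]) -> tuple[np.ndarray, np.ndarray]:
    if samples.sw_del is None:
        raise ValueError("DMC run was made without force recording")
    ebar = samples.ebar()
    num = -(samples.sw_del + 2.0 * (samples.swe_dln - ebar * samples.sw_dln))
    if k is not None and k > 0:
        if k not in samples.sw_hs:
            raise ValueError(f"history window {k} was not recorded during the run")
        num = num - (samples.swe_hs[k] - ebar * samples.sw_hs[k])
    force = num.sum(axis=0) / samples.sw.sum()
    per_block = num / samples.sw[:, None, None]
    return force, per_block


def _estimate(force: np.ndarray, per_block: np.ndarray, n: int) -> ForceEstimate:
    errors = np.empty_like(force)
    B = per_block.shape[0]
    for a in range(force.shape[0]):
        for i in range(3):
            s = per_block[:, a, i]
            errors[a, i] = blocking_error(s) if B >= 16 else np.std(s, ddof=1) / np.sqrt(max(B, 2))
    return ForceEstimate(force, errors, n)


def force_re(result: DmcResult) -> ForceEstimate:
    """Reynolds estimator: the VMC force expression on the DMC distribution."""
    force, blocks = _force_blocks(result.samples, None)
    return _estimate(force, blocks, int(result.samples.sw.sum()))


def force_vd(result: DmcResult, k_hist: Optional[int] = None) -> ForceEstimate:
    """Variational drift-diffusion estimator with a k_hist branching window.

    Reduces exactly to the RE estimator at k_hist = 0; for an exact
    wavefunction (constant E_L) all covariance terms vanish and it equals
    the VMC force.
    """
    k = result.config.k_hist if k_hist is None else int(k_hist)
    if k < 0:
        raise ValueError("k_hist must be >= 0")
    force, blocks = _force_blocks(result.samples, k)
    return _estimate(force, blocks, int(result.samples.sw.sum()))


def force_hybrid(f_re: ForceEstimate, f_vmc: ForceEstimate) -> ForceEstimate:
    """Generalized hybrid estimator 2 F_RE - F_VMC (independent-run errors)."""
    if f_re.forces.shape != f_vmc.forces.shape:
        raise ValueError("force estimates have mismatched shapes")
    return ForceEstimate(
        2.0 * f_re.forces - f_vmc.forces,
        np.sqrt(4.0 * f_re.errors**2 + f_vmc.errors**2),
        f_re.n_samples,
    )


def timestep_extrapolate(
    results: Sequence[tuple[float, float, float]]
) -> tuple[float, float]:
    """Error-weighted linear fit E(tau) = a + b tau; returns (a, sigma_a).

    Duplicate time-steps are inverse-variance averaged before the fit; at
    least two distinct time-steps are required.
    """
    by_tau: dict[float, list[tuple[float, float]]] = {}
    for tau, val, err in results:
        by_tau.setdefault(float(tau), []).append((float(val), float(err)))
    if len(by_tau) < 2:
        raise ValueError("need at least two distinct time-steps to extrapolate")
    taus, vals, errs = [], [], []
    for tau, entries in sorted(by_tau.items()):
        v = np.array([e[0] for e in entries])
        s = np.array([e[1] for e in entries])
        if np.all(s > 0):
            wts = 1.0 / s**2
            vals.append(np.sum(wts * v) / np.sum(wts))
            errs.append(1.0 / np.sqrt(np.sum(wts)))
        else:
            vals.append(v.mean())
            errs.append(0.0)
        taus.append(tau)
    taus = np.array(taus)
    vals = np.array(vals)
    errs = np.array(errs)
    wts = np.ones_like(errs) if np.any(errs == 0) else 1.0 / errs**2
    X = np.stack([np.ones_like(taus), taus], axis=1)
    A = X.T @ (wts[:, None] * X)
    beta = np.linalg.solve(A, X.T @ (wts * vals))
    cov = np.linalg.inv(A)
    if np.any(errs == 0):
        sigma = 0.0
    else:
        sigma = float(np.sqrt(cov[0, 0]))
    return float(beta[0]), sigma
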