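"""Jastrow-Slater trial wavefunctions and every derivative the estimators need.

The wavefunction is Psi(R) = J(R) * sum_i c_i D_i(R) with a strictly
positive Jastrow correlation factor J = exp(U) and a linear expansion of
determinants D_i over s-type exponential ("slater") and Gaussian
primitives centered on the nuclei.  With one or two electrons a
determinant reduces to a product of occupied orbitals (opposite spins),
which is all the analytic oracle systems require.

Everything is evaluated in the log domain, vectorized over a batch of
electron configurations, and returns:

* log|Psi| and its sign,
* the drift velocity V = grad log|Psi| per electron,
* the Laplacian ratio lap(Psi)/Psi and the local energy E_L,
* nuclear log-derivatives d ln Psi / d R_alpha (Jastrow electron-nucleus
  terms plus the Pulay dependence through atom-centered orbitals),
* nuclear derivatives of the local energy (centered finite differences,
  step 1e-5 bohr),
* log-derivatives with respect to every optimizable parameter,
* the node distance d = |Psi| / |grad Psi|, zero exactly on a node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .systems import (
    AnalyticReference,
    CoulombPotential,
    Geometry,
    HarmonicPotential,
    ModelSystem,
)

__all__ = [
    "Orbital",
    "JastrowFactor",
    "DeterminantExpansion",
    "TrialWavefunction",
    "WfDerivatives",
    "evaluate",
    "local_energy",
    "node_distance",
    "parameter_gradients",
    "exact_wavefunction",
    "slater_lcao",
    "save_wavefunction",
    "load_wavefunction",
]


@dataclass(frozen=True)
class Orbital:
    """s-type primitive centered on nucleus ``center``.

    kind "slater": exp(-zeta |r - R_c|); kind "gaussian": exp(-zeta |r - R_c|^2).
    """

    kind: str
    zeta: float
    center: int

    def __post_init__(self) -> None:
        if self.kind not in ("slater", "gaussian"):
            raise ValueError(f"unknown orbital kind {self.kind!r}")
        if self.zeta <= 0:
            raise ValueError("orbital exponent must be positive")


@dataclass(frozen=True, eq=False)
class JastrowFactor:
    """exp(U) with U = sum_{e,a} en[a] * s/(1+s) + sum_{e<e'} ee * r/(1+r).

    The Pade form s/(1+s) saturates at large separation, so the factor is
    strictly positive and bounded; linear parameters make the log-derivative
    with respect to each parameter equal to its correlation term.
    """

    en: np.ndarray
    ee: Optional[float] = None

    def __post_init__(self) -> None:
        en = np.atleast_1d(np.asarray(self.en, float))
        object.__setattr__(self, "en", en)
        if not np.all(np.isfinite(en)):
            raise ValueError("Jastrow parameters must be finite")
        if self.ee is not None and not np.isfinite(self.ee):
            raise ValueError("Jastrow parameters must be finite")


@dataclass(frozen=True, eq=False)
class DeterminantExpansion:
    orbitals: tuple[Orbital, ...]
    determinants: tuple[tuple[int, ...], ...]
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "orbitals", tuple(self.orbitals))
        dets = tuple(tuple(int(o) for o in d) for d in self.determinants)
        object.__setattr__(self, "determinants", dets)
        c = np.atleast_1d(np.asarray(self.coefficients, float))
        object.__setattr__(self, "coefficients", c)
        if len(dets) != c.size or c.size == 0:
            raise ValueError("one coefficient per determinant required")
        if not np.any(c != 0):
            raise ValueError("coefficient vector must be nonzero")
        if len(set(dets)) != len(dets):
            raise ValueError("occupation patterns must be distinct")
        n_orb = len(self.orbitals)
        n_e = len(dets[0])
        for d in dets:
            if len(d) != n_e:
                raise ValueError("all determinants must occupy the same electron count")
            if any(o < 0 or o >= n_orb for o in d):
                raise ValueError("determinant references unknown orbital")


@dataclass(frozen=True, eq=False)
class TrialWavefunction:
    """Jastrow-Slater wavefunction bound to a model system.

    ``optimize`` selects which parameter groups enter the variational
    parameter vector (order fixed: jastrow_en, jastrow_ee, coefficients,
    exponents).
    """

    system: ModelSystem
    jastrow: JastrowFactor
    determinantal: DeterminantExpansion
    optimize: tuple[str, ...] = ("jastrow_en", "exponents")

    _GROUPS = ("jastrow_en", "jastrow_ee", "coefficients", "exponents")

    def __post_init__(self) -> None:
        object.__setattr__(self, "optimize", tuple(self.optimize))
        for g in self.optimize:
            if g not in self._GROUPS:
                raise ValueError(f"unknown parameter group {g!r}")
        if self.jastrow.en.size != self.system.geometry.n_nuclei:
            raise ValueError("one electron-nucleus Jastrow parameter per nucleus")
        for orb in self.determinantal.orbitals:
            if orb.center >= self.system.geometry.n_nuclei:
                raise ValueError("orbital center references missing nucleus")
        if len(self.determinantal.determinants[0]) != self.system.n_electrons:
            raise ValueError("determinants must occupy n_electrons orbitals")

    # -- variational parameter vector ------------------------------------
    @property
    def params(self) -> np.ndarray:
        chunks = []
        if "jastrow_en" in self.optimize:
            chunks.append(self.jastrow.en)
        if "jastrow_ee" in self.optimize and self.jastrow.ee is not None:
            chunks.append([self.jastrow.ee])
        if "coefficients" in self.optimize:
            chunks.append(self.determinantal.coefficients)
        if "exponents" in self.optimize:
            chunks.append([o.zeta for o in self.determinantal.orbitals])
        if not chunks:
            return np.empty(0)
        return np.concatenate([np.atleast_1d(np.asarray(c, float)) for c in chunks])

    @property
    def n_params(self) -> int:
        return self.params.size

    def with_params(self, vec: np.ndarray) -> "TrialWavefunction":
        vec = np.asarray(vec, float)
        if vec.shape != (self.n_params,):
            raise ValueError("parameter vector has wrong length")
        i = 0
        jas, det = self.jastrow, self.determinantal
        if "jastrow_en" in self.optimize:
            n = jas.en.size
            jas = replace(jas, en=vec[i : i + n].copy())
            i += n
        if "jastrow_ee" in self.optimize and self.jastrow.ee is not None:
            jas = replace(jas, ee=float(vec[i]))
            i += 1
        if "coefficients" in self.optimize:
            n = det.coefficients.size
            det = replace(det, coefficients=vec[i : i + n].copy())
            i += n
        if "exponents" in self.optimize:
            orbs = tuple(
                replace(o, zeta=float(max(vec[i + k], 1e-3)))
                for k, o in enumerate(det.orbitals)
            )
            det = replace(det, orbitals=orbs)
            i += len(orbs)
        return replace(self, jastrow=jas, determinantal=det)

    def with_geometry(self, geometry: Geometry) -> "TrialWavefunction":
        return replace(self, system=self.system.with_geometry(geometry))


@dataclass
class WfDerivatives:
    """All per-sample quantities the VMC/DMC estimators consume (batched)."""

    log_abs: np.ndarray          # (B,)
    sign: np.ndarray             # (B,)
    drift: np.ndarray            # (B, n_e, 3), grad log|Psi|, 1/bohr
    lap_ratio: np.ndarray        # (B,), lap(Psi)/Psi summed over electrons
    local_energy: np.ndarray     # (B,), hartree
    dln_dR: np.ndarray           # (B, n_n, 3)
    deL_dR: Optional[np.ndarray]  # (B, n_n, 3), hartree/bohr
    dln_dp: Optional[np.ndarray]  # (B, P)
    node_distance: np.ndarray    # (B,), bohr


# ---------------------------------------------------------------------------
# core evaluation


def _pade(s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """u = s/(1+s) and its first two radial derivatives."""
    d = 1.0 + s
    return s / d, 1.0 / d**2, -2.0 / d**3


def _orbital_tables(wf, elec, nuclei):
    """Per (sample, electron, orbital): log value, grad-log, lap ratio,
    d ln / d zeta, d ln / d R_center (sign such that adding it moves the center).
    """
    dets = wf.determinantal
    B, n_e = elec.shape[:2]
    n_o = len(dets.orbitals)
    logv = np.empty((B, n_e, n_o))
    glog = np.empty((B, n_e, n_o, 3))
    lap = np.empty((B, n_e, n_o))
    dzeta = np.empty((B, n_e, n_o))
    dcent = np.empty((B, n_e, n_o, 3))
    for k, orb in enumerate(dets.orbitals):
        rc = elec - nuclei[orb.center][None, None, :]  # (B, n_e, 3)
        s = np.linalg.norm(rc, axis=-1)
        z = orb.zeta
        if orb.kind == "slater":
            with np.errstate(divide="ignore", invalid="ignore"):
                unit = rc / s[..., None]
                logv[:, :, k] = -z * s
                glog[:, :, k] = -z * unit
                lap[:, :, k] = z * z - 2.0 * z / s
                dzeta[:, :, k] = -s
                dcent[:, :, k] = z * unit
        else:  # gaussian
            logv[:, :, k] = -z * s**2
            glog[:, :, k] = -2.0 * z * rc
            lap[:, :, k] = 4.0 * z * z * s**2 - 6.0 * z
            dzeta[:, :, k] = -(s**2)
            dcent[:, :, k] = 2.0 * z * rc
    return logv, glog, lap, dzeta, dcent


def _core(wf: TrialWavefunction, elec: np.ndarray, nuclei: np.ndarray,
          want_param: bool = False, want_nuclear: bool = False):
    """Log-domain evaluation of the full wavefunction on a batch.

    Evaluation exactly on a node legitimately produces inf/nan entries;
    they are flagged (sign 0, node distance 0) by the callers, so float
    warnings are suppressed for the whole computation.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        return _core_impl(wf, elec, nuclei, want_param, want_nuclear)


def _core_impl(wf, elec, nuclei, want_param, want_nuclear):
    dets = wf.determinantal
    jas = wf.jastrow
    B, n_e = elec.shape[:2]
    n_n = nuclei.shape[0]
    logv, glog, lap, dzeta, dcent = _orbital_tables(wf, elec, nuclei)

    occ = np.array(dets.determinants)            # (n_d, n_e)
    n_d = occ.shape[0]
    # log-product per determinant, stabilized by the per-sample maximum
    lp = np.empty((B, n_d))
    for d in range(n_d):
        lp[:, d] = logv[:, np.arange(n_e), occ[d]].sum(axis=1)
    M = lp.max(axis=1)
    expl = np.exp(lp - M[:, None])
    dtil = expl @ dets.coefficients              # (B,)
    with np.errstate(divide="ignore", invalid="ignore"):
        wgt = dets.coefficients[None, :] * expl / dtil[:, None]   # signed, sums to 1

    # determinant part derivatives
    grad_lnD = np.zeros((B, n_e, 3))
    lapD = np.zeros((B,))
    for d in range(n_d):
        g = glog[:, np.arange(n_e), occ[d]]       # (B, n_e, 3)
        grad_lnD += wgt[:, d, None, None] * g
        lapD += wgt[:, d] * lap[:, np.arange(n_e), occ[d]].sum(axis=1)

    # Jastrow: electron-nucleus
    rn = elec[:, :, None, :] - nuclei[None, None, :, :]     # (B, n_e, n_n, 3)
    sn = np.linalg.norm(rn, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        un_hat = rn / sn[..., None]
    u, up, upp = _pade(sn)
    a = jas.en[None, None, :]
    U = np.sum(a * u, axis=(1, 2))
    grad_U = np.sum((a * up)[..., None] * un_hat, axis=2)   # (B, n_e, 3)
    lap_U = np.sum(a * (upp + 2.0 * up / sn), axis=(1, 2))
    # electron-electron
    if jas.ee is not None and n_e >= 2:
        for i in range(n_e):
            for j in range(i + 1, n_e):
                rij = elec[:, i] - elec[:, j]
                r = np.linalg.norm(rij, axis=-1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    hat = rij / r[:, None]
                ue, uep, uepp = _pade(r)
                U += jas.ee * ue
                grad_U[:, i] += (jas.ee * uep)[:, None] * hat
                grad_U[:, j] -= (jas.ee * uep)[:, None] * hat
                lap_U += 2.0 * jas.ee * (uepp + 2.0 * uep / r)

    log_abs = M + np.log(np.abs(dtil)) + U
    sign = np.sign(dtil)
    drift = grad_lnD + grad_U
    lap_ratio = (
        lapD
        + 2.0 * np.sum(grad_lnD * grad_U, axis=(1, 2))
        + np.sum(grad_U**2, axis=(1, 2))
        + lap_U
    )

    out = {"log_abs": log_abs, "sign": sign, "drift": drift, "lap_ratio": lap_ratio}

    if want_nuclear:
        dln_dR = np.zeros((B, n_n, 3))
        # Jastrow e-n: moving nucleus alpha changes s = |r - R_alpha|
        dln_dR += np.sum((a * up)[..., None] * (-un_hat), axis=1)
        # Pulay term through atom-centered orbitals
        for d in range(n_d):
            for e in range(n_e):
                k = occ[d, e]
                c = dets.orbitals[k].center
                dln_dR[:, c, :] += wgt[:, d, None] * dcent[:, e, k]
        out["dln_dR"] = dln_dR

    if want_param:
        cols = []
        if "jastrow_en" in wf.optimize:
            cols.append(np.sum(u, axis=1))                    # (B, n_n)
        if "jastrow_ee" in wf.optimize and jas.ee is not None:
            tot = np.zeros((B,))
            for i in range(n_e):
                for j in range(i + 1, n_e):
                    r = np.linalg.norm(elec[:, i] - elec[:, j], axis=-1)
                    tot += _pade(r)[0]
            cols.append(tot[:, None])
        if "coefficients" in wf.optimize:
            with np.errstate(divide="ignore", invalid="ignore"):
                cols.append(expl / dtil[:, None])             # (B, n_d)
        if "exponents" in wf.optimize:
            dz = np.zeros((B, len(dets.orbitals)))
            for d in range(n_d):
                for e in range(n_e):
                    k = occ[d, e]
                    dz[:, k] += wgt[:, d] * dzeta[:, e, k]
            cols.append(dz)
        out["dln_dp"] = (
            np.concatenate(cols, axis=1) if cols else np.empty((B, 0))
        )
    return out


def _as_batch(electrons: np.ndarray, n_e: int) -> tuple[np.ndarray, bool]:
    elec = np.asarray(electrons, float)
    if elec.ndim == 2:
        return elec[None, :, :], True
    if elec.ndim == 3 and elec.shape[1] == n_e:
        return elec, False
    raise ValueError("electrons must have shape (n_e, 3) or (B, n_e, 3)")


def evaluate(
    wf: TrialWavefunction,
    electrons: np.ndarray,
    *,
    nuclear: bool = True,
    params: bool = True,
    el_step: float = 1e-5,
) -> WfDerivatives:
    """Full evaluation: value, drift, local energy, nuclear and parameter
    derivatives, and node distance, for a batch of electron configurations.

    ``deL_dR`` is obtained by centered finite differences over the nuclear
    coordinates (step ``el_step`` bohr); the wavefunction follows the
    nuclei through its orbital centers and electron-nucleus Jastrow terms.
    """
    elec, single = _as_batch(electrons, wf.system.n_electrons)
    nuclei = wf.system.geometry.positions
    core = _core(wf, elec, nuclei, want_param=params, want_nuclear=nuclear)
    v_pot = wf.system.potential_energy(elec)
    e_loc = -0.5 * core["lap_ratio"] + v_pot

    drift = core["drift"]
    dnorm = np.sqrt(np.sum(drift**2, axis=(1, 2)))
    with np.errstate(divide="ignore", invalid="ignore"):
        node_d = 1.0 / dnorm
    bad = ~np.isfinite(core["log_abs"]) | ~np.isfinite(dnorm) | (core["sign"] == 0)
    node_d = np.where(bad, 0.0, node_d)

    deL = None
    if nuclear:
        n_n = nuclei.shape[0]
        deL = np.empty((elec.shape[0], n_n, 3))
        for a_ in range(n_n):
            for i in range(3):
                for sgn, slot in ((+1, 0), (-1, 1)):
                    shifted = nuclei.copy()
                    shifted[a_, i] += sgn * el_step
                    geo = wf.system.geometry.with_positions(shifted)
                    c = _core(wf, elec, shifted)
                    el = -0.5 * c["lap_ratio"] + wf.system.potential_energy(elec, geo)
                    if slot == 0:
                        plus = el
                    else:
                        deL[:, a_, i] = (plus - el) / (2.0 * el_step)

    return WfDerivatives(
        log_abs=core["log_abs"],
        sign=core["sign"],
        drift=drift,
        lap_ratio=core["lap_ratio"],
        local_energy=e_loc,
        dln_dR=core.get("dln_dR"),
        deL_dR=deL,
        dln_dp=core.get("dln_dp"),
        node_distance=node_d,
    )


def local_energy(system: ModelSystem, wf: TrialWavefunction, electrons: np.ndarray) -> np.ndarray:
    """E_L = -1/2 lap(Psi)/Psi + V; constant iff Psi is an exact eigenfunction."""
    if system is not wf.system and system != wf.system:
        wf = replace(wf, system=system)
    elec, single = _as_batch(electrons, system.n_electrons)
    core = _core(wf, elec, system.geometry.positions)
    el = -0.5 * core["lap_ratio"] + system.potential_energy(elec)
    return el[0] if single else el


def node_distance(wf: TrialWavefunction, electrons: np.ndarray) -> np.ndarray:
    """First-order distance to the nodal surface, |Psi| / |grad Psi|."""
    elec, single = _as_batch(electrons, wf.system.n_electrons)
    d = evaluate(wf, elec, nuclear=False, params=False).node_distance
    return float(d[0]) if single else d


def parameter_gradients(wf: TrialWavefunction, electrons: np.ndarray) -> np.ndarray:
    """d ln Psi / d p_i for every optimizable parameter."""
    elec, single = _as_batch(electrons, wf.system.n_electrons)
    g = evaluate(wf, elec, nuclear=False, params=True).dln_dp
    return g[0] if single else g


# ---------------------------------------------------------------------------
# constructors


def _wf_from_spec(system: ModelSystem, spec: dict,
                  jastrow_en: Optional[Sequence[float]] = None,
                  jastrow_ee: Optional[float] = None,
                  optimize: tuple[str, ...] = ("jastrow_en", "exponents")) -> TrialWavefunction:
    orbitals = tuple(
        Orbital(o["kind"], float(o["zeta"]), int(o["center"])) for o in spec["orbitals"]
    )
    det = DeterminantExpansion(
        orbitals,
        tuple(tuple(d) for d in spec["determinants"]),
        np.asarray(spec["coefficients"], float),
    )
    en = np.zeros(system.geometry.n_nuclei) if jastrow_en is None else np.asarray(jastrow_en, float)
    jas = JastrowFactor(en, jastrow_ee)
    return TrialWavefunction(system, jas, det, optimize)


def exact_wavefunction(system: ModelSystem) -> TrialWavefunction:
    """The analytic ground state of a system with a closed-form reference."""
    if system.reference is None or system.reference.wavefunction_spec is None:
        raise ValueError(f"system {system.name} has no analytic wavefunction")
    return _wf_from_spec(system, system.reference.wavefunction_spec)


def slater_lcao(
    system: ModelSystem,
    zeta: float | Sequence[float],
    jastrow_en: Optional[Sequence[float]] = None,
    coefficients: Optional[Sequence[float]] = None,
    optimize: tuple[str, ...] = ("jastrow_en", "exponents"),
) -> TrialWavefunction:
    """One s-type exponential per nucleus, symmetric combination by default."""
    n_n = system.geometry.n_nuclei
    zetas = np.broadcast_to(np.atleast_1d(np.asarray(zeta, float)), (n_n,))
    spec = {
        "orbitals": [{"kind": "slater", "zeta": float(z), "center": a} for a, z in enumerate(zetas)],
        "determinants": [[a] for a in range(n_n)] if system.n_electrons == 1 else None,
        "coefficients": list(coefficients) if coefficients is not None else [1.0] * n_n,
    }
    if system.n_electrons != 1:
        raise NotImplementedError("slater_lcao builds one-electron wavefunctions")
    return _wf_from_spec(system, spec, jastrow_en=jastrow_en, optimize=optimize)


# ---------------------------------------------------------------------------
# serialization (deterministic round-trip)


def _system_to_dict(system: ModelSystem) -> dict:
    pot = system.potential
    if isinstance(pot, HarmonicPotential):
        pot_d = {"kind": "harmonic", "k": pot.k, "center_index": pot.center_index}
    elif isinstance(pot, CoulombPotential):
        pot_d = {"kind": "coulomb"}
    else:
        raise ValueError("cannot serialize this potential")
    d = {
        "name": system.name,
        "n_electrons": system.n_electrons,
        "positions": system.geometry.positions.tolist(),
        "charges": system.geometry.charges.tolist(),
        "labels": list(system.geometry.labels),
        "potential": pot_d,
    }
    if system.reference is not None:
        d["reference"] = {
            "energy": system.reference.energy,
            "forces": np.asarray(system.reference.forces).tolist(),
            "wavefunction_spec": system.reference.wavefunction_spec,
        }
    return d


def _system_from_dict(d: dict) -> ModelSystem:
    geo = Geometry(np.array(d["positions"]), np.array(d["charges"]), tuple(d["labels"]))
    pd = d["potential"]
    if pd["kind"] == "harmonic":
        pot = HarmonicPotential(k=pd["k"], center_index=pd["center_index"])
    else:
        pot = CoulombPotential()
    ref = None
    if "reference" in d:
        r = d["reference"]
        ref = AnalyticReference(r["energy"], np.array(r["forces"]), r.get("wavefunction_spec"))
    return ModelSystem(geo, int(d["n_electrons"]), pot, ref, name=d.get("name", "system"))


def wavefunction_to_dict(wf: TrialWavefunction) -> dict:
    return {
        "format": "qmcforces-wf-1",
        "system": _system_to_dict(wf.system),
        "jastrow": {
            "en": wf.jastrow.en.tolist(),
            "ee": wf.jastrow.ee,
        },
        "orbitals": [
            {"kind": o.kind, "zeta": o.zeta, "center": o.center}
            for o in wf.determinantal.orbitals
        ],
        "determinants": [list(d) for d in wf.determinantal.determinants],
        "coefficients": wf.determinantal.coefficients.tolist(),
        "optimize": list(wf.optimize),
    }


def wavefunction_from_dict(d: dict) -> TrialWavefunction:
    if d.get("format") != "qmcforces-wf-1":
        raise ValueError("unrecognized wavefunction file format")
    system = _system_from_dict(d["system"])
    wf = _wf_from_spec(
        system,
        {
            "orbitals": d["orbitals"],
            "determinants": d["determinants"],
            "coefficients": d["coefficients"],
        },
        jastrow_en=d["jastrow"]["en"],
        jastrow_ee=d["jastrow"]["ee"],
        optimize=tuple(d["optimize"]),
    )
    return wf


def save_wavefunction(wf: TrialWavefunction, path) -> None:
    with open(path, "w") as fh:
        json.dump(wavefunction_to_dict(wf), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_wavefunction(path) -> TrialWavefunction:
    with open(path) as fh:
        return wavefunction_from_dict(json.load(fh))
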