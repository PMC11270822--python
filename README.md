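# qmcforces

Quantum Monte Carlo energies and **nuclear forces** for molecular model
systems, with the machinery needed to turn those forces into
machine-learned force fields: variational Monte Carlo (VMC) and
fixed-node diffusion Monte Carlo (DMC) engines, three DMC force
estimators, CIPSI selected configuration interaction with Epstein-Nesbet
PT2, and a dataset-curation / kernel-model / Langevin-MD / vibrational-
spectrum pipeline.  Everything is validated against analytic
few-particle systems whose ground states are known in closed form.

It is written for people who study QMC force estimators and QMC-trained
force fields and want a small, fully testable implementation of the
whole chain — not for production many-electron chemistry.

## The methods

The energy is `E = ∫ dR P(R) E_L(R)` with local energy
`E_L = (HΨ)/Ψ`, sampled from `P ∝ |Ψ|²` (VMC) or from the mixed
distribution `P ∝ ΦΨ` (DMC), where Φ is the fixed-node solution grown by
the short-time Green's function with drift `V = ∇Ψ/Ψ` and branching
factor `exp(S)`, `S = τ{E_T − [E_L(R′)+E_L(R)]/2}`.

Forces are `F_α = −dE/dR_α`.  The package implements:

* **VMC**: the Hellmann-Feynman + Pulay estimator
  `F_α = −⟨∂E_L/∂R_α⟩ − 2⟨(E_L−Ē) ∂lnΨ/∂R_α⟩`, exact against the VMC
  energy surface once the wavefunction is fully energy-optimized
  (stochastic reconfiguration is included);
* **DMC-RE** (Reynolds): the VMC expression averaged over the mixed
  distribution — cheap but biased when Ψ is approximate;
* **DMC-VD** (variational drift-diffusion): RE plus the covariance of
  `E_L` with the sum of branching-factor derivatives `∂S/∂R_α` over a
  trailing window of `k_hist` steps along each walker's ancestry — the
  window must exceed the `E_L` correlation time, and the estimator costs
  nothing beyond the stored histories;
* **RE-hybrid**: `2F_RE − F_VMC`, cancelling the leading
  mixed-estimator bias at the price of larger fluctuations.

All force estimators diverge in variance near the nodal surface; each
sample is damped by `f_ε(x) = 9x² − 15x⁴ + 7x⁶` for `x = d/ε < 1`, with
`d = |Ψ|/|∇Ψ|` the node distance (defaults ε = 0.1 au in VMC, 0.05 au
in DMC).

The determinantal part of the Jastrow-Slater trial function can be grown
by **CIPSI**: external determinants are ranked by their Epstein-Nesbet
second-order contribution `e_γ = |⟨γ|H|Ψ⟩|²/(E − H_γγ)` and absorbed
iteratively; the total `E^(PT2)` → 0 at full CI, and expansions at
different geometries can be built to **match** a shared `E^(PT2)`
target, balancing wavefunction quality across a potential-energy
surface.

Downstream, configuration pools are curated by geometry clustering
(40 clusters) plus per-cluster energy k-means (5 each), a kernel ridge
model is trained on forces, scored by the mean absolute deviation
(kcal/mol/Å), and driven through BAOAB Langevin MD to
velocity-autocorrelation vibrational spectra.

## A worked example

`examples/03_dmc_force_estimators.py` runs all three DMC estimators on
the one-electron two-center molecule at separation 2 bohr with a
deliberately poor trial wavefunction (bare atomic-orbital LCAO, no
Jastrow):

```
measured E_L correlation time: 38 steps -> k_hist = 227
DMC energy: -0.60457 +- 0.00150 hartree
  VMC    force (z, nucleus B): +0.0551 +- 0.0027
  RE     force (z, nucleus B): +0.0285 +- 0.0022
  hybrid force (z, nucleus B): +0.0019 +- 0.0052
  VD     force (z, nucleus B): +0.0057 +- 0.0025
```

The molecule sits essentially at its equilibrium separation, so the true
force is ≈ 0.  The raw VMC estimator on this poor wavefunction is badly
off (+0.055 hartree/bohr), RE halves the error but remains biased
(+0.029), while the hybrid and VD estimators recover the correct answer
— VD with error bars as small as RE's.  The other examples walk through
the zero-variance checks, VMC force/energy consistency, CIPSI and PT2
matching, dataset curation and kernel training, and MD spectra; each
prints the numbers it computes and what they mean.

A thin CLI mirrors the library (`qmcforces vmc|dmc|extrapolate|cipsi|
match-pt2|curate|sample-hist|train|mad|md|spectrum|fixtures`); every
stage takes a seed and echoes its full configuration into a JSON run
archive so results are reproducible bit for bit.

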