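# Methods

`qmcforces` implements variational and diffusion Monte Carlo energies
and nuclear forces, a CIPSI selected-CI layer, and a downstream
machine-learned force-field pipeline, all validated on analytic
few-particle model systems.  This note records the models, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.
Internal units are Hartree atomic units throughout; Angstrom, kcal/mol,
fs, K and cm^-1 appear only at the I/O boundary.

## Model systems and oracles

Every estimator in the package is checked against a system whose answer
is known independently:

* **Hydrogenic atom** (charge Z): exact ground state `exp(-Z r)`,
  energy `-Z^2/2`, zero nuclear force by symmetry.
* **3D harmonic well** (spring k): exact ground state
  `exp(-sqrt(k) r^2 / 2)`, energy `(3/2) sqrt(k)`, zero force.
* **Two-center one-electron molecule** (H2+-like, nuclear repulsion
  included): no closed form; its force oracle is a centered finite
  difference of independently computed energies, `F = -dE/dR`, which
  shares no code with any estimator under test.
* **Toy CI Hamiltonians**: a one-electron two-level model whose full CI
  is the closed-form 2x2 eigenproblem, and seeded random Hermitian
  integral tables with exact 8-fold two-electron symmetry.
* **Analytic nuclear surfaces** for the force-field pipeline: pair
  springs between all atoms (forces a function of internal geometry,
  hence learnable from distance descriptors) and independent per-atom
  springs (ideal for thermostat and spectrum benchmarks).

The finite-difference oracle uses step 0.01 bohr by default with the
two runs' statistical errors propagated in quadrature.  For *stochastic*
(VMC/DMC) energies the studies use step 0.05 bohr instead: the noise of
a centered difference scales as sigma_E / (2h), and at desk-scale
statistics 0.01 bohr would bury the signal, while the O(h^2) truncation
error at 0.05 bohr (~1e-4 hartree/bohr here) stays far below the
stochastic error bars.

## Trial wavefunctions

Jastrow-Slater form `Psi = exp(U) * sum_i c_i D_i` with s-type
exponential and Gaussian primitives centered on nuclei, and a Pade
Jastrow `U = sum a_alpha s/(1+s) + b r_ee/(1+r_ee)` whose linear
parameters make `d lnPsi / d p` equal to the correlation term itself.
With one or two electrons a determinant is a product of occupied
orbitals (opposite spins), which is all the oracle systems need; higher
angular momenta, backflow and three-body terms are out of scope.

Evaluation is in the log domain, batched over walker configurations.
Analytic expressions supply the drift `V = grad ln|Psi|`, the Laplacian
ratio, the parameter log-derivatives, and the nuclear log-derivatives
(the electron-nucleus Jastrow term plus the Pulay dependence through the
atom-centered orbitals, for which `d lnphi / d R_c = -grad_r lnphi`).
The nuclear derivative of the local energy is a centered finite
difference over the nuclear coordinates (step 1e-5 bohr); the tests
cross-check it against an independent step and every analytic derivative
against finite differences.

**Node distance.** The regularization needs a quantity that vanishes on
the nodal surface; the package uses the first-order distance
`d = |Psi| / |grad Psi|` (equivalently `1/|V|`).  The reciprocal
`|grad Psi / Psi|` diverges at a node and cannot serve as a distance,
so the distance convention is adopted and documented here.

## VMC

Metropolis sampling with isotropic Gaussian single-electron moves; the
proposal width is tuned toward ~50% acceptance during burn-in and then
frozen, so a chain is bit-reproducible under its seed.  An optional
guiding density `Psi_g = sqrt(Psi^2 + (g Psi_ref)^2)` (with `Psi_ref` a
nodeless sum of nuclear exponentials) is finite at the nodes; samples
are reweighted by `(Psi/Psi_g)^2`.  The exact guiding form used in
production QMC codes is not uniquely prescribed; this smooth floor
satisfies the same contract and reduces to plain `|Psi|^2` at `g = 0`.

The force estimator is the Hellmann-Feynman + Pulay expansion with
mean-energy subtraction,

    F_alpha = -<dE_L/dR_alpha> - 2<(E_L - Ebar) dlnPsi/dR_alpha>,

with every per-sample force term multiplied by the node-regularization
polynomial `f_eps(x) = 9x^2 - 15x^4 + 7x^6` for `x = d/eps < 1` (f(1)=1,
continuous at the boundary).  Defaults: eps = 0.1 bohr in VMC and
0.05 bohr in DMC.  On nodeless systems f = 1 identically and the
regularized and raw estimators coincide to machine precision.

The parameter term `dE/dp = 2<(E_L - Ebar) dlnPsi/dp>` is exposed
separately: after full energy minimization it is statistically zero, so
the VMC force is the full derivative of the VMC energy — the tests
verify this by comparing against the finite-difference energy slope.

**Stochastic reconfiguration.** Overlap matrix
`S_ij = <O_i O_j> - <O_i><O_j>` of the parameter log-derivatives, energy
gradient `g_i = 2<(E_L-Ebar) O_i>`, update
`p <- p - step (S + damping diag S)^(-1) g` with a fresh seeded sample
per iteration (defaults: step 0.5, damping 0.05).  On hydrogen started
at exponent 0.6 it recovers 1.00 to well within 0.02.

**Blocking.** Errors come from Flyvbjerg-Petersen reblocking; the quoted
error is the largest level estimate among levels that retain at least 32
blocks — the plateau region for correlated data, while still
statistically stable.  The integrated autocorrelation time (Sokal
window) is used to size DMC history windows.

## DMC

Importance-sampled drift-diffusion with all-electron moves,
accept/reject against the trial density (node crossings rejected), and
branching weight `exp(S)` with the symmetrized
`S = tau (E_T - [E_L(R') + E_L(R)]/2)`; on rejection `S` degenerates to
`tau (E_T - E_L(R))` and its derivative is recorded accordingly, since
the weight was still applied.  Stability near nodes follows common
practice: per-electron smooth drift cap
`V (-1 + sqrt(1 + 2 tau |V|^2)) / (tau |V|^2)` and local energies
windowed to `E_best +/- 2/sqrt(tau)` inside `S` (the branching-factor
derivative is zeroed for windowed samples).  Defaults follow the
production protocol this package models: tau = 0.005 au, k_hist = 900,
eps = 0.05 au; the toy studies use larger tau and correspondingly
smaller windows, always above the measured E_L correlation time.

Population control: stochastic integer splitting `w -> floor(w + u)`
with children inheriting the parent's coordinates *and* full
branching-derivative history (the history window must follow each
walker's ancestry); trial-energy feedback
`E_T = E_best - (damping/tau) ln(N/target)` with the running energy
estimate damped over at least 10/tau steps.  Feedback couples to the
force covariance terms, so force runs use weak damping (0.005) and
populations of several hundred walkers; the studies showed the residual
population-control bias falls below the statistical error under these
settings.

**Force estimators.** With per-sample regularization factor f and walker
weights w:

* RE: the VMC expression averaged over the mixed distribution.
* VD: RE minus the covariance `<(E_L - Ebar) sum_{j in window} dS_j/dR>`
  where the window holds the last k_hist branching-derivative vectors
  along the walker's ancestry.  At k_hist = 0 it *is* RE (asserted to
  machine precision); for an exact wavefunction all covariance terms
  vanish and every estimator reduces to the VMC force.  The window sums
  are maintained incrementally, so VD costs nothing beyond the stored
  histories.
* Hybrid: `2 F_RE - F_VMC`, errors combined in quadrature assuming
  independent runs.

Statistical errors are per-component (a documented choice), from
blocking over per-block estimates that share the global mean energy.

**Time-step extrapolation** is an inverse-variance-weighted linear fit
in tau; duplicate time-steps are averaged first, and the intercept error
comes from the fit covariance.

## Selected CI

Determinants are occupation patterns over spin orbitals; matrix elements
come from the Slater-Condon rules over a symmetric one-electron matrix
and a chemist-notation two-electron tensor with exact 8-fold symmetry.
The test suite re-derives the Hamiltonian through an independent
second-quantized construction (explicit creation/annihilation operators
with fermionic signs) and requires exact agreement.

Epstein-Nesbet PT2: `e_gamma = |<gamma|H|Psi>|^2 / (E - H_gamma,gamma)`
over all external determinants connected by singles/doubles, with the
current variational energy in the denominator; vanishing denominators
are flagged and excluded with a warning.  CIPSI moves the largest-|e|
candidates into the space one batch at a time (default 1 for
deterministic trajectories), ties broken lexicographically.  PT2
matching returns, per geometry, the smallest iterate whose |PT2| falls
at or below the shared target (overshoot below the target is accepted;
with single-determinant selection steps the overshoot is bounded by one
contribution, which keeps the cross-geometry spread within the target
scale).

## Force-field pipeline

**Curation**: Ward agglomerative clustering of geometry descriptors
(sorted inverse pairwise distances) into 40 groups, k-means on energy
into 5 sub-groups each, and the configuration nearest each energy
centroid selected — 200 distinct configurations from a pool of 2000,
then a seeded 100/100 train/validation split.  A pool exactly equal to
the requested product is returned as-is: sub-clustering cannot
guarantee a bijection when geometry clusters are smaller than the
energy-cluster count.  Histogram sampling draws per energy bin in
proportion to occupancy (largest-remainder rounding, default 25 bins,
without replacement).

**Kernel model**: RBF kernel ridge regression from the descriptor to the
flattened force vector (plus an energy head), i.e. a plain kernel force
model standing in for symmetry-adapted gradient-domain models.  The
length scale defaults to 5x the median pairwise descriptor distance —
wide enough that the model starts in the smooth near-linear regime of a
thermal ensemble; ridge default 1e-8, and the zero-regularization limit
interpolates the training forces.  The descriptor is invariant under
rotations while forces are covariant, so the irreducible error on a
non-rotated thermal ensemble scales with the typical libration angle
(~2-3% of the force RMS at the amplitudes used); benchmark references
use well-separated pair distances so the sorted descriptor keeps a
stable ordering.

**MAD** is the mean absolute deviation over configurations, atoms and
Cartesian components, converted to kcal/mol/A at the boundary
(component averaging is the common benchmarking convention; a vector-
norm average would differ by a constant factor).

**MD**: BAOAB-split Langevin dynamics; the thermostat time constant maps
to friction `gamma = 1/tau_thermostat`, and `gamma = 0` reduces to
velocity Verlet with bounded energy oscillation (the secular drift over
10^4 steps is at rounding level).  Defaults: 0.2 fs step, 300 K, 100 fs
time constant.

**Spectra**: mass-weighted Hann-windowed periodogram of the velocities
(the Wiener-Khinchin transform of the VACF), summed over atoms and
components; intensities are nonnegative by construction and the
frequency axis is cm^-1.  The harmonic benchmark uses a 1000 fs
thermostat: the Langevin line width `~gamma` must stay below the
frequency-grid spacing of an 8 ps trajectory for the peak to be
seed-independent within one bin; the MD defaults above are unchanged.

## Validation studies (`qmcforces.protocols`)

`scripts/acceptance.py` reruns all of these from a single seed.  The
force-consistency study deserves its conditions spelled out: two-center
system at R = 2 bohr, tau = 0.02 au.  The *optimized* wavefunction (SR
on LCAO exponents + electron-nucleus Jastrow) demonstrates VMC
force/energy consistency.  The *degraded* wavefunction is the bare
atomic-orbital guess (LCAO, zeta = 1, no Jastrow) — the natural
"unoptimized single determinant"; on it the RE estimator shows a
mixed-distribution bias of ~0.03 hartree/bohr that VD (k_hist = 6x the
measured E_L autocorrelation time) and the hybrid remove.  The DMC
energy of this nodeless system is trial-independent, so the
finite-difference oracle runs use the optimized wavefunction for its
~4x smaller variance.  Problem sizes (5000 steps x 500 walkers for the
force run, 20000 x 500 for each oracle energy) were chosen so the RE
bias resolves at better than 3 sigma against the oracle noise.

## What the synthetic benchmarks do not show

The oracle systems are one-electron (plus enumerable CI toys): they
exercise every estimator identity, the node regularization machinery,
and the statistical pipeline, but not many-electron determinant algebra,
pseudopotentials, or real basis-set effects.  The synthetic ensembles
are Gaussian perturbations without rotations or conformational
transitions, so force-field scores here say nothing about descriptor
completeness on fluxional molecules.  Passing these studies means the
algorithms are implemented as specified and are internally and
statistically consistent — not that production-scale accuracy on real
molecules is reproduced.
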