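"""Physical constants and unit conversions.

Everything internal is Hartree atomic units (hartree, bohr, m_e, atomic
time unit).  Angstrom, kcal/mol, fs, K and cm^-1 appear only at the I/O
boundary.
"""

# CODATA 2018
BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903

KCALMOL_PER_HARTREE = 627.5094740631

#: hartree/bohr -> kcal/mol/Angstrom (the unit forces are reported in)
FORCE_AU_TO_KCAL_PER_ANG = KCALMOL_PER_HARTREE / ANGSTROM_PER_BOHR

#: photon wavenumber of 1 hartree, cm^-1
CM1_PER_HARTREE = 219474.6313632

#: atomic time units per femtosecond
AU_PER_FS = 41.341374575751

#: electron masses per atomic mass unit (dalton)
ME_PER_AMU = 1822.888486209

#: Boltzmann constant, hartree / kelvin
KB_HARTREE = 3.166811563e-6

#: a few nuclear masses (amu) for MD on toy systems
ATOMIC_MASSES_AMU = {
    "X": 1.0,
    "H": 1.00782503,
    "He": 4.00260325,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
}
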