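"""Extended-XYZ and plain-text tabular formats.

XYZ files store positions in Angstrom (file convention); internally
everything is bohr.  The comment line carries ``key=value`` fields
(``energy=`` in hartree) and a ``Properties=`` descriptor; per-atom
force columns are hartree/bohr.  Frames without forces are marked
absent, not zero.  Integral tables are whitespace-delimited text: a
header with the orbital count and core energy, then indexed one- and
two-electron entries (unique under 8-fold symmetry).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .mlff import ConfigurationSet
from .systems import Geometry, IntegralTable
from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM

__all__ = [
    "read_extended_xyz",
    "write_extended_xyz",
    "read_integral_table",
    "write_integral_table",
    "write_spectrum",
]

_CHARGES = {"X": 1.0, "H": 1.0, "He": 2.0, "C": 6.0, "N": 7.0, "O": 8.0}


class XyzParseError(ValueError):
    pass


def _parse_comment(line: str) -> dict:
    """key=value fields; bare quotes around values are stripped."""
    out = {}
    for tok in line.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v.strip('"')
    return out


def read_extended_xyz(path, strict: bool = True) -> ConfigurationSet:
    """Parse a (multi-frame) extended-XYZ file into a configuration set.

    Positions are converted Angstrom -> bohr.  Frames must share the atom
    count; malformed count lines and truncated frames raise
    :class:`XyzParseError` naming the offending line.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Geometry] = []
    energies: list[float] = []
    forces: list[Optional[np.ndarray]] = []
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError:
            raise XyzParseError(
                f"line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if i + 1 + nat >= len(lines) + 1 and strict:
            raise XyzParseError(f"frame {frame_idx}: truncated (starts line {i + 1})")
        fields = _parse_comment(lines[i + 1] if i + 1 < len(lines) else "")
        has_forces = "forces" in fields.get("Properties", "")
        syms, pos, frc = [], [], []
        for j in range(nat):
            k = i + 2 + j
            if k >= len(lines):
                raise XyzParseError(f"frame {frame_idx}: truncated at line {k + 1}")
            parts = lines[k].split()
            if len(parts) < 4:
                raise XyzParseError(f"line {k + 1}: expected 'El x y z [fx fy fz]'")
            syms.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
            if has_forces or len(parts) >= 7:
                frc.append([float(v) for v in parts[4:7]])
        geo = Geometry(
            np.asarray(pos) * BOHR_PER_ANGSTROM,
            np.array([_CHARGES.get(s, 1.0) for s in syms]),
            tuple(syms),
        )
        if frames and geo.n_nuclei != frames[0].n_nuclei:
            raise XyzParseError(
                f"frame {frame_idx} (line {i + 1}): atom count {nat} differs "
                f"from first frame ({frames[0].n_nuclei})"
            )
        frames.append(geo)
        energies.append(float(fields.get("energy", "nan")))
        forces.append(np.asarray(frc) if frc else None)
        i += 2 + nat
        frame_idx += 1
    if not frames:
        raise XyzParseError("no frames found")
    n_at = frames[0].n_nuclei
    any_forces = any(f is not None for f in forces)
    if strict and any_forces and any(f is None for f in forces):
        raise XyzParseError("some frames carry forces and some do not")
    farr = (
        np.stack([f if f is not None else np.full((n_at, 3), np.nan) for f in forces])
        if any_forces
        else np.full((len(frames), n_at, 3), np.nan)
    )
    return ConfigurationSet(tuple(frames), np.array(energies), farr, label="file")


def write_extended_xyz(cs: ConfigurationSet, path) -> None:
    """Write a configuration set as extended XYZ (Angstrom / hartree /
    hartree-per-bohr); round-trips through :func:`read_extended_xyz`."""
    with open(path, "w") as fh:
        for geo, e, f in zip(cs.configurations, cs.energies, cs.forces):
            has_f = np.all(np.isfinite(f))
            props = "species:S:1:pos:R:3" + (":forces:R:3" if has_f else "")
            fh.write(f"{geo.n_nuclei}\n")
            comment = f"Properties={props}"
            if np.isfinite(e):
                comment += f" energy={float(e)!r}"
            fh.write(comment + "\n")
            for a in range(geo.n_nuclei):
                # positions are the only unit-converted column; 12 significant
                # digits keep the write->read->write cycle byte-stable while
                # energies/forces (stored in native units) use full precision
                x, y, z = (float(v) for v in geo.positions[a] * ANGSTROM_PER_BOHR)
                row = f"{geo.labels[a]} {x:.12g} {y:.12g} {z:.12g}"
                if has_f:
                    row += f" {float(f[a, 0])!r} {float(f[a, 1])!r} {float(f[a, 2])!r}"
                fh.write(row + "\n")


def write_integral_table(table: IntegralTable, path) -> None:
    n = table.n_orbitals
    with open(path, "w") as fh:
        fh.write(f"n_orbitals {n}\ncore {float(table.core)!r}\n")
        for p in range(n):
            for q in range(p, n):
                if table.h1[p, q] != 0.0:
                    fh.write(f"h1 {p} {q} {float(table.h1[p, q])!r}\n")
        seen = set()
        for p in range(n):
            for q in range(n):
                for r in range(n):
                    for s in range(n):
                        key = min(
                            (p, q, r, s), (q, p, r, s), (p, q, s, r), (q, p, s, r),
                            (r, s, p, q), (s, r, p, q), (r, s, q, p), (s, r, q, p),
                        )
                        if key in seen or table.eri[p, q, r, s] == 0.0:
                            continue
                        seen.add(key)
                        fh.write(f"eri {key[0]} {key[1]} {key[2]} {key[3]} {float(table.eri[key])!r}\n")


def read_integral_table(path) -> IntegralTable:
    n = None
    core = 0.0
    entries_h1, entries_eri = [], []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            parts = raw.split()
            if not parts or parts[0].startswith("#"):
                continue
            tag = parts[0]
            if tag == "n_orbitals":
                n = int(parts[1])
            elif tag == "core":
                core = float(parts[1])
            elif tag == "h1":
                entries_h1.append((int(parts[1]), int(parts[2]), float(parts[3])))
            elif tag == "eri":
                entries_eri.append(
                    (int(parts[1]), int(parts[2]), int(parts[3]), int(parts[4]), float(parts[5]))
                )
            else:
                raise ValueError(f"{path}: unknown record {tag!r} at line {ln}")
    if n is None:
        raise ValueError(f"{path}: missing n_orbitals header")
    h1 = np.zeros((n, n))
    for p, q, v in entries_h1:
        h1[p, q] = h1[q, p] = v
    eri = np.zeros((n, n, n, n))
    for p, q, r, s, v in entries_eri:
        for a, b, c, d in {
            (p, q, r, s), (q, p, r, s), (p, q, s, r), (q, p, s, r),
            (r, s, p, q), (s, r, p, q), (r, s, q, p), (s, r, q, p),
        }:
            eri[a, b, c, d] = v
    return IntegralTable(n, h1, eri, core)


def write_spectrum(spectrum, path) -> None:
    """Two-column text: frequency (cm^-1), intensity (arbitrary units)."""
    with open(path, "w") as fh:
        fh.write("# frequency_cm1 intensity\n")
        for f, s in zip(spectrum.frequencies_cm1, spectrum.intensity):
            fh.write(f"{float(f)!r} {float(s)!r}\n")
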