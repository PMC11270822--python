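"""Run configuration files and result archives.

A run configuration is a flat ``key = value`` text file (one pair per
line, ``#`` comments).  Every stage declares its allowed keys and
rejects unknown ones; physical quantities are in the declared internal
units (bohr, hartree, au time) unless the key name says otherwise
(``*_fs``, ``*_k``).  A run archive is a JSON document echoing the full
configuration next to the results, so a run can be reproduced
bit-for-bit from its archive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any, Optional

import numpy as np

from . import systems

ARCHIVE_FORMAT = "qmcforces-archive-1"

__all__ = [
    "RunConfig",
    "read_run_config",
    "parse_system",
    "write_run_archive",
    "read_run_archive",
    "ArchiveError",
]

# stage -> {key: type}; "seed" and "output" are always allowed
_SCHEMAS: dict[str, dict[str, type]] = {
    "vmc": {
        "system": str, "wavefunction": str, "zeta": float, "jastrow_en": float,
        "steps": int, "walkers": int, "burn_in": int, "step_size": float,
        "eps": float, "guiding_offset": float, "forces": bool,
    },
    "dmc": {
        "system": str, "wavefunction": str, "zeta": float, "jastrow_en": float,
        "tau": float, "population": int, "k_hist": int, "steps": int,
        "equilibration": int, "eps": float, "forces": bool, "et_damping": float,
    },
    "cipsi": {
        "integrals": str, "n_electrons": int, "sz": int, "n_select": int,
        "max_determinants": int, "pt2_target": float,
    },
    "match-pt2": {
        "integrals": str, "n_electrons": int, "sz": int, "reference_pt2": float,
        "tolerance": float, "n_select": int,
    },
}


@dataclass(frozen=True)
class RunConfig:
    stage: str
    options: dict
    seed: int = 0
    output: Optional[str] = None


def _coerce(key: str, value: str, typ: type) -> Any:
    if typ is bool:
        if value.lower() in ("1", "true", "yes"):
            return True
        if value.lower() in ("0", "false", "no"):
            return False
        raise ValueError(f"{key}: expected a boolean, got {value!r}")
    return typ(value)


def read_run_config(path, stage: str) -> RunConfig:
    """Parse and validate a flat key-value configuration for a stage."""
    if stage not in _SCHEMAS:
        raise ValueError(f"unknown stage {stage!r}")
    schema = _SCHEMAS[stage]
    opts: dict[str, Any] = {}
    seed = 0
    output = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, value = (t.strip() for t in line.split("=", 1))
            if key == "seed":
                seed = int(value)
            elif key == "output":
                output = value
            elif key in schema:
                opts[key] = _coerce(key, value, schema[key])
            else:
                raise ValueError(
                    f"{path}:{ln}: unknown key {key!r} for stage {stage!r} "
                    f"(allowed: {sorted(schema) + ['seed', 'output']})"
                )
    return RunConfig(stage, opts, seed, output)


def parse_system(spec: str) -> systems.ModelSystem:
    """Compact system spec: ``hydrogenic:Z=1``, ``harmonic:k=1``,
    ``two-center:R=2.0,charges=1:1``."""
    kind, _, rest = spec.partition(":")
    params: dict[str, str] = {}
    if rest:
        for tok in rest.split(","):
            k, _, v = tok.partition("=")
            params[k.strip()] = v.strip()
    if kind == "hydrogenic":
        return systems.make_hydrogenic_atom(float(params.get("Z", 1.0)))
    if kind == "harmonic":
        return systems.make_harmonic_atom(float(params.get("k", 1.0)))
    if kind == "two-center":
        charges = tuple(float(c) for c in params.get("charges", "1:1").split(":"))
        return systems.make_two_center_system(float(params.get("R", 2.0)), charges)
    raise ValueError(f"unknown system spec {spec!r}")


class ArchiveError(RuntimeError):
    pass


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_run_archive(results: dict, config: dict, path) -> None:
    """Lossless archive of results plus the full configuration echo."""
    doc = {
        "format": ARCHIVE_FORMAT,
        "config": _to_jsonable(config),
        "results": _to_jsonable(results),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_run_archive(path) -> dict:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ArchiveError(f"{path}: corrupt or truncated archive ({exc})") from exc
    if doc.get("format") != ARCHIVE_FORMAT:
        raise ArchiveError(
            f"{path}: archive format {doc.get('format')!r} does not match "
            f"{ARCHIVE_FORMAT!r}; migrate the file before reading"
        )
    return doc
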