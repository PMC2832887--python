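"""Configuration files, tabular output and run manifests.

A system specification is a JSON (or YAML) document::

    {"tfs": ["A", "B"],
     "concentrations_nM": {"A": 5.0, "B": 1.0},
     "kinetics": {"k0_assoc": [[...]], "k0_dissoc": [[...]]},   # or
     "energies": {"G0_kcal": [...], "E0_kcal": [[...]],
                  "temperature_K": 298.15, "prefactor_per_s": 1.0},  # or
     "raw_M": [[...]],
     "rho_per_s": [...],
     "cascade": {"gamma_per_s": ..., "beta_per_s": ..., "gamma_p_per_s": ...}}

Exactly one of ``kinetics`` / ``energies`` / ``raw_M`` must be present.
``k0_assoc``/``k0_dissoc`` are N x 2^N; the entry used for reaction
``s -> s XOR f`` is taken from ``k0_assoc`` when ``f`` is free in ``s`` and
from ``k0_dissoc`` when bound (a single merged ``"k0"`` matrix is also
accepted).  Infinite barriers may be written as the string ``"inf"``.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cascade import CascadeParams
from .state_space import EnergeticModel, PromoterSystem, kinetics_from_energies

__all__ = ["load_config", "save_config", "write_table", "RunManifest"]


def _as_float_array(obj, name):
    def conv(x):
        if isinstance(x, str):
            if x.lower() in ("inf", "+inf", "infinity"):
                return math.inf
            raise ValueError(f"{name}: cannot parse {x!r}")
        return float(x)

    arr = np.array(obj, dtype=object)
    return np.vectorize(conv, otypes=[float])(arr).astype(float)


def load_config(path) -> tuple[PromoterSystem, Optional[EnergeticModel], Optional[CascadeParams]]:
    """Parse and validate a system specification file."""
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return parse_config(doc)


def parse_config(doc: dict):
    if not isinstance(doc, dict):
        raise ValueError("config root must be a mapping")
    missing = [k for k in ("tfs", "rho_per_s") if k not in doc]
    sources = [k for k in ("kinetics", "energies", "raw_M") if k in doc]
    if len(sources) != 1:
        raise ValueError(
            f"exactly one of kinetics/energies/raw_M required, found {sources or 'none'}"
        )
    if "raw_M" not in doc and "concentrations_nM" not in doc:
        missing.append("concentrations_nM")
    if missing:
        raise ValueError(f"config is missing required keys: {missing}")
    tfs = tuple(doc["tfs"])
    n = len(tfs)
    n_states = 2**n
    rho = _as_float_array(doc["rho_per_s"], "rho_per_s")
    if rho.shape != (n_states,):
        raise ValueError(f"rho_per_s must have length 2^N={n_states}, got {rho.shape}")

    conc = None
    if "concentrations_nM" in doc:
        cdoc = doc["concentrations_nM"]
        extra = set(cdoc) - set(tfs)
        if extra or set(tfs) - set(cdoc):
            raise ValueError(
                f"concentrations_nM keys must match tfs; extra={sorted(extra)}, "
                f"missing={sorted(set(tfs) - set(cdoc))}"
            )
        conc = np.array([float(cdoc[t]) for t in tfs])

    em = None
    src = sources[0]
    if src == "raw_M":
        raw = _as_float_array(doc["raw_M"], "raw_M")
        system = PromoterSystem(tf_names=tfs, rho=rho, raw_M=raw)
    elif src == "kinetics":
        kin = doc["kinetics"]
        if "k0" in kin:
            k0 = _as_float_array(kin["k0"], "k0")
        else:
            for key in ("k0_assoc", "k0_dissoc"):
                if key not in kin:
                    raise ValueError(f"kinetics requires k0 or both k0_assoc/k0_dissoc")
            ka = _as_float_array(kin["k0_assoc"], "k0_assoc")
            kd = _as_float_array(kin["k0_dissoc"], "k0_dissoc")
            if ka.shape != (n, n_states) or kd.shape != (n, n_states):
                raise ValueError(f"k0_assoc/k0_dissoc must be {n}x{n_states}")
            k0 = np.where(
                [[s >> f & 1 for s in range(n_states)] for f in range(n)], kd, ka
            )
        system = PromoterSystem(tf_names=tfs, k0=k0, concentrations=conc, rho=rho)
    else:
        en = doc["energies"]
        em = EnergeticModel(
            G0=_as_float_array(en["G0_kcal"], "G0_kcal"),
            E0=_as_float_array(en["E0_kcal"], "E0_kcal"),
            temperature=float(en.get("temperature_K", 298.15)),
            prefactor=float(en.get("prefactor_per_s", 1.0)),
        )
        system = PromoterSystem(
            tf_names=tfs,
            k0=kinetics_from_energies(em, conc),
            concentrations=conc,
            rho=rho,
        )

    cascade = None
    if "cascade" in doc:
        c = doc["cascade"]
        cascade = CascadeParams(
            gamma=float(c["gamma_per_s"]),
            beta=float(c["beta_per_s"]),
            gamma_p=float(c["gamma_p_per_s"]),
        )
    return system, em, cascade


def save_config(
    path,
    system: PromoterSystem,
    em: Optional[EnergeticModel] = None,
    cascade: Optional[CascadeParams] = None,
) -> None:
    """Serialize a system back to the JSON config dialect (lossless floats)."""
    doc: dict = {"tfs": list(system.tf_names)}
    if system.concentrations is not None:
        doc["concentrations_nM"] = {
            t: float(c) for t, c in zip(system.tf_names, system.concentrations)
        }
    if em is not None:
        doc["energies"] = {
            "G0_kcal": em.G0.tolist(),
            "E0_kcal": [[("inf" if math.isinf(v) else v) for v in row] for row in em.E0],
            "temperature_K": em.temperature,
            "prefactor_per_s": em.prefactor,
        }
    elif system.raw_M is not None:
        doc["raw_M"] = system.raw_M.tolist()
    else:
        doc["kinetics"] = {"k0": system.k0.tolist()}
    doc["rho_per_s"] = system.rho.tolist()
    if cascade is not None:
        doc["cascade"] = {
            "gamma_per_s": cascade.gamma,
            "beta_per_s": cascade.beta,
            "gamma_p_per_s": cascade.gamma_p,
        }
    Path(path).write_text(json.dumps(doc, indent=1))


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility sidecar emitted next to every output table."""

    command: str
    package_version: str
    seed: Optional[int]
    content_sha256: str
    timestamp: str
    outputs: tuple


def write_table(
    records,
    path,
    command: str = "",
    seed: Optional[int] = None,
) -> RunManifest:
    """Write homogeneous records as TSV (17 significant digits) + manifest."""
    path = Path(path)
    df = pd.DataFrame(list(records))
    content = df.to_csv(sep="\t", index=False, float_format="%.17g")
    path.write_text(content)
    digest = hashlib.sha256(content.encode()).hexdigest()
    manifest = RunManifest(
        command=command,
        package_version=__version__,
        seed=seed,
        content_sha256=digest,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        outputs=(str(path),),
    )
    Path(str(path) + ".manifest.json").write_text(json.dumps(asdict(manifest), indent=1))
    return manifest
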