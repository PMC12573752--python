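"""Structured text (YAML) run configuration.

Sections: system / grid / functionals / mm_model / scf / output.  Every
driver default lives here; a config file only overrides what it names.
"""

from __future__ import annotations

import yaml

from .driver import RunConfig
from .exceptions import ParseError
from .functionals import KineticConfig

__all__ = ["load_config", "dump_config"]


def _kinetic_from(d: dict, default: KineticConfig) -> KineticConfig:
    return KineticConfig(
        family=d.get("family", default.family),
        lam=float(d.get("lambda", default.lam)),
        mu_k=float(d.get("mu_k", default.mu_k)),
        kappa_k=float(d.get("kappa_k", default.kappa_k)),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ParseError(f"invalid YAML: {exc}") from exc
    cfg = RunConfig()
    grid = data.get("grid", {})
    cfg.cutoff = float(grid.get("cutoff", cfg.cutoff))
    fns = data.get("functionals", {})
    cfg.kinetic_additive = _kinetic_from(fns.get("kinetic_additive", {}), cfg.kinetic_additive)
    cfg.kinetic_nonadditive = _kinetic_from(
        fns.get("kinetic_nonadditive", {}), cfg.kinetic_nonadditive
    )
    cfg.include_ts_nad = bool(fns.get("include_ts_nad", cfg.include_ts_nad))
    cfg.include_xc_nad = bool(fns.get("include_xc_nad", cfg.include_xc_nad))
    mm = data.get("mm_model", {})
    cfg.polarizable = bool(mm.get("polarizable", cfg.polarizable))
    cfg.thole_a = float(mm.get("thole_a", cfg.thole_a))
    for el, params in mm.get("elements", {}).items():
        cfg.mm_params.setdefault(el, {}).update(
            {k: float(v) for k, v in params.items()}
        )
    scf = data.get("scf", {})
    cfg.scf_energy_tol = float(scf.get("energy_tol", cfg.scf_energy_tol))
    cfg.scf_density_tol = float(scf.get("density_tol", cfg.scf_density_tol))
    cfg.max_outer = int(scf.get("max_outer", cfg.max_outer))
    cfg.dipole_mixing = float(scf.get("dipole_mixing", cfg.dipole_mixing))
    cfg.inner_tol = float(scf.get("inner_tol", cfg.inner_tol))
    cfg.inner_max_iter = int(scf.get("inner_max_iter", cfg.inner_max_iter))
    cfg.scan_convergence_band = float(
        scf.get("scan_convergence_band", cfg.scan_convergence_band)
    )
    sysd = data.get("system", {})
    cfg.declared_charge = float(sysd.get("charge", cfg.declared_charge))
    return cfg


def dump_config(cfg: RunConfig, path):
    data = {
        "system": {"charge": cfg.declared_charge},
        "grid": {"cutoff": cfg.cutoff},
        "functionals": {
            "kinetic_additive": {
                "family": cfg.kinetic_additive.family,
                "lambda": cfg.kinetic_additive.lam,
            },
            "kinetic_nonadditive": {
                "family": cfg.kinetic_nonadditive.family,
                "mu_k": cfg.kinetic_nonadditive.mu_k,
                "kappa_k": cfg.kinetic_nonadditive.kappa_k,
            },
            "include_ts_nad": cfg.include_ts_nad,
            "include_xc_nad": cfg.include_xc_nad,
        },
        "mm_model": {
            "polarizable": cfg.polarizable,
            "thole_a": cfg.thole_a,
            "elements": cfg.mm_params,
        },
        "scf": {
            "energy_tol": cfg.scf_energy_tol,
            "density_tol": cfg.scf_density_tol,
            "max_outer": cfg.max_outer,
            "dipole_mixing": cfg.dipole_mixing,
            "inner_tol": cfg.inner_tol,
            "inner_max_iter": cfg.inner_max_iter,
            "scan_convergence_band": cfg.scan_convergence_band,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
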