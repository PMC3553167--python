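"""Model configuration files (YAML or JSON) and their echo into outputs.

A configuration is a mapping with keys ``P``, ``M``, ``allocation``
(``{family, E0, k}``) and ``survival`` (``{family, c0, delta, a}``).  The
parsed mapping is echoed verbatim, as canonical JSON, into the comment
header of every file the package writes, so an output always carries the
exact configuration that produced it.
"""

from __future__ import annotations

import json
from typing import Any, Mapping

import yaml

from .exceptions import DomainError
from .model_core import AllocationCurve, LifeHistoryModel, OffspringSurvivalCurve

DEFAULT_CONFIG: dict[str, Any] = {
    "P": 0.5,
    "M": 10.0,
    "allocation": {"family": "exponential", "E0": 0.8, "k": 0.5},
    "survival": {"family": "power", "c0": 0.5, "delta": 1.0},
}


def load_config(path) -> dict[str, Any]:
    """Parse a YAML/JSON model configuration file into a plain mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise DomainError(f"configuration file {path} must contain a mapping")
    return dict(cfg)


def model_from_config(cfg: Mapping[str, Any]) -> LifeHistoryModel:
    """Build a LifeHistoryModel from a configuration mapping.

    Missing keys fall back to the package defaults (exponential allocation
    E0=0.8, k=0.5; power survival c0=0.5, delta=1; P=0.5, M=10).
    """
    alloc_cfg = {**DEFAULT_CONFIG["allocation"], **dict(cfg.get("allocation") or {})}
    surv_cfg = {**DEFAULT_CONFIG["survival"], **dict(cfg.get("survival") or {})}
    allocation = AllocationCurve(
        family=alloc_cfg["family"],
        E0=float(alloc_cfg["E0"]),
        k=float(alloc_cfg["k"]),
    )
    survival = OffspringSurvivalCurve(
        family=surv_cfg["family"],
        c0=float(surv_cfg.get("c0", 0.5)),
        delta=None if surv_cfg.get("delta") is None else float(surv_cfg["delta"]),
        a=None if surv_cfg.get("a") is None else float(surv_cfg["a"]),
    )
    return LifeHistoryModel(
        P=float(cfg.get("P", DEFAULT_CONFIG["P"])),
        M=float(cfg.get("M", DEFAULT_CONFIG["M"])),
        allocation=allocation,
        survival=survival,
    )


def config_of_model(model: LifeHistoryModel) -> dict[str, Any]:
    """Round-trippable configuration mapping for a model."""
    surv: dict[str, Any] = {"family": model.survival.family, "c0": model.survival.c0}
    if model.survival.delta is not None:
        surv["delta"] = model.survival.delta
    if model.survival.a is not None:
        surv["a"] = model.survival.a
    return {
        "P": model.P,
        "M": model.M,
        "allocation": {
            "family": model.allocation.family,
            "E0": model.allocation.E0,
            "k": model.allocation.k,
        },
        "survival": surv,
    }


def config_echo(cfg: Mapping[str, Any]) -> str:
    """Canonical single-line JSON echo of a parsed configuration."""
    return json.dumps(cfg, sort_keys=True, separators=(",", ":"))
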