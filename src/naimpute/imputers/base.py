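"""Imputer registry and the uniform imputation contract.

Every method is a function ``f(X, seed=None, **params) -> (filled, diagnostics)``
operating on a features x samples float array with NaN missing cells.  The
public entry points wrap that contract so every result is guaranteed to

* be complete (zero missing cells), and
* preserve every observed cell of the input bit-for-bit.

Methods carry the field's family taxonomy: SV (single value), GS (global
structure), LS (local similarity); and a fast/slow tier reflecting practical
runtime.  BPCA, trKNN and GMS are plugin slots: their algorithms live in
external packages and can be registered at run time without touching core
code.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from ..data import ExpressionMatrix

__all__ = [
    "ImputerSpec",
    "ImputationResult",
    "register",
    "register_plugin",
    "available_methods",
    "method_info",
    "impute",
    "run_methods",
    "FAST_METHODS",
    "PLUGIN_SLOTS",
]

#: the 16 methods of the fast tier (served natively)
FAST_METHODS = (
    "zero", "minimum", "colmedian", "rowmedian",
    "mindet", "minprob", "pi", "qrilc",
    "svd", "mle", "impseq", "impseqrob",
    "knn", "seqknn", "lls", "grr",
)

#: slow-tier slots whose algorithms must be supplied as plugins
PLUGIN_SLOTS = ("bpca", "trknn", "gms")


@dataclass
class ImputerSpec:
    """A method key plus its parameters and (for stochastic methods) a seed."""

    method_name: str
    params: dict = field(default_factory=dict)
    seed: int | None = None


@dataclass
class ImputationResult:
    matrix: ExpressionMatrix
    method_name: str
    diagnostics: dict = field(default_factory=dict)


@dataclass
class _Registered:
    func: object
    family: str  # SV / GS / LS
    tier: str  # fast / slow
    stochastic: bool


_REGISTRY: dict[str, _Registered] = {}


def register(name: str, family: str, tier: str, stochastic: bool = False):
    """Decorator registering an imputation function under a registry key."""

    def wrap(func):
        _REGISTRY[name] = _Registered(func, family, tier, stochastic)
        return func

    return wrap


def register_plugin(name: str, func, family: str = "LS", stochastic: bool = False) -> None:
    """Fill a plugin slot (bpca / trknn / gms) or add a new method."""
    _REGISTRY[name] = _Registered(func, family, "slow", stochastic)


def available_methods() -> list[str]:
    return sorted(_REGISTRY)


def method_info(name: str) -> _Registered:
    return _lookup(name)


def _lookup(name: str) -> _Registered:
    if name not in _REGISTRY:
        if name in PLUGIN_SLOTS:
            raise KeyError(
                f"{name!r} is a plugin slot; supply an implementation via "
                f"register_plugin(). Registered methods: {available_methods()}"
            )
        raise KeyError(f"unknown method {name!r}; registered: {available_methods()}")
    return _REGISTRY[name]


def impute(m: ExpressionMatrix, method: str, seed: int | None = None, **params) -> ImputationResult:
    """Run one registered method; enforce completeness and observed-cell preservation."""
    entry = _lookup(method)
    if entry.stochastic and seed is None:
        raise ValueError(f"method {method!r} is stochastic and requires a seed")
    X = m.values.copy()
    observed = ~np.isnan(X)
    t0 = time.perf_counter()
    filled, diagnostics = entry.func(X, seed=seed, **params)
    runtime = time.perf_counter() - t0
    filled = np.asarray(filled, dtype=float)
    filled[observed] = m.values[observed]  # observed cells are inviolate
    if np.isnan(filled).any():
        raise RuntimeError(f"method {method!r} left missing cells")
    diagnostics = dict(diagnostics or {})
    diagnostics.setdefault("runtime", runtime)
    return ImputationResult(m.with_values(filled), method, diagnostics)


def run_methods(
    m: ExpressionMatrix, specs: list[ImputerSpec]
) -> tuple[list[ImputationResult], dict[str, str]]:
    """Run a batch of specs in order; per-method failures are captured, not fatal.

    Unknown method names raise up front (listing the registry) so a typo
    cannot silently drop a method from the benchmark.
    """
    for spec in specs:
        _lookup(spec.method_name)
    results: list[ImputationResult] = []
    failures: dict[str, str] = {}
    for spec in specs:
        try:
            results.append(impute(m, spec.method_name, seed=spec.seed, **spec.params))
        except Exception as exc:  # noqa: BLE001 - batch isolation is the contract
            warnings.warn(f"method {spec.method_name!r} failed: {exc}")
            failures[spec.method_name] = str(exc)
    return results, failures
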