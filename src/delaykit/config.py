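"""JSON/YAML model configuration.

Canonical schema (JSON; YAML accepted as a convenience alias)::

    {
      "species": ["X"],
      "initial": {"X": 0},
      "reactions": [
        {"reactants": {}, "products": {"X": 1}, "rate": 10.0},
        {"reactants": {"X": 1}, "products": {}, "rate": 1.0,
         "delay": {"kind": "completion_only", "value": 2.0}}
      ]
    }

A reaction carries either a mass-action ``rate`` or a ``propensity``
expression over the declared species names.  The expression language is
deliberately tiny — numbers, species symbols, ``+ - * / **``,
parentheses, ``pow`` and ``exp`` — so Hill terms stay portable.

Alternatively a config selects a named preset::

    {"preset": "bursty", "params": {"alpha": 0.0282, "b": 3.46, "tau": 120}}

Presets: ``bursty``, ``refractory``, ``rna_velocity``, ``ast``,
``toggle``.
"""

from __future__ import annotations

import ast as _pyast
import json
import math
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from . import models
from .network import (
    DelayKind,
    DelaySpec,
    ReactionNetwork,
    SpeciesSet,
    build_network,
    make_reaction,
)

__all__ = [
    "ConfigError",
    "compile_expression",
    "parse_model_dict",
    "parse_model_config",
    "write_model_config",
    "network_to_dict",
    "PRESETS",
]


class ConfigError(ValueError):
    """A model configuration violates the schema."""


_ALLOWED_CALLS = {"pow": pow, "exp": math.exp}
_ALLOWED_NODES = (
    _pyast.Expression, _pyast.BinOp, _pyast.UnaryOp, _pyast.Constant,
    _pyast.Name, _pyast.Call, _pyast.Load,
    _pyast.Add, _pyast.Sub, _pyast.Mult, _pyast.Div, _pyast.Pow,
    _pyast.USub, _pyast.UAdd,
)


def compile_expression(expr: str, species: Sequence[str]) -> Callable:
    """Compile a propensity expression into ``counts -> float``.

    Only arithmetic on numeric literals and declared species names is
    admitted (plus ``pow`` and ``exp``); anything else is a schema error.
    """
    try:
        tree = _pyast.parse(expr, mode="eval")
    except SyntaxError as e:
        raise ConfigError(f"malformed propensity expression {expr!r}: {e}") from None
    index = {name: i for i, name in enumerate(species)}
    for node in _pyast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ConfigError(
                f"disallowed construct {type(node).__name__} in expression {expr!r}")
        if isinstance(node, _pyast.Constant) and not isinstance(node.value, (int, float)):
            raise ConfigError(f"non-numeric literal in expression {expr!r}")
        if isinstance(node, _pyast.Call):
            if not isinstance(node.func, _pyast.Name) or node.func.id not in _ALLOWED_CALLS:
                raise ConfigError(f"only pow/exp calls allowed in expression {expr!r}")
        if isinstance(node, _pyast.Name):
            if node.id not in index and node.id not in _ALLOWED_CALLS:
                raise ConfigError(
                    f"undeclared species {node.id!r} in expression {expr!r}")
    code = compile(tree, "<propensity>", "eval")

    def propensity(counts):
        env = {name: counts[i] for name, i in index.items()}
        env.update(_ALLOWED_CALLS)
        return eval(code, {"__builtins__": {}}, env)

    propensity.expression = expr  # type: ignore[attr-defined]
    return propensity


def _parse_delay(obj, label: str) -> DelaySpec:
    if obj is None:
        return DelaySpec.none()
    if not isinstance(obj, dict) or "kind" not in obj:
        raise ConfigError(f"{label}: delay must be an object with a 'kind'")
    try:
        kind = DelayKind(obj["kind"])
    except ValueError:
        raise ConfigError(f"{label}: unknown delay kind {obj['kind']!r}") from None
    if kind is DelayKind.NONE:
        return DelaySpec.none()
    if "value" in obj:
        return DelaySpec(kind, float(obj["value"]))
    dist = obj.get("distribution")
    params = obj.get("params", {})
    samplers = {
        "fixed": lambda rng: float(params["value"]),
        "exponential": lambda rng: rng.exponential(float(params.get("scale", 1.0))),
        "uniform": lambda rng: rng.uniform(float(params.get("low", 0.0)),
                                           float(params.get("high", 1.0))),
        "gamma": lambda rng: rng.gamma(float(params.get("shape", 1.0)),
                                       float(params.get("scale", 1.0))),
    }
    if dist not in samplers:
        raise ConfigError(
            f"{label}: delay needs a 'value' or a distribution in {sorted(samplers)}")
    return DelaySpec(kind, samplers[dist])


PRESETS = {
    "bursty": models.bursty_model,
    "refractory": models.refractory_model,
    "rna_velocity": models.rna_velocity_model,
    "ast": None,  # handled specially (parameter object + B + degrader)
    "toggle": models.toggle_switch_model,
}


def _build_preset(name: str, params: dict):
    if name == "bursty":
        net = models.bursty_model(**params)
        return net, np.zeros(1, dtype=np.int64)
    if name == "refractory":
        net = models.refractory_model(**params)
        return net, np.array([1, 0, 0, 0], dtype=np.int64)
    if name == "toggle":
        net = models.toggle_switch_model(**params)
        return net, np.zeros(2, dtype=np.int64)
    if name == "rna_velocity":
        model = models.rna_velocity_model(**params)
        return model, np.zeros(2, dtype=np.int64)
    if name == "ast":
        params = dict(params)
        B = float(params.pop("B", 6023.0))
        degrader = params.pop("degrader", None)
        initial = params.pop("initial", None)
        ast_params = models.ASTParameters(**params)
        net = models.ast_model(ast_params, B=B, degrader=degrader)
        init = (np.asarray(initial, dtype=np.int64) if initial is not None
                else np.zeros(4, dtype=np.int64))
        return net, init
    raise ConfigError(f"unknown preset {name!r}; valid presets: {sorted(PRESETS)}")


def parse_model_dict(cfg: dict):
    """Validate a config mapping and return ``(network_or_model, initial_counts)``."""
    if not isinstance(cfg, dict):
        raise ConfigError("model config must be a mapping")
    if "preset" in cfg:
        return _build_preset(cfg["preset"], cfg.get("params", {}))
    for key in ("species", "reactions"):
        if key not in cfg:
            raise ConfigError(f"model config missing required field {key!r}")
    species = SpeciesSet(tuple(cfg["species"]))
    reactions = []
    for k, rx in enumerate(cfg["reactions"]):
        label = f"reactions[{k}]"
        if not isinstance(rx, dict):
            raise ConfigError(f"{label}: must be an object")
        reactants = {str(a): int(b) for a, b in rx.get("reactants", {}).items()}
        products = {str(a): int(b) for a, b in rx.get("products", {}).items()}
        for nm in list(reactants) + list(products):
            if nm not in species.names:
                raise ConfigError(f"{label}: undeclared species {nm!r}")
        has_rate = "rate" in rx
        has_expr = "propensity" in rx
        if has_rate == has_expr:
            raise ConfigError(f"{label}: exactly one of 'rate' or 'propensity' required")
        rate = float(rx["rate"]) if has_rate else None
        if rate is not None and rate < 0:
            raise ConfigError(f"{label}: rate must be >= 0")
        prop = compile_expression(rx["propensity"], species.names) if has_expr else None
        delay = _parse_delay(rx.get("delay"), label)
        reactions.append(make_reaction(species, reactants, products, rate=rate,
                                       propensity=prop, delay=delay,
                                       name=rx.get("name", f"r{k}")))
    network = build_network(species, reactions)
    initial = np.zeros(species.size, dtype=np.int64)
    for nm, c in cfg.get("initial", {}).items():
        if nm not in species.names:
            raise ConfigError(f"initial: undeclared species {nm!r}")
        initial[species.index(nm)] = int(c)
    if (initial < 0).any():
        raise ConfigError("initial counts must be >= 0")
    return network, initial


def parse_model_config(path) -> tuple:
    """Read and validate a JSON (or YAML) model configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        try:
            cfg = json.loads(text)
        except json.JSONDecodeError as e:
            raise ConfigError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from None
    return parse_model_dict(cfg)


def network_to_dict(network: ReactionNetwork, initial=None) -> dict:
    """Serialise an explicit network back to the canonical schema.

    Custom propensities round-trip only when they were compiled from an
    expression (the compiled closure remembers its source); delay samplers
    are not serialisable and raise.
    """
    species = network.species.names
    out = {"species": list(species), "reactions": []}
    if initial is not None:
        out["initial"] = {nm: int(c) for nm, c in zip(species, initial) if int(c) != 0}
    for r in network.reactions:
        rc = r.reactant_counts
        if r.delay.kind is DelayKind.NONE:
            prod_vec = r.s_column + rc
        elif r.delay.kind is DelayKind.CONSUMING:
            prod_vec = r.s_delay_column
        else:
            prod_vec = r.s_delay_column + rc
        entry: dict = {
            "reactants": {species[i]: int(v) for i, v in enumerate(rc) if v},
            "products": {species[i]: int(v) for i, v in enumerate(prod_vec) if v},
        }
        if r.custom_propensity is not None:
            expr = getattr(r.custom_propensity, "expression", None)
            if expr is None:
                raise ConfigError(
                    f"reaction {r.name!r}: opaque custom propensity cannot be serialised")
            entry["propensity"] = expr
        else:
            entry["rate"] = float(r.rate_constant)
        if r.delay.kind is not DelayKind.NONE:
            if callable(r.delay.delay):
                raise ConfigError(
                    f"reaction {r.name!r}: delay sampler functions cannot be serialised")
            entry["delay"] = {"kind": r.delay.kind.value, "value": float(r.delay.delay)}
        if r.name:
            entry["name"] = r.name
        out["reactions"].append(entry)
    return out


def write_model_config(network: ReactionNetwork, path, initial=None) -> None:
    Path(path).write_text(json.dumps(network_to_dict(network, initial), indent=2) + "\n")
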