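"""Declarative model configuration: a small, versioned YAML dialect.

A model file looks like::

    schema: 1
    volume: 100.0
    species:
      - {name: S, class: slow, initial: 45.2}
      - {name: EE, class: fast, initial: 0.5}
    reactions:
      - {reactants: {}, products: {S: 1}, rate_constant: 0.5}
      - {reactants: {S: 1, EE: 1}, products: {EES: 1}, rate_constant: 5e-3}
      - {reactants: {S: 1}, products: {}, rate: "0.2*S/(1 + S)"}
    conservation_laws:
      - {coefficients: {EE: 1, EES: 1, SEES: 1}, total: 1.0}

``rate_constant`` declares a mass-action law; ``rate`` declares a custom
macroscopic rate expression in the species names.  Unknown keys are
rejected, and declared conservation laws must lie in the left null space of
the stoichiometric matrix.  Serialising a parsed network and re-parsing it
yields an equivalent network.
"""

from __future__ import annotations

from pathlib import Path

import sympy as sp
import yaml

from .network import ConservationLaw, NetworkError, Reaction, ReactionNetwork, Species

__all__ = ["ConfigError", "parse_model_config", "serialize_model", "networks_equal"]

SCHEMA_VERSION = 1

_TOP_KEYS = {"schema", "volume", "species", "reactions", "conservation_laws"}
_SPECIES_KEYS = {"name", "class", "initial"}
_REACTION_KEYS = {"reactants", "products", "rate_constant", "rate", "name"}
_LAW_KEYS = {"coefficients", "total"}


class ConfigError(ValueError):
    """Malformed model configuration."""


def _check_keys(mapping: dict, allowed: set, context: str) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")


def parse_model_config(path: str | Path) -> ReactionNetwork:
    """Parse and validate a model file into a :class:`ReactionNetwork`."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML ({exc})") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(doc, _TOP_KEYS, str(path))
    if doc.get("schema") != SCHEMA_VERSION:
        raise ConfigError(
            f"{path}: unsupported schema version {doc.get('schema')!r} "
            f"(expected {SCHEMA_VERSION})"
        )
    species = []
    for i, item in enumerate(doc.get("species", [])):
        _check_keys(item, _SPECIES_KEYS, f"{path}: species[{i}]")
        try:
            species.append(
                Species(
                    name=str(item["name"]),
                    timescale_class=item.get("class", "slow"),
                    initial_concentration=float(item.get("initial", 0.0)),
                )
            )
        except (KeyError, NetworkError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: species[{i}]: {exc}") from exc
    reactions = []
    for i, item in enumerate(doc.get("reactions", [])):
        _check_keys(item, _REACTION_KEYS, f"{path}: reactions[{i}]")
        has_k = "rate_constant" in item
        has_rate = "rate" in item
        if has_k == has_rate:
            raise ConfigError(
                f"{path}: reactions[{i}]: give exactly one of "
                "'rate_constant' (mass action) or 'rate' (custom law)"
            )
        try:
            stoich = {}
            for key in ("reactants", "products"):
                entry = item.get(key, {}) or {}
                _check_keys(entry, set(map(str, entry)), f"{path}: reactions[{i}].{key}")
                stoich[key] = {str(s): int(c) for s, c in entry.items()}
            if has_k:
                rxn = Reaction(
                    stoich["reactants"], stoich["products"],
                    rate_constant=float(item["rate_constant"]),
                    name=item.get("name"),
                )
            else:
                rxn = Reaction(
                    stoich["reactants"], stoich["products"],
                    rate_law="custom", rate_expression=str(item["rate"]),
                    name=item.get("name"),
                )
        except (NetworkError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: reactions[{i}]: {exc}") from exc
        reactions.append(rxn)
    laws = []
    for i, item in enumerate(doc.get("conservation_laws", []) or []):
        _check_keys(item, _LAW_KEYS, f"{path}: conservation_laws[{i}]")
        try:
            laws.append(
                ConservationLaw(
                    {str(s): float(c) for s, c in item["coefficients"].items()},
                    float(item["total"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: conservation_laws[{i}]: {exc}") from exc
    try:
        return ReactionNetwork(
            species, reactions, float(doc.get("volume", 1.0)), laws
        )
    except NetworkError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def serialize_model(net: ReactionNetwork) -> str:
    """Render a network back to the YAML dialect (eliminations are not
    serialised; re-apply them after parsing)."""
    doc: dict = {
        "schema": SCHEMA_VERSION,
        "volume": float(net.volume),
        "species": [
            {
                "name": s.name,
                "class": s.timescale_class,
                "initial": float(s.initial_concentration),
            }
            for s in net.species
        ],
        "reactions": [],
        "conservation_laws": [
            {
                "coefficients": {k: float(v) for k, v in law.coefficients.items()},
                "total": float(law.total),
            }
            for law in net.conservation_laws
        ],
    }
    for r in net.reactions:
        item: dict = {
            "reactants": {k: int(v) for k, v in r.reactants.items()},
            "products": {k: int(v) for k, v in r.products.items()},
        }
        if r.rate_law == "mass_action":
            item["rate_constant"] = float(r.rate_constant)
        else:
            item["rate"] = str(r.rate_expression)
        if r.name:
            item["name"] = r.name
        doc["reactions"].append(item)
    if not doc["conservation_laws"]:
        del doc["conservation_laws"]
    return yaml.safe_dump(doc, sort_keys=False)


def networks_equal(a: ReactionNetwork, b: ReactionNetwork) -> bool:
    """Structural equality up to symbolic equivalence of custom rate laws."""
    if a.species != b.species or a.volume != b.volume:
        return False
    if len(a.reactions) != len(b.reactions):
        return False
    if [
        (dict(l.coefficients), l.total) for l in a.conservation_laws
    ] != [(dict(l.coefficients), l.total) for l in b.conservation_laws]:
        return False
    syms = {s.name: sp.Symbol(s.name, real=True) for s in a.species}
    for ra, rb in zip(a.reactions, b.reactions):
        if dict(ra.reactants) != dict(rb.reactants):
            return False
        if dict(ra.products) != dict(rb.products):
            return False
        diff = sp.simplify(ra.rate_expr(syms) - rb.rate_expr(syms))
        if diff != 0:
            return False
    return True
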