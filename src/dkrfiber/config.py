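"""Flat key-value configuration and reference presets.

A configuration is plain text of ``key=value`` pairs separated by whitespace
or newlines (``#`` starts a comment). Keys are either the dimensionless
groups and bulk state (phi2, b0, theta, gamma, xi1, xi2, phi_frac, s1b, s2b,
x_conv) or the physical-parameter names accepted by
:class:`~dkrfiber.model_core.PhysicalParameters`; mixing the two vocabularies
in one document is rejected. Unknown keys are an error, values are decimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

from .exceptions import ConfigurationError, DkrError
from .model_core import BulkState, DimensionlessParameters, PhysicalParameters, to_dimensionless

logger = logging.getLogger(__name__)

DIMENSIONLESS_KEYS = ("phi2", "b0", "theta", "gamma", "xi1", "xi2", "phi_frac")
BULK_KEYS = ("s1b", "s2b", "x_conv")
PHYSICAL_KEYS = tuple(f.name for f in fields(PhysicalParameters))

#: defaults: the weak-diffusion reference column (table4 at B0 = 8.68)
DEFAULTS = {
    "phi2": 0.5,
    "b0": 8.68,
    "theta": 3.27,
    "gamma": 1.0,
    "xi1": 2.0,
    "xi2": 0.03,
    "phi_frac": 1.0,
    "s1b": 1.0,
    "s2b": 1.0,
    "x_conv": 0.0,
}


@dataclass(frozen=True)
class ParameterBundle:
    """A validated pair of dimensionless parameters and bulk state."""

    params: DimensionlessParameters
    bulk: BulkState

    def to_config_text(self) -> str:
        parts = [
            f"{k}={getattr(self.params, k)!r}" for k in DIMENSIONLESS_KEYS
        ] + [f"{k}={getattr(self.bulk, k)!r}" for k in BULK_KEYS]
        return " ".join(parts)


def _parse_pairs(text: str) -> dict[str, float]:
    pairs: dict[str, float] = {}
    for line in text.splitlines() or [text]:
        line = line.split("#", 1)[0]
        for token in line.split():
            if "=" not in token:
                raise ConfigurationError(
                    f"malformed token {token!r}: expected key=value"
                )
            key, _, raw = token.partition("=")
            key = key.strip()
            if key in pairs:
                raise ConfigurationError(f"duplicate key {key!r}")
            try:
                pairs[key] = float(raw)
            except ValueError:
                raise ConfigurationError(
                    f"value for {key!r} is not decimal: {raw!r}"
                ) from None
    return pairs


def load_config(source: str | Path) -> ParameterBundle:
    """Parse a config document (path or literal text) into a bundle.

    Missing dimensionless keys take the documented defaults (logged); an
    entirely empty document yields the all-defaults bundle with a warning.
    Physical-parameter documents must be complete and are mapped through
    :func:`~dkrfiber.model_core.to_dimensionless`.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "=" not in source and Path(source).is_file()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)

    pairs = _parse_pairs(text)
    unknown = set(pairs) - set(DIMENSIONLESS_KEYS) - set(BULK_KEYS) - set(PHYSICAL_KEYS)
    if unknown:
        raise ConfigurationError(
            f"unknown configuration keys: {sorted(unknown)}; "
            f"expected dimensionless keys {DIMENSIONLESS_KEYS + BULK_KEYS} "
            "or physical-parameter names"
        )

    physical = {k: v for k, v in pairs.items() if k in PHYSICAL_KEYS and k not in DIMENSIONLESS_KEYS}
    if physical:
        dimless_extra = set(pairs) & set(DIMENSIONLESS_KEYS)
        if dimless_extra:
            raise ConfigurationError(
                "config mixes physical and dimensionless parameter keys: "
                f"{sorted(dimless_extra)} alongside {sorted(physical)}"
            )
        try:
            phys = PhysicalParameters(**{k: v for k, v in pairs.items() if k in PHYSICAL_KEYS})
        except TypeError as exc:
            raise ConfigurationError(f"incomplete physical parameter set: {exc}") from exc
        bulk_pairs = {k: v for k, v in pairs.items() if k in BULK_KEYS}
        try:
            return ParameterBundle(to_dimensionless(phys), BulkState(**bulk_pairs))
        except DkrError as exc:
            raise ConfigurationError(str(exc)) from exc

    if not pairs:
        logger.warning("empty configuration: using all defaults %s", DEFAULTS)
    merged = dict(DEFAULTS)
    merged.update(pairs)
    defaults_used = sorted(set(DEFAULTS) - set(pairs))
    if pairs and defaults_used:
        logger.debug("defaults applied for %s", defaults_used)
    try:
        params = DimensionlessParameters(
            **{k: merged[k] for k in DIMENSIONLESS_KEYS}
        )
        bulk = BulkState(**{k: merged[k] for k in BULK_KEYS})
    except DkrError as exc:
        raise ConfigurationError(str(exc)) from exc
    return ParameterBundle(params, bulk)


def preset(name: str) -> dict:
    """Full parameter bundle(s) for a reference table id (table2..table9).

    For profile tables the result maps each varied column value to a
    :class:`ParameterBundle`; for the effectiveness tables it carries the
    base parameters, the modulus headers and the row values.
    """
    from . import reference

    if name in reference.PROFILE_TABLE_PARAMS:
        layout = reference.PROFILE_TABLE_PARAMS[name]
        return {
            "kind": "profile",
            "species": layout["species"],
            "columns": {
                col: ParameterBundle(reference.table_parameters(name, col), BulkState())
                for col in layout["columns"]
            },
        }
    if name == "table2":
        return {
            "kind": "mief",
            "base": dict(reference.MIEF_TABLE_BASE, theta=reference.MIEF_TABLE2_THETA),
            "vary": "s1b",
            "cells": reference.MIEF_TABLE2,
        }
    if name == "table3":
        return {
            "kind": "mief",
            "base": dict(reference.MIEF_TABLE_BASE),
            "vary": "theta",
            "cells": reference.MIEF_TABLE3,
        }
    raise ConfigurationError(f"unknown preset {name!r}")


PRESET_NAMES = tuple(f"table{i}" for i in range(2, 10))
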