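"""File formats: versioned JSON netlists and CSV transfer-function surfaces.

The netlist document (schema ``perceptgene-netlist/1``) describes a
:class:`~perceptgene.network.NetworkSpec`: external inputs, one block per
perceptgene unit (inputs, weights, scales, bias, hill, basal, activation),
optional multiplicative junctions, and the output unit.  Surfaces travel
as CSV with one column per input named ``input:<name>``, an ``output``
column, and a ``replicate`` column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PerceptgeneParams, Surface
from .network import NetworkSpec

__all__ = [
    "NetlistError",
    "netlist_to_dict",
    "netlist_from_dict",
    "write_netlist",
    "read_netlist",
    "write_surface",
    "read_surface",
]

SCHEMA = "perceptgene-netlist/1"

_UNIT_FIELDS = {"inputs", "weights", "scales", "bias", "hill", "basal", "activation"}
_TOP_FIELDS = {"schema", "inputs", "units", "junctions", "output"}


class NetlistError(ValueError):
    """Schema violation, naming the offending field."""


def netlist_to_dict(spec: NetworkSpec) -> dict:
    """Canonical JSON-ready form of a network spec."""
    return {
        "schema": SCHEMA,
        "inputs": list(spec.external_inputs),
        "units": {
            name: {
                "inputs": list(p.input_names),
                "weights": list(p.weights),
                "scales": list(p.input_scales),
                "bias": p.bias,
                "hill": p.hill,
                "basal": p.basal,
                "activation": p.activation_kind,
            }
            for name, p in sorted(spec.units.items())
        },
        "junctions": {k: list(v) for k, v in sorted(spec.junctions.items())},
        "output": spec.output,
    }


def netlist_from_dict(doc: dict, strict: bool = True) -> NetworkSpec:
    if not isinstance(doc, dict):
        raise NetlistError("netlist document must be a JSON object")
    schema = doc.get("schema")
    if schema != SCHEMA:
        raise NetlistError(f"field 'schema': expected {SCHEMA!r}, got {schema!r}")
    if strict:
        unknown = set(doc) - _TOP_FIELDS
        if unknown:
            raise NetlistError(f"unknown top-level fields: {sorted(unknown)}")
    for fld in ("inputs", "units", "output"):
        if fld not in doc:
            raise NetlistError(f"missing required field {fld!r}")
    units = {}
    for name, u in doc["units"].items():
        if not isinstance(u, dict):
            raise NetlistError(f"field 'units.{name}': must be an object")
        if strict:
            unknown = set(u) - _UNIT_FIELDS
            if unknown:
                raise NetlistError(
                    f"unknown fields in 'units.{name}': {sorted(unknown)}"
                )
        for fld in ("inputs", "weights", "scales"):
            if fld not in u:
                raise NetlistError(f"missing field 'units.{name}.{fld}'")
        try:
            units[name] = PerceptgeneParams(
                input_names=tuple(u["inputs"]),
                weights=tuple(u["weights"]),
                input_scales=tuple(u["scales"]),
                bias=float(u.get("bias", 1.0)),
                hill=float(u.get("hill", 1.0)),
                basal=float(u.get("basal", 1e-4)),
                activation_kind=u.get("activation", "sigmoid"),
            )
        except (TypeError, ValueError) as exc:
            raise NetlistError(f"invalid unit 'units.{name}': {exc}") from exc
    try:
        return NetworkSpec(
            units=units,
            external_inputs=tuple(doc["inputs"]),
            output=doc["output"],
            junctions={k: tuple(v) for k, v in doc.get("junctions", {}).items()},
        )
    except ValueError as exc:
        raise NetlistError(str(exc)) from exc


def write_netlist(spec: NetworkSpec, path) -> None:
    Path(path).write_text(json.dumps(netlist_to_dict(spec), indent=2) + "\n")


def read_netlist(path, strict: bool = True) -> NetworkSpec:
    return netlist_from_dict(json.loads(Path(path).read_text()), strict=strict)


def write_surface(surface: Surface, path) -> None:
    """Surface -> CSV with columns input:<name>..., output, replicate."""
    mesh = surface.meshgrid()
    flat = {f"input:{name}": m.ravel() for name, m in mesh.items()}
    n_grid = next(iter(flat.values())).size
    rows = []
    reps = surface.replicates
    outs = surface.outputs if reps > 1 else surface.outputs[np.newaxis]
    for r in range(reps):
        df = pd.DataFrame(flat)
        df["output"] = outs[r].ravel()
        df["replicate"] = r + 1
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_surface(path, coordinates: str = "linear") -> Surface:
    df = pd.read_csv(path)
    input_cols = [c for c in df.columns if c.startswith("input:")]
    if not input_cols:
        raise ValueError("surface CSV has no 'input:<name>' columns")
    if "output" not in df.columns:
        raise ValueError("surface CSV has no 'output' column")
    names = [c.split(":", 1)[1] for c in input_cols]
    if coordinates == "linear":
        for c in input_cols:
            if (df[c] <= 0).any():
                raise ValueError(
                    f"column {c!r} contains non-positive concentrations"
                )
    reps = sorted(df["replicate"].unique()) if "replicate" in df.columns else [1]
    axes = {n: np.unique(df[f"input:{n}"].to_numpy()) for n in names}
    shape = tuple(len(v) for v in axes.values())
    n_grid = int(np.prod(shape))
    outs = np.empty((len(reps), *shape))
    for k, r in enumerate(reps):
        sub = df[df["replicate"] == r] if "replicate" in df.columns else df
        if len(sub) != n_grid:
            raise ValueError(
                f"replicate {r}: expected {n_grid} grid rows, got {len(sub)}"
            )
        sub = sub.sort_values(input_cols)
        outs[k] = sub["output"].to_numpy().reshape(shape)
    outputs = outs if len(reps) > 1 else outs[0]
    return Surface(inputs=axes, outputs=outputs, coordinates=coordinates,
                   replicates=len(reps))
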