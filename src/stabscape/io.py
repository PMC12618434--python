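"""Model/arrangement file parsing, run configuration, and report writing.

Model files are a small JSON dialect with exact-rational expressions only::

    {"variables": ["y", "z"],
     "parameters": ["beta_y", "beta_z", "gamma_y", "gamma_z"],
     "rates": ["beta_y*y*(1-y) - gamma_y*y", "..."],
     "fixed": {"d": "1"}}

Arrangement files carry raw boundary polynomials::

    {"parameters": ["a1", "a2"], "polynomials": ["(a1-5)^2 + ..."]}
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import sympy as sp

from .boundaries import HypersurfaceArrangement
from .expressions import ExpressionError, parse_expression
from .models import ParametricODESystem

__all__ = [
    "RunConfig",
    "parse_model_file",
    "parse_arrangement_file",
    "write_arrangement_file",
    "write_region_report",
]


@dataclass
class RunConfig:
    """Run configuration shared by the CLI commands.

    Every run writes a manifest (the configuration, the seeds actually used
    and the software version) next to its outputs for reproducibility.
    """

    seed: int = 0
    tolerances: dict = field(default_factory=dict)
    elimination_timeout: float | None = 600.0
    positive_orthant: bool = True
    output_dir: str = "."
    verbosity: int = 0
    seeds_used: list = field(default_factory=list)

    def write_manifest(self, path: str | Path) -> Path:
        from . import __version__

        path = Path(path)
        payload = dict(dataclasses.asdict(self), version=__version__)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def parse_model_file(path: str | Path) -> ParametricODESystem:
    """Read a model JSON file into a :class:`ParametricODESystem`.

    Expressions are parsed exactly over the rationals; float literals and
    undeclared identifiers are rejected with a location message.
    """
    path = Path(path)
    payload = json.loads(path.read_text())
    for key in ("variables", "parameters", "rates"):
        if key not in payload:
            raise ExpressionError(f"model file {path} is missing the {key!r} field")
    try:
        return ParametricODESystem.from_strings(
            variables=payload["variables"],
            parameters=payload["parameters"],
            rates=payload["rates"],
            fixed=payload.get("fixed"),
            name=payload.get("name", path.stem),
        )
    except ExpressionError as exc:
        raise ExpressionError(f"{path}: {exc}") from None


def parse_arrangement_file(path: str | Path) -> HypersurfaceArrangement:
    """Read an arrangement JSON file into a :class:`HypersurfaceArrangement`."""
    path = Path(path)
    payload = json.loads(path.read_text())
    params = [sp.Symbol(p) for p in payload["parameters"]]
    names = {p.name: p for p in params}
    try:
        polys = [parse_expression(text, names) for text in payload["polynomials"]]
    except ExpressionError as exc:
        raise ExpressionError(f"{path}: {exc}") from None
    return HypersurfaceArrangement.from_polynomials(params, polys)


def write_arrangement_file(arr: HypersurfaceArrangement, path: str | Path) -> Path:
    """Serialize an arrangement with degrees and provenance tags."""
    path = Path(path)
    payload = {
        "parameters": [p.name for p in arr.parameters],
        "polynomials": [str(p) for p in arr.polynomials],
        "degrees": arr.degrees,
        "is_coordinate": list(arr.is_coordinate),
        "provenance": {
            str(i): [list(t) for t in tags] for i, tags in arr.provenance.items()
        },
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def write_region_report(reports, path: str | Path) -> dict[str, Path]:
    """Write ``regions.csv`` and ``regions.json`` for a list of region reports.

    Field ordering is fixed so identical runs produce byte-identical files.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("refusing to write an empty region report")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    param_names = [p.name for p in reports[0].parameters]
    rows = []
    for rep in sorted(reports, key=lambda r: r.region_id):
        row = {"region_id": rep.region_id}
        for name, value in zip(param_names, rep.representative):
            row[name] = float(value)
        row["n_real_positive"] = rep.n_real_positive
        row["stable_set"] = "|".join(sorted(rep.stable_set.labels))
        row["stable_set_name"] = rep.stable_set.display_name
        row["bistable"] = rep.bistable
        row["empty_stable_set"] = rep.empty_stable_set
        row["near_boundary"] = rep.near_boundary
        rows.append(row)

    csv_path = path / "regions.csv"
    json_path = path / "regions.json"
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.12g")
    json_path.write_text(json.dumps(rows, indent=2) + "\n")
    return {"csv": csv_path, "json": json_path}
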