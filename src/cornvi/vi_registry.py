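"""Vegetation-index library over five-band reflectance.

A vegetation index (VI) is a fixed arithmetic combination of band
reflectances designed to track canopy greenness, chlorophyll content or
structure.  This module holds the registry of index definitions, evaluates
them on :class:`~cornvi.bands.BandSet` values, and assembles the per-flight
plots x indices panel (:class:`VIMatrix`) that the screening stage consumes.

Every formula is declared as an arithmetic expression over the symbols
``B, G, R, RE, NIR`` (plus named constants) and compiled once by a small
safe expression grammar supporting ``+ - * / ** sqrt`` and parentheses.
The same grammar backs user extension of the registry from a YAML/JSON
config file, so built-in and user-supplied indices go through one code path.

Missing-value policy: any evaluation that divides by zero, takes the square
root of a negative number, or otherwise leaves the finite range yields NaN
("missing"), never an exception — downstream correlation screens drop
missing cells pairwise.
"""

from __future__ import annotations

import ast
import json
import math
import operator
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

from .bands import BAND_NAMES, BandSet

__all__ = [
    "VIDefinition",
    "FlightMeta",
    "VIMatrix",
    "compile_formula",
    "register",
    "register_from_config",
    "registered_names",
    "get_definition",
    "compute_vi",
    "compute_panel",
    "panels_to_long_frame",
    "panels_from_long_frame",
]

_BAND_SYMBOLS = {"B": "blue", "G": "green", "R": "red", "RE": "rededge", "NIR": "nir"}


class UnknownVIError(KeyError):
    """Lookup of a VI name that is not registered."""


class FormulaSyntaxError(ValueError):
    """An index formula uses syntax outside the safe arithmetic grammar."""


# ---------------------------------------------------------------------------
# safe expression grammar

_BINOPS: dict[type, Callable[[float, float], float]] = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
    ast.Pow: operator.pow,
}


def compile_formula(expression: str, constants: Mapping[str, float] | None = None
                    ) -> tuple[Callable[..., float], frozenset[str]]:
    """Compile an arithmetic expression over ``B, G, R, RE, NIR`` to a function.

    Returns ``(func, required_bands)`` where ``func(blue, green, red,
    rededge, nir)`` evaluates the expression and ``required_bands`` is the
    set of band names the expression references.  Only ``+ - * / **``,
    unary minus, ``sqrt(...)``, numbers, band symbols and the supplied
    constant names are permitted; anything else raises
    :class:`FormulaSyntaxError`.
    """
    constants = dict(constants or {})
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise FormulaSyntaxError(f"cannot parse formula {expression!r}: {exc}") from exc

    used_bands: set[str] = set()

    def build(node: ast.AST) -> Callable[[Mapping[str, float]], float]:
        if isinstance(node, ast.Expression):
            return build(node.body)
        if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
            op = _BINOPS[type(node.op)]
            left, right = build(node.left), build(node.right)
            return lambda env: op(left(env), right(env))
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
            sign = -1.0 if isinstance(node.op, ast.USub) else 1.0
            inner = build(node.operand)
            return lambda env: sign * inner(env)
        if isinstance(node, ast.Call):
            if not (isinstance(node.func, ast.Name) and node.func.id == "sqrt"
                    and len(node.args) == 1 and not node.keywords):
                raise FormulaSyntaxError(
                    f"only sqrt(x) calls are allowed in formulas: {expression!r}")
            inner = build(node.args[0])
            return lambda env: math.sqrt(inner(env))
        if isinstance(node, ast.Name):
            name = node.id
            if name in _BAND_SYMBOLS:
                used_bands.add(_BAND_SYMBOLS[name])
                return lambda env, _n=name: env[_n]
            if name in constants:
                value = float(constants[name])
                return lambda env, _v=value: _v
            raise FormulaSyntaxError(
                f"unknown symbol {name!r} in formula {expression!r}; "
                f"bands are {sorted(_BAND_SYMBOLS)} and constants {sorted(constants)}")
        if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            return lambda env, _v=float(node.value): _v
        raise FormulaSyntaxError(
            f"disallowed construct {type(node).__name__} in formula {expression!r}")

    body = build(tree)

    def func(blue: float, green: float, red: float, rededge: float, nir: float) -> float:
        env = {"B": blue, "G": green, "R": red, "RE": rededge, "NIR": nir}
        try:
            value = body(env)
        except (ZeroDivisionError, ValueError, OverflowError):
            return math.nan
        return value if math.isfinite(value) else math.nan

    return func, frozenset(used_bands)


# ---------------------------------------------------------------------------
# registry

@dataclass(frozen=True)
class VIDefinition:
    """A named vegetation-index formula over the five sensor bands."""

    name: str
    formula: str
    func: Callable[..., float] = field(repr=False, compare=False)
    required_bands: frozenset[str] = frozenset()
    reference: str = ""


_REGISTRY: dict[str, VIDefinition] = {}


def _canonical_key(name: str) -> str:
    return name.replace("/", "_").strip().lower()


def register(name: str, formula: str, *, constants: Mapping[str, float] | None = None,
             reference: str = "", overwrite: bool = False) -> VIDefinition:
    """Register an index under its canonical name ("TCARI/OSAVI" -> "TCARI_OSAVI")."""
    canonical = name.replace("/", "_").strip()
    key = _canonical_key(canonical)
    if key in _REGISTRY and not overwrite:
        raise ValueError(f"VI {canonical!r} already registered")
    func, bands = compile_formula(formula, constants)
    definition = VIDefinition(canonical, formula, func, bands, reference)
    _REGISTRY[key] = definition
    return definition


def register_from_config(source: str | Path | Mapping) -> list[VIDefinition]:
    """Extend the registry from a YAML/JSON mapping ``name -> {formula, constants?, reference?}``."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        try:
            entries = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            entries = yaml.safe_load(text)
    else:
        entries = source
    if not isinstance(entries, Mapping):
        raise FormulaSyntaxError("registry config must map VI names to definitions")
    out = []
    for name, spec in entries.items():
        if isinstance(spec, str):
            spec = {"formula": spec}
        out.append(register(name, spec["formula"],
                            constants=spec.get("constants"),
                            reference=spec.get("reference", ""),
                            overwrite=bool(spec.get("overwrite", False))))
    return out


def registered_names() -> list[str]:
    return sorted(d.name for d in _REGISTRY.values())


def get_definition(name: str) -> VIDefinition:
    try:
        return _REGISTRY[_canonical_key(name)]
    except KeyError:
        raise UnknownVIError(
            f"no VI named {name!r}; registered: {', '.join(registered_names())}"
        ) from None


def compute_vi(name: str, bands: BandSet) -> float:
    """Value of the registered formula on one BandSet; NaN on zero denominators."""
    return get_definition(name).func(*bands.as_tuple())


# ---------------------------------------------------------------------------
# built-in index library
#
# Two-band structural indices, soil-adjusted family, red-edge chlorophyll
# family (the screen's expected winners), and the visible-band indices.
# Constants follow the canonical published forms: SAVI L=0.5, OSAVI 0.16,
# WDRVI alpha=0.2, EVI G=2.5/C1=6/C2=7.5/L=1.

_BUILTINS: list[tuple[str, str, dict[str, float], str]] = [
    ("NDVI", "(NIR - R) / (NIR + R)", {}, "Rouse et al. 1974"),
    ("GNDVI", "(NIR - G) / (NIR + G)", {}, "Gitelson et al. 1996"),
    ("reNDVI", "(NIR - RE) / (NIR + RE)", {}, "Gitelson & Merzlyak 1994"),
    ("SR705", "NIR / RE", {}, "Sims & Gamon 2002"),
    ("MTCI", "(NIR - RE) / (RE - R)", {}, "Dash & Curran 2004"),
    ("LCI", "(NIR - RE) / (NIR + R)", {}, "Datt 1999"),
    ("RIrededge", "NIR / RE - 1", {}, "Gitelson et al. 2003"),
    ("CIgreen", "NIR / G - 1", {}, "Gitelson et al. 2003"),
    ("RIgreen", "NIR / G - 1", {}, "Gitelson et al. 2003"),
    ("PBI", "NIR / G", {}, "Rama Rao et al. 2008"),
    ("CVI", "NIR * R / (G * G)", {}, "Vincini et al. 2008"),
    ("mND705", "(NIR - RE) / (NIR + RE - 2 * B)", {}, "Sims & Gamon 2002"),
    ("mSR705", "(NIR - B) / (RE - B)", {}, "Sims & Gamon 2002"),
    ("DATT", "(NIR - RE) / (NIR - R)", {}, "Datt 1999"),
    ("SAVI", "(1 + L) * (NIR - R) / (NIR + R + L)", {"L": 0.5}, "Huete 1988"),
    ("OSAVI", "(NIR - R) / (NIR + R + 0.16)", {}, "Rondeaux et al. 1996"),
    ("MSAVI", "0.5 * (2 * NIR + 1 - sqrt((2 * NIR + 1) ** 2 - 8 * (NIR - R)))", {},
     "Qi et al. 1994"),
    ("RDVI", "(NIR - R) / sqrt(NIR + R)", {}, "Roujean & Breon 1995"),
    ("EVI", "Gf * (NIR - R) / (NIR + C1 * R - C2 * B + L)",
     {"Gf": 2.5, "C1": 6.0, "C2": 7.5, "L": 1.0}, "Huete et al. 2002"),
    ("WDRVI", "(alpha * NIR - R) / (alpha * NIR + R)", {"alpha": 0.2},
     "Gitelson 2004"),
    ("VARI", "(G - R) / (G + R - B)", {}, "Gitelson et al. 2002"),
    ("TGI", "-0.5 * ((668 - 475) * (R - G) - (668 - 560) * (R - B))", {},
     "Hunt et al. 2011"),
    ("TVI", "0.5 * (120 * (NIR - G) - 200 * (R - G))", {}, "Broge & Leblanc 2001"),
    ("MCARI", "((RE - R) - 0.2 * (RE - G)) * (RE / R)", {}, "Daughtry et al. 2000"),
    ("MCARI2",
     "1.5 * (2.5 * (NIR - R) - 1.3 * (NIR - G)) / "
     "sqrt((2 * NIR + 1) ** 2 - (6 * NIR - 5 * sqrt(R)) - 0.5)", {},
     "Haboudane et al. 2004"),
    ("TCARI_OSAVI",
     "(3 * ((RE - R) - 0.2 * (RE - G) * (RE / R))) / ((NIR - R) / (NIR + R + 0.16))",
     {}, "Haboudane et al. 2002"),
    ("ARI", "1 / G - 1 / RE", {}, "Gitelson et al. 2001"),
    ("mARI", "NIR * (1 / G - 1 / RE)", {}, "Gitelson et al. 2001"),
    ("CRIrededge", "1 / B - 1 / RE", {}, "Gitelson et al. 2002"),
    ("RVI", "NIR / R", {}, "Jordan 1969"),
    ("SR445", "NIR / B", {}, "Sims & Gamon 2002"),
]

for _name, _formula, _constants, _ref in _BUILTINS:
    register(_name, _formula, constants=_constants, reference=_ref)

#: The five red-edge chlorophyll indices stable across all study years.
CORE_CHLOROPHYLL_VIS = ("LCI", "MTCI", "RIrededge", "mSR705", "mND705")


# ---------------------------------------------------------------------------
# per-flight panel

@dataclass(frozen=True)
class FlightMeta:
    """One UAV flight: acquisition date, days after planting, phenology label."""

    date: str
    dap: int
    stage: str


@dataclass
class VIMatrix:
    """Plots x indices panel for one flight of one year.

    ``values`` is indexed by plot_id with one column per canonical VI name;
    missing cells are NaN (zero-denominator evaluations or plots with no
    canopy pixels), never silently zero.
    """

    year: int
    flight: FlightMeta
    values: pd.DataFrame

    @property
    def plot_ids(self) -> list:
        return list(self.values.index)

    @property
    def vi_names(self) -> list[str]:
        return list(self.values.columns)


def compute_panel(plot_bandsets: Mapping[object, BandSet | None],
                  names: Iterable[str], flight: FlightMeta, year: int) -> VIMatrix:
    """Evaluate ``names`` cell-wise over per-plot BandSets into a VIMatrix.

    A ``None`` BandSet (plot with no retained canopy pixels) yields an
    all-missing row.  Raises on an empty plot map or empty name list, and on
    any unregistered name before computing anything.
    """
    names = [get_definition(n).name for n in names]
    if not plot_bandsets:
        raise ValueError("compute_panel: no plots supplied")
    if not names:
        raise ValueError("compute_panel: empty VI name list")
    rows = {}
    for plot_id, bands in plot_bandsets.items():
        if bands is None:
            rows[plot_id] = [math.nan] * len(names)
        else:
            rows[plot_id] = [compute_vi(n, bands) for n in names]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    values.index.name = "plot_id"
    return VIMatrix(year=year, flight=flight, values=values)


def panels_to_long_frame(panels: Iterable[VIMatrix]) -> pd.DataFrame:
    """Serialize panels to long form: year, date, dap, stage, plot_id, vi_name, value."""
    records = []
    for panel in panels:
        long = panel.values.reset_index().melt(
            id_vars="plot_id", var_name="vi_name", value_name="value")
        long.insert(0, "year", panel.year)
        long.insert(1, "date", panel.flight.date)
        long.insert(2, "dap", panel.flight.dap)
        long.insert(3, "stage", panel.flight.stage)
        records.append(long)
    return pd.concat(records, ignore_index=True)


def panels_from_long_frame(frame: pd.DataFrame) -> list[VIMatrix]:
    panels = []
    for (year, date, dap, stage), group in frame.groupby(
            ["year", "date", "dap", "stage"], sort=True):
        values = group.pivot(index="plot_id", columns="vi_name", values="value")
        values.columns.name = None
        panels.append(VIMatrix(int(year), FlightMeta(str(date), int(dap), str(stage)),
                               values))
    panels.sort(key=lambda p: (p.year, p.flight.dap))
    return panels
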