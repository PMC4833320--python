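"""Flux matrices, spatial flux fields and Manifest files.

Time-resolved reaction fluxes (mmol gDW^-1 h^-1) come either from plain
TSV tables keyed by reaction id, or from a COMETS-style flux log that
records one flux vector per (time, grid cell, model).  A Manifest file
ties models, flux data, optional spatial layout and an optional hidden-
metabolite list together in one place.

Manifest dialect (tab-separated ``key<TAB>value...`` lines, ``#`` comments)::

    model   <format>   <path-or-URL>     # format in {sbml, comets, edgelist}
    flux    <path-or-URL>
    layout  <path-or-URL>
    hidden  <path-or-URL>
    option.<name>   <value>

Relative paths are resolved against the manifest's own directory; URLs
(anything containing ``://``) are kept verbatim.

COMETS flux-log dialect (MATLAB-style assignments, 1-based indices)::

    fluxes{t}{x}{y}{m} = [v1 v2 ... vK];

where ``K`` must equal the reaction count of model ``m``; vectors bind
positionally to that model's reaction order.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ParseError, ValidationError
from .model_io import MetabolicModel

MODEL_FORMATS = ("sbml", "comets", "edgelist")


@dataclass
class FluxSeries:
    """Per-reaction flux time series for one model."""

    model_id: str
    values: Dict[str, np.ndarray]
    n_time: int
    time_step: Optional[float] = None  # hours

    def __post_init__(self) -> None:
        for rid, arr in list(self.values.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.n_time,):
                raise ValidationError(
                    f"flux series for {rid!r} has length {arr.shape}, expected ({self.n_time},)"
                )
            self.values[rid] = arr

    def at(self, rid: str, t: int) -> float:
        arr = self.values.get(rid)
        return float(arr[t]) if arr is not None else 0.0


@dataclass
class FluxField:
    """Grid of per-model flux series; optional per-cell biomass (gDW)."""

    width: int
    height: int
    cells: Dict[Tuple[int, int], Dict[str, FluxSeries]]
    biomass: Optional[Dict[Tuple[int, int, str], np.ndarray]] = None

    def __post_init__(self) -> None:
        n_times = {s.n_time for series in self.cells.values() for s in series.values()}
        if len(n_times) > 1:
            raise ValidationError(f"cells disagree on n_time: {sorted(n_times)}")
        for (x, y) in self.cells:
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValidationError(f"cell ({x},{y}) outside {self.width}x{self.height} grid")

    @property
    def n_time(self) -> int:
        for series in self.cells.values():
            for s in series.values():
                return s.n_time
        return 0

    @property
    def model_ids(self) -> List[str]:
        return sorted({m for series in self.cells.values() for m in series})


@dataclass
class ManifestSpec:
    """Parsed Manifest: model entries plus optional flux/layout/hidden files."""

    model_entries: List[Tuple[str, str]]  # (path-or-URL, format tag)
    flux_entry: Optional[str] = None
    layout_entry: Optional[str] = None
    hidden_metabolites_entry: Optional[str] = None
    options: Dict[str, str] = field(default_factory=dict)


def _resolve(value: str, base: Path) -> str:
    if "://" in value:
        return value
    p = Path(value)
    return str(p if p.is_absolute() else (base / p))


def read_manifest(path: str | Path) -> ManifestSpec:
    """Read a Manifest file; see the module docstring for the dialect."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"manifest not found: {path}")
    base = path.parent
    models: List[Tuple[str, str]] = []
    flux = layout = hidden = None
    options: Dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"\t+|\s{2,}| ", line)
        parts = [p for p in parts if p]
        key = parts[0].lower()
        if key == "model":
            if len(parts) < 3:
                raise ParseError(f"{path.name}:{lineno}: model line needs <format> <path>")
            fmt, mpath = parts[1].lower(), parts[2]
            if fmt not in MODEL_FORMATS:
                raise ValidationError(f"{path.name}:{lineno}: unknown model format {fmt!r}")
            models.append((_resolve(mpath, base), fmt))
        elif key in ("flux", "layout", "hidden"):
            if len(parts) < 2:
                raise ParseError(f"{path.name}:{lineno}: {key} line needs a path")
            val = _resolve(parts[1], base)
            if key == "flux":
                flux = val
            elif key == "layout":
                layout = val
            else:
                hidden = val
        elif key.startswith("option."):
            options[key[len("option."):]] = parts[1] if len(parts) > 1 else ""
        else:
            raise ParseError(f"{path.name}:{lineno}: unknown manifest key {parts[0]!r}")
    if not models:
        raise ValidationError(f"{path.name}: manifest declares no model entries")
    return ManifestSpec(model_entries=models, flux_entry=flux, layout_entry=layout,
                        hidden_metabolites_entry=hidden, options=options)


def read_hidden_list(path: str | Path) -> List[str]:
    """Read a hidden-metabolite list: one id per line, ``#`` comments."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# Plain flux tables
# ---------------------------------------------------------------------------

def _looks_numeric(tokens: Sequence[str]) -> bool:
    def is_num(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    return all(is_num(t) for t in tokens) and len(tokens) > 0


def read_flux_table(
    path: str | Path,
    model_id: str,
    reactions: Optional[Iterable[str]] = None,
    time_step: Optional[float] = None,
) -> FluxSeries:
    """Read a TSV flux table: header of reaction ids, one row per time point.

    The transposed orientation (reaction ids in the first column, one
    column per time point) is auto-detected.  When ``reactions`` is given,
    orientation is chosen by id overlap; columns whose id is unknown are
    dropped with a warning, and an error is raised if both orientations
    match fewer than 50% of ids.
    """
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise ParseError(f"flux table not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.empty:
        raise ParseError(f"{path.name}: empty flux table")

    header = [str(v) for v in df.iloc[0].tolist()]
    first_col = [str(v) for v in df.iloc[:, 0].tolist()]

    def orient_rows_time() -> Dict[str, np.ndarray]:
        # header row = reaction ids (a leading time column labelled 't'/'time' allowed)
        cols = header
        body = df.iloc[1:].reset_index(drop=True)
        data: Dict[str, np.ndarray] = {}
        for j, rid in enumerate(cols):
            if rid.lower() in ("t", "time"):
                continue
            data[rid] = body.iloc[:, j].astype(float).to_numpy()
        return data

    def orient_cols_time() -> Dict[str, np.ndarray]:
        body = df
        start = 0
        if not _looks_numeric([str(v) for v in df.iloc[0, 1:].tolist()]):
            body = df.iloc[1:].reset_index(drop=True)
        return {
            str(body.iloc[i, 0]): body.iloc[i, 1:].astype(float).to_numpy()
            for i in range(start, len(body))
        }

    header_is_ids = not _looks_numeric(header)
    firstcol_is_ids = not _looks_numeric(first_col[1:] if header_is_ids else first_col)

    candidates = []
    if header_is_ids:
        candidates.append(orient_rows_time)
    if firstcol_is_ids:
        candidates.append(orient_cols_time)
    if not candidates:
        raise ParseError(f"{path.name}: could not locate reaction ids in header or first column")

    if reactions is not None:
        known = set(reactions)
        best, best_frac = None, -1.0
        for cand in candidates:
            try:
                data = cand()
            except ValueError:
                continue  # not parseable in this orientation
            frac = (sum(r in known for r in data) / len(data)) if data else 0.0
            if frac > best_frac:
                best, best_frac = data, frac
        if best_frac < 0.5:
            raise ValidationError(
                f"{path.name}: <50% of ids match model {model_id!r} reactions in either "
                "orientation; check that reaction IDs match the model"
            )
        dropped = sorted(set(best) - known)
        if dropped:
            warnings.warn(
                f"{path.name}: dropping {len(dropped)} unknown reaction column(s): "
                + ", ".join(dropped[:5]),
                stacklevel=2,
            )
            best = {r: v for r, v in best.items() if r in known}
        data = best
    else:
        data = candidates[0]()

    lengths = {len(v) for v in data.values()}
    if len(lengths) != 1:
        raise ParseError(f"{path.name}: ragged flux table")
    return FluxSeries(model_id=model_id, values=data, n_time=lengths.pop(),
                      time_step=time_step)


def write_flux_table(series: FluxSeries, path: str | Path) -> None:
    """Write a FluxSeries as a TSV (reactions in columns, rows = time)."""
    rids = sorted(series.values)
    lines = ["\t".join(rids)]
    for t in range(series.n_time):
        lines.append("\t".join(f"{series.values[r][t]:.10g}" for r in rids))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# COMETS flux logs
# ---------------------------------------------------------------------------

_FLUX_LINE = re.compile(
    r"fluxes\{(\d+)\}\{(\d+)\}\{(\d+)\}\{(\d+)\}\s*=\s*\[([^\]]*)\]\s*;"
)


def read_comets_flux_log(
    path: str | Path,
    models: Sequence[MetabolicModel],
    time_step: Optional[float] = None,
) -> FluxField:
    """Parse a COMETS-style flux log into a :class:`FluxField`.

    Missing (time, cell, model) entries are filled with zero flux and a
    warning — sparse logs from long simulations remain loadable.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"flux log not found: {path}")
    order = {i + 1: m for i, m in enumerate(models)}
    raw: Dict[Tuple[int, int, int, int], np.ndarray] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("%", "#")):
            continue
        m = _FLUX_LINE.match(line)
        if m is None:
            raise ParseError(f"{path.name}:{lineno}: unrecognized flux-log line")
        t, x, y, mi = (int(g) for g in m.groups()[:4])
        if mi not in order:
            raise ValidationError(
                f"{path.name}:{lineno}: model index {mi} out of range (1..{len(models)})"
            )
        vec = np.array([float(v) for v in m.group(5).split()])
        model = order[mi]
        if len(vec) != len(model.reactions):
            raise ValidationError(
                f"{path.name}: flux vector at t={t} x={x} y={y} m={mi} has length "
                f"{len(vec)}, model {model.id!r} has {len(model.reactions)} reactions"
            )
        raw[(t, x, y, mi)] = vec
    if not raw:
        raise ParseError(f"{path.name}: no flux assignments found")

    ts = sorted({k[0] for k in raw})
    xs = {k[1] for k in raw}
    ys = {k[2] for k in raw}
    n_time = max(ts)  # 1-based in the log
    width, height = max(xs), max(ys)
    expected_t = set(range(1, n_time + 1))
    if set(ts) != expected_t:
        missing = sorted(expected_t - set(ts))
        warnings.warn(
            f"{path.name}: missing time step(s) {missing}; filling with zero flux",
            stacklevel=2,
        )

    cells: Dict[Tuple[int, int], Dict[str, FluxSeries]] = {}
    for x in range(1, width + 1):
        for y in range(1, height + 1):
            per_model: Dict[str, FluxSeries] = {}
            for mi, model in order.items():
                rids = [r.id for r in model.reactions]
                mat = np.zeros((n_time, len(rids)))
                seen = False
                for t in range(1, n_time + 1):
                    vec = raw.get((t, x, y, mi))
                    if vec is not None:
                        mat[t - 1] = vec
                        seen = True
                if seen:
                    per_model[model.id] = FluxSeries(
                        model_id=model.id,
                        values={rid: mat[:, j].copy() for j, rid in enumerate(rids)},
                        n_time=n_time,
                        time_step=time_step,
                    )
            if per_model:
                cells[(x - 1, y - 1)] = per_model
    return FluxField(width=width, height=height, cells=cells)


def write_comets_flux_log(field: FluxField, models: Sequence[MetabolicModel],
                          path: str | Path) -> None:
    """Write a FluxField in the assignment dialect read by :func:`read_comets_flux_log`."""
    order = {m.id: i + 1 for i, m in enumerate(models)}
    rid_order = {m.id: [r.id for r in m.reactions] for m in models}
    lines = []
    for t in range(1, field.n_time + 1):
        for (x, y) in sorted(field.cells):
            for model_id in sorted(field.cells[(x, y)], key=lambda m: order[m]):
                series = field.cells[(x, y)][model_id]
                vec = " ".join(
                    f"{series.at(rid, t - 1):.10g}" for rid in rid_order[model_id]
                )
                lines.append(
                    f"fluxes{{{t}}}{{{x + 1}}}{{{y + 1}}}{{{order[model_id]}}} = [{vec}];"
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Spatial selection / averaging
# ---------------------------------------------------------------------------

def select_point(field: FluxField, x: int, y: int) -> Dict[str, FluxSeries]:
    """Return the flux series of one grid cell, unchanged."""
    if not (0 <= x < field.width and 0 <= y < field.height):
        raise ValidationError(
            f"point ({x},{y}) outside the {field.width}x{field.height} grid"
        )
    cell = field.cells.get((x, y))
    if cell is None:
        raise ValidationError(f"no flux data recorded at ({x},{y})")
    return cell


def average_over_grid(field: FluxField, biomass_weighted: bool = False) -> Dict[str, FluxSeries]:
    """Average fluxes over all grid cells, per model/reaction/time point.

    Unweighted arithmetic mean by default; cells lacking a model contribute
    zero flux for it.  With ``biomass_weighted=True``, each cell is weighted
    by that model's biomass trajectory (requires ``field.biomass``).
    """
    if not field.cells:
        raise ValidationError("flux field has no cells")
    n_time = field.n_time
    out: Dict[str, FluxSeries] = {}
    for model_id in field.model_ids:
        rids = sorted({
            rid for cell in field.cells.values()
            for rid in cell.get(model_id, FluxSeries(model_id, {}, n_time)).values
        })
        acc = {rid: np.zeros(n_time) for rid in rids}
        wsum = np.zeros(n_time)
        n_cells = 0
        for (x, y), cell in field.cells.items():
            series = cell.get(model_id)
            if biomass_weighted:
                if field.biomass is None:
                    raise ValidationError("biomass weighting requested but field has no biomass")
                w = np.asarray(field.biomass.get((x, y, model_id), np.zeros(n_time)), dtype=float)
            else:
                w = np.ones(n_time)
            wsum += w
            n_cells += 1
            if series is None:
                continue
            for rid in rids:
                acc[rid] += w * series.values.get(rid, np.zeros(n_time))
        denom = np.where(wsum == 0, 1.0, wsum)
        out[model_id] = FluxSeries(
            model_id=model_id,
            values={rid: acc[rid] / denom for rid in rids},
            n_time=n_time,
        )
    return out


# ---------------------------------------------------------------------------
# Simple spatial layout file (grid dims + biomass)
# ---------------------------------------------------------------------------

def read_layout_file(path: str | Path) -> Dict[str, object]:
    """Read a minimal spatial layout file.

    Dialect::

        grid <width> <height>
        biomass <x> <y> <model_id> <v_t0> <v_t1> ...

    Returns ``{"width": w, "height": h, "biomass": {(x, y, model): array}}``.
    """
    path = Path(path)
    width = height = None
    biomass: Dict[Tuple[int, int, str], np.ndarray] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "grid":
            width, height = int(parts[1]), int(parts[2])
        elif parts[0] == "biomass":
            x, y, mid = int(parts[1]), int(parts[2]), parts[3]
            biomass[(x, y, mid)] = np.array([float(v) for v in parts[4:]])
        else:
            raise ParseError(f"{path.name}:{lineno}: unknown layout key {parts[0]!r}")
    if width is None:
        raise ValidationError(f"{path.name}: layout file missing 'grid' line")
    return {"width": width, "height": height, "biomass": biomass}
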