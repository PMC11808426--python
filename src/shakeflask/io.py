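"""File I/O and the tabular characterization driver.

Snapshots travel as legacy-VTK ASCII structured grids (STRUCTURED_POINTS,
cell- or point-centered, velocity as one 3-vector array or three scalars)
or as delimited text with one row per cell. Operating-condition tables are
delimited text in lab units (rpm, mm, mL, mPa·s, °C); everything is
converted to SI exactly once at this boundary.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlations as corr
from . import properties as props
from .fieldpost import ContactLine, FieldGrid

__all__ = [
    "load_fields",
    "save_fields",
    "write_vtk",
    "read_vtk",
    "write_delimited",
    "read_delimited",
    "characterize",
    "contact_lines_to_frame",
]

_OPTIONAL_FIELDS = ("k", "omega")


# ----------------------------------------------------------------- VTK ---

def write_vtk(grid: FieldGrid, path, velocity_as: str = "vector") -> None:
    """Write a snapshot as legacy-VTK ASCII STRUCTURED_POINTS cell data.

    ``velocity_as='vector'`` emits one VECTORS array named ``velocity``;
    ``'scalars'`` emits three SCALARS arrays named u, v, w.
    """
    nx, ny, nz = grid.shape
    dx, dy, dz = grid.spacing
    origin = (grid.x[0] - dx / 2, grid.y[0] - dy / 2, grid.z[0] - dz / 2)
    n_cells = nx * ny * nz

    def flat(a: np.ndarray) -> np.ndarray:
        return a.ravel(order="F")  # VTK: x fastest, then y, then z

    buf = _io.StringIO()
    buf.write("# vtk DataFile Version 3.0\n")
    buf.write("shakeflask two-phase snapshot\n")
    buf.write("ASCII\nDATASET STRUCTURED_POINTS\n")
    buf.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
    buf.write(f"ORIGIN {origin[0]:.17g} {origin[1]:.17g} {origin[2]:.17g}\n")
    buf.write(f"SPACING {dx:.17g} {dy:.17g} {dz:.17g}\n")
    buf.write(f"CELL_DATA {n_cells}\n")
    if velocity_as == "vector":
        buf.write("VECTORS velocity double\n")
        uvw = np.stack([flat(grid.u), flat(grid.v), flat(grid.w)], axis=1)
        np.savetxt(buf, uvw, fmt="%.17g")
    elif velocity_as == "scalars":
        for name in ("u", "v", "w"):
            _write_scalar(buf, name, flat(getattr(grid, name)))
    else:
        raise ValueError("velocity_as must be 'vector' or 'scalars'")
    _write_scalar(buf, "alpha", flat(grid.alpha))
    for name in _OPTIONAL_FIELDS:
        arr = getattr(grid, name)
        if arr is not None:
            _write_scalar(buf, name, flat(arr))
    Path(path).write_text(buf.getvalue())


def _write_scalar(buf, name: str, data: np.ndarray) -> None:
    buf.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
    np.savetxt(buf, data, fmt="%.17g")


class VTKParseError(ValueError):
    pass


def read_vtk(path) -> FieldGrid:
    """Read a legacy-VTK ASCII STRUCTURED_POINTS snapshot.

    Accepts CELL_DATA (cell-centered, DIMENSIONS are node counts) or
    POINT_DATA (values taken as cell centers directly); velocity either as
    a VECTORS array or three SCALARS u/v/w.
    """
    tokens = Path(path).read_text().split("\n")
    it = iter(range(len(tokens)))
    dims = origin = spacing = None
    n_values = None
    centered = None
    arrays: dict[str, np.ndarray] = {}
    i = 0
    lines = tokens

    def parse_error(msg: str, lineno: int) -> VTKParseError:
        return VTKParseError(f"{path}: line {lineno + 1}: {msg}")

    while i < len(lines):
        line = lines[i].strip()
        up = line.upper()
        if up.startswith("DATASET"):
            if "STRUCTURED_POINTS" not in up:
                raise parse_error("only STRUCTURED_POINTS datasets supported", i)
        elif up.startswith("DIMENSIONS"):
            dims = tuple(int(t) for t in line.split()[1:4])
        elif up.startswith("ORIGIN"):
            origin = tuple(float(t) for t in line.split()[1:4])
        elif up.startswith("SPACING"):
            spacing = tuple(float(t) for t in line.split()[1:4])
        elif up.startswith("CELL_DATA") or up.startswith("POINT_DATA"):
            centered = "cell" if up.startswith("CELL_DATA") else "point"
            n_values = int(line.split()[1])
        elif up.startswith("SCALARS"):
            name = line.split()[1]
            i += 1  # LOOKUP_TABLE line
            if not lines[i].strip().upper().startswith("LOOKUP_TABLE"):
                raise parse_error(f"expected LOOKUP_TABLE after SCALARS {name}", i)
            vals, i = _read_floats(lines, i + 1, n_values, path)
            arrays[name] = vals
            continue
        elif up.startswith("VECTORS"):
            name = line.split()[1]
            vals, i = _read_floats(lines, i + 1, 3 * n_values, path)
            arrays[name] = vals.reshape(-1, 3)
            continue
        i += 1

    if dims is None or origin is None or spacing is None or centered is None:
        raise VTKParseError(f"{path}: missing DIMENSIONS/ORIGIN/SPACING/DATA header")
    if centered == "cell":
        shape = tuple(d - 1 for d in dims)
        centers0 = tuple(o + s / 2 for o, s in zip(origin, spacing))
    else:
        shape = dims
        centers0 = origin
    nx, ny, nz = shape
    x = centers0[0] + spacing[0] * np.arange(nx)
    y = centers0[1] + spacing[1] * np.arange(ny)
    z = centers0[2] + spacing[2] * np.arange(nz)

    def unflat(a: np.ndarray) -> np.ndarray:
        return a.reshape(shape, order="F")

    if "velocity" in arrays:
        vel = arrays.pop("velocity")
        u, v, w = (unflat(vel[:, j]) for j in range(3))
    elif all(n in arrays for n in ("u", "v", "w")):
        u, v, w = (unflat(arrays.pop(n)) for n in ("u", "v", "w"))
    else:
        raise VTKParseError(
            f"{path}: velocity missing (need a 'velocity' VECTORS array or "
            "scalars u, v, w)"
        )
    if "alpha" not in arrays:
        raise VTKParseError(f"{path}: volume fraction missing (no 'alpha' array)")
    alpha = unflat(arrays.pop("alpha"))
    if np.any(alpha < -1e-6) or np.any(alpha > 1 + 1e-6):
        raise ValueError(f"{path}: volume fraction outside [0, 1] beyond 1e-6")
    optional = {
        n: unflat(arrays[n]) for n in _OPTIONAL_FIELDS if n in arrays
    }
    return FieldGrid(x, y, z, u=u, v=v, w=w, alpha=alpha, **optional)


def _read_floats(lines, start: int, count: int, path):
    vals: list[float] = []
    i = start
    while len(vals) < count and i < len(lines):
        s = lines[i].strip()
        if s:
            try:
                vals.extend(float(t) for t in s.split())
            except ValueError as exc:
                raise VTKParseError(f"{path}: line {i + 1}: {exc}") from None
        i += 1
    if len(vals) < count:
        raise VTKParseError(f"{path}: truncated data array (expected {count} values)")
    return np.array(vals[:count]), i


# ----------------------------------------------------------- delimited ---

def write_delimited(grid: FieldGrid, path, sep: str = ",") -> None:
    """Write a snapshot as delimited text, one row per cell."""
    X, Y, Z = np.meshgrid(grid.x, grid.y, grid.z, indexing="ij")
    cols = {
        "x": X.ravel(), "y": Y.ravel(), "z": Z.ravel(),
        "u": grid.u.ravel(), "v": grid.v.ravel(), "w": grid.w.ravel(),
        "alpha": grid.alpha.ravel(),
    }
    for name in _OPTIONAL_FIELDS:
        arr = getattr(grid, name)
        if arr is not None:
            cols[name] = arr.ravel()
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def read_delimited(path, sep: str = ",") -> FieldGrid:
    """Read a delimited snapshot (columns x,y,z,u,v,w,alpha[,k,omega])."""
    df = pd.read_csv(path, sep=sep)
    required = {"x", "y", "z", "u", "v", "w"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "alpha" not in df.columns:
        raise ValueError(f"{path}: volume fraction missing (no 'alpha' column)")
    x = np.unique(df["x"].to_numpy())
    y = np.unique(df["y"].to_numpy())
    z = np.unique(df["z"].to_numpy())
    shape = (len(x), len(y), len(z))
    if len(df) != np.prod(shape):
        raise ValueError(f"{path}: rows do not form a full structured grid")
    order = np.lexsort(
        (df["z"].to_numpy(), df["y"].to_numpy(), df["x"].to_numpy())
    )
    def take(col):
        return df[col].to_numpy()[order].reshape(shape)
    optional = {n: take(n) for n in _OPTIONAL_FIELDS if n in df.columns}
    return FieldGrid(
        x, y, z, u=take("u"), v=take("v"), w=take("w"), alpha=take("alpha"),
        **optional,
    )


def load_fields(path, format: str | None = None) -> FieldGrid:
    """Load a snapshot; format 'vtk_legacy' or 'delimited' (by extension
    when omitted: .vtk is VTK, anything else delimited)."""
    if format is None:
        format = "vtk_legacy" if str(path).endswith(".vtk") else "delimited"
    if format == "vtk_legacy":
        return read_vtk(path)
    if format == "delimited":
        return read_delimited(path)
    raise ValueError(f"unknown snapshot format {format!r}")


def save_fields(grid: FieldGrid, path, format: str | None = None, **kw) -> None:
    if format is None:
        format = "vtk_legacy" if str(path).endswith(".vtk") else "delimited"
    if format == "vtk_legacy":
        write_vtk(grid, path, **kw)
    elif format == "delimited":
        write_delimited(grid, path, **kw)
    else:
        raise ValueError(f"unknown snapshot format {format!r}")


# ------------------------------------------------------- characterize ---

# recognized aliases -> (canonical name, conversion to SI)
_COLUMN_ALIASES = {
    "n_rpm": ("n", lambda v: v / 60.0),
    "n_hz": ("n", lambda v: v),
    "n_1s": ("n", lambda v: v),
    "d_mm": ("d", lambda v: v * 1e-3),
    "d_m": ("d", lambda v: v),
    "d0_mm": ("d0", lambda v: v * 1e-3),
    "d0_m": ("d0", lambda v: v),
    "VL_mL": ("VL", lambda v: v * 1e-6),
    "VL_m3": ("VL", lambda v: v),
    "rho_kgm3": ("rho", lambda v: v),
    "eta_mPas": ("eta", lambda v: v * 1e-3),
    "eta_Pas": ("eta", lambda v: v),
    "K_mPasm": ("K", lambda v: v * 1e-3),
    "K_Pasm": ("K", lambda v: v),
    "m": ("m", lambda v: v),
    "T_C": ("T", lambda v: v + 273.15),
    "T_K": ("T", lambda v: v),
}

#: molecular weights used for the default oxygen-in-water diffusion
#: coefficient in the characterization report, kg/mol
MW_O2 = 0.032
MW_WATER = 0.018


def characterize(
    table: pd.DataFrame,
    flask: str | None = None,
    use_correction: bool = True,
) -> pd.DataFrame:
    """One report row per operating condition.

    Input columns are lab-unit aliases (``n_rpm``/``n_hz``, ``d_mm``,
    ``d0_mm``, ``VL_mL``, ``rho_kgm3``, ``eta_mPas`` or ``K_mPasm`` +
    ``m``, ``T_C``); ``flask`` names a preset supplying ``d`` when the
    table has no diameter column. Power-law rows are first resolved to an
    effective Newtonian viscosity via the Giese fixed point. The kLa
    column uses the SEGW diffusion coefficient of O2 in water at the row
    temperature and resolved viscosity. Row-level failures are reported in
    an ``error`` column and do not stop the run.
    """
    rows = []
    for _, raw in table.iterrows():
        si: dict[str, float] = {}
        for col, value in raw.items():
            if col in _COLUMN_ALIASES and pd.notna(value):
                name, conv = _COLUMN_ALIASES[col]
                si[name] = conv(float(value))
        out: dict[str, object] = {}
        try:
            rows.append(_characterize_row(si, flask, use_correction, out))
        except Exception as exc:  # noqa: BLE001 - per-row error reporting
            out["error"] = str(exc)
            rows.append(out)
    return pd.DataFrame(rows)


def _characterize_row(
    si: dict[str, float], flask: str | None, use_correction: bool,
    out: dict[str, object],
) -> dict[str, object]:
    if "d" not in si:
        if flask is None:
            raise ValueError("no flask diameter: supply a d column or a preset")
        si["d"] = corr.FLASK_PRESETS[flask]
    cond = corr.ShakingConditions(
        n=si["n"], d=si["d"], d0=si["d0"], VL=si["VL"], T=si.get("T", 293.15)
    )
    rho = si.get("rho", 1000.0)

    if "eta" in si:
        eta_eff = si["eta"]
        out["gamma_eff_1_s"] = math.nan
        out["eta_eff_mPas"] = math.nan
    elif "K" in si and "m" in si:
        fluid_pl = corr.FluidSpec(rho=rho, rheology=corr.PowerLaw(si["K"], si["m"]))
        fp = corr.effective_viscosity_fixed_point(cond, fluid_pl)
        eta_eff = fp.eta_eff
        out["gamma_eff_1_s"] = fp.gamma_eff
        out["eta_eff_mPas"] = fp.eta_eff * 1e3
    else:
        raise ValueError("no rheology: supply eta or (K, m)")

    fluid = corr.FluidSpec(rho=rho, rheology=corr.Newtonian(eta_eff))
    state = corr.dimensionless_groups(cond, fluid)
    report = corr.power_input_corrected(cond, fluid) if use_correction else None
    pair = props.SolutePair(
        MW_solute=MW_O2, MW_solvent=MW_WATER, T=cond.T, eta=eta_eff
    )
    DL = props.diffusion_coefficient(pair)
    out.update(
        {
            "Re": state.Re,
            "Re_film": state.Re_film,
            "Ph": state.Ph,
            "regime": corr.classify_regime(state.Ph).label,
            "Ne_prime": float(corr.newton_number(state.Re)),
            "P_per_V_Wm3": corr.power_input_inphase(cond, fluid),
            "P_per_V_corrected_Wm3": (
                report.P_per_V_corrected if report is not None else math.nan
            ),
            "kLa_1_s": corr.kla_correlation(cond, fluid, DL),
            "error": "",
        }
    )
    return out


def contact_lines_to_frame(lines: list[ContactLine]) -> pd.DataFrame:
    """Contact lines as delimited-friendly table (offset_um, azimuth_deg,
    height_mm; absent heights are empty cells)."""
    frames = [
        pd.DataFrame(
            {
                "offset_um": cl.offset * 1e6,
                "azimuth_deg": cl.azimuth,
                "height_mm": cl.height * 1e3,
            }
        )
        for cl in lines
    ]
    return pd.concat(frames, ignore_index=True)
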