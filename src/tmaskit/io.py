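"""Reading and writing the package's text formats.

Scan maps travel as long-format CSV (x_mm, y_mm, z_mm, amplitude — the
out-of-plane column is constant for a 2-D map); configurations as YAML with
bench units (MHz/mm/MPa) converted to strict SI on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acoustic import CartesianGrid, ComplexPressureField, Medium, TransducerSpec
from .beam import ScanMap

__all__ = [
    "write_scan_map",
    "read_scan_map",
    "write_field_csv",
    "load_config",
]

_PLANE_COLS = {"xy": ("x_mm", "y_mm", "z_mm"), "xz": ("x_mm", "z_mm", "y_mm")}


def write_scan_map(m: ScanMap, path) -> None:
    """Write a 2-D scan map as long-format CSV with full 3-D coordinates."""
    kind, _, offset = m.plane.partition("@")
    c0, c1 = np.meshgrid(m.coords[0], m.coords[1], indexing="ij")
    col0, col1, col_fixed = _PLANE_COLS.get(kind, ("c0_mm", "c1_mm", "offset_mm"))
    fixed = float(offset.rstrip("m")) if offset.endswith("mm") else 0.0
    pd.DataFrame(
        {
            col0: c0.ravel(),
            col1: c1.ravel(),
            col_fixed: fixed,
            "amplitude": m.amplitude.ravel(),
        }
    ).to_csv(path, index=False)


def read_scan_map(path) -> ScanMap:
    """Reconstruct a :class:`ScanMap` from long-format CSV.

    The two coordinate columns with more than one distinct value become the
    map axes (row-major in their sorted order).
    """
    df = pd.read_csv(path)
    coord_cols = [c for c in df.columns if c.endswith("_mm")]
    if "amplitude" not in df.columns or len(coord_cols) < 2:
        raise ValueError("scan-map CSV needs *_mm coordinate columns and 'amplitude'")
    varying = [c for c in coord_cols if df[c].nunique() > 1]
    if len(varying) != 2:
        raise ValueError("expected exactly two varying coordinate columns")
    a, b = varying
    pivot = df.pivot_table(index=a, columns=b, values="amplitude")
    kind = "xy" if set(varying) == {"x_mm", "y_mm"} else (
        "xz" if set(varying) == {"x_mm", "z_mm"} else "plane"
    )
    return ScanMap(
        plane=kind,
        coords=(pivot.index.to_numpy(float), pivot.columns.to_numpy(float)),
        coord_labels=(a, b),
        amplitude=pivot.to_numpy(float),
    )


def write_field_csv(field: ComplexPressureField, path) -> None:
    """Write |p| of a 3-D field as long-format CSV (x_mm, y_mm, z_mm, amplitude)."""
    g = field.grid
    x, y, z = np.meshgrid(g.x, g.y, g.z, indexing="ij")
    pd.DataFrame(
        {
            "x_mm": x.ravel() * 1e3,
            "y_mm": y.ravel() * 1e3,
            "z_mm": z.ravel() * 1e3,
            "amplitude": field.magnitude().ravel(),
        }
    ).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML configuration into SI-unit objects.

    Recognized sections::

        transducer: {frequency_mhz | frequency_hz, focus_mm, aperture_mm,
                     drive_pa (default 1.0)}
        medium:     {rho, cs, sigma}
        grid:       {x_mm: [min, max], y_mm: [...], z_mm: [...], step_mm}

    Returns a dict with whichever of ``transducer``/``medium``/``grid`` were
    present, as :class:`TransducerSpec`, :class:`Medium`,
    :class:`CartesianGrid`.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    out: dict = {}
    if "transducer" in cfg:
        t = cfg["transducer"]
        freq = t["frequency_hz"] if "frequency_hz" in t else t["frequency_mhz"] * 1e6
        out["transducer"] = TransducerSpec(
            carrier_frequency=float(freq),
            geometric_focus=float(t["focus_mm"]) * 1e-3,
            aperture_diameter=float(t["aperture_mm"]) * 1e-3,
            surface_drive=float(t.get("drive_pa", 1.0)),
        )
    if "medium" in cfg:
        m = cfg["medium"]
        out["medium"] = Medium(
            density=float(m.get("rho", 1000.0)),
            sound_speed=float(m.get("cs", 1450.0)),
            conductivity=float(m.get("sigma", 1.0)),
        )
    if "grid" in cfg:
        g = cfg["grid"]
        out["grid"] = CartesianGrid.regular(
            tuple(v * 1e-3 for v in g["x_mm"]),
            tuple(v * 1e-3 for v in g["y_mm"]),
            tuple(v * 1e-3 for v in g["z_mm"]),
            float(g["step_mm"]) * 1e-3,
        )
    return out
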