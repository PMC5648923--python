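"""Export and configuration I/O.

Geometry and equilibrium states are written in legacy ASCII VTK
unstructured-grid format (readable by ParaView and friends): node
coordinates in mm, hexahedral cells, cell data (segment id, mean infarct
fraction) and optional point data (displacement).  Pipeline configuration
is read from TOML files whose keys mirror the dataclass fields, with units
in the key names where they are dimensional.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .geometry import GeometryConfig, InfarctSpec, LVGeometry
from .materials import PassiveParams
from .active import ActiveParams, CalciumTransient
from .cohort import NoiseConfig

__all__ = ["write_vtk", "write_run_metadata", "load_config"]

_VTK_HEX = 12


def write_vtk(path, geom: LVGeometry, displacement=None, point_data=None,
              cell_data=None):
    """Write the mesh as a legacy ASCII VTK unstructured grid.

    ``displacement`` (n, 3) is written as a point-data vector field;
    additional scalar fields may be passed as name -> array dicts
    (point_data per node, cell_data per element).  Segment ids and the
    element-mean infarct fraction are always included as cell data.
    """
    path = Path(path)
    n = geom.n_nodes
    E = geom.n_elems
    cd = {"segment_id": geom.segment_id.astype(float),
          "infarct_fraction": geom.phi.mean(axis=1)}
    if cell_data:
        cd.update({k: np.asarray(v, dtype=float) for k, v in cell_data.items()})
    pd_ = dict(point_data or {})
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("lvmech ventricle\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        for p in geom.nodes:
            fh.write("%.9g %.9g %.9g\n" % tuple(p))
        fh.write(f"\nCELLS {E} {E * 9}\n")
        for c in geom.elems:
            fh.write("8 " + " ".join(str(int(i)) for i in c) + "\n")
        fh.write(f"\nCELL_TYPES {E}\n")
        fh.write("\n".join([str(_VTK_HEX)] * E) + "\n")
        fh.write(f"\nCELL_DATA {E}\n")
        for name, arr in cd.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join("%.9g" % v for v in arr) + "\n")
        if displacement is not None or pd_:
            fh.write(f"\nPOINT_DATA {n}\n")
            if displacement is not None:
                fh.write("VECTORS displacement double\n")
                for d in np.asarray(displacement, dtype=float):
                    fh.write("%.9g %.9g %.9g\n" % tuple(d))
            for name, arr in pd_.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join("%.9g" % v for v in np.asarray(arr)) + "\n")
    return path


def write_run_metadata(path, passive: PassiveParams = None,
                       active: ActiveParams = None, extra: dict = None):
    """Echo the parameter sets of a run into a metadata JSON file."""
    meta = {}
    if passive is not None:
        meta["passive"] = passive.to_dict()
    if active is not None:
        meta["active"] = active.to_dict()
    if extra:
        meta.update(extra)
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# configuration files

# Documented TOML sections and the dataclasses they populate.  Dimensional
# keys carry units in their names (mm, kPa, mmHg, rad, deg, uM, s).
_SECTIONS = {
    "geometry": GeometryConfig,
    "infarct": InfarctSpec,
    "passive": PassiveParams,
    "noise": NoiseConfig,
}


def load_config(path) -> dict:
    """Load a pipeline configuration TOML.

    Recognized sections: [geometry] -> GeometryConfig, [infarct] ->
    InfarctSpec, [passive] -> PassiveParams, [active] -> ActiveParams
    (with optional [active.calcium] -> CalciumTransient), [noise] ->
    NoiseConfig.  Unknown sections are returned verbatim under their own
    names; missing sections fall back to defaults and are omitted.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    out = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            out[name] = cls(**raw.pop(name))
    if "active" in raw:
        spec = dict(raw.pop("active"))
        if "calcium" in spec:
            spec["calcium"] = CalciumTransient(**spec["calcium"])
        if "A" in spec:
            spec["A"] = tuple(spec["A"])
        if "alpha_rate" in spec:
            spec["alpha_rate"] = tuple(spec["alpha_rate"])
        out["active"] = ActiveParams(**spec)
    out.update(raw)
    return out
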