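"""State snapshot I/O: hierarchical HDF5 container plus CSV agent export."""

from __future__ import annotations

import pandas as pd

from .geometry import (LAYER_NAMES, AgentPopulation, ECMField,
                       VesselCrossSection)

__all__ = ["write_snapshot", "read_snapshot_agents", "agents_frame"]


def agents_frame(pop: AgentPopulation) -> pd.DataFrame:
    """Agent table (id, x, y, layer) as a DataFrame."""
    return pd.DataFrame({
        "id": pop.ids,
        "x": pop.pos[:, 0],
        "y": pop.pos[:, 1],
        "layer": [LAYER_NAMES.get(int(l), str(l)) for l in pop.layer],
    })


def write_snapshot(path: str, section: VesselCrossSection,
                   pop: AgentPopulation, ecm: ECMField, t_hours: float,
                   fields=None) -> None:
    """Write one saved time into a single hierarchical container file."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["t_hours"] = float(t_hours)
        f.attrs["h"] = section.grid.h
        f.attrs["origin"] = section.grid.origin
        ag = f.create_group("agents")
        ag.create_dataset("id", data=pop.ids)
        ag.create_dataset("xy", data=pop.pos)
        ag.create_dataset("layer", data=pop.layer)
        ag.create_dataset("mitosis_clock", data=pop.mitosis_clock)
        ag.create_dataset("ecm_clock", data=pop.ecm_clock)
        f.create_dataset("ecm_density", data=ecm.density)
        f.create_dataset("region_mask", data=section.region_mask)
        mg = f.create_group("membranes")
        for name, m in zip(("lumen_wall", "iel", "external_wall"),
                           section.membranes()):
            g = mg.create_group(name)
            g.create_dataset("points", data=m.points)
            g.create_dataset("rest_lengths", data=m.rest_lengths)
            g.attrs["stiffness"] = m.stiffness
        if fields is not None:
            fg = f.create_group("fields")
            fg.create_dataset("axial_velocity", data=fields.axial_velocity)
            fg.create_dataset("sigma", data=fields.sigma)
            fg.create_dataset("G", data=fields.G)
            fg.create_dataset("tau_wall", data=fields.tau_wall)


def read_snapshot_agents(path: str) -> pd.DataFrame:
    import h5py

    with h5py.File(path, "r") as f:
        return pd.DataFrame({
            "id": f["agents/id"][:],
            "x": f["agents/xy"][:, 0],
            "y": f["agents/xy"][:, 1],
            "layer": f["agents/layer"][:],
        })
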