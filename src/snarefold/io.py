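"""Reading and writing the package's plain-text formats.

Constructs and trap/membrane parameters travel as TOML; trajectories and
FECs as tab-separated tables; fit results as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .membrane import MembraneModel
from .polymer import PolymerSegment
from .tether import ConstructModel, FoldingState, TrapSystem


def load_construct(path) -> tuple[ConstructModel, TrapSystem]:
    """Read a construct + trap configuration from a TOML file.

    Expected layout::

        [handle]
        contour_nm = 768.4
        persistence_nm = 40.0

        [traps]
        stiffness_pn_per_nm = 0.1
        pull_speed_nm_per_s = 10.0

        [[states]]
        name = "folded"
        unfolded_contour_nm = 3.65
        structured_extension_nm = 2.0
        folding_energy_kbt = -36.7
        zipper_position_aa = 36
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    handle = PolymerSegment(
        cfg["handle"]["contour_nm"], cfg["handle"]["persistence_nm"]
    )
    traps = TrapSystem(
        effective_stiffness=cfg.get("traps", {}).get("stiffness_pn_per_nm", 0.1),
        pull_speed=cfg.get("traps", {}).get("pull_speed_nm_per_s", 10.0),
    )
    states = tuple(
        FoldingState(
            name=s["name"],
            unfolded_contour=s["unfolded_contour_nm"],
            structured_extension=s["structured_extension_nm"],
            folding_energy=s.get("folding_energy_kbt", 0.0),
            zipper_position=s.get("zipper_position_aa"),
        )
        for s in sorted(cfg["states"], key=lambda s: s["unfolded_contour_nm"])
    )
    construct = ConstructModel(
        states=states,
        dna_handle=handle,
        peptide_persistence=cfg.get("peptide", {}).get("persistence_nm", 0.6),
    )
    return construct, traps


def dump_construct(construct: ConstructModel, traps: TrapSystem, path) -> None:
    """Write a construct + trap configuration as TOML."""
    lines = [
        "[handle]",
        f"contour_nm = {construct.dna_handle.contour_length}",
        f"persistence_nm = {construct.dna_handle.persistence_length}",
        "",
        "[peptide]",
        f"persistence_nm = {construct.peptide_persistence}",
        "",
        "[traps]",
        f"stiffness_pn_per_nm = {traps.effective_stiffness}",
        f"pull_speed_nm_per_s = {traps.pull_speed}",
    ]
    for s in construct.states:
        lines += [
            "",
            "[[states]]",
            f'name = "{s.name}"',
            f"unfolded_contour_nm = {s.unfolded_contour}",
            f"structured_extension_nm = {s.structured_extension}",
            f"folding_energy_kbt = {s.folding_energy}",
        ]
        if s.zipper_position is not None:
            lines.append(f"zipper_position_aa = {s.zipper_position}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_membrane(path) -> MembraneModel:
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    m = cfg.get("membrane", cfg)
    return MembraneModel(
        em=m.get("em_kbt", 50.0),
        alpha=m.get("alpha", 0.5),
        d1=m.get("d1_nm", 2.5),
        d2=m.get("d2_nm", 6.0),
        dc=m.get("dc_nm", 1.0),
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="list")
        return super().default(obj)


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")
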