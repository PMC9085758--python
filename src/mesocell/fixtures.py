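"""Synthetic layout fixtures: raster + matching config generators.

These reproduce the schematic geometries of the bundled model setups at a
configurable grid size: a well-mixed single compartment, a storage region
with a diffusion barrier and passages, a 1 um^2 apical membrane patch,
and the full cell section with four basolateral influx nodes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from mesocell.models import CompartmentParams, make_storage_space

__all__ = ["generate_fixture", "FIXTURE_KINDS", "COLORS"]

COLORS = {
    "cytosol": (220, 220, 220),
    "storage-boundary": (120, 120, 200),
    "storage": (60, 60, 160),
    "exterior": (255, 255, 255),
    "patch": (200, 160, 160),
}

FIXTURE_KINDS = ("well_mixed", "storage_region", "apical_patch", "full_cell")


def _save(ids: np.ndarray, regions: list[str], path: Path) -> None:
    rgb = np.zeros((*ids.shape, 3), np.uint8)
    for k, name in enumerate(regions):
        rgb[ids == k] = COLORS[name]
    Image.fromarray(rgb, "RGB").save(path)


def generate_fixture(kind: str, out_dir: str | Path, n: int = 30,
                     passages: int = 2, permeability: float = 0.01,
                     seed: int = 1) -> dict[str, Path]:
    """Emit a PNG layout plus a matching YAML config; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    png = out / f"{kind}.png"
    cfg_path = out / f"{kind}.yaml"

    if kind == "well_mixed":
        _save(np.zeros((1, 1), int), ["cytosol"], png)
        cfg = {"model": "phospho", "duration": 300.0, "seed": seed,
               "params": {}}
    elif kind == "storage_region":
        p = CompartmentParams(n=n, permeability=permeability, ring=True,
                              passages=passages)
        space = make_storage_space(p)
        _save(space.region_ids,
              ["cytosol", "storage-boundary", "storage"], png)
        cfg = {"model": "compartment", "duration": 300.0, "seed": seed,
               "params": {"n": n, "permeability": permeability,
                          "ring": True, "passages": passages}}
    elif kind == "apical_patch":
        ids = np.zeros((2, 100), int)
        ids[0, :] = 1
        _save(ids, ["patch", "exterior"], png)
        cfg = {"model": "endocytosis", "duration": 300.0, "seed": seed,
               "params": {}}
    elif kind == "full_cell":
        ids = np.zeros((12, 12), int)
        ids[0, :] = 3
        ids[7:11, 4:8] = 1
        ids[8:10, 5:7] = 2
        _save(ids, ["cytosol", "storage-boundary", "storage", "exterior"],
              png)
        # four cAMP influx grid points on the basolateral edge
        cfg = {"model": "full_activation", "duration": 180.0, "seed": seed,
               "params": {"n": 12}}
    else:
        raise ValueError(
            f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")

    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return {"raster": png, "config": cfg_path}
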