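"""Initial membrane geometries.

Circular rest shapes only: the circular 2D cross-section is the most extreme
shearing orientation of a red cell in a narrow channel and the configuration
the model is calibrated for.  The channel packing places ``n_cells`` equal
circles in a staggered periodic arrangement whose radius realizes the target
2D hematocrit (area fraction) exactly.
"""

from __future__ import annotations

import math

import numpy as np

from .membrane import MembraneMesh

__all__ = ["channel_packing", "single_cell"]


def single_cell(
    center: tuple[float, float], radius: float, n_nodes: int = 80
) -> MembraneMesh:
    """One circular cell (um units)."""
    return MembraneMesh.circle(center, radius, n_nodes)


def channel_packing(
    n_cells: int = 12,
    hematocrit: float = 0.38,
    length: float = 80.0,
    width: float = 20.0,
    n_nodes: int = 80,
    seed: int = 0,
    jitter: float = 0.05,
) -> list[MembraneMesh]:
    """Periodic staggered packing of circular cells at a target hematocrit.

    The cell radius is set from the area fraction,
    r = sqrt(hct * L * H / (n pi)); cells are laid out in rows (two rows of
    six for the default twelve), the second row offset by half the x
    spacing.  A small seeded positional jitter (``jitter`` um RMS) breaks
    the perfect mirror symmetry of the packing so the flow develops within
    a short simulated window; jitter never moves cells into walls or each
    other.
    """
    if not 0 < hematocrit < 0.9:
        raise ValueError("hematocrit must be in (0, 0.9)")
    radius = math.sqrt(hematocrit * length * width / (n_cells * math.pi))
    rows = 2 if n_cells % 2 == 0 and n_cells >= 6 else 1
    per_row = n_cells // rows
    dx = length / per_row
    if 2 * radius >= min(dx, width / rows):
        raise ValueError("cells do not fit the requested packing")
    rng = np.random.default_rng(seed)
    gap_wall = width / (2 * rows) - radius  # clearance to wall / row midline
    meshes = []
    for row in range(rows):
        yc = width * (2 * row + 1) / (2 * rows)
        for i in range(per_row):
            xc = (i + 0.5 + 0.5 * row) * dx
            jx, jy = rng.normal(0.0, jitter, size=2)
            cap = min(0.4 * gap_wall, 0.2 * (dx - 2 * radius))
            jx = float(np.clip(jx, -cap, cap))
            jy = float(np.clip(jy, -cap, cap))
            meshes.append(
                MembraneMesh.circle(((xc + jx) % length, yc + jy), radius, n_nodes)
            )
    return meshes
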