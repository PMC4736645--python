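"""Neighbour tables for the Moore (k=8) lattice.

Tables are flat-indexed (row-major, ``site = r * width + c``) and packed:
``nbr[s, :n_nbr[s]]`` are the valid neighbour indices of ``s``.  Under
toroidal boundaries every node has exactly 8 neighbours; under no-flux
boundaries edge and corner nodes have 5 and 3.  The ``absorbing`` mask
marks the one-node boundary ring used by the strip assays (empty under
toroidal boundaries).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: Fixed Moore-neighbourhood offset order (row, col).
MOORE_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@lru_cache(maxsize=32)
def neighbor_table(height: int, width: int, boundary: str):
    """Return ``(nbr, n_nbr, absorbing)`` flat arrays for the lattice.

    ``nbr``: int32 (N, 8) packed neighbour indices (-1 padding);
    ``n_nbr``: int32 (N,) valid neighbour counts;
    ``absorbing``: bool (N,) boundary-ring mask (all False if toroidal).
    """
    n = height * width
    nbr = np.full((n, 8), -1, dtype=np.int32)
    n_nbr = np.zeros(n, dtype=np.int32)
    absorbing = np.zeros(n, dtype=bool)
    toroidal = boundary == "toroidal"
    for r in range(height):
        for c in range(width):
            s = r * width + c
            k = 0
            for dr, dc in MOORE_OFFSETS:
                rr, cc = r + dr, c + dc
                if toroidal:
                    rr %= height
                    cc %= width
                elif not (0 <= rr < height and 0 <= cc < width):
                    continue
                nbr[s, k] = rr * width + cc
                k += 1
            n_nbr[s] = k
            if not toroidal and (r in (0, height - 1) or c in (0, width - 1)):
                absorbing[s] = True
    nbr.setflags(write=False)
    n_nbr.setflags(write=False)
    absorbing.setflags(write=False)
    return nbr, n_nbr, absorbing


@lru_cache(maxsize=100_000)
def neighbor_sites_rc(height: int, width: int, boundary: str, site: tuple[int, int]):
    """Neighbours of ``site=(row, col)`` as a tuple of (row, col) pairs."""
    r, c = site
    if not (0 <= r < height and 0 <= c < width):
        raise IndexError(f"site {site!r} outside {height}x{width} lattice")
    nbr, n_nbr, _ = neighbor_table(height, width, boundary)
    s = r * width + c
    return tuple((int(j) // width, int(j) % width) for j in nbr[s, : n_nbr[s]])
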