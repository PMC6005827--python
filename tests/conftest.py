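"""Shared fixtures: phantom-based geometry setups and one converged
Poiseuille benchmark reused by several test modules (it is the expensive
session fixture; everything else is cheap)."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

import hemovox as hv
from hemovox.benchmarks import poiseuille_tube_benchmark


@pytest.fixture(scope="session")
def poiseuille():
    """Converged steady Poiseuille run in a voxelized tube, R = 10 voxels."""
    return poiseuille_tube_benchmark()


@pytest.fixture(scope="session")
def tube_setup():
    """Small straight-tube phantom with the full geometry chain prepared."""
    vol, truth = hv.straight_tube_phantom(
        dims=(25, 25, 24), spacing=(0.25,) * 3, radius=2.0, wall_width=0.5
    )
    lumen = hv.region_grow(vol, (12, 12, 12), 500.0)
    patches = hv.identify_openings(lumen, vol.spacing, "z_min")
    ls = hv.smooth_levelset(hv.build_levelset(vol, 500.0))
    inflow_patch = next(p for p in patches if p.role == "inflow")
    frame = hv.inplane_radius(
        hv.vessel_centerline(lumen, inflow_patch, vol.spacing), vol.spacing
    )
    return dict(
        volume=vol, truth=truth, lumen=lumen, patches=patches,
        levelset=ls, frame=frame,
    )


def bfs_flood_fill(intensity, seed, threshold, gradient_cap=None):
    """Reference region growing: queue-based breadth-first search, one voxel
    at a time (independent of the vectorized frontier implementation)."""
    I = np.asarray(intensity, dtype=float)
    dims = I.shape
    seen = np.zeros(dims, dtype=bool)
    if not I[seed] > threshold:
        raise ValueError("seed fails threshold")
    seen[seed] = True
    q = deque([seed])
    while q:
        cur = q.popleft()
        for ax in range(3):
            for d in (-1, 1):
                nb = list(cur)
                nb[ax] += d
                if nb[ax] < 0 or nb[ax] >= dims[ax]:
                    continue
                nb = tuple(nb)
                if seen[nb] or not I[nb] > threshold:
                    continue
                if gradient_cap is not None and abs(I[nb] - I[cur]) >= gradient_cap:
                    continue
                seen[nb] = True
                q.append(nb)
    return seen
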