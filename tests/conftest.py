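"""Shared fixtures: small geometric fixtures and cached simulation runs."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from atriamap import geometry as geo
from atriamap import membrane, monodomain


@pytest.fixture(scope="session")
def sphere_surface() -> geo.TriSurface:
    """Closed icosphere, radius 20 mm, N = 642 nodes."""
    ico = trimesh.creation.icosphere(3, radius=20.0)
    return geo.TriSurface(np.asarray(ico.vertices),
                          np.asarray(ico.faces, dtype=np.int64))


@pytest.fixture(scope="session")
def coarse_sphere_surface() -> geo.TriSurface:
    ico = trimesh.creation.icosphere(2, radius=20.0)
    return geo.TriSurface(np.asarray(ico.vertices),
                          np.asarray(ico.faces, dtype=np.int64))


@pytest.fixture(scope="session")
def atrium() -> geo.TriSurface:
    """Default synthetic atrium (holes cut, labeled)."""
    return geo.make_synthetic_atrium(seed=1)


@pytest.fixture(scope="session")
def strip():
    """Thin strip lattice with longitudinal fibers plus a recorded beat.

    One steady-state paced beat at CL 600 ms with the surrogate membrane;
    used by conduction-velocity, electrogram-morphology and transmembrane-
    current tests.
    """
    lat = geo.bar_lattice((160, 8, 7), h=0.25)
    fib = geo.FiberField(np.tile([1.0, 0.0, 0.0], (lat.n_voxels, 1)))
    model = membrane.get_model("surrogate")
    site = np.where(lat.ijk[:, 0] < 3)[0]
    stim = monodomain.StimulusProtocol(site=site, cycle_length=600.0,
                                       max_beats=4)
    rec = monodomain.run_monodomain(lat, fib, model, None, stim,
                                    output_dt=0.5)
    return lat, fib, rec


def strip_activation_times(lat, rec):
    """Upstroke times along the strip midline (from Vm, not electrograms)."""
    ny = lat.ijk[:, 1].max() + 1
    nz = lat.ijk[:, 2].max() + 1
    mid = np.where((lat.ijk[:, 1] == ny // 2) & (lat.ijk[:, 2] == nz // 2))[0]
    x = lat.centers[mid, 0]
    ta = rec.times[np.argmax(np.diff(rec.vm[:, mid], axis=0), axis=0)]
    return x, ta


def conduction_velocity(lat, rec, lo=10.0, hi=30.0) -> float:
    x, ta = strip_activation_times(lat, rec)
    sel = (x > lo) & (x < hi)
    return float(np.polyfit(ta[sel], x[sel], 1)[0])
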