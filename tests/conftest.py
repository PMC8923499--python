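import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import settings

from swimtel.hydrofield import VelocityField
from swimtel.synthgen import ScenarioConfig, gen_array, gen_field

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_uniform_field(u=0.5, v=0.0, length=400.0, width=50.0, depth=4.0,
                       duration=7200.0):
    """Spatially and temporally uniform field on a coarse grid."""
    x = np.linspace(0, length, 21)
    y = np.linspace(0, width, 11)
    z = np.linspace(-depth, 0, 9)
    t = np.array([0.0, duration])
    shape = (t.size, z.size, y.size, x.size)
    ds = xr.Dataset(
        {
            "u": (("t", "z", "y", "x"), np.full(shape, float(u))),
            "v": (("t", "z", "y", "x"), np.full(shape, float(v))),
            "bed": (("y", "x"), np.full((y.size, x.size), -depth)),
            "surface": (("t", "y", "x"), np.zeros((t.size, y.size, x.size))),
        },
        coords={"t": t, "z": z, "y": y, "x": x},
    )
    return VelocityField(ds)


def make_profile_field(profile, length=200.0, width=50.0, depth=4.0,
                       duration=7200.0, nz=41):
    """Field u = profile(z), v = 0 (z from bed to surface, positive up)."""
    x = np.linspace(0, length, 11)
    y = np.linspace(0, width, 11)
    z = np.linspace(-depth, 0, nz)
    t = np.array([0.0, duration])
    u1d = profile(z)
    u = np.broadcast_to(
        u1d[None, :, None, None], (t.size, z.size, y.size, x.size)
    ).copy()
    ds = xr.Dataset(
        {
            "u": (("t", "z", "y", "x"), u),
            "v": (("t", "z", "y", "x"), np.zeros_like(u)),
            "bed": (("y", "x"), np.full((y.size, x.size), -depth)),
            "surface": (("t", "y", "x"), np.zeros((t.size, y.size, x.size))),
        },
        coords={"t": t, "z": z, "y": y, "x": x},
    )
    return VelocityField(ds)


def make_planar_field(ufunc, vfunc, extent=200.0, depth=4.0, duration=7200.0):
    """Depth-uniform field with u = ufunc(x, y), v = vfunc(x, y)."""
    x = np.linspace(-extent, extent, 81)
    y = np.linspace(-extent, extent, 81)
    z = np.linspace(-depth, 0, 5)
    t = np.array([0.0, duration])
    X, Y = np.meshgrid(x, y, indexing="xy")  # (y, x)
    u2 = ufunc(X, Y)
    v2 = vfunc(X, Y)
    u = np.broadcast_to(u2[None, None], (t.size, z.size, y.size, x.size)).copy()
    v = np.broadcast_to(v2[None, None], (t.size, z.size, y.size, x.size)).copy()
    ds = xr.Dataset(
        {
            "u": (("t", "z", "y", "x"), u),
            "v": (("t", "z", "y", "x"), v),
            "bed": (("y", "x"), np.full((y.size, x.size), -depth)),
            "surface": (("t", "y", "x"), np.zeros((t.size, y.size, x.size))),
        },
        coords={"t": t, "z": z, "y": y, "x": x},
    )
    return VelocityField(ds)


@pytest.fixture(scope="session")
def small_array():
    cfg = ScenarioConfig(seed=0, n_receivers=5)
    return gen_array(cfg)


@pytest.fixture(scope="session")
def triangle_array():
    """Equilateral triangle of receivers at equal depth."""
    s = 100.0
    pts = np.array(
        [[0.0, 0.0], [s, 0.0], [s / 2, s * np.sqrt(3) / 2]]
    )
    return pd.DataFrame(
        {
            "id": ["A", "B", "C"],
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": [-3.0, -3.0, -3.0],
            "role": ["reference", "cabled", "autonomous"],
        }
    )


@pytest.fixture(scope="session")
def uniform_field():
    return make_uniform_field()
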