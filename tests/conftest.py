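import numpy as np
import pytest

from anatomap.geometry import make_sheet, offset_layer
from anatomap.layers import SurfaceLayer


@pytest.fixture
def unit_sheet():
    """1 mm x 1 mm flat sheet in z=0 with an isometric chart."""
    return make_sheet(1.0, 1.0, 4, 4, name="unit_sheet")


@pytest.fixture
def parallel_sheets():
    """Two parallel unit sheets separated by 0.5 mm along z."""
    a = make_sheet(1.0, 1.0, 4, 4, name="plane_a")
    b = offset_layer(a, 0.5, name="plane_b")
    return a, b


def sphere_band(radius: float, name: str, n_lon: int = 48, n_lat: int = 24) -> SurfaceLayer:
    """Latitude band of a sphere (+-75 deg), quads, longitude/latitude chart.

    Poles are excluded so every face is a clean quad; the chart is
    (longitude fraction, latitude fraction).  Used for radial-projection
    oracles: interpolated vertex normals of a sphere are radial.
    """
    lat = np.linspace(-np.radians(75), np.radians(75), n_lat + 1)
    lon = np.linspace(0.0, 2 * np.pi * 0.9, n_lon + 1)  # open band, injective chart
    LO, LA = np.meshgrid(lon, lat)
    verts = radius * np.stack(
        [np.cos(LA) * np.cos(LO), np.cos(LA) * np.sin(LO), np.sin(LA)], axis=-1
    ).reshape(-1, 3)
    faces = []
    for j in range(n_lat):
        for i in range(n_lon):
            a = j * (n_lon + 1) + i
            faces.append((a, a + 1, a + n_lon + 2, a + n_lon + 1))
    uv = np.stack(
        [(LO / lon[-1]).ravel(), ((LA - lat[0]) / (lat[-1] - lat[0])).ravel()], axis=1
    )
    uv_corners = [uv[list(f)] for f in faces]
    return SurfaceLayer(name=name, vertices=verts, faces=faces, uv_corners=uv_corners)


@pytest.fixture
def spheres():
    return sphere_band(1.0, "sphere_r1"), sphere_band(2.0, "sphere_r2")
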