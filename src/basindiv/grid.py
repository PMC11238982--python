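"""Regular longitude/latitude grids used throughout the pipeline.

Cells are half-open ``[x, x + size) x [y, y + size)`` boxes identified by the
coordinates of their south-west corner.  Longitudes are always wrapped into
``[-180, 180)`` before any cell arithmetic so the antimeridian is handled
uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0


def wrap_lon(lon):
    """Wrap longitudes into ``[-180, 180)``."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def great_circle_km(lon1, lat1, lon2, lat2, radius=EARTH_RADIUS_KM):
    """Haversine great-circle distance in kilometres (broadcasting)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid over a rectangular window.

    Parameters
    ----------
    cell_size : float
        Cell edge in degrees; must divide 360 evenly.
    lon_min, lon_max, lat_min, lat_max : float
        Bounds of the gridded window.  ``lon_min`` may exceed ``lon_max``
        numerically only after wrapping; the window itself is treated as a
        plain rectangle in wrapped coordinates.
    """

    cell_size: float = 1.0
    lon_min: float = -180.0
    lon_max: float = 180.0
    lat_min: float = -90.0
    lat_max: float = 90.0

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        n = 360.0 / self.cell_size
        if abs(n - round(n)) > 1e-9:
            raise ValueError("cell_size must divide 360 evenly")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("empty grid bounds")

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size))

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size))

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    def cell_of(self, lon, lat):
        """SW corner of the cell containing each point (vectorised).

        Longitudes are wrapped into ``[-180, 180)`` first; a latitude of
        exactly +90 is assigned to the topmost band.
        """
        lon = wrap_lon(lon)
        lat = np.clip(np.asarray(lat, dtype=float), -90.0, np.nextafter(90.0, -np.inf))
        x = np.floor(lon / self.cell_size) * self.cell_size
        y = np.floor(lat / self.cell_size) * self.cell_size
        return x, y

    def cell_corners(self):
        """SW corners of every cell as two 1-D arrays (lon-major order)."""
        xs = self.lon_min + self.cell_size * np.arange(self.n_lon)
        ys = self.lat_min + self.cell_size * np.arange(self.n_lat)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return gx.ravel(), gy.ravel()

    def cell_centers(self):
        gx, gy = self.cell_corners()
        return gx + self.cell_size / 2.0, gy + self.cell_size / 2.0


def cell_id(x, y) -> str:
    """Canonical string id for a cell's SW corner."""
    return f"{x:g}_{y:g}"


def parse_cell_id(cid: str):
    x, y = cid.split("_")
    return float(x), float(y)


def cell_ids(xs, ys):
    return [cell_id(x, y) for x, y in zip(np.asarray(xs).ravel(), np.asarray(ys).ravel())]
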