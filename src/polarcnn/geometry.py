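"""Bullseye geometry: coronary territories and the segment grid.

The polar map (bullseye) projects the left-ventricular myocardium onto a
disc: apex at the center, basal segments at the rim. The three coronary
territories occupy fixed 120-degree sectors in the conventional display
orientation (anterior up, inferior down, lateral right):

* LAD  — anterior/septal, angular span [30, 150) deg
* LCx  — lateral,         angular span [-90, 30) deg
* RCA  — inferior,        angular span [150, 270) deg

Angles are measured counter-clockwise from image east with the y axis
pointing up (i.e. 90 deg is the top of the image). The apex is a central
disc of radius 0.25 (fraction of the bullseye radius), subdivided into
quadrant segments; the annulus outside it is divided into ``n_rings``
radial rings x ``n_sectors`` angular sectors. Segment ids index apex
segments first, then ring-major outer segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TERRITORIES = ("LAD", "LCx", "RCA")


def _wrap_deg(theta):
    """Wrap angles into [-90, 270), the union of the territory spans."""
    return (np.asarray(theta, dtype=float) + 90.0) % 360.0 - 90.0


@dataclass(frozen=True)
class TerritoryLayout:
    """Angular/radial layout of the bullseye segment grid."""

    apex_radius: float = 0.25
    n_rings: int = 3
    n_sectors: int = 12
    n_apex_sectors: int = 4
    territory_spans: dict = field(
        default_factory=lambda: {
            "LCx": (-90.0, 30.0),
            "LAD": (30.0, 150.0),
            "RCA": (150.0, 270.0),
        }
    )

    def __post_init__(self):
        if not 0.0 < self.apex_radius < 1.0:
            raise ValueError("apex_radius must lie strictly inside (0, 1)")
        spans = sorted(self.territory_spans.values())
        total = sum(hi - lo for lo, hi in spans)
        if not np.isclose(total, 360.0):
            raise ValueError("territory spans must partition [0, 360)")

    @property
    def sector_width(self) -> float:
        return 360.0 / self.n_sectors

    @property
    def n_segments(self) -> int:
        return self.n_apex_sectors + self.n_rings * self.n_sectors

    @property
    def ring_edges(self) -> np.ndarray:
        """Radial ring boundaries over (apex_radius, 1]."""
        return self.apex_radius + (1.0 - self.apex_radius) * np.arange(
            self.n_rings + 1
        ) / self.n_rings

    def sector_center(self, sector: int) -> float:
        return -90.0 + (sector + 0.5) * self.sector_width

    def territory_of_angle(self, theta_deg: float) -> str:
        th = float(_wrap_deg(theta_deg))
        for name, (lo, hi) in self.territory_spans.items():
            if lo <= th < hi:
                return name
        raise ValueError(f"angle {theta_deg} not covered by territory spans")

    def segment_territories(self) -> list[str]:
        """Territory name per segment id (apex segments map to 'apex')."""
        terr = ["apex"] * self.n_apex_sectors
        for _ in range(self.n_rings):
            for s in range(self.n_sectors):
                terr.append(self.territory_of_angle(self.sector_center(s)))
        return terr

    def segment_of(self, r_frac, theta_deg):
        """Vectorized (radius fraction, angle deg) -> segment id; -1 outside."""
        r = np.asarray(r_frac, dtype=float)
        th = _wrap_deg(theta_deg)
        seg = np.full(r.shape, -1, dtype=int)
        inside = r <= 1.0
        apex = inside & (r <= self.apex_radius)
        apex_sector = (
            np.floor((th + 90.0) / (360.0 / self.n_apex_sectors)).astype(int)
            % self.n_apex_sectors
        )
        seg[apex] = apex_sector[apex]
        outer = inside & ~apex
        ring = np.minimum(
            (
                (r - self.apex_radius)
                / (1.0 - self.apex_radius)
                * self.n_rings
            ).astype(int),
            self.n_rings - 1,
        )
        sector = np.floor((th + 90.0) / self.sector_width).astype(int) % self.n_sectors
        seg[outer] = (
            self.n_apex_sectors + ring[outer] * self.n_sectors + sector[outer]
        )
        return seg

    def segment_centers(self) -> np.ndarray:
        """(n_segments, 2) array of (radius fraction, angle deg) centers."""
        centers = []
        for a in range(self.n_apex_sectors):
            centers.append(
                (
                    self.apex_radius / 2.0,
                    -90.0 + (a + 0.5) * 360.0 / self.n_apex_sectors,
                )
            )
        edges = self.ring_edges
        for ring in range(self.n_rings):
            r_mid = (edges[ring] + edges[ring + 1]) / 2.0
            for s in range(self.n_sectors):
                centers.append((r_mid, self.sector_center(s)))
        return np.array(centers)

    def adjacency(self) -> list[set]:
        """Neighbor sets per segment (angular, radial and apex contacts)."""
        nbrs = [set() for _ in range(self.n_segments)]

        def link(a, b):
            nbrs[a].add(b)
            nbrs[b].add(a)

        na = self.n_apex_sectors
        for a in range(na):
            link(a, (a + 1) % na)
        for ring in range(self.n_rings):
            for s in range(self.n_sectors):
                sid = na + ring * self.n_sectors + s
                link(sid, na + ring * self.n_sectors + (s + 1) % self.n_sectors)
                if ring + 1 < self.n_rings:
                    link(sid, sid + self.n_sectors)
        # apex quadrants touch the sectors of the innermost ring they overlap
        for s in range(self.n_sectors):
            apex_sector = int(
                (self.sector_center(s) + 90.0) // (360.0 / na)
            ) % na
            link(apex_sector, na + s)
        return nbrs


def polar_coordinates(size: int, radius_px: float | None = None):
    """Per-pixel (radius fraction, angle deg) for a centered bullseye.

    Angle follows the display convention (CCW from east, y up); rows of
    the image increase downward.
    """
    if radius_px is None:
        radius_px = 0.45 * size
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dx = xx - c
    dy = c - yy  # flip: image rows grow downward
    r = np.hypot(dx, dy) / radius_px
    theta = np.degrees(np.arctan2(dy, dx))
    return r, theta
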