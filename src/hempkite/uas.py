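"""Per-plant trait extraction from reconstructed aerial products.

The pipeline mirrors a standard UAS phenotyping workflow: the RGB
orthoimage is converted to an excess-green map, binarized with Otsu's
threshold, and connected components give plant centers; per plant, the
point cloud is cropped to a fixed bounding box, a RANSAC ground plane
separates soil from canopy, and canopy height / projected area / volume
are measured; vegetation indices are averaged over a circular region of
the five-band multispectral orthoimage at each plant center.

Rasters are numpy arrays with a GDAL-style geotransform
(x0, dx, 0, y0, 0, dy); point clouds are (N, 3) or (N, 6) XYZ(+RGB)
arrays, stored on disk as plain XYZ text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "Scene",
    "PlantROI",
    "CanopyMetrics",
    "excess_green",
    "otsu_threshold",
    "locate_plants",
    "ransac_ground_plane",
    "canopy_metrics",
    "vegetation_indices",
    "read_xyz",
    "write_xyz",
]

#: Field-layout constants: per-plant bounding box (m) and spectral ROI radius (m).
BOX_ACROSS_ROW = 1.83
BOX_WITHIN_ROW = 1.22
ROI_RADIUS = 0.28

MSP_BANDS = ("blue", "green", "red", "rededge", "nir")


@dataclass
class Scene:
    """Co-registered aerial products for one flight.

    rgb : (H, W, 3) reflectance-like array.
    msp : (H, W, 5) array, bands ordered blue, green, red, red-edge, NIR.
    cloud : (N, 3) or (N, 6) XYZ(+RGB) points, same ground frame (m).
    geotransform : GDAL 6-tuple (x0, dx, 0, y0, 0, dy); dy typically < 0.
    """

    rgb: np.ndarray
    msp: np.ndarray
    cloud: np.ndarray
    geotransform: tuple

    def pixel_to_ground(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        x0, dx, _, y0, _, dy = self.geotransform
        cols = np.asarray(cols, dtype=float)
        rows = np.asarray(rows, dtype=float)
        return x0 + (cols + 0.5) * dx, y0 + (rows + 0.5) * dy

    def ground_to_pixel(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x0, dx, _, y0, _, dy = self.geotransform
        col = (np.asarray(x, dtype=float) - x0) / dx - 0.5
        row = (np.asarray(y, dtype=float) - y0) / dy - 0.5
        return row, col


@dataclass(frozen=True)
class PlantROI:
    """One plant's analysis region: a fixed box for the cloud crop and a
    circle for the spectral summary, both centered on the plant."""

    center: tuple[float, float]          # ground (x, y), m
    box: tuple[float, float] = (BOX_ACROSS_ROW, BOX_WITHIN_ROW)
    radius: float = ROI_RADIUS


@dataclass
class CanopyMetrics:
    """Canopy morphology from the classified point cloud."""

    height: float            # m above the ground plane (99th percentile)
    projected_area: float    # m² of occupied grid cells
    volume: float            # m³, Σ cell-max-height × cell area
    n_canopy_points: int
    plane: tuple[float, float, float, float]   # ax + by + cz + d = 0
    empty: bool = False


def excess_green(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel excess green index 2G − R − B of a 3-band image."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("rgb must be (H, W, 3)")
    return 2.0 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]


def otsu_threshold(img: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: the histogram level maximizing between-class
    variance over a 256-bin histogram of the observed range."""
    img = np.asarray(img, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("constant map has no threshold")
    return float(threshold_otsu(img, nbins=nbins))


def locate_plants(binary: np.ndarray, geotransform: tuple,
                  min_blob_px: int = 50) -> np.ndarray:
    """Plant centers (ground x, y) from an 8-connected component labeling
    of the binary vegetation map, sorted row-major by field position.

    Components below ``min_blob_px`` pixels are discarded.  Returns an
    (n, 2) array; empty (with a warning) when nothing is found.
    """
    binary = np.asarray(binary).astype(bool)
    lab = measure.label(binary, connectivity=2)
    props = measure.regionprops(lab)
    centers = []
    x0, dx, _, y0, _, dy = geotransform
    for p in props:
        if p.area < min_blob_px:
            continue
        r, c = p.centroid
        centers.append((x0 + (c + 0.5) * dx, y0 + (r + 0.5) * dy))
    if not centers:
        warnings.warn("no plant components found", stacklevel=2)
        return np.empty((0, 2))
    centers = np.array(centers)
    order = np.lexsort((centers[:, 0], -centers[:, 1] if dy < 0 else centers[:, 1]))
    return centers[order]


def ransac_ground_plane(cloud: np.ndarray, dist_thresh: float = 0.05,
                        iters: int = 500, seed: int | None = None
                        ) -> tuple[tuple, np.ndarray]:
    """Fit the ground plane by random sample consensus.

    Random 3-point samples propose planes; the plane with the most points
    within ``dist_thresh`` of it wins and is refit by least squares on its
    inliers.  Returns ``(plane, is_ground)`` where plane is (a, b, c, d)
    with unit normal (c ≥ 0) for ax + by + cz + d = 0 and ``is_ground`` is
    the boolean inlier mask; the remainder are canopy points.
    """
    pts = np.asarray(cloud, dtype=float)[:, :3]
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    best_count = -1
    best_normal, best_d = None, None
    for _ in range(iters):
        i = rng.choice(n, size=3, replace=False)
        p0, p1, p2 = pts[i]
        normal = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        normal = normal / norm
        d = -normal @ p0
        dist = np.abs(pts @ normal + d)
        count = int((dist <= dist_thresh).sum())
        if count > best_count:
            best_count, best_normal, best_d = count, normal, d
    if best_normal is None:
        raise ValueError("all sampled triplets were collinear")
    inliers = np.abs(pts @ best_normal + best_d) <= dist_thresh
    # least-squares refit on inliers (smallest singular vector of centered pts)
    P = pts[inliers]
    centroid = P.mean(axis=0)
    _, _, vt = np.linalg.svd(P - centroid, full_matrices=False)
    normal = vt[-1]
    if normal[2] < 0:
        normal = -normal
    d = -normal @ centroid
    is_ground = np.abs(pts @ normal + d) <= dist_thresh
    return (float(normal[0]), float(normal[1]), float(normal[2]), float(d)), is_ground


def _crop_box(cloud: np.ndarray, roi: PlantROI) -> np.ndarray:
    cx, cy = roi.center
    bx, by = roi.box
    pts = np.asarray(cloud, dtype=float)
    m = (
        (np.abs(pts[:, 0] - cx) <= bx / 2.0)
        & (np.abs(pts[:, 1] - cy) <= by / 2.0)
    )
    return pts[m]


def canopy_metrics(cloud: np.ndarray, plane: tuple, roi: PlantROI,
                   grid_res: float = 0.05,
                   height_percentile: float = 99.0) -> CanopyMetrics:
    """Canopy height, projected area, and volume for one plant.

    ``cloud`` should be the canopy-classified points (any extra columns
    are ignored); they are cropped to the ROI box.  Heights are signed
    distances above the ground plane; canopy height is their
    ``height_percentile`` percentile (99th by default, robust to stray
    points), projected area counts occupied cells of a ``grid_res`` grid,
    and volume sums cell-max height × cell area.
    """
    a, b, c, d = plane
    pts = _crop_box(np.asarray(cloud, dtype=float)[:, :3], roi)
    if pts.shape[0] == 0:
        return CanopyMetrics(0.0, 0.0, 0.0, 0, plane, empty=True)
    h = pts @ np.array([a, b, c]) + d            # signed distance (unit normal)
    h = np.maximum(h, 0.0)
    cx, cy = roi.center
    bx, by = roi.box
    ix = np.floor((pts[:, 0] - (cx - bx / 2)) / grid_res).astype(int)
    iy = np.floor((pts[:, 1] - (cy - by / 2)) / grid_res).astype(int)
    nx = int(np.ceil(bx / grid_res))
    ny = int(np.ceil(by / grid_res))
    ix = np.clip(ix, 0, nx - 1)
    iy = np.clip(iy, 0, ny - 1)
    cell = ix * ny + iy
    cell_max = np.zeros(nx * ny)
    np.maximum.at(cell_max, cell, h)
    occupied = np.zeros(nx * ny, dtype=bool)
    occupied[cell] = True
    area = float(occupied.sum()) * grid_res**2
    volume = float(cell_max[occupied].sum()) * grid_res**2
    return CanopyMetrics(
        height=float(np.percentile(h, height_percentile)),
        projected_area=area,
        volume=volume,
        n_canopy_points=int(pts.shape[0]),
        plane=plane,
    )


def _index_maps(msp: np.ndarray) -> dict[str, np.ndarray]:
    B, G, R, RE, NIR = (msp[..., i] for i in range(5))
    old = np.seterr(divide="ignore", invalid="ignore")
    try:
        out = {
            "NDVI": (NIR - R) / (NIR + R),
            "GNDVI": (NIR - G) / (NIR + G),
            "GCI": NIR / G - 1.0,
            "EVI": 2.5 * (NIR - R) / (NIR + 6.0 * R - 7.5 * B + 1.0),
            "OSAVI": (NIR - R) / (NIR + R + 0.16),
            "MSAVI2": (2.0 * NIR + 1.0
                       - np.sqrt(np.maximum((2.0 * NIR + 1.0) ** 2
                                            - 8.0 * (NIR - R), 0.0))) / 2.0,
            "MNLI": 1.5 * (NIR**2 - R) / (NIR**2 + R + 0.5),
        }
    finally:
        np.seterr(**old)
    return out


def vegetation_indices(msp: np.ndarray, geotransform: tuple,
                       center: tuple[float, float],
                       radius: float = ROI_RADIUS) -> dict[str, float]:
    """Mean of the seven vegetation indices over a circular ROI.

    Indices: NDVI, GNDVI, GCI, EVI, OSAVI, MSAVI2, MNLI, each computed
    per pixel then averaged over the circle; non-finite pixels (zero
    denominators) are excluded per index, their counts reported under
    ``n_dropped_<index>``.
    """
    msp = np.asarray(msp, dtype=float)
    if msp.ndim != 3 or msp.shape[2] != 5:
        raise ValueError("msp must be (H, W, 5)")
    H, W = msp.shape[:2]
    x0, dx, _, y0, _, dy = geotransform
    cols = np.arange(W)
    rows = np.arange(H)
    gx = x0 + (cols + 0.5) * dx
    gy = y0 + (rows + 0.5) * dy
    XX, YY = np.meshgrid(gx, gy)
    circle = (XX - center[0]) ** 2 + (YY - center[1]) ** 2 <= radius**2
    if not circle.any():
        raise ValueError("circular ROI falls outside the raster")
    out: dict[str, float] = {}
    for name, m in _index_maps(msp).items():
        vals = m[circle]
        finite = np.isfinite(vals)
        out[name] = float(vals[finite].mean()) if finite.any() else float("nan")
        out[f"n_dropped_{name}"] = int((~finite).sum())
    return out


def write_scene(scene: Scene, directory) -> None:
    """Persist a scene: rasters as TIFF, cloud as XYZ text, geotransform as
    JSON sidecar."""
    import json
    from pathlib import Path

    import tifffile

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / "rgb.tif", scene.rgb.astype(np.float32),
                     photometric="rgb")
    tifffile.imwrite(d / "msp.tif", scene.msp.astype(np.float32),
                     photometric="minisblack", planarconfig="contig")
    write_xyz(d / "cloud.xyz", scene.cloud)
    (d / "geotransform.json").write_text(json.dumps(list(scene.geotransform)))


def read_scene(directory) -> Scene:
    import json
    from pathlib import Path

    import tifffile

    d = Path(directory)
    return Scene(
        rgb=np.asarray(tifffile.imread(d / "rgb.tif"), dtype=float),
        msp=np.asarray(tifffile.imread(d / "msp.tif"), dtype=float),
        cloud=read_xyz(d / "cloud.xyz"),
        geotransform=tuple(json.loads((d / "geotransform.json").read_text())),
    )


def read_xyz(path) -> np.ndarray:
    """Read a whitespace-delimited XYZ(+RGB) text point cloud."""
    return np.loadtxt(path, ndmin=2)


def write_xyz(path, cloud: np.ndarray) -> None:
    np.savetxt(path, np.asarray(cloud, dtype=float), fmt="%.5f")
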