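"""Visual outputs from localisation tables.

Three renderings of a 3D localisation map are supported: density-weighted
Gaussian splatting (each localisation contributes unit mass spread over its
lateral precision), plain 2D histogramming, and constant-diameter point
clouds (every localisation a 30 nm sphere, the representation used for
close-up views).  A z-colour mode maps axial position linearly onto a
colormap across the axial capture range.  Rendering never mutates the input
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import add_spot
from .io import LocalizationTable

#: conventional channel colours: GLT-1 blue, bassoon magenta, Homer1 green
DEFAULT_CHANNEL_COLORS = {
    "GLT1": (0.0, 0.4, 1.0),
    "bassoon": (1.0, 0.0, 1.0),
    "Homer1": (0.0, 1.0, 0.0),
}


@dataclass
class RenderConfig:
    pixel_nm: float = 10.0
    mode: str = "gaussian"  # gaussian | histogram | pointcloud
    point_diameter_nm: float = 30.0
    z_range_nm: tuple[float, float] = (-1000.0, 1000.0)
    colormap: str = "viridis"
    channel_colors: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_COLORS))

    def __post_init__(self) -> None:
        if self.pixel_nm <= 0 or self.point_diameter_nm <= 0:
            raise ValueError("pixel_nm and point_diameter_nm must be positive")
        if self.mode not in ("gaussian", "histogram", "pointcloud"):
            raise ValueError(f"unknown render mode {self.mode!r}")


def _extent(table: LocalizationTable, cfg: RenderConfig) -> tuple[int, int]:
    if len(table) == 0:
        return 16, 16
    # pad by the splat kernel support so border spots keep their full mass
    pad = int(np.ceil(4.0 * float(table.df["sigma_xy_nm"].max()) / cfg.pixel_nm)) + 1
    nx = int(np.ceil(table.df["x_nm"].max() / cfg.pixel_nm)) + 1 + pad
    ny = int(np.ceil(table.df["y_nm"].max() / cfg.pixel_nm)) + 1 + pad
    return max(nx, 1), max(ny, 1)


def render_2d(
    table: LocalizationTable, cfg: RenderConfig | None = None
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """2D projections per channel plus a colour merge.

    Gaussian mode splats each localisation with sigma = its lateral
    precision, conserving total mass (= localisation count) for interior
    spots; histogram mode bins localisations into pixels.  Returns
    ({channel: image}, merged RGB).
    """
    cfg = cfg or RenderConfig()
    nx, ny = _extent(table, cfg)
    images: dict[str, np.ndarray] = {}
    for ch in table.channels:
        sub = table.df[table.df["channel"] == ch]
        img = np.zeros((ny, nx))
        if cfg.mode == "histogram":
            cols = (sub["x_nm"].to_numpy() / cfg.pixel_nm).astype(int)
            rows = (sub["y_nm"].to_numpy() / cfg.pixel_nm).astype(int)
            ok = (cols >= 0) & (cols < nx) & (rows >= 0) & (rows < ny)
            np.add.at(img, (rows[ok], cols[ok]), 1.0)
        else:
            for row in sub.itertuples(index=False):
                add_spot(
                    img,
                    row.x_nm / cfg.pixel_nm,
                    row.y_nm / cfg.pixel_nm,
                    max(row.sigma_xy_nm / cfg.pixel_nm, 0.3),
                    1.0,
                )
        images[ch] = img

    merged = np.zeros((ny, nx, 3))
    for ch, img in images.items():
        color = np.asarray(cfg.channel_colors.get(ch, (1.0, 1.0, 1.0)))
        peak = img.max()
        if peak > 0:
            merged += (img / peak)[:, :, None] * color[None, None, :]
    return images, np.clip(merged, 0.0, 1.0)


def render_z_colored(table: LocalizationTable, cfg: RenderConfig | None = None) -> np.ndarray:
    """Histogram-rendered image coloured by mean z over ``z_range_nm``."""
    import matplotlib

    cfg = cfg or RenderConfig(mode="histogram")
    nx, ny = _extent(table, cfg)
    density = np.zeros((ny, nx))
    zsum = np.zeros((ny, nx))
    df = table.df
    cols = (df["x_nm"].to_numpy() / cfg.pixel_nm).astype(int)
    rows = (df["y_nm"].to_numpy() / cfg.pixel_nm).astype(int)
    ok = (cols >= 0) & (cols < nx) & (rows >= 0) & (rows < ny)
    np.add.at(density, (rows[ok], cols[ok]), 1.0)
    np.add.at(zsum, (rows[ok], cols[ok]), df["z_nm"].to_numpy()[ok])
    z0, z1 = cfg.z_range_nm
    with np.errstate(invalid="ignore", divide="ignore"):
        zmean = np.where(density > 0, zsum / np.maximum(density, 1), z0)
    frac = np.clip((zmean - z0) / (z1 - z0), 0.0, 1.0)
    rgba = matplotlib.colormaps[cfg.colormap](frac)
    brightness = density / density.max() if density.max() > 0 else density
    return rgba[:, :, :3] * brightness[:, :, None]


def export_pointcloud(table: LocalizationTable, cfg: RenderConfig | None, path) -> None:
    """ASCII PLY point cloud: one vertex per localisation with a constant
    radius property (default diameter 30 nm) and per-channel colour."""
    cfg = cfg or RenderConfig(mode="pointcloud")
    df = table.df
    n = len(df)
    radius = cfg.point_diameter_nm / 2.0
    header = [
        "ply",
        "format ascii 1.0",
        f"comment radius_nm {radius:.6f}",
        f"element vertex {n}",
        "property float x",
        "property float y",
        "property float z",
        "property float radius",
        "property uchar red",
        "property uchar green",
        "property uchar blue",
        "end_header",
    ]
    lines = list(header)
    for row in df.itertuples(index=False):
        r, g, b = cfg.channel_colors.get(row.channel, (1.0, 1.0, 1.0))
        lines.append(
            f"{row.x_nm:.6f} {row.y_nm:.6f} {row.z_nm:.6f} {radius:.6f} "
            f"{int(r * 255)} {int(g * 255)} {int(b * 255)}"
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pointcloud(path) -> tuple[np.ndarray, float]:
    """Read back an exported PLY: (n, 3) centres and the sphere radius."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    n = next(int(ln.split()[-1]) for ln in lines if ln.startswith("element vertex"))
    start = lines.index("end_header") + 1
    data = np.array([[float(v) for v in ln.split()[:4]] for ln in lines[start : start + n]])
    data = data.reshape(n, 4) if n else np.zeros((0, 4))
    radius = data[0, 3] if n else float("nan")
    return data[:, :3], radius


def save_image_png(image: np.ndarray, path) -> None:
    """Save a 2D array or RGB image as PNG (no axes; 1 px per render pixel)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    plt.imsave(path, image, origin="lower", cmap=None if image.ndim == 3 else "magma")


def save_image_tiff(image: np.ndarray, path) -> None:
    """Save a rendering as 16-bit TIFF (scaled to the full dynamic range)."""
    import tifffile

    img = np.asarray(image, dtype=float)
    peak = img.max()
    scaled = (img / peak * 65535).astype(np.uint16) if peak > 0 else img.astype(np.uint16)
    tifffile.imwrite(path, scaled)
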