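"""Synthetic assay-data generators with exact ground truth.

Every input the quantification stack consumes can be produced here with a
known answer: confluent epithelial monolayer fields with nuclei, cell
boundaries and compartment-assigned puncta; 3D stacks of spherical plaques;
log-normal cytometry event tables; linear fluorogenic kinetics; and voltage
traces with a stimulation artifact followed by an EPSP at a set latency.

All generators are deterministic given their seed (bit-identical outputs on
repeated calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.segmentation import find_boundaries

from .image2d import EARLY_ENDOSOME, LYSOSOME, SURFACE, ImageSet

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Rendered intensity levels (arbitrary units).
_BG = 10.0
_NUCLEUS_LEVEL = 120.0
_CELL_BODY_LEVEL = 40.0
_RIM_LEVEL = 200.0
_PUNCTA_LEVEL = 150.0
_GFP_LEVEL = 80.0

#: Width of the cell-boundary rim band (px) where surface puncta live.
RIM_WIDTH_PX = 3.0


class PackingError(ValueError):
    """Raised when requested objects cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class MonolayerParams:
    """Parameters of a synthetic confluent-monolayer field."""

    field_shape: tuple[int, int] = (576, 576)
    n_cells: int = 20
    nucleus_diameter_px: tuple[float, float] = (20.0, 60.0)
    puncta_diameter_px: tuple[float, float] = (8.0, 20.0)
    punctae_per_cell: float = 10.0
    compartment_fractions: tuple[float, float, float] = (0.6, 0.25, 0.15)
    transfected_fraction: float = 0.0
    gain_field_amplitude: float = 0.0
    noise_poisson_scale: float = 1.0
    noise_gaussian_sd: float = 2.0
    pixel_size_um: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.compartment_fractions) - 1.0) > 1e-9:
            raise ValueError("compartment_fractions must sum to 1 within 1e-9")
        if any(f < 0 for f in self.compartment_fractions):
            raise ValueError("compartment_fractions must be non-negative")
        for name in ("nucleus_diameter_px", "puncta_diameter_px"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.transfected_fraction <= 1.0:
            raise ValueError("transfected_fraction must lie in [0, 1]")
        if self.punctae_per_cell < 0:
            raise ValueError("punctae_per_cell must be >= 0")


@dataclass
class GroundTruth:
    """Exact ground truth accompanying one rendered monolayer field."""

    nucleus_centroids: np.ndarray  # (n, 2) row, col
    nucleus_diameters_px: np.ndarray
    cell_label_mask: np.ndarray  # consecutive positive labels, 0 = background
    puncta_records: pd.DataFrame  # puncta_id, row, col, diameter_px,
    #                               compartment, cell_label, transfected
    transfected_cells: set[int]
    rim_mask: np.ndarray
    gain_field: np.ndarray | None = None

    def compartment_counts(self) -> dict[str, int]:
        counts = self.puncta_records["compartment"].value_counts()
        return {
            k: int(counts.get(k, 0)) for k in (SURFACE, EARLY_ENDOSOME, LYSOSOME)
        }

    def compartment_fractions_pct(self) -> tuple[float, float, float]:
        counts = self.compartment_counts()
        total = sum(counts.values())
        if total == 0:
            return (float("nan"),) * 3
        return tuple(100.0 * counts[k] / total for k in (SURFACE, EARLY_ENDOSOME, LYSOSOME))


@dataclass
class TraceParams:
    """Parameters of a synthetic intracellular voltage trace."""

    sampling_rate_hz: float = 40000.0
    duration_ms: float = 30.0
    stim_time_ms: float = 5.0
    artifact_amplitude_mv: float = 40.0
    artifact_width_ms: float = 0.15
    true_latency_ms: float | None = 0.8
    epsp_amplitude_mv: float = 10.0
    epsp_rise_ms: float = 0.3
    epsp_decay_ms: float = 3.0
    baseline_noise_sd_mv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.true_latency_ms is not None and self.true_latency_ms <= 0:
            raise ValueError("true_latency_ms must be > 0")
        if (
            self.true_latency_ms is not None
            and self.epsp_amplitude_mv > 0
            and self.true_latency_ms < 1000.0 / self.sampling_rate_hz
        ):
            raise ValueError(
                "true_latency_ms shorter than one sample period is undetectable"
            )


# ---------------------------------------------------------------------------
# Rendering helpers
# ---------------------------------------------------------------------------


def _render_gaussian_spot(
    image: np.ndarray, row: float, col: float, fwhm_px: float, amplitude: float
) -> None:
    """Add an isotropic Gaussian spot (FWHM = requested diameter) in place.

    The tail beyond 1.1x the half-maximum radius is rolled off with a cosine
    taper (zero past 1.6x), which leaves the half-maximum contour — and hence
    the spot's measurable diameter — exact while keeping neighboring spots
    from contaminating each other's half-maximum footprints.
    """
    sigma = fwhm_px * FWHM_TO_SIGMA
    r_half = fwhm_px / 2.0
    r_max = 1.6 * r_half
    half = int(np.ceil(r_max)) + 1
    r0, r1 = int(np.floor(row)) - half, int(np.floor(row)) + half + 1
    c0, c1 = int(np.floor(col)) - half, int(np.floor(col)) + half + 1
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, image.shape[0]), min(c1, image.shape[1])
    if r0c >= r1c or c0c >= c1c:
        return
    rr = np.arange(r0c, r1c)[:, None]
    cc = np.arange(c0c, c1c)[None, :]
    dist = np.sqrt((rr - row) ** 2 + (cc - col) ** 2)
    taper = np.clip((dist - 1.1 * r_half) / (0.5 * r_half), 0.0, 1.0)
    weight = np.cos(taper * np.pi / 2.0) ** 2
    image[r0c:r1c, c0c:c1c] += (
        amplitude * weight * np.exp(-(dist**2) / (2.0 * sigma**2))
    )


def _render_disk(
    image: np.ndarray, row: float, col: float, radius: float, level: float
) -> None:
    """Add an anti-aliased disk of the given radius in place."""
    half = int(np.ceil(radius)) + 2
    r0, r1 = int(np.floor(row)) - half, int(np.floor(row)) + half + 1
    c0, c1 = int(np.floor(col)) - half, int(np.floor(col)) + half + 1
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, image.shape[0]), min(c1, image.shape[1])
    rr = np.arange(r0c, r1c)[:, None]
    cc = np.arange(c0c, c1c)[None, :]
    dist = np.sqrt((rr - row) ** 2 + (cc - col) ** 2)
    image[r0c:r1c, c0c:c1c] += level * np.clip(radius - dist + 0.5, 0.0, 1.0)


def make_gain_field(
    shape: tuple[int, int], amplitude: float, seed: int
) -> np.ndarray:
    """Smooth low-order polynomial gain field, mean-normalized to 1.

    ``amplitude`` sets the relative modulation depth (e.g. 0.2 for +/-20%).
    """
    rng = np.random.default_rng(seed + 77003)
    h, w = shape
    y = np.linspace(-1.0, 1.0, h)[:, None]
    x = np.linspace(-1.0, 1.0, w)[None, :]
    coeffs = rng.uniform(-1.0, 1.0, size=5)
    surface = (
        coeffs[0] * x
        + coeffs[1] * y
        + coeffs[2] * x * y
        + coeffs[3] * (x**2 - 1.0 / 3.0)
        + coeffs[4] * (y**2 - 1.0 / 3.0)
    )
    peak = np.max(np.abs(surface))
    if peak > 0:
        surface = surface / peak
    gain = 1.0 + amplitude * surface
    gain = np.maximum(gain, 0.05)
    return gain / gain.mean()


# ---------------------------------------------------------------------------
# Monolayer generator
# ---------------------------------------------------------------------------


def _place_nuclei(
    params: MonolayerParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Place nucleus centers on a jittered grid.

    A grid layout keeps the tessellated cells roughly even-sized, so every
    cell has room for its puncta complement (both rim length for surface
    punctae and interior area for endosomal ones). Raises
    :class:`PackingError` when a grid slot cannot hold the largest nucleus.
    """
    h, w = params.field_shape
    lo, hi = params.nucleus_diameter_px
    n = params.n_cells
    diameters = rng.uniform(lo, hi, size=n)
    if n == 0:
        return np.empty((0, 2)), diameters
    n_rows = max(int(round(np.sqrt(n * h / w))), 1)
    n_cols = int(np.ceil(n / n_rows))
    slot_h, slot_w = h / n_rows, w / n_cols
    if min(slot_h, slot_w) < hi + 6.0:
        raise PackingError(
            f"cannot place {n} nuclei of diameter {lo}-{hi}px in a "
            f"{h}x{w} field without overlap"
        )
    slots = list(range(n_rows * n_cols))
    rng.shuffle(slots)
    centers = []
    for i in range(n):
        slot = slots[i]
        gr, gc = divmod(slot, n_cols)
        jitter = 0.22
        r = (gr + 0.5 + rng.uniform(-jitter, jitter)) * slot_h
        c = (gc + 0.5 + rng.uniform(-jitter, jitter)) * slot_w
        centers.append((r, c))
    return np.asarray(centers, dtype=float).reshape(-1, 2), diameters


def _cell_tessellation(
    shape: tuple[int, int], centers: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Assign each pixel to the cell whose nucleus boundary is nearest."""
    h, w = shape
    if len(centers) == 0:
        return np.zeros(shape, dtype=np.int32)
    rr = np.arange(h)[:, None, None]
    cc = np.arange(w)[None, :, None]
    dist = np.sqrt(
        (rr - centers[:, 0][None, None, :]) ** 2
        + (cc - centers[:, 1][None, None, :]) ** 2
    ) - radii[None, None, :]
    return (np.argmin(dist, axis=2) + 1).astype(np.int32)


def _rim_mask(cell_labels: np.ndarray, width: float = RIM_WIDTH_PX) -> np.ndarray:
    """Band of pixels within ``width`` px of a cell-cell boundary.

    The field edge is not a cell boundary (the monolayer continues beyond
    the imaged region), so no rim is drawn there.
    """
    boundaries = find_boundaries(cell_labels, mode="thick")
    dist = ndi.distance_transform_edt(~boundaries)
    return (dist < width) & (cell_labels > 0)


def _place_punctae(
    params: MonolayerParams,
    cell_labels: np.ndarray,
    rim: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Place compartment-assigned puncta inside each cell without overlap."""
    n_per_cell = int(round(params.punctae_per_cell))
    n_cells = int(cell_labels.max())
    compartments = np.array([SURFACE, EARLY_ENDOSOME, LYSOSOME])
    dist_to_rim = ndi.distance_transform_edt(~rim)

    h, w = cell_labels.shape
    rr_grid = np.arange(h)[:, None]
    cc_grid = np.arange(w)[None, :]
    # punctae clipped by the field edge are unmeasurable; keep them inside
    edge_dist = np.minimum(
        np.minimum(rr_grid, h - 1 - rr_grid), np.minimum(cc_grid, w - 1 - cc_grid)
    ).astype(float)

    # per-cell candidate pixel caches (coordinates + their clearances)
    cell_pixels: dict[int, tuple] = {}
    for cell in range(1, n_cells + 1):
        rows, cols = np.nonzero(cell_labels == cell)
        cell_pixels[cell] = (
            rows,
            cols,
            rim[rows, cols],
            dist_to_rim[rows, cols],
            edge_dist[rows, cols],
        )

    # draw every puncta's compartment and diameter up front, then place the
    # rim-bound surface punctae before the interior ones (largest first) so
    # interior punctae cannot starve the (1-D, scarcer) rim band and large
    # punctae are not squeezed out by earlier small ones
    lo, hi = params.puncta_diameter_px
    draws = []
    for cell in range(1, n_cells + 1):
        for _ in range(n_per_cell):
            comp = rng.choice(compartments, p=params.compartment_fractions)
            diameter = float(rng.uniform(lo, hi))
            draws.append((cell, comp, diameter))
    order = sorted(
        (i for i, d in enumerate(draws) if d[1] == SURFACE),
        key=lambda i: -draws[i][2],
    )
    order += sorted(
        (i for i, d in enumerate(draws) if d[1] != SURFACE),
        key=lambda i: -draws[i][2],
    )

    placed_r = np.empty(0)
    placed_c = np.empty(0)
    placed_rad = np.empty(0)
    positions: dict[int, tuple[float, float]] = {}
    for i in order:
        cell, comp, diameter = draws[i]
        rows, cols, on_rim, rim_dist, edge = cell_pixels[cell]
        radius = diameter / 2.0
        edge_ok = edge >= radius + 2.0
        if comp == SURFACE:
            sel = on_rim & edge_ok
        else:
            sel = (rim_dist >= radius + 2.5) & edge_ok
        cand_r, cand_c = rows[sel], cols[sel]
        margin = 1.0 if comp == SURFACE else 2.0
        placed = False
        for _try in range(4000):
            if cand_r.size == 0:
                break
            k = rng.integers(cand_r.size)
            r = float(cand_r[k]) + rng.uniform(-0.5, 0.5)
            c = float(cand_c[k]) + rng.uniform(-0.5, 0.5)
            min_dist = radius + placed_rad + margin
            if np.all((r - placed_r) ** 2 + (c - placed_c) ** 2 >= min_dist**2):
                placed = True
                break
        if not placed:
            raise PackingError(
                f"cannot place {n_per_cell} punctae in cell {cell}; "
                "reduce punctae_per_cell or puncta diameter"
            )
        positions[i] = (r, c)
        placed_r = np.append(placed_r, r)
        placed_c = np.append(placed_c, c)
        placed_rad = np.append(placed_rad, radius)

    records = [
        {
            "puncta_id": i,
            "row": positions[i][0],
            "col": positions[i][1],
            "diameter_px": draws[i][2],
            "compartment": draws[i][1],
            "cell_label": draws[i][0],
            "transfected": False,
        }
        for i in range(len(draws))
    ]
    return pd.DataFrame.from_records(
        records,
        columns=[
            "puncta_id",
            "row",
            "col",
            "diameter_px",
            "compartment",
            "cell_label",
            "transfected",
        ],
    )


def _apply_noise(
    image: np.ndarray, params: MonolayerParams, rng: np.random.Generator
) -> np.ndarray:
    out = image
    if params.noise_poisson_scale > 0:
        out = rng.poisson(
            np.maximum(out, 0.0) * params.noise_poisson_scale
        ).astype(float) / params.noise_poisson_scale
    if params.noise_gaussian_sd > 0:
        out = out + rng.normal(0.0, params.noise_gaussian_sd, size=out.shape)
    return np.maximum(out, 0.0)


def make_monolayer(
    params: MonolayerParams,
    well_id: str = "well",
    site_id: str = "site",
) -> tuple[ImageSet, GroundTruth]:
    """Render a confluent monolayer field with exact ground truth.

    Channels produced: ``DNA`` (nuclei), ``CX43`` (all puncta), ``ITGA3``
    (cell body + bright boundary rim + surface puncta co-rendered), ``EEA1``
    (early-endosome marker puncta), ``LAMP1`` (lysosome marker puncta), and
    ``GFP`` when ``transfected_fraction > 0``. Puncta are isotropic Gaussians
    with FWHM equal to the requested diameter; surface puncta sit in the
    boundary rim band, marker puncta are co-centered with their Cx43 puncta.
    A smooth multiplicative gain field and Poisson-Gaussian noise are applied
    when configured.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.field_shape

    # dart-throwing can exhaust a crowded cell's rim; retry the whole layout
    # (same rng stream, so still deterministic in the seed) before giving up
    last_error: Exception | None = None
    for _attempt in range(8):
        try:
            centers, diameters = _place_nuclei(params, rng)
            radii = diameters / 2.0
            cell_labels = _cell_tessellation(params.field_shape, centers, radii)
            rim = _rim_mask(cell_labels)
            punctae = _place_punctae(params, cell_labels, rim, rng)
            break
        except PackingError as err:
            last_error = err
    else:
        raise PackingError(str(last_error))

    n_cells = len(centers)
    transfected: set[int] = set()
    if params.transfected_fraction > 0 and n_cells > 0:
        flags = rng.random(n_cells) < params.transfected_fraction
        transfected = {i + 1 for i in range(n_cells) if flags[i]}
    if len(punctae):
        punctae["transfected"] = punctae["cell_label"].isin(transfected)

    dna = np.full((h, w), _BG, dtype=float)
    cx43 = np.full((h, w), _BG, dtype=float)
    itga3 = np.full((h, w), _BG, dtype=float)
    eea1 = np.full((h, w), _BG, dtype=float)
    lamp1 = np.full((h, w), _BG, dtype=float)

    for (r, c), rad in zip(centers, radii):
        _render_disk(dna, r, c, rad, _NUCLEUS_LEVEL)
    if n_cells > 0:
        itga3 += _CELL_BODY_LEVEL * (cell_labels > 0)
        itga3 += _RIM_LEVEL * rim

    marker_channel = {EARLY_ENDOSOME: eea1, LYSOSOME: lamp1}
    for rec in punctae.itertuples():
        _render_gaussian_spot(cx43, rec.row, rec.col, rec.diameter_px, _PUNCTA_LEVEL)
        if rec.compartment == SURFACE:
            _render_gaussian_spot(
                itga3, rec.row, rec.col, rec.diameter_px, _PUNCTA_LEVEL
            )
        else:
            _render_gaussian_spot(
                marker_channel[rec.compartment],
                rec.row,
                rec.col,
                rec.diameter_px,
                _PUNCTA_LEVEL,
            )

    channels = {"DNA": dna, "CX43": cx43, "ITGA3": itga3, "EEA1": eea1, "LAMP1": lamp1}
    if params.transfected_fraction > 0:
        gfp = np.full((h, w), 3.0, dtype=float)
        for lab in transfected:
            gfp += (_GFP_LEVEL - 3.0) * (cell_labels == lab)
        channels["GFP"] = gfp

    gain = None
    if params.gain_field_amplitude > 0:
        gain = make_gain_field(params.field_shape, params.gain_field_amplitude, params.seed)
        channels = {k: v * gain for k, v in channels.items()}
    channels = {k: _apply_noise(v, params, rng) for k, v in channels.items()}

    imageset = ImageSet(
        channels=channels,
        pixel_size_um=params.pixel_size_um,
        well_id=well_id,
        site_id=site_id,
    )
    truth = GroundTruth(
        nucleus_centroids=centers,
        nucleus_diameters_px=diameters,
        cell_label_mask=cell_labels,
        puncta_records=punctae,
        transfected_cells=transfected,
        rim_mask=rim,
        gain_field=gain,
    )
    return imageset, truth


# ---------------------------------------------------------------------------
# 3D z-stack generator
# ---------------------------------------------------------------------------


def make_zstack(
    volumes_um3: list[float],
    shape_zyx: tuple[int, int, int] = (32, 256, 256),
    pixel_size_um: float = 0.1,
    slice_increment_um: float = 0.4,
    marker_volumes_um3: list[float] | None = None,
    seed: int = 0,
    background: float = 5.0,
    amplitude: float = 150.0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray | None]:
    """Render spherical plaques of the requested physical volumes in 3D.

    Returns ``(volume, truth, marker_volume)`` where ``truth`` has one row
    per plaque (``plaque_id``, ``z``, ``y``, ``x``, ``volume_um3``,
    ``in_marker``) carrying exactly the requested analytic volumes, and
    ``marker_volume`` (or None) renders a co-centered marker sphere for the
    plaques flagged by ``marker_volumes_um3``.
    """
    if pixel_size_um <= 0 or slice_increment_um <= 0:
        raise ValueError("voxel dimensions must be positive")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape_zyx
    vol = np.full(shape_zyx, background, dtype=float)
    marker = (
        np.full(shape_zyx, background, dtype=float)
        if marker_volumes_um3 is not None
        else None
    )
    records = []
    radii = [float((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)) for v in volumes_um3]
    centers: list[tuple[float, float, float]] = []
    for i, (v, r_um) in enumerate(zip(volumes_um3, radii)):
        rz = r_um / slice_increment_um
        rxy = r_um / pixel_size_um
        for _try in range(20000):
            z = rng.uniform(rz + 2, nz - rz - 2)
            y = rng.uniform(rxy + 2, ny - rxy - 2)
            x = rng.uniform(rxy + 2, nx - rxy - 2)
            ok = True
            for j, (zj, yj, xj) in enumerate(centers):
                sep_um = np.sqrt(
                    ((z - zj) * slice_increment_um) ** 2
                    + ((y - yj) * pixel_size_um) ** 2
                    + ((x - xj) * pixel_size_um) ** 2
                )
                if sep_um < r_um + radii[j] + 1.0:
                    ok = False
                    break
            if ok:
                break
        else:
            raise PackingError("cannot place plaques without overlap; enlarge field")
        centers.append((z, y, x))
        in_marker = bool(marker_volumes_um3 and i < len(marker_volumes_um3) and marker_volumes_um3[i])
        records.append(
            {"plaque_id": i, "z": z, "y": y, "x": x, "volume_um3": float(v), "in_marker": in_marker}
        )
        _render_sphere(vol, (z, y, x), r_um, pixel_size_um, slice_increment_um, amplitude)
        if marker is not None and in_marker:
            _render_sphere(
                marker, (z, y, x), r_um * 1.2, pixel_size_um, slice_increment_um, amplitude
            )
    if noise_sd > 0:
        vol = np.maximum(vol + rng.normal(0.0, noise_sd, size=vol.shape), 0.0)
        if marker is not None:
            marker = np.maximum(
                marker + rng.normal(0.0, noise_sd, size=marker.shape), 0.0
            )
    truth = pd.DataFrame.from_records(
        records, columns=["plaque_id", "z", "y", "x", "volume_um3", "in_marker"]
    )
    return vol, truth, marker


def _render_sphere(
    volume: np.ndarray,
    center_zyx: tuple[float, float, float],
    radius_um: float,
    pixel_size_um: float,
    slice_increment_um: float,
    amplitude: float,
) -> None:
    """Add a sphere with a half-voxel anti-aliased edge (physical units)."""
    cz, cy, cx = center_zyx
    rz = radius_um / slice_increment_um
    rxy = radius_um / pixel_size_um
    z0, z1 = max(int(cz - rz) - 2, 0), min(int(cz + rz) + 3, volume.shape[0])
    y0, y1 = max(int(cy - rxy) - 2, 0), min(int(cy + rxy) + 3, volume.shape[1])
    x0, x1 = max(int(cx - rxy) - 2, 0), min(int(cx + rxy) + 3, volume.shape[2])
    zz = (np.arange(z0, z1)[:, None, None] - cz) * slice_increment_um
    yy = (np.arange(y0, y1)[None, :, None] - cy) * pixel_size_um
    xx = (np.arange(x0, x1)[None, None, :] - cx) * pixel_size_um
    dist = np.sqrt(zz**2 + yy**2 + xx**2)
    edge = pixel_size_um  # in-plane voxel pitch sets the edge softness
    volume[z0:z1, y0:y1, x0:x1] += amplitude * np.clip(
        (radius_um - dist) / edge + 0.5, 0.0, 1.0
    )


# ---------------------------------------------------------------------------
# Cytometry, kinetics, traces
# ---------------------------------------------------------------------------


def make_cytometry(
    n_events: int,
    log10_mean: float,
    log10_sd: float,
    seed: int = 0,
    condition: str = "cond",
    timepoint: float = 0.0,
    stain: str = "target",
) -> pd.DataFrame:
    """Log-normal cytometry event table.

    Per-event fluorescence is ``10**N(log10_mean, log10_sd)`` so the
    population geometric mean converges to ``10**log10_mean``.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if log10_sd < 0:
        raise ValueError("log10_sd must be >= 0")
    rng = np.random.default_rng(seed)
    values = 10.0 ** rng.normal(log10_mean, log10_sd, size=n_events)
    return pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "fluorescence": values,
            "condition": condition,
            "timepoint": timepoint,
            "stain": stain,
        }
    )


def make_efflux_events(
    conditions: dict[str, tuple[float, float]],
    timepoints_min: list[float],
    n_events: int = 5000,
    log10_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Event tables for an exponential-efflux experiment.

    ``conditions`` maps condition name to ``(initial_log10_mean, rate_per_min)``;
    at time t the population geometric mean is ``10**initial * exp(-rate*t)``.
    """
    frames = []
    sub = 0
    for cond, (log10_g0, rate) in conditions.items():
        for t in timepoints_min:
            mean = log10_g0 + np.log10(np.exp(-rate * t))
            frames.append(
                make_cytometry(
                    n_events,
                    mean,
                    log10_sd,
                    seed=seed + 104729 * sub,
                    condition=cond,
                    timepoint=float(t),
                )
            )
            sub += 1
    return pd.concat(frames, ignore_index=True)


def make_kinetic_series(
    intercept: float,
    slope: float,
    t_step_min: float = 2.0,
    duration_min: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear fluorogenic-substrate accumulation series.

    Defaults produce 16 points at t = 0, 2, ..., 30 min.
    """
    if t_step_min <= 0 or duration_min < 0:
        raise ValueError("time step must be > 0 and duration >= 0")
    t = np.arange(0.0, duration_min + 0.5 * t_step_min, t_step_min)
    y = intercept + slope * t
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    return pd.DataFrame({"time_min": t, "fluorescence": y})


def make_trace(params: TraceParams) -> tuple[pd.DataFrame, dict]:
    """Voltage trace with a stimulation artifact and (optionally) an EPSP.

    Returns ``(trace, truth)``. ``trace`` has columns ``time_ms`` and
    ``voltage_mv``; ``truth`` records the artifact onset, the EPSP onset
    (``None`` when ``epsp_amplitude_mv == 0``), and the true latency. The
    EPSP rises linearly over ``epsp_rise_ms`` and decays exponentially.
    """
    fs_khz = params.sampling_rate_hz / 1000.0
    n = int(round(params.duration_ms * fs_khz)) + 1
    t = np.arange(n) / fs_khz
    v = np.zeros(n)

    # biphasic stimulation artifact: one sine cycle starting at stim_time
    a0 = params.stim_time_ms
    width = params.artifact_width_ms
    in_art = (t >= a0) & (t < a0 + width)
    v[in_art] += params.artifact_amplitude_mv * np.sin(
        2.0 * np.pi * (t[in_art] - a0) / width
    )

    onset_ms = None
    if params.epsp_amplitude_mv > 0 and params.true_latency_ms is not None:
        onset_ms = a0 + params.true_latency_ms
        dt = t - onset_ms
        rise = (dt >= 0) & (dt < params.epsp_rise_ms)
        decay = dt >= params.epsp_rise_ms
        v[rise] += params.epsp_amplitude_mv * dt[rise] / params.epsp_rise_ms
        v[decay] += params.epsp_amplitude_mv * np.exp(
            -(dt[decay] - params.epsp_rise_ms) / params.epsp_decay_ms
        )

    if params.baseline_noise_sd_mv > 0:
        rng = np.random.default_rng(params.seed)
        v = v + rng.normal(0.0, params.baseline_noise_sd_mv, size=n)

    trace = pd.DataFrame({"time_ms": t, "voltage_mv": v})
    truth = {
        "artifact_onset_ms": a0,
        "epsp_onset_ms": onset_ms,
        "true_latency_ms": params.true_latency_ms if onset_ms is not None else None,
    }
    return trace, truth


def make_spike_train(
    n_events: int,
    window_s: float = 5.0,
    sampling_rate_hz: float = 10000.0,
    amplitude_mv: float = 20.0,
    spike_width_ms: float = 2.0,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Trace containing ``n_events`` well-separated depolarization events."""
    rng = np.random.default_rng(seed)
    fs_khz = sampling_rate_hz / 1000.0
    duration_ms = window_s * 1000.0
    n = int(round(duration_ms * fs_khz)) + 1
    t = np.arange(n) / fs_khz
    v = np.zeros(n)
    if n_events > 0:
        # events on an even grid with jitter, keeping them well separated
        grid = np.linspace(
            spike_width_ms * 2, duration_ms - spike_width_ms * 2, n_events
        )
        times = grid + rng.uniform(-0.3, 0.3, n_events) * spike_width_ms
        for t0 in times:
            dt = t - t0
            mask = (dt >= 0) & (dt < spike_width_ms)
            v[mask] += amplitude_mv * np.sin(np.pi * dt[mask] / spike_width_ms)
    if noise_sd_mv > 0:
        v = v + rng.normal(0.0, noise_sd_mv, size=n)
    return pd.DataFrame({"time_ms": t, "voltage_mv": v})
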