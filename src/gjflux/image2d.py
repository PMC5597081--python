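"""High-content 2D quantification pipeline.

Implements the per-field processing chain for multi-channel fluorescence
fields of epithelial monolayers: plate-level illumination correction,
nuclei/cell segmentation, transfection partitioning, puncta detection with a
diameter gate, surface-object identification, three-way subcellular
compartment assignment (surface / early endosome / lysosome), hierarchical
aggregation, and bilateral-tract ROI densitometry on sum projections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon2mask
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed
from skimage.transform import downscale_local_mean, resize

logger = logging.getLogger(__name__)

#: Compartment labels used throughout the package.
SURFACE = "surface"
EARLY_ENDOSOME = "EE"
LYSOSOME = "LYS"
OTHER = "other"

MARKER_COMPARTMENT = {"EEA1": EARLY_ENDOSOME, "LAMP1": LYSOSOME}


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ImageSet:
    """A registered multi-channel field of view.

    Parameters
    ----------
    channels
        Mapping of channel name (``DNA``, ``CX43``, ``ITGA3``, ``EEA1``,
        ``LAMP1``, ``GFP``) to a 2D float array. All channels must share the
        same shape and be non-negative.
    pixel_size_um
        Lateral pixel size in microns per pixel.
    well_id, site_id
        Identifiers used by the aggregation stage.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    well_id: str = "well"
    site_id: str = "site"

    def __post_init__(self) -> None:
        shapes = {np.asarray(c).shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class GainField:
    """Smooth multiplicative illumination field, normalized to mean 1."""

    field: np.ndarray

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        if np.any(self.field <= 0):
            raise ValueError("gain field must be strictly positive everywhere")
        mean = self.field.mean()
        if abs(mean - 1.0) > 1e-6:
            raise ValueError(f"gain field mean {mean} != 1 within 1e-6")


@dataclass
class PunctaSet:
    """Detected point-like objects from one channel of one field.

    ``table`` has one row per object with columns ``label``, ``row``, ``col``
    (intensity-weighted centroid), ``area_px`` (half-maximum footprint),
    ``equivalent_diameter_px``, ``integrated_intensity``, ``peak_intensity``,
    ``cell_label`` and ``transfected``. ``label_mask`` stores each object's
    half-maximum pixel footprint for intersection tests.
    """

    table: pd.DataFrame
    label_mask: np.ndarray

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()


@dataclass
class CompartmentFractions:
    """Three-way subcellular localization of puncta, normalized to 100%."""

    pct_surface: float
    pct_early_endosome: float
    pct_lysosome: float
    n_punctae: int
    n_other: int = 0
    punctae_per_cell: float = float("nan")

    def __post_init__(self) -> None:
        total = self.pct_surface + self.pct_early_endosome + self.pct_lysosome
        if self.n_punctae > 0 and abs(total - 100.0) > 1e-6:
            raise ValueError(f"fractions sum to {total}, expected 100")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.pct_surface, self.pct_early_endosome, self.pct_lysosome)


@dataclass
class ROIQuant:
    """Densitometry of bilateral-tract ROIs on a sum projection.

    Per ROI: area (px^2 and um^2), mean grey value (MGV) and integrated
    density (area x MGV). Combined: the area-weighted mean MGV over both
    tracts and the total integrated density derived from it.
    """

    per_roi: pd.DataFrame
    weighted_mean_mgv: float
    total_area_px: float
    total_area_um2: float
    total_integrated_density: float


# ---------------------------------------------------------------------------
# Illumination correction
# ---------------------------------------------------------------------------


def compute_gain_field(
    images: list[np.ndarray],
    window_px: int = 200,
    downscale: int = 4,
) -> GainField:
    """Estimate a per-channel illumination gain from one or more fields.

    The per-pixel mean over the supplied fields is median filtered with a
    square ``window_px`` window and normalized to mean 1. The median filter is
    evaluated on a ``downscale``-reduced copy for tractability (the window is
    reduced accordingly), which leaves smooth illumination structure intact.

    Raises
    ------
    ValueError
        If no images are given or the window exceeds the image extent.
    """
    if len(images) == 0:
        raise ValueError("need at least one image to estimate a gain field")
    stack = np.stack([np.asarray(im, dtype=float) for im in images])
    mean_image = stack.mean(axis=0)
    if window_px > min(mean_image.shape):
        raise ValueError(
            f"median window {window_px} exceeds image extent {mean_image.shape}"
        )
    small = downscale_local_mean(mean_image, (downscale, downscale))
    win = max(3, int(round(window_px / downscale)) | 1)
    filtered = ndi.median_filter(small, size=win, mode="nearest")
    gain = resize(filtered, mean_image.shape, order=1, mode="edge", anti_aliasing=False)
    floor = max(gain.max() * 1e-6, 1e-12)
    gain = np.maximum(gain, floor)
    gain = gain / gain.mean()
    return GainField(gain)


def correct_illumination(image: np.ndarray, gain: GainField) -> np.ndarray:
    """Divide a raw image by its channel's illumination gain field."""
    image = np.asarray(image, dtype=float)
    if image.shape != gain.field.shape:
        raise ValueError(
            f"image shape {image.shape} != gain shape {gain.field.shape}"
        )
    return image / gain.field


def correct_imageset(
    imageset: ImageSet, gains: dict[str, GainField]
) -> ImageSet:
    """Apply per-channel gain correction; channels without a gain pass through."""
    corrected = {
        name: correct_illumination(arr, gains[name]) if name in gains else arr
        for name, arr in imageset.channels.items()
    }
    return ImageSet(
        channels=corrected,
        pixel_size_um=imageset.pixel_size_um,
        well_id=imageset.well_id,
        site_id=imageset.site_id,
    )


# ---------------------------------------------------------------------------
# Threshold policies
# ---------------------------------------------------------------------------


def _resolve_threshold(image: np.ndarray, policy, context: str) -> float:
    """Resolve a threshold policy to an absolute intensity.

    ``policy`` may be the string ``"otsu"``, the string ``"quantile:Q"``
    (e.g. ``"quantile:0.99"``), or a number used as an absolute threshold.
    Every resolved threshold is logged for auditability.
    """
    if isinstance(policy, str):
        if policy == "otsu":
            flat = image[np.isfinite(image)]
            if flat.size == 0 or flat.max() == flat.min():
                thr = float(flat.max()) if flat.size else 0.0
            else:
                thr = float(threshold_otsu(flat))
        elif policy.startswith("quantile:"):
            q = float(policy.split(":", 1)[1])
            thr = float(np.quantile(image, q))
        else:
            raise ValueError(f"unknown threshold policy {policy!r}")
    else:
        thr = float(policy)
    logger.info("threshold[%s] policy=%r -> %.4f", context, policy, thr)
    return thr


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def _equivalent_diameter(area_px: float) -> float:
    return float(np.sqrt(4.0 * area_px / np.pi))


def segment_nuclei(
    dna_channel: np.ndarray,
    min_diameter_px: float = 20.0,
    max_diameter_px: float = 60.0,
    solidity_min: float = 0.8,
    threshold: str | float = "otsu",
    diameter_tol_px: float = 0.5,
) -> np.ndarray:
    """Segment nuclei from the DNA channel.

    Thresholds the channel, splits touching nuclei with a distance-transform
    watershed, and removes objects outside the equivalent-circle diameter gate
    ``[min_diameter_px, max_diameter_px]`` or below ``solidity_min``
    (circularity proxy). The gate is applied with a half-pixel measurement
    tolerance because sub-pixel diameter estimates are below the precision of
    thresholded area measurements.

    Returns a label mask with consecutive positive labels; background is 0.
    An empty image yields an empty (all-zero) mask, not an error.
    """
    dna = np.asarray(dna_channel, dtype=float)
    thr = _resolve_threshold(dna, threshold, "nuclei")
    mask = dna > thr
    if not mask.any():
        return np.zeros(dna.shape, dtype=np.int32)
    mask = ndi.binary_fill_holes(mask)
    distance = ndi.distance_transform_edt(mask)
    min_sep = max(1, int(round(min_diameter_px / 2)))
    peaks = peak_local_max(
        distance, min_distance=min_sep, labels=mask, exclude_border=False
    )
    markers = np.zeros(dna.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndi.label(mask)
    labels = watershed(-distance, markers=markers, mask=mask)

    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for prop in regionprops(labels):
        diam = _equivalent_diameter(prop.area)
        if not (
            min_diameter_px - diameter_tol_px
            <= diam
            <= max_diameter_px + diameter_tol_px
        ):
            continue
        if prop.solidity < solidity_min:
            continue
        out[labels == prop.label] = next_label
        next_label += 1
    return out


def segment_cells(
    nuclei_mask: np.ndarray,
    cell_channel: np.ndarray,
    threshold: str | float = "otsu",
) -> np.ndarray:
    """Propagate cell regions from nucleus seeds over the cell channel.

    Cells grow from the nuclei by watershed on the distance transform from the
    nuclei, constrained to above-threshold cell-channel pixels. Exactly one
    cell label is produced per nucleus label and each cell contains its seed;
    a nucleus falling outside the foreground degenerates to its own mask
    (logged).
    """
    nuclei = np.asarray(nuclei_mask)
    channel = np.asarray(cell_channel, dtype=float)
    if nuclei.shape != channel.shape:
        raise ValueError("nuclei mask and cell channel shapes differ")
    n_nuclei = int(nuclei.max())
    if n_nuclei == 0:
        return np.zeros(nuclei.shape, dtype=np.int32)
    thr = _resolve_threshold(channel, threshold, "cells")
    foreground = (channel > thr) | (nuclei > 0)
    # single-pixel noise dropouts inside cells would orphan any puncta whose
    # centroid lands on them; close and fill before propagation
    foreground = ndi.binary_closing(foreground, structure=np.ones((3, 3)))
    foreground = ndi.binary_fill_holes(foreground)
    distance = ndi.distance_transform_edt(nuclei == 0)
    cells = watershed(distance, markers=nuclei.astype(np.int32), mask=foreground)
    for lab in range(1, n_nuclei + 1):
        if not np.any(cells == lab):
            logger.warning("nucleus %d outside foreground; cell = nucleus", lab)
            cells[nuclei == lab] = lab
    return cells.astype(np.int32)


def _exact_otsu(values: np.ndarray) -> float:
    """Otsu's criterion evaluated over every split of a small sample.

    Histogram-binned Otsu cannot separate values that share a bin, which
    matters for per-cell summaries (tens of values). Returns the midpoint of
    the best between-class split; if all values are equal, returns that value
    (so nothing exceeds the threshold).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return float(x[-1])
    best_thr, best_var = float(x[-1]), -np.inf
    csum = np.cumsum(x)
    total = csum[-1]
    for i in range(1, n):
        if x[i] == x[i - 1]:
            continue
        w1 = i / n
        mu1 = csum[i - 1] / i
        mu2 = (total - csum[i - 1]) / (n - i)
        var_b = w1 * (1 - w1) * (mu1 - mu2) ** 2
        if var_b > best_var:
            best_var = var_b
            best_thr = (x[i - 1] + x[i]) / 2.0
    return float(best_thr)


def partition_transfected(
    cell_mask: np.ndarray,
    gfp_channel: np.ndarray | None,
    threshold: str | float = "otsu",
) -> dict[int, bool]:
    """Call each cell transfected iff its mean GFP exceeds a threshold.

    The default policy is Otsu over the per-cell mean GFP values; a numeric
    ``threshold`` overrides it as an absolute cutoff on the per-cell mean.
    """
    if gfp_channel is None:
        raise ValueError("transfection partitioning requested without a GFP channel")
    cells = np.asarray(cell_mask)
    gfp = np.asarray(gfp_channel, dtype=float)
    labels = np.unique(cells)
    labels = labels[labels > 0]
    if labels.size == 0:
        return {}
    means = ndi.mean(gfp, labels=cells, index=labels)
    means = np.atleast_1d(means)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold policy {threshold!r}")
        thr = _exact_otsu(means)
    else:
        thr = float(threshold)
    logger.info("threshold[gfp per-cell means] -> %.4f", thr)
    return {int(lab): bool(m > thr) for lab, m in zip(labels, means)}


# ---------------------------------------------------------------------------
# Puncta detection
# ---------------------------------------------------------------------------


_PUNCTA_COLUMNS = [
    "label",
    "row",
    "col",
    "area_px",
    "equivalent_diameter_px",
    "integrated_intensity",
    "peak_intensity",
    "cell_label",
    "transfected",
]


def detect_punctae(
    channel: np.ndarray,
    cell_mask: np.ndarray,
    d_min: float = 8.0,
    d_max: float = 20.0,
    threshold: str | float = "otsu",
    diameter_tol_px: float = 0.5,
    transfected: dict[int, bool] | None = None,
    smooth_sigma: float = 1.0,
) -> PunctaSet:
    """Detect primary puncta objects inside the cellular mask.

    Candidate pixels are above-threshold and inside the cell mask. Peaks are
    found on a matched-filter smoothing of the channel (scaled to ``d_min``)
    so one object yields one peak, and the image is partitioned into peak
    zones by watershed. Each object's extent is the set of zone pixels above
    half of its own peak height over the field background (median), measured
    on a lightly smoothed image with the smoothing kernel's width removed
    analytically — so the size estimate equals the full-width-at-half-maximum
    of a diffraction-limited spot and is invariant to per-object intensity
    scaling. Objects are gated by equivalent-circle diameter in
    ``[d_min, d_max]`` (inclusive, with a ``diameter_tol_px`` measurement
    tolerance) and assigned to the cell containing their centroid; objects
    whose centroid falls outside every cell are discarded.
    """
    img = np.asarray(channel, dtype=float)
    cells = np.asarray(cell_mask)
    if img.shape != cells.shape:
        raise ValueError("channel and cell mask shapes differ")
    background = float(np.median(img))
    thr = _resolve_threshold(img, threshold, "punctae")
    candidate = (img > thr) & (cells > 0)
    empty = PunctaSet(
        table=pd.DataFrame(columns=_PUNCTA_COLUMNS),
        label_mask=np.zeros(img.shape, dtype=np.int32),
    )
    if not candidate.any():
        return empty

    meas = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    peak_sigma = max(1.5, d_min / 3.0)
    peak_img = gaussian(img, sigma=peak_sigma, preserve_range=True)
    min_sep = max(2, int(round(0.8 * d_min)))
    peaks = peak_local_max(
        peak_img, min_distance=min_sep, labels=candidate, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndi.label(candidate)
    # zones of influence over the full frame: the half-maximum core may
    # extend slightly beyond the candidate threshold for dim objects
    zones = watershed(-peak_img, markers=markers)

    records = []
    out_mask = np.zeros(img.shape, dtype=np.int32)
    next_label = 1
    n_zones = int(zones.max())
    zone_slices = ndi.find_objects(zones)
    for zi in range(1, n_zones + 1):
        sl = zone_slices[zi - 1]
        if sl is None:
            continue
        zone = zones[sl] == zi
        local_meas = meas[sl]
        zone_cand = zone & candidate[sl]
        if not zone_cand.any():
            continue
        peak = float(local_meas[zone_cand].max())
        half = background + 0.5 * (peak - background)
        core = zone & (local_meas >= half)
        # keep only the connected blob containing the peak: a zone can span
        # far-away above-half pixels that belong to no detected object
        peak_positions = np.nonzero(zone_cand & (local_meas == peak))
        core_labels, _ = ndi.label(core)
        peak_component = core_labels[peak_positions[0][0], peak_positions[1][0]]
        if peak_component == 0:
            continue
        core = core_labels == peak_component
        area = int(core.sum())
        if area == 0:
            continue
        d_raw = _equivalent_diameter(area)
        # remove the measurement kernel's contribution to the apparent FWHM
        fwhm_factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
        diam = fwhm_factor * np.sqrt(
            max((d_raw / fwhm_factor) ** 2 - smooth_sigma**2, 0.0)
        )
        if not (d_min - diameter_tol_px <= diam <= d_max + diameter_tol_px):
            continue
        crr, ccc = np.nonzero(core)
        crr = crr + sl[0].start
        ccc = ccc + sl[1].start
        weights = np.maximum(meas[crr, ccc] - background, 0.0)
        wsum = weights.sum()
        if wsum <= 0:
            continue
        row = float((crr * weights).sum() / wsum)
        col = float((ccc * weights).sum() / wsum)
        cell_label = int(cells[int(round(row)), int(round(col))])
        if cell_label == 0:
            continue
        records.append(
            {
                "label": next_label,
                "row": row,
                "col": col,
                "area_px": area,
                "equivalent_diameter_px": diam,
                "integrated_intensity": float((img[crr, ccc] - background).sum()),
                "peak_intensity": peak,
                "cell_label": cell_label,
                "transfected": bool(transfected.get(cell_label, False))
                if transfected
                else False,
            }
        )
        out_mask[crr, ccc] = next_label
        next_label += 1
    if not records:
        return empty
    return PunctaSet(table=pd.DataFrame.from_records(records), label_mask=out_mask)


def surface_objects(
    itga3_channel: np.ndarray,
    threshold: str | float = "otsu",
    pixel_size_um: float = 1.0,
) -> tuple[np.ndarray, dict[str, float]]:
    """Binary surface mask from the ITGA3 channel plus area statistics.

    Returns ``(mask, stats)`` where ``stats`` holds ``area_px`` and
    ``area_um2`` for the normalization of surface-localized puncta levels.
    """
    img = np.asarray(itga3_channel, dtype=float)
    if img.size == 0 or img.max() == img.min():
        mask = np.zeros(img.shape, dtype=bool)
    else:
        thr = _resolve_threshold(img, threshold, "surface")
        mask = img > thr
    area_px = float(mask.sum())
    return mask, {"area_px": area_px, "area_um2": area_px * pixel_size_um**2}


# ---------------------------------------------------------------------------
# Compartment assignment
# ---------------------------------------------------------------------------


def assign_compartments(
    cx43: PunctaSet,
    surface_mask: np.ndarray,
    marker_punctae: dict[str, PunctaSet],
    n_cells: int | None = None,
    mode: str = "pixel",
) -> tuple[CompartmentFractions, pd.DataFrame]:
    """Assign each Cx43 puncta to surface, early endosome, or lysosome.

    A puncta is *surface* if its pixel footprint intersects the ITGA3 surface
    mask; otherwise *early endosome* (resp. *lysosome*) if it intersects an
    ``EEA1`` (resp. ``LAMP1``) marker puncta footprint. Multi-hit puncta are
    resolved with priority surface > EEA1 > LAMP1. Remaining puncta are
    labeled ``other`` and excluded from the three-way fractions, which are
    normalized to sum to 100%.

    Parameters
    ----------
    marker_punctae
        Mapping from marker kind (``EEA1`` and/or ``LAMP1``) to the marker's
        :class:`PunctaSet` from the same field. Any other key is an error.
    mode
        ``"pixel"`` (default) tests footprint intersection (>= 1 shared
        pixel); ``"centroid"`` tests centroid containment instead.

    Returns
    -------
    (fractions, table)
        ``fractions`` is the :class:`CompartmentFractions`; ``table`` is the
        Cx43 puncta table with an added ``compartment`` column.
    """
    for kind in marker_punctae:
        if kind not in MARKER_COMPARTMENT:
            raise ValueError(
                f"marker kind {kind!r} not in {sorted(MARKER_COMPARTMENT)}"
            )
    if mode not in ("pixel", "centroid"):
        raise ValueError(f"unknown colocalization mode {mode!r}")
    surface = np.asarray(surface_mask, dtype=bool)

    marker_masks = {
        kind: ps.label_mask > 0 for kind, ps in marker_punctae.items()
    }
    calls = []
    table = cx43.table.copy()
    for _, punc in table.iterrows():
        lab = int(punc["label"])
        if mode == "pixel":
            footprint = cx43.label_mask == lab
            if surface[footprint].any():
                calls.append(SURFACE)
                continue
            hit = None
            for kind in ("EEA1", "LAMP1"):
                mask = marker_masks.get(kind)
                if mask is not None and mask[footprint].any():
                    hit = MARKER_COMPARTMENT[kind]
                    break
            calls.append(hit if hit else OTHER)
        else:
            r, c = int(round(punc["row"])), int(round(punc["col"]))
            if surface[r, c]:
                calls.append(SURFACE)
                continue
            hit = None
            for kind in ("EEA1", "LAMP1"):
                mask = marker_masks.get(kind)
                if mask is not None and mask[r, c]:
                    hit = MARKER_COMPARTMENT[kind]
                    break
            calls.append(hit if hit else OTHER)
    table["compartment"] = calls

    counts = table["compartment"].value_counts()
    n_surface = int(counts.get(SURFACE, 0))
    n_ee = int(counts.get(EARLY_ENDOSOME, 0))
    n_lys = int(counts.get(LYSOSOME, 0))
    n_other = int(counts.get(OTHER, 0))
    n_classified = n_surface + n_ee + n_lys
    if n_classified == 0:
        raise ValueError("no puncta classified into any compartment")
    fractions = CompartmentFractions(
        pct_surface=100.0 * n_surface / n_classified,
        pct_early_endosome=100.0 * n_ee / n_classified,
        pct_lysosome=100.0 * n_lys / n_classified,
        n_punctae=n_classified,
        n_other=n_other,
        punctae_per_cell=(len(table) / n_cells) if n_cells else float("nan"),
    )
    return fractions, table


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def aggregate_well(site_records: pd.DataFrame) -> pd.Series:
    """Aggregate per-site records of a single well by unweighted mean.

    Raises if records from more than one well are mixed into the call.
    """
    if len(site_records) == 0:
        raise ValueError("no site records to aggregate")
    wells = site_records["well_id"].unique()
    if len(wells) > 1:
        raise ValueError(f"mixed wells in one aggregation call: {sorted(wells)}")
    numeric = site_records.select_dtypes("number")
    out = numeric.mean()
    out["well_id"] = wells[0]
    if "condition" in site_records:
        out["condition"] = site_records["condition"].iloc[0]
    out["n_sites"] = len(site_records)
    return out


def aggregate_plate(site_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hierarchical aggregation: sites -> wells -> conditions.

    Sites are averaged (unweighted) within each well; well means are then
    averaged within each condition. Returns ``(well_table, condition_table)``
    each carrying the number of units aggregated at that level.
    """
    required = {"well_id", "condition"}
    missing = required - set(site_table.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    value_cols = [
        c
        for c in site_table.select_dtypes("number").columns
        if c not in ("site_id",)
    ]
    wells = (
        site_table.groupby(["condition", "well_id"])[value_cols]
        .mean()
        .join(site_table.groupby(["condition", "well_id"]).size().rename("n_sites"))
        .reset_index()
    )
    conditions = (
        wells.groupby("condition")[value_cols]
        .mean()
        .join(wells.groupby("condition").size().rename("n_wells"))
        .reset_index()
    )
    return wells, conditions


# ---------------------------------------------------------------------------
# Tract densitometry
# ---------------------------------------------------------------------------


def sum_slices(zstack: np.ndarray) -> np.ndarray:
    """Sum projection over focal planes (axis 0)."""
    stack = np.asarray(zstack, dtype=float)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a stack of >= 1 slice")
    return stack.sum(axis=0)


def quantify_tracts(
    projection: np.ndarray,
    roi_polygons: list[np.ndarray],
    pixel_size_um: float = 1.0,
) -> ROIQuant:
    """Densitometry of the two bilateral-tract ROIs on a sum projection.

    Each ROI polygon is an (N, 2) array of (row, col) vertices; pixels are
    included by a center-in-polygon test. Per ROI the area, mean grey value
    (MGV) and integrated density (area x MGV) are reported; the combined
    readout is the area-weighted mean MGV over both tracts and the total
    integrated density it implies.
    """
    img = np.asarray(projection, dtype=float)
    if len(roi_polygons) != 2:
        raise ValueError("bilateral-tract readout requires exactly 2 ROI polygons")
    rows = []
    for i, poly in enumerate(roi_polygons):
        mask = polygon2mask(img.shape, np.asarray(poly, dtype=float))
        area = float(mask.sum())
        if area == 0:
            raise ValueError(f"ROI {i} selects no pixels")
        mgv = float(img[mask].mean())
        rows.append(
            {
                "roi": i,
                "area_px": area,
                "area_um2": area * pixel_size_um**2,
                "mgv": mgv,
                "integrated_density": area * mgv,
            }
        )
    per_roi = pd.DataFrame(rows)
    total_area = float(per_roi["area_px"].sum())
    weighted_mgv = float(
        (per_roi["area_px"] * per_roi["mgv"]).sum() / total_area
    )
    return ROIQuant(
        per_roi=per_roi,
        weighted_mean_mgv=weighted_mgv,
        total_area_px=total_area,
        total_area_um2=total_area * pixel_size_um**2,
        total_integrated_density=weighted_mgv * total_area,
    )
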