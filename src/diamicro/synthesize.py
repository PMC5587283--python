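"""Seeded synthetic confocal imagery with known ground truth.

Two image families are emulated, mirroring how a muscle-morphometry study
images a diaphragm:

* **Longitudinal striation images** (:func:`generate_striation_image`):
  parallel fibers with periodic banding along the fiber axis — the
  alpha-actinin Z-line pattern whose spatial period is the sarcomere
  length.  Fibers are separated by dark interstitial gaps of controlled
  relative width, and a chosen fraction of fibers carry a "Y" branch.

* **Cross-section images** (:func:`generate_cross_section`): a
  laminin-like boundary channel drawn around space-filling Voronoi cells
  (the fiber profiles), a nuclei channel with one nucleus per fiber placed
  centrally or peripherally, and point-like macrophages present in both
  the nuclei and CD68 channels.

A third generator (:func:`sample_cohort`) skips imagery entirely and draws
per-image metric values for every genotype x age x region group from
configurable means/SDs, producing the long-format table the statistics
engine consumes.

Every generator is a pure function of its spec (which embeds an integer
seed); identical specs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, cKDTree
from scipy.stats import norm
from shapely.geometry import Polygon, box
from skimage.segmentation import find_boundaries

from .errors import CalibrationError, ConfigurationError, PackingError
from .io import CalibratedImage

__all__ = [
    "StriationSpec",
    "CrossSectionSpec",
    "CohortSpec",
    "GroundTruth",
    "generate_striation_image",
    "generate_cross_section",
    "sample_cohort",
    "truncated_mean",
    "GENOTYPES",
    "AGES_MONTHS",
    "REGIONS",
    "METRICS",
]

GENOTYPES = ("control", "mdx")
AGES_MONTHS = (3, 7, 10)
REGIONS = ("dorsal", "midcostal", "ventral")
#: canonical metric vocabulary used throughout the package
METRICS = (
    "sarcomere_length_um",
    "interstitial_ratio",
    "percent_branched",
    "csa_um2",
    "percent_regenerating",
    "macrophage_density_per_mm2",
)

_BRANCH_HALF_ANGLE_DEG = 15.0  # daughter branches diverge at +/-15 degrees


@dataclass(frozen=True)
class StriationSpec:
    """Parameters of a longitudinal striated-fiber image.

    ``period_um`` is the banding period (sarcomere length) along the fiber
    axis; ``gap_to_fiber_ratio`` is the target interstitial-to-fiber width
    ratio; ``branch_fraction`` of fibers carry one in-frame Y junction.
    """

    period_um: float = 2.5
    pixel_size_um: float = 0.1
    image_shape: tuple[int, int] = (512, 512)
    fiber_width_um: float = 6.0
    gap_to_fiber_ratio: float = 0.26
    branch_fraction: float = 0.0
    orientation_deg: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    width_jitter: float = 0.08  # relative SD of fiber/gap widths

    def __post_init__(self) -> None:
        if self.period_um <= 2.0 * self.pixel_size_um:
            raise CalibrationError(
                f"period {self.period_um} um <= 2 pixels "
                f"({2 * self.pixel_size_um} um): below Nyquist"
            )
        if not 0.0 <= self.branch_fraction <= 1.0:
            raise ConfigurationError("branch_fraction must lie in [0, 1]")
        if self.gap_to_fiber_ratio < 0:
            raise ConfigurationError("gap_to_fiber_ratio must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CrossSectionSpec:
    """Parameters of a cross-section (laminin / nuclei / CD68) image."""

    n_fibers: int = 40
    csa_mean_um2: float = 500.0
    csa_sd_um2: float = 150.0
    central_nucleus_fraction: float = 0.0
    macrophage_density_per_mm2: float = 0.0
    pixel_size_um: float = 0.25
    image_shape: tuple[int, int] = (512, 512)
    seed: int = 0
    nucleus_radius_um: float = 1.5
    macrophage_radius_um: float = 2.0
    # distractor objects for colocalization tests (not macrophages)
    n_cd68_only: int = 0
    n_free_nuclei: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ConfigurationError("n_fibers must be >= 1")
        if not 0.0 <= self.central_nucleus_fraction <= 1.0:
            raise ConfigurationError("central_nucleus_fraction must lie in [0, 1]")
        if self.macrophage_density_per_mm2 < 0:
            raise ConfigurationError("macrophage_density_per_mm2 must be >= 0")
        if self.csa_mean_um2 <= 0 or self.csa_sd_um2 < 0:
            raise ConfigurationError("csa_mean_um2 > 0 and csa_sd_um2 >= 0 required")


@dataclass
class GroundTruth:
    """Generator-side truth paired with each synthetic image.

    Only the fields relevant to the generating family are populated.
    Raster fields (label masks) live here for in-memory use; the JSON
    sidecar written by :func:`diamicro.io.write_ground_truth` carries the
    vector fields only.
    """

    # striation images
    true_period_um: float | None = None
    orientation_deg: float | None = None
    fiber_ids: list[int] = field(default_factory=list)
    branched_fiber_ids: list[int] = field(default_factory=list)
    fiber_widths_um: list[float] = field(default_factory=list)
    gap_widths_um: list[float] = field(default_factory=list)
    true_interstitial_ratio: float | None = None
    # cross-sections
    polygons_um: list[list[tuple[float, float]]] = field(default_factory=list)
    polygon_areas_um2: list[float] = field(default_factory=list)
    central_nucleus_flags: list[bool] = field(default_factory=list)
    nucleus_centroids_um: list[tuple[float, float]] = field(default_factory=list)
    macrophage_centroids_um: list[tuple[float, float]] = field(default_factory=list)
    macrophage_count: int | None = None
    # rasters (in-memory only)
    label_mask: np.ndarray | None = None
    fiber_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# longitudinal striation images
# ---------------------------------------------------------------------------

def _rotated_coords(shape: tuple[int, int], pixel_size_um: float, orientation_deg: float):
    """(u, v) um coordinate grids: u along the fiber axis, v across it."""
    rows, cols = shape
    y = (np.arange(rows) + 0.5)[:, None] * pixel_size_um
    x = (np.arange(cols) + 0.5)[None, :] * pixel_size_um
    th = math.radians(orientation_deg)
    u = x * math.cos(th) + y * math.sin(th)
    v = -x * math.sin(th) + y * math.cos(th)
    return u, v


def generate_striation_image(spec: StriationSpec) -> tuple[CalibratedImage, GroundTruth]:
    """Render parallel banded fibers with known period, gaps and branches.

    The banding waveform is a raised cosine along the fiber axis,
    ``0.5 * (1 + cos(2 pi u / period))``, so the modal period is known
    analytically and thresholding recovers ~50% duty-cycle bands.
    Fibers are laid out across the fiber axis with jittered widths; a
    branched fiber splits at a junction (placed uniformly in the middle
    60% of the frame) into two half-width daughters diverging at +/-15
    degrees, striations parallel to the trunk.  Branched fibers receive a
    wide enough layout slot that daughters never merge with neighbours.
    """
    rng = np.random.default_rng(spec.seed)
    u, v = _rotated_coords(spec.image_shape, spec.pixel_size_um, spec.orientation_deg)
    u_min, u_max = float(u.min()), float(u.max())
    v_min, v_max = float(v.min()), float(v.max())

    w_mean = spec.fiber_width_um
    g_mean = spec.gap_to_fiber_ratio * w_mean
    tan_b = math.tan(math.radians(_BRANCH_HALF_ANGLE_DEG))

    # pre-draw jitters and junction positions so the layout is a pure
    # function of (branched slot set), enabling the two-pass assignment
    n_max = int((v_max - v_min) / max(w_mean * 0.5, 1e-6)) + 8
    g_draws = g_mean * (1.0 + spec.width_jitter * rng.standard_normal(n_max))
    w_draws = np.maximum(2 * spec.pixel_size_um,
                         w_mean * (1.0 + spec.width_jitter * rng.standard_normal(n_max)))
    u0_draws = u_min + (0.2 + 0.6 * rng.random(n_max)) * (u_max - u_min)
    priority = rng.permutation(n_max)  # branch-assignment order

    # the Y geometry stays inside the trunk's own slot (daughter outer
    # edges reach +/- w/2), so the layout is independent of which fibers
    # branch and the branch count can be set exactly afterwards
    placed: list[tuple[int, float, float, float]] = []
    cursor = v_min
    for i in range(n_max):
        g = max(spec.pixel_size_um, float(g_draws[i])) if spec.gap_to_fiber_ratio > 0 else 0.0
        w = float(w_draws[i])
        center = cursor + g + 0.5 * w
        if center + 0.5 * w > v_max + 0.5 * w and placed:
            break
        if cursor >= v_max:
            break
        placed.append((i, center, w, g))
        cursor = center + 0.5 * w

    k = int(round(spec.branch_fraction * len(placed)))
    # only fibers fully in frame can carry a (detectable) Y
    eligible = [i for i, center, w, _ in placed
                if center - 0.5 * w >= v_min and center + 0.5 * w <= v_max]
    k = min(k, len(eligible))
    branched_slots = set(sorted(eligible, key=lambda s: priority[s])[:k])

    label = np.zeros(spec.image_shape, dtype=np.int32)
    banding = 0.5 * (1.0 + np.cos(2.0 * np.pi * u / spec.period_um))

    widths: list[float] = []
    gaps: list[float] = []
    branched_ids: list[int] = []
    fiber_ids: list[int] = []

    for fid, (slot, center, w, g) in enumerate(placed, start=1):
        fiber_ids.append(fid)
        widths.append(w)
        if g > 0:
            gaps.append(g)
        if slot in branched_slots:
            # Y: trunk splits at u0; quarter-width daughters diverge at
            # +/-15 deg until their centres sit at +/- 3w/8 (outer edges
            # at the slot boundary), then run parallel to the trunk
            u0 = float(u0_draws[slot])
            dv = v - center
            off = np.clip(u - u0, 0.0, None) * tan_b
            np.minimum(off, 3.0 * w / 8.0, out=off)
            trunk = (u < u0) & (np.abs(dv) < w / 2.0)
            d1 = (u >= u0) & (np.abs(dv - off) < w / 8.0)
            d2 = (u >= u0) & (np.abs(dv + off) < w / 8.0)
            region = trunk | d1 | d2
            branched_ids.append(fid)
        else:
            region = np.abs(v - center) < w / 2.0
        label[region] = fid

    fiber_mask = label > 0
    img = np.where(fiber_mask, banding, 0.0)
    if spec.noise_sd > 0:
        img = img + spec.noise_sd * rng.standard_normal(spec.image_shape)
    img = img.astype(np.float32)

    true_ratio = (float(np.mean(gaps)) / float(np.mean(widths))) if gaps else 0.0
    truth = GroundTruth(
        true_period_um=spec.period_um,
        orientation_deg=spec.orientation_deg,
        fiber_ids=fiber_ids,
        branched_fiber_ids=branched_ids,
        fiber_widths_um=widths,
        gap_widths_um=gaps,
        true_interstitial_ratio=true_ratio,
        label_mask=label,
        fiber_mask=fiber_mask,
    )
    return CalibratedImage(img, spec.pixel_size_um), truth


# ---------------------------------------------------------------------------
# cross-section images
# ---------------------------------------------------------------------------

def _voronoi_cells_in_rect(seeds: np.ndarray, rect: tuple[float, float, float, float]) -> list[Polygon]:
    """Bounded Voronoi cells of ``seeds`` clipped to a rectangle.

    Seeds are mirrored across each rectangle edge so every original cell
    is finite; cells are then intersected with the rectangle.
    """
    x0, y0, x1, y1 = rect
    mirrored = [seeds]
    for axis, lo, hi in ((0, x0, x1), (1, y0, y1)):
        for bound in (lo, hi):
            m = seeds.copy()
            m[:, axis] = 2 * bound - m[:, axis]
            mirrored.append(m)
    allpts = np.vstack(mirrored)
    vor = Voronoi(allpts)
    clip = box(x0, y0, x1, y1)
    cells = []
    for i in range(len(seeds)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(clip)
        cells.append(poly)
    return cells


def generate_cross_section(spec: CrossSectionSpec) -> tuple[CalibratedImage, GroundTruth]:
    """Render a 3-channel cross-section with known per-fiber truth.

    Fibers tessellate a centred sub-rectangle of the field sized to
    ``n_fibers * csa_mean_um2``; the tessellation is the Voronoi diagram
    of blue-noise (jittered-grid) seed points, so cells are convex and
    space-filling like laminin-bounded fiber profiles.  The returned
    stack has channel roles ``laminin`` (boundaries), ``nuclei`` and
    ``cd68``.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_shape
    px = spec.pixel_size_um
    field_w, field_h = cols * px, rows * px
    area_req = spec.n_fibers * spec.csa_mean_um2
    if area_req > 0.95 * field_w * field_h:
        raise PackingError(
            f"{spec.n_fibers} fibers at mean {spec.csa_mean_um2} um2 need "
            f"{area_req:.0f} um2 but the field has {field_w * field_h:.0f} um2"
        )
    # centred region with the field's aspect ratio
    reg_h = math.sqrt(area_req * field_h / field_w)
    reg_w = area_req / reg_h
    x0, y0 = (field_w - reg_w) / 2.0, (field_h - reg_h) / 2.0
    x1, y1 = x0 + reg_w, y0 + reg_h

    # jittered grid of exactly n_fibers seeds
    nx = max(1, int(round(math.sqrt(spec.n_fibers * reg_w / reg_h))))
    ny = int(math.ceil(spec.n_fibers / nx))
    cells_xy = [(i, j) for j in range(ny) for i in range(nx)]
    keep = rng.choice(len(cells_xy), size=spec.n_fibers, replace=False)
    cw, ch = reg_w / nx, reg_h / ny
    jitter = 0.5 * min(0.9, spec.csa_sd_um2 / spec.csa_mean_um2)
    seeds = np.empty((spec.n_fibers, 2))
    for k, idx in enumerate(sorted(keep.tolist())):
        i, j = cells_xy[idx]
        cx = x0 + (i + 0.5) * cw + jitter * cw * (2 * rng.random() - 1)
        cy = y0 + (j + 0.5) * ch + jitter * ch * (2 * rng.random() - 1)
        seeds[k] = (cx, cy)

    polygons = _voronoi_cells_in_rect(seeds, (x0, y0, x1, y1))

    # rasterize by nearest-seed assignment of pixel centres inside the region
    yy = (np.arange(rows) + 0.5) * px
    xx = (np.arange(cols) + 0.5) * px
    X, Y = np.meshgrid(xx, yy)
    inside = (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1)
    label = np.zeros(spec.image_shape, dtype=np.int32)
    pts = np.column_stack([X[inside], Y[inside]])
    if len(pts):
        _, nearest = cKDTree(seeds).query(pts)
        label[inside] = nearest + 1

    boundary = find_boundaries(label, mode="thick")
    laminin = boundary.astype(np.float32)

    # nuclei: one per fiber, central or peripheral by flag
    n_central = int(round(spec.central_nucleus_fraction * spec.n_fibers))
    flags = np.zeros(spec.n_fibers, dtype=bool)
    if n_central:
        flags[rng.choice(spec.n_fibers, size=n_central, replace=False)] = True

    from scipy import ndimage as ndi

    interiors = label.copy()
    interiors[boundary] = 0
    nuclei = np.zeros(spec.image_shape, dtype=np.float32)
    nuc_centroids: list[tuple[float, float]] = []
    r_nuc_px = max(2, int(round(spec.nucleus_radius_um / px)))
    Yp, Xp = np.mgrid[0:rows, 0:cols]
    for k in range(spec.n_fibers):
        cell = interiors == k + 1
        if not cell.any():
            nuc_centroids.append((float("nan"), float("nan")))
            continue
        edt = ndi.distance_transform_edt(cell)
        dmax = edt.max()
        if flags[k]:
            # innermost point: normalized boundary distance 1.0
            r, c = np.unravel_index(int(np.argmax(edt)), edt.shape)
        else:
            # outer 15% band, away from the very edge
            nd = edt / max(dmax, 1e-9)
            band = cell & (nd > 0.02) & (nd <= 0.15)
            if not band.any():
                band = cell & (nd <= 0.3)
            idxs = np.flatnonzero(band)
            pick = idxs[int(rng.integers(len(idxs)))]
            r, c = np.unravel_index(pick, edt.shape)
        disk = (Yp - r) ** 2 + (Xp - c) ** 2 <= r_nuc_px**2
        nuclei[disk & cell] = 1.0
        nuc_centroids.append(((c + 0.5) * px, (r + 0.5) * px))

    # macrophages: Poisson count, min-separation placement, in both channels
    cd68 = np.zeros(spec.image_shape, dtype=np.float32)
    r_mac_px = max(2, int(round(spec.macrophage_radius_um / px)))
    field_mm2 = field_w * field_h / 1e6
    n_mac = int(rng.poisson(spec.macrophage_density_per_mm2 * field_mm2))
    placed: list[tuple[float, float]] = []  # pixel coords of all point objects
    mac_centroids: list[tuple[float, float]] = []

    def _place(min_sep_px: float, tries: int = 200) -> tuple[int, int] | None:
        for _ in range(tries):
            r = int(rng.integers(r_mac_px + 1, rows - r_mac_px - 1))
            c = int(rng.integers(r_mac_px + 1, cols - r_mac_px - 1))
            if all((r - pr) ** 2 + (c - pc) ** 2 > min_sep_px**2 for pr, pc in placed):
                return r, c
        return None

    sep = 2 * r_mac_px + 3
    for _ in range(n_mac):
        pos = _place(sep)
        if pos is None:
            break
        r, c = pos
        placed.append((r, c))
        disk = (Yp - r) ** 2 + (Xp - c) ** 2 <= r_mac_px**2
        cd68[disk] = 1.0
        nuclei[disk] = 1.0
        mac_centroids.append(((c + 0.5) * px, (r + 0.5) * px))
    for _ in range(spec.n_cd68_only):
        pos = _place(sep + r_nuc_px)
        if pos is None:
            break
        r, c = pos
        placed.append((r, c))
        cd68[(Yp - r) ** 2 + (Xp - c) ** 2 <= r_mac_px**2] = 1.0
    for _ in range(spec.n_free_nuclei):
        pos = _place(sep + r_nuc_px)
        if pos is None:
            break
        r, c = pos
        placed.append((r, c))
        nuclei[(Yp - r) ** 2 + (Xp - c) ** 2 <= r_nuc_px**2] = 1.0

    stack = np.stack([laminin, nuclei, cd68])
    image = CalibratedImage(stack, px, channels={"laminin": 0, "nuclei": 1, "cd68": 2})
    truth = GroundTruth(
        polygons_um=[list(p.exterior.coords) for p in polygons],
        polygon_areas_um2=[float(p.area) for p in polygons],
        central_nucleus_flags=flags.tolist(),
        nucleus_centroids_um=nuc_centroids,
        macrophage_centroids_um=mac_centroids,
        macrophage_count=len(mac_centroids),
        label_mask=label,
    )
    return image, truth


# ---------------------------------------------------------------------------
# cohort-level sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Per-group metric distributions for a full 2 x 3 x 3 cohort.

    ``group_params`` maps ``(genotype, age_months, region)`` to
    ``{metric: (mean, sd)}`` for each of the six metrics.  Draws are
    normal, redrawn while negative (all six metrics are nonnegative).
    """

    group_params: dict[tuple[str, int, str], dict[str, tuple[float, float]]]
    n_per_group: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for g in GENOTYPES:
            for a in AGES_MONTHS:
                for r in REGIONS:
                    key = (g, a, r)
                    if key not in self.group_params:
                        raise ConfigurationError(f"missing group {key}")
                    for m in METRICS:
                        if m not in self.group_params[key]:
                            raise ConfigurationError(f"group {key} missing metric {m!r}")
                        mu, sd = self.group_params[key][m]
                        if sd < 0:
                            raise ConfigurationError(f"negative SD for {key}/{m}")
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")


def truncated_mean(mu: float, sd: float) -> float:
    """Expected value of a normal(mu, sd) draw redrawn while negative.

    This is what :func:`sample_cohort` actually generates, so parameter
    recovery is judged against it rather than the untruncated mean.
    """
    if sd == 0:
        return mu
    a = mu / sd
    return mu + sd * norm.pdf(a) / norm.cdf(a)


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a long-format metric table for the full cohort.

    Returns columns ``genotype, age_months, region, image_id, metric,
    value``; ``n_per_group`` synthetic images per group each carry one
    draw of every metric.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for g in GENOTYPES:
        for a in AGES_MONTHS:
            for r in REGIONS:
                params = spec.group_params[(g, a, r)]
                for m in METRICS:
                    mu, sd = params[m]
                    vals = mu + sd * rng.standard_normal(spec.n_per_group)
                    bad = vals < 0
                    while bad.any():
                        vals[bad] = mu + sd * rng.standard_normal(int(bad.sum()))
                        bad = vals < 0
                    for i, val in enumerate(vals):
                        records.append(
                            (g, a, r, f"{g}_{a}m_{r}_{i:04d}", m, float(val))
                        )
    return pd.DataFrame.from_records(
        records, columns=["genotype", "age_months", "region", "image_id", "metric", "value"]
    )
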