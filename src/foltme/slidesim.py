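"""Synthetic multiround bright-field IHC slide generator.

Renders regions of interest (ROIs) of follicular-lymphoma-like tissue with
fully known ground truth: elliptical follicles (the intrafollicular, IF,
compartment) embedded in extrafollicular (EF) tissue, marker-positive cells
placed as Poisson point processes at configurable per-compartment densities
(cells per high-power field, HPF), a CD21 follicular-dendritic-cell
meshwork confined to follicle interiors, and per-round geometric
distortions emulating the washing/re-staining cycle of sequential IHC.

Images are composed through the same Beer-Lambert stain model that
:mod:`foltme.stains` inverts, so rendering and deconvolution are exact
inverses up to 8-bit quantization — every downstream stage (unmixing,
registration, segmentation, counting) can be scored against truth.

An HPF is modeled as a square field of 0.0625 mm^2 (250 um x 250 um, the
conventional 40x field); densities are always expressed per HPF regardless
of the rendered pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .registration import Transform
from .stains import StainMatrix, compose

__all__ = [
    "HPF_AREA_UM2",
    "Follicle",
    "Cell",
    "SlideConfig",
    "RenderConfig",
    "SlideGroundTruth",
    "generate_slide",
    "render_round",
    "distort_round",
    "hpf_area_px",
]

HPF_AREA_UM2 = 62_500.0  # 0.0625 mm^2 = 250 um square at 40x

DEFAULT_PANEL = {  # marker -> (round index, chromogen)
    "CD21": (0, "AEC"),
    "CD68": (1, "AEC"),
    "CD163": (2, "AEC"),
    "CD8": (3, "AEC"),
}


def hpf_area_px(pixel_size_um: float) -> float:
    return HPF_AREA_UM2 / pixel_size_um**2


@dataclass(frozen=True)
class Follicle:
    """Ellipse in pixel coordinates: center (row, col), semi-axes, angle."""
    center: tuple[float, float]
    axes: tuple[float, float]
    angle: float

    def mask(self, shape) -> np.ndarray:
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
        dr, dc = rr - self.center[0], cc - self.center[1]
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        u = dr * ca + dc * sa
        v = -dr * sa + dc * ca
        return (u / self.axes[0]) ** 2 + (v / self.axes[1]) ** 2 <= 1.0


@dataclass(frozen=True)
class Cell:
    marker: str
    compartment: str  # "IF" or "EF"
    center: tuple[float, float]  # (row, col) px
    radius: float  # px
    amplitude: float  # peak chromogen concentration, OD units


@dataclass
class SlideConfig:
    """Geometry and composition of one synthetic ROI.

    Densities are cells/HPF per marker and compartment; the expected count
    in a compartment is density * compartment_area / HPF_area (Poisson).
    ``coexpression`` maps (marker_a, marker_b) to the fraction of marker_b
    cells placed exactly at marker_a cell centers (double positives, e.g.
    CD68/CD163).
    """
    roi_size: int = 1000
    pixel_size_um: float = 0.25
    target_if_fraction: float = 0.5
    if_fraction_tol: float = 0.05
    follicle_radius_range_um: tuple[float, float] = (40.0, 90.0)
    cell_radius_um: float = 3.5
    cell_amplitude: float = 0.9
    densities: dict = dc_field(default_factory=lambda: {
        "CD68": {"IF": 40.0, "EF": 60.0},
        "CD163": {"IF": 2.0, "EF": 45.0},
        "CD8": {"IF": 2.0, "EF": 30.0},
    })
    coexpression: dict = dc_field(default_factory=dict)
    panel: dict = dc_field(default_factory=lambda: dict(DEFAULT_PANEL))


@dataclass
class RenderConfig:
    """Photometric model of one staining round."""
    hematoxylin_intensity: float = 0.45
    hematoxylin_texture: float = 0.15
    noise_sd: float = 0.015  # OD units
    I0: float = 255.0
    chromogen_by_round: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        for v in (self.hematoxylin_intensity, self.hematoxylin_texture):
            if not 0.0 <= v <= 1.0:
                raise ValueError("intensities must lie in [0, 1] OD scale")


@dataclass
class SlideGroundTruth:
    """Everything needed to score the pipeline against this ROI."""
    roi_size: int
    pixel_size_um: float
    follicles: list
    cells: list
    follicle_mask: np.ndarray
    panel: dict
    round_transforms: dict = dc_field(default_factory=dict)
    config: SlideConfig | None = None
    seed: int | None = None

    @property
    def if_fraction(self) -> float:
        return float(self.follicle_mask.mean())

    def cells_of(self, marker: str, compartment: str | None = None):
        return [c for c in self.cells
                if c.marker == marker
                and (compartment is None or c.compartment == compartment)]

    def counts(self, marker: str) -> dict[str, int]:
        return {comp: len(self.cells_of(marker, comp)) for comp in ("IF", "EF")}


def _place_follicles(cfg: SlideConfig, rng: np.random.Generator):
    """Add random ellipses until the union covers the target fraction.

    Greedy accept/reject on the realized union area; the loop stops inside
    the configured tolerance band or errors after a bounded number of
    attempts (the band is wide enough that this is virtually impossible at
    default settings)."""
    shape = (cfg.roi_size, cfg.roi_size)
    mask = np.zeros(shape, dtype=bool)
    follicles: list[Follicle] = []
    r_lo, r_hi = (r / cfg.pixel_size_um for r in cfg.follicle_radius_range_um)
    lo = cfg.target_if_fraction - cfg.if_fraction_tol
    hi = cfg.target_if_fraction + cfg.if_fraction_tol
    for _ in range(4000):
        if mask.mean() >= lo:
            break
        a = rng.uniform(r_lo, r_hi)
        b = a * rng.uniform(0.7, 1.0)
        f = Follicle(center=(rng.uniform(0, cfg.roi_size),
                             rng.uniform(0, cfg.roi_size)),
                     axes=(a, b), angle=rng.uniform(0, np.pi))
        fm = f.mask(shape)
        new = mask | fm
        if new.mean() <= hi:
            # skip proposals mostly swallowed by existing follicles
            if (fm & ~mask).sum() < 0.4 * fm.sum():
                continue
            mask = new
            follicles.append(f)
    if not lo <= mask.mean() <= hi:
        raise RuntimeError("could not reach target follicle coverage; "
                           "widen if_fraction_tol or the radius range")
    return follicles, mask


def _sample_points(region_mask: np.ndarray, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    idx = np.flatnonzero(region_mask)
    chosen = rng.choice(idx, size=n, replace=True)
    rr, cc = np.unravel_index(chosen, region_mask.shape)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
    return np.stack([rr, cc], axis=1) + jitter


def generate_slide(config: SlideConfig | None = None,
                   seed: int | None = None) -> SlideGroundTruth:
    """Generate the ground truth of one ROI.

    Counts per marker/compartment are Poisson with mean
    ``density * compartment_area_px / hpf_area_px``; positions are uniform
    within the compartment.  Double positives are injected by re-using a
    random subset of the partner marker's centers.
    """
    config = config or SlideConfig()
    if not 0.0 < config.target_if_fraction < 1.0:
        raise ValueError("target IF fraction must lie in (0, 1)")
    for marker, dens in config.densities.items():
        for comp, d in dens.items():
            if d < 0:
                raise ValueError(f"negative density for {marker}/{comp}")
    rng = np.random.default_rng(seed)
    follicles, if_mask = _place_follicles(config, rng)
    masks = {"IF": if_mask, "EF": ~if_mask}
    hpf_px = hpf_area_px(config.pixel_size_um)
    cell_r = config.cell_radius_um / config.pixel_size_um

    cells: list[Cell] = []
    by_marker: dict[str, list[Cell]] = {}
    shared_from = {b: (a, frac) for (a, b), frac in config.coexpression.items()}

    for marker in config.panel:
        if marker == "CD21":
            continue  # meshwork stain, not a discrete cell population
        dens = config.densities.get(marker, {})
        mcells: list[Cell] = []
        for comp in ("IF", "EF"):
            d = float(dens.get(comp, 0.0))
            lam = d * masks[comp].sum() / hpf_px
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n == 0:
                continue
            partner = shared_from.get(marker)
            pts = []
            n_shared = 0
            if partner is not None:
                pool = [c.center for c in by_marker.get(partner[0], [])
                        if c.compartment == comp]
                n_shared = min(int(round(partner[1] * n)), len(pool))
                if n_shared:
                    take = rng.choice(len(pool), size=n_shared, replace=False)
                    pts.extend([pool[i] for i in take])
            if n - n_shared > 0:
                fresh = _sample_points(masks[comp], n - n_shared, rng)
                pts.extend(map(tuple, fresh))
            for p in pts:
                mcells.append(Cell(marker, comp, (float(p[0]), float(p[1])),
                                   cell_r, config.cell_amplitude))
        by_marker[marker] = mcells
        cells.extend(mcells)

    return SlideGroundTruth(roi_size=config.roi_size,
                            pixel_size_um=config.pixel_size_um,
                            follicles=follicles, cells=cells,
                            follicle_mask=if_mask, panel=dict(config.panel),
                            config=config, seed=seed)


def _stamp_gaussians(shape, centers, sigma: float, amplitude: float,
                     out: np.ndarray | None = None) -> np.ndarray:
    """Add Gaussian-profile disks at sub-pixel centers (local stamps)."""
    if out is None:
        out = np.zeros(shape)
    if len(centers) == 0:
        return out
    half = max(2, int(np.ceil(3 * sigma)))
    for r0, c0 in centers:
        ri, ci = int(round(r0)), int(round(c0))
        r_lo, r_hi = max(0, ri - half), min(shape[0], ri + half + 1)
        c_lo, c_hi = max(0, ci - half), min(shape[1], ci + half + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr = np.arange(r_lo, r_hi)[:, None] - r0
        cc = np.arange(c_lo, c_hi)[None, :] - c0
        out[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(
            -(rr**2 + cc**2) / (2 * sigma**2))
    return out


def hematoxylin_field(truth: SlideGroundTruth, config: RenderConfig,
                      seed_offset: int = 0) -> np.ndarray:
    """Counterstain texture, identical across rounds (same tissue).

    Smooth pseudo-nuclear texture: band-limited noise on top of a constant
    base, slightly denser inside follicles.  Provides the gradients the
    registration chain aligns on."""
    rng = np.random.default_rng((truth.seed or 0) * 1000 + 777 + seed_offset)
    shape = truth.follicle_mask.shape
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    noise /= max(noise.std(), 1e-9)
    base = config.hematoxylin_intensity * (1.0
                                           + 0.15 * truth.follicle_mask)
    return np.clip(base + config.hematoxylin_texture * noise, 0.0, 1.0)


def _cd21_meshwork(truth: SlideGroundTruth) -> np.ndarray:
    """FDC meshwork: ridge-like texture strictly inside follicles."""
    rng = np.random.default_rng((truth.seed or 0) * 1000 + 21)
    shape = truth.follicle_mask.shape
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), 3.0)
    tex = np.abs(tex)
    tex /= max(tex.max(), 1e-9)
    return truth.follicle_mask * (0.35 + 0.55 * tex)


def marker_concentration(truth: SlideGroundTruth, marker: str) -> np.ndarray:
    """Noise-free chromogen concentration map of one marker."""
    shape = truth.follicle_mask.shape
    if marker == "CD21":
        return _cd21_meshwork(truth)
    out = np.zeros(shape)
    for cell in truth.cells_of(marker):
        _stamp_gaussians(shape, [cell.center], cell.radius / 2.0,
                         cell.amplitude, out)
    return out


def render_round(truth: SlideGroundTruth, round_index: int,
                 config: RenderConfig | None = None,
                 seed: int | None = None) -> np.ndarray:
    """Render one staining round to an 8-bit RGB bright-field image.

    Hematoxylin + the round's chromogen concentration maps are pushed
    through the stain matrix (:func:`foltme.stains.compose`); additive
    Gaussian OD noise models sensor/staining variability.  Deterministic
    for a fixed seed (default derived from the slide seed and round)."""
    config = config or RenderConfig()
    markers = [m for m, (r, _) in truth.panel.items() if r == round_index]
    if not markers:
        raise ValueError(f"no marker assigned to round {round_index}")
    chrom_names = {truth.panel[m][1] for m in markers}
    if len(chrom_names) != 1:
        raise ValueError("one chromogen per round")
    chrom = config.chromogen_by_round.get(round_index, chrom_names.pop())
    M = StainMatrix.for_chromogen(chrom)

    hema = hematoxylin_field(truth, config)
    chrom_map = np.zeros_like(hema)
    for m in markers:
        chrom_map += marker_concentration(truth, m)

    rng = np.random.default_rng(seed if seed is not None
                                else (truth.seed or 0) * 1000 + round_index)
    shape = hema.shape
    channels = np.stack([hema, chrom_map, np.zeros(shape)], axis=-1)
    if config.noise_sd > 0:
        channels = channels + rng.normal(0.0, config.noise_sd,
                                         channels.shape)
    return compose(np.clip(channels, 0.0, None), M, I0=config.I0)


def distort_round(image: np.ndarray, transform: Transform,
                  background: float = 255.0) -> np.ndarray:
    """Warp a rendered round by its ground-truth sampling transform."""
    from .registration import warp

    if transform.field is not None:
        mag = np.linalg.norm(transform.field, axis=-1).max()
        if mag >= 15.0:
            raise ValueError("displacement field exceeds the 15 px bound")
    out = warp(image, transform, background=background)
    if image.dtype == np.uint8:
        out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return out
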