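"""Optical-density conversion and stain-matrix color deconvolution.

Chromogenic IHC stains absorb light multiplicatively, so they mix *linearly*
in optical-density (OD) space: ``OD = -log10((I + eps) / I0)`` per RGB
channel.  A slide stained with up to three chromogens can therefore be
unmixed by a 3x3 linear solve against a matrix whose rows are the unit OD
absorption vectors of the individual stains (Ruifrok & Johnston color
deconvolution).  This module implements the forward model (:func:`compose`),
its inverse (:func:`deconvolve`), and pseudo-color compositing of
co-registered concentration channels from sequential staining rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainMatrix",
    "ConcentrationImage",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "compose",
    "pseudo_color",
    "HEMATOXYLIN",
    "DAB",
    "AEC",
]

# Published Ruifrok-Johnston absorption vectors (unnormalized, R/G/B order).
HEMATOXYLIN = (0.650, 0.704, 0.286)
DAB = (0.268, 0.570, 0.776)
AEC = (0.2743, 0.6796, 0.6803)

_DEFAULT_I0 = 255.0
_DEFAULT_EPS = 1.0


@dataclass(frozen=True)
class StainMatrix:
    """Unit-row stain basis in OD-RGB space.

    Rows are stains, columns are R, G, B.  Rows are L2-normalized on
    construction; the matrix must be well conditioned (cond < 1e6) so that
    the per-pixel unmixing solve is stable.
    """

    names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain matrix has a zero row")
        m = m / norms[:, None]
        if np.linalg.cond(m) >= 1e6:
            raise ValueError("stain matrix is singular or near-singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "names", tuple(self.names))

    @classmethod
    def from_vectors(cls, names, vectors) -> "StainMatrix":
        """Build from two or three stain vectors.

        With two vectors the third ("residual") row is their normalized
        cross product, completing an invertible basis that absorbs whatever
        signal the named stains do not explain.
        """
        vs = [np.asarray(v, float) for v in vectors]
        names = list(names)
        if len(vs) == 2:
            r = np.cross(vs[0], vs[1])
            vs.append(r / np.linalg.norm(r))
            names.append("residual")
        if len(vs) != 3:
            raise ValueError("need 2 or 3 stain vectors")
        return cls(tuple(names), np.vstack(vs))

    @classmethod
    def hdx(cls) -> "StainMatrix":
        """Hematoxylin + DAB + residual (standard brown-chromogen IHC)."""
        return cls.from_vectors(["hematoxylin", "DAB"], [HEMATOXYLIN, DAB])

    @classmethod
    def hax(cls) -> "StainMatrix":
        """Hematoxylin + AEC + residual (sequential-IHC red chromogen)."""
        return cls.from_vectors(["hematoxylin", "AEC"], [HEMATOXYLIN, AEC])

    @classmethod
    def for_chromogen(cls, chromogen: str) -> "StainMatrix":
        try:
            vec = {"DAB": DAB, "AEC": AEC, "AP-red": AEC}[chromogen]
        except KeyError:
            raise ValueError(f"unknown chromogen {chromogen!r}") from None
        return cls.from_vectors(["hematoxylin", chromogen], [HEMATOXYLIN, vec])

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=list(self.names),
                     columns=["R", "G", "B"]).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "StainMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(tuple(df.index), df.to_numpy(float))


@dataclass
class ConcentrationImage:
    """Unmixed stain concentration channels (H, W, n_stains), OD units."""

    channels: np.ndarray
    names: tuple[str, ...]
    clipped_fraction: float = 0.0

    def channel(self, name: str) -> np.ndarray:
        return self.channels[..., self.names.index(name)]


def rgb_to_od(rgb: np.ndarray, I0: float = _DEFAULT_I0,
              eps: float = _DEFAULT_EPS) -> np.ndarray:
    """Convert an 8-bit RGB image to optical density.

    OD = -log10((I + eps) / I0); ``eps`` (default one grey level) keeps
    fully black pixels finite.
    """
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    rgb = np.asarray(rgb, dtype=float)
    return -np.log10((rgb + eps) / I0)


def od_to_rgb(od: np.ndarray, I0: float = _DEFAULT_I0,
              eps: float = _DEFAULT_EPS) -> np.ndarray:
    """Exact inverse of :func:`rgb_to_od`, quantized to uint8."""
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    intensity = I0 * np.power(10.0, -np.asarray(od, float)) - eps
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8)


def deconvolve(od: np.ndarray, M: StainMatrix,
               clip_negative: bool = True) -> ConcentrationImage:
    """Unmix an OD image into per-stain concentrations.

    Solves ``OD = C @ M`` per pixel.  Negative concentrations (noise pushed
    outside the stain simplex) are clipped to zero by default and the
    clipped fraction recorded — the residual channel routinely absorbs
    camera noise, so some clipping is normal.
    """
    od = np.asarray(od, float)
    if od.shape[-1] != 3:
        raise ValueError("OD image must have 3 channels")
    conc = od @ M.inverse
    clipped = 0.0
    if clip_negative:
        neg = conc < 0
        clipped = float(neg.mean())
        conc = np.where(neg, 0.0, conc)
    return ConcentrationImage(conc, M.names, clipped)


def compose(channels: np.ndarray, M: StainMatrix, I0: float = _DEFAULT_I0,
            eps: float = _DEFAULT_EPS) -> np.ndarray:
    """Render stain concentrations to an 8-bit RGB image (Beer-Lambert).

    ``I = I0 * 10**(-(C @ M))`` with the same eps convention as
    :func:`rgb_to_od`, so compose -> rgb_to_od -> deconvolve round-trips to
    within 8-bit quantization error.
    """
    channels = np.asarray(channels, float)
    if np.any(channels < 0):
        raise ValueError("concentrations must be non-negative")
    od = channels @ M.matrix
    return od_to_rgb(od, I0=I0, eps=eps)


def pseudo_color(channels: dict[str, np.ndarray],
                 colormap: dict[str, tuple[float, float, float]]) -> np.ndarray:
    """Additive pseudo-fluorescence composite of co-registered channels.

    Each marker channel is multiplied by its assigned RGB color and the
    results summed, so double positives appear as the color sum (green +
    red -> yellow).  Output is uint8; channels are assumed in [0, 1]-ish OD
    units and the blend is clipped at 1.
    """
    if not channels:
        raise ValueError("no channels supplied")
    shapes = {ch.shape for ch in channels.values()}
    if len(shapes) != 1:
        raise ValueError(f"channel shapes differ: {shapes}")
    shape = shapes.pop()
    out = np.zeros(shape + (3,), dtype=float)
    for name, ch in channels.items():
        color = np.asarray(colormap[name], float)
        out += np.clip(np.asarray(ch, float), 0, None)[..., None] * color
    return (np.clip(out, 0, 1) * 255).round().astype(np.uint8)
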