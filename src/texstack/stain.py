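"""H&E stain separation in optical-density space.

Beer–Lambert: a pixel transmitting intensity ``I`` against background ``I0``
has optical density ``OD = -log(I / I0)`` per RGB channel, and the OD of a
mixed stain is linear in dye concentrations: ``od = c_h v_h + c_e v_e +
c_r v_r`` with unit stain vectors ``v``. Separation inverts that 3x3 system
per pixel; single-stain images are re-rendered from one concentration
channel alone. All internal math is on ``[0, 1]`` reals — quantization to
8 bits happens only at file I/O, which keeps round trips exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = [
    "StainModel",
    "ConcentrationMaps",
    "rgb_to_od",
    "od_to_rgb",
    "separate_stains",
    "simulate_single_stain",
    "compose_tile",
    "normalize_to_reference",
    "estimate_stain_model",
]

#: Widely published H&E optical-density directions (before normalization).
_H_RAW = (0.65, 0.70, 0.29)
_E_RAW = (0.07, 0.99, 0.11)

_OD_EPS = 1e-8  # channel floor before the log; declared clipping rule


@dataclass(frozen=True)
class StainModel:
    """Unit OD stain vectors (rows: hematoxylin, eosin, residual)."""

    vectors: np.ndarray
    background_intensity: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ParameterError(f"stain matrix must be 3x3, got {v.shape}")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise ParameterError("stain vectors must be nonzero")
        object.__setattr__(self, "vectors", v / norms[:, None])
        if abs(np.linalg.det(self.vectors)) < 1e-8:
            raise ParameterError("stain vectors are linearly dependent")
        if self.background_intensity <= 0:
            raise ParameterError("background intensity must be positive")

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.vectors[0]

    @property
    def eosin(self) -> np.ndarray:
        return self.vectors[1]

    @property
    def residual(self) -> np.ndarray:
        return self.vectors[2]

    @classmethod
    def reference_he(cls) -> "StainModel":
        """The fixed reference model: published H and E vectors plus their
        normalized cross product as the residual direction."""
        h = np.asarray(_H_RAW) / np.linalg.norm(_H_RAW)
        e = np.asarray(_E_RAW) / np.linalg.norm(_E_RAW)
        r = np.cross(h, e)
        return cls(np.stack([h, e, r / np.linalg.norm(r)]))


@dataclass(frozen=True)
class ConcentrationMaps:
    """Per-pixel dye concentrations (OD units), nonnegative after clipping."""

    c_h: np.ndarray
    c_e: np.ndarray
    c_res: np.ndarray
    clipped_fraction: float = 0.0  # share of negative mass removed by clipping


def rgb_to_od(tile: np.ndarray, background_intensity: float = 1.0) -> np.ndarray:
    """Optical density per channel; values <= the floor are clipped first."""
    tile = np.asarray(tile, dtype=float)
    return -np.log(np.clip(tile, _OD_EPS, None) / background_intensity)


def od_to_rgb(od: np.ndarray, background_intensity: float = 1.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (no clipping)."""
    return background_intensity * np.exp(-np.asarray(od, dtype=float))


def separate_stains(tile: np.ndarray, model: StainModel) -> ConcentrationMaps:
    """Recover H/E/residual concentration maps from an RGB tile.

    Solves ``od = c @ M`` per pixel by inverting the stain matrix ``M``
    (rows = unit stain vectors). Negative concentrations — possible when a
    pixel's color lies outside the stain simplex — are clipped to zero and
    the removed mass is reported as ``clipped_fraction``.
    """
    od = rgb_to_od(tile, model.background_intensity)
    conc = od.reshape(-1, 3) @ np.linalg.inv(model.vectors)
    neg = float(np.clip(conc, None, 0.0).sum())
    total = float(np.abs(conc).sum())
    conc = np.clip(conc, 0.0, None).reshape(od.shape)
    clipped = abs(neg) / total if total > 0 else 0.0
    return ConcentrationMaps(conc[..., 0], conc[..., 1], conc[..., 2], clipped)


def simulate_single_stain(
    maps: ConcentrationMaps, which: str, model: StainModel
) -> np.ndarray:
    """Re-render a tile as if dyed with a single stain.

    ``rgb = I0 * exp(-c_which * v_which)`` per pixel.
    """
    if which == "hematoxylin":
        c, v = maps.c_h, model.hematoxylin
    elif which == "eosin":
        c, v = maps.c_e, model.eosin
    else:
        raise ParameterError(f"unknown stain {which!r}")
    od = np.asarray(c, dtype=float)[..., None] * v
    return od_to_rgb(od, model.background_intensity)


def compose_tile(maps: ConcentrationMaps, model: StainModel) -> np.ndarray:
    """Render the full tile from all three concentration channels."""
    stack = np.stack([maps.c_h, maps.c_e, maps.c_res], axis=-1)
    od = stack.reshape(-1, 3) @ model.vectors
    return od_to_rgb(od.reshape(maps.c_h.shape + (3,)), model.background_intensity)


def normalize_to_reference(
    tile: np.ndarray, estimated: StainModel, reference: StainModel
) -> np.ndarray:
    """Re-render a tile's concentrations under fixed reference vectors.

    Concentrations computed under the tile's own (estimated) stain model are
    recombined with the reference model's vectors, so tiles from different
    staining batches land in one common color frame.
    """
    maps = separate_stains(tile, estimated)
    return compose_tile(maps, reference)


def estimate_stain_model(
    tile: np.ndarray,
    od_floor: float = 0.15,
    angle_percentiles: tuple[float, float] = (1.0, 99.0),
    background_intensity: float = 1.0,
) -> StainModel:
    """Estimate per-tile H&E vectors by the extreme-angle heuristic.

    High-OD pixels are projected onto the plane of their two leading
    singular directions; the extreme angular percentiles of that projection
    are taken as the two stain directions (the more blue-absorbing one is
    labeled eosin). A stand-in for vector detectors whose exact selection
    condition varies between implementations; the pipeline default uses the
    fixed :meth:`StainModel.reference_he` instead.
    """
    od = rgb_to_od(tile, background_intensity).reshape(-1, 3)
    strong = od[np.linalg.norm(od, axis=1) > od_floor]
    if len(strong) < 16:
        raise ParameterError("too few high-OD pixels to estimate stain vectors")
    _, _, vt = np.linalg.svd(strong - 0.0, full_matrices=False)
    basis = vt[:2]
    if basis[0].sum() < 0:
        basis = -basis
    proj = strong @ basis.T
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, angle_percentiles)
    v1 = np.cos(lo) * basis[0] + np.sin(lo) * basis[1]
    v2 = np.cos(hi) * basis[0] + np.sin(hi) * basis[1]
    v1 = np.abs(v1) / np.linalg.norm(v1)
    v2 = np.abs(v2) / np.linalg.norm(v2)
    # Hematoxylin absorbs more red+blue relative to green than eosin does.
    if v1[0] + v1[2] < v2[0] + v2[2]:
        v1, v2 = v2, v1
    r = np.cross(v1, v2)
    return StainModel(
        np.stack([v1, v2, r / np.linalg.norm(r)]), background_intensity
    )
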