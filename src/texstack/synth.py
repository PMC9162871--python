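"""Synthetic cohort, MRI phantom and H&E tile generation.

Stands in for an undeposited clinical cohort: per-patient 3D volumes for
three MRI sequences with anisotropic spacing, an ellipsoidal tumour ROI, and
an RGB histology tile composed through Beer–Lambert mixing of hematoxylin
and eosin concentration fields. The binary prediction target is EGFR status
derived from a simulated immunohistochemistry (IHC) staining percentage.

Class signal is injected through one dial, ``texture_effect``: it scales the
positive class's texture correlation length and amplitude (multiplicatively)
and its lesion axes (additively, toward the configured positive-class axes).
At ``texture_effect = 0`` the two classes are statistically identical — the
null case used to calibrate the downstream pipeline.

Every generator is a pure function of ``(params, seed, patient_id)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .preprocess import RoiMask, Volume
from .stain import ConcentrationMaps, StainModel, compose_tile

__all__ = [
    "CohortRecord",
    "SynthParams",
    "SEQUENCES",
    "generate_cohort",
    "apply_exclusions",
    "ihc_to_status",
    "simulate_mri_case",
    "simulate_he_tile",
]

#: Acquisition grid per sequence: (spacing_mm, shape). All sequences share a
#: 5 mm slice thickness and one field of view; diffusion imaging is coarser
#: in-plane than the fast-spin-echo sequences, as on a clinical scanner.
SEQUENCES: dict[str, tuple[tuple[float, float, float], tuple[int, int, int]]] = {
    "DWI": ((5.0, 1.75, 1.75), (12, 32, 32)),
    "T1FSE": ((5.0, 0.875, 0.875), (12, 64, 64)),
    "T2FSE": ((5.0, 0.875, 0.875), (12, 64, 64)),
}

_SEQUENCE_BACKGROUND = {"DWI": 0.8, "T1FSE": 1.0, "T2FSE": 1.2}

_STREAM_COHORT, _STREAM_MRI, _STREAM_TILE = 0, 1, 2


@dataclass(frozen=True)
class CohortRecord:
    """One patient of the simulated cohort."""

    patient_id: str
    has_complete_sequences: bool
    has_egfr_result: bool
    ihc_percent_positive: float | None = None
    egfr_status: str | None = None  # "positive" / "negative"
    split: str = "unassigned"  # "train" / "test" / "unassigned"
    covariates: dict[str, str] = field(default_factory=dict)

    @property
    def usable(self) -> bool:
        return self.has_complete_sequences and self.has_egfr_result

    @property
    def label(self) -> int:
        if self.egfr_status is None:
            raise ParameterError(f"{self.patient_id} has no EGFR status")
        return int(self.egfr_status == "positive")


@dataclass(frozen=True)
class SynthParams:
    """Cohort- and phantom-generation settings.

    ``lesion_axes_mm`` gives ellipsoid semi-axes per class (negative,
    positive); the positive class's *effective* axes are interpolated from
    the negative class's by ``texture_effect``, so the two classes coincide
    geometrically at zero effect. ``noise_sd`` scales the unstructured voxel
    noise added on top of the smooth texture field.
    """

    n_initial: int = 187
    n_missing_sequences: int = 51
    n_missing_egfr: int = 22
    prevalence: float = 0.6
    texture_effect: float = 1.0
    lesion_axes_mm: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (10.0, 8.0, 7.0),
        (10.4, 8.3, 7.2),
    )
    noise_sd: float = 1.0
    seed: int = 0
    tile_px: int = 96

    def __post_init__(self) -> None:
        if self.n_initial <= 0:
            raise ParameterError("n_initial must be positive")
        if min(self.n_missing_sequences, self.n_missing_egfr) < 0:
            raise ParameterError("exclusion counts must be nonnegative")
        if self.n_missing_sequences + self.n_missing_egfr >= self.n_initial:
            raise ParameterError("exclusions must leave at least one usable patient")
        if not 0.0 < self.prevalence < 1.0:
            raise ParameterError("prevalence must lie in (0, 1)")
        if self.texture_effect < 0:
            raise ParameterError("texture_effect must be nonnegative")
        for axes in self.lesion_axes_mm:
            if any(a <= 0 for a in axes):
                raise ParameterError("lesion axes must be positive")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")


def ihc_to_status(percent_positive: float) -> tuple[str, str]:
    """Map an IHC staining fraction to its grade and binary status.

    Bands: ``< 5%`` → ``-``; ``5–25%`` → ``+``; ``(25, 50]%`` → ``++``;
    ``> 50%`` → ``+++``. Only ``-`` is negative. Boundaries are closed on
    the left at 5% and half-open elsewhere, so every fraction in [0, 1]
    falls in exactly one band.
    """
    p = float(percent_positive)
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"staining fraction must be in [0, 1], got {p}")
    if p < 0.05:
        grade = "-"
    elif p <= 0.25:
        grade = "+"
    elif p <= 0.50:
        grade = "++"
    else:
        grade = "+++"
    return grade, ("negative" if grade == "-" else "positive")


def _rng_for(params: SynthParams, patient_id: str, stream: int) -> np.random.Generator:
    """Independent substream per (seed, patient, stage)."""
    pid_hash = zlib.crc32(patient_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([params.seed, pid_hash, stream]))


def generate_cohort(params: SynthParams) -> list[CohortRecord]:
    """Draw a full cohort, exclusion flags and IHC-derived labels.

    Exactly ``n_missing_sequences`` records lack complete imaging and a
    disjoint ``n_missing_egfr`` lack a distinct EGFR result. Everyone else
    is labeled positive with probability ``prevalence``; the staining
    fraction is drawn uniformly within the label's IHC band so grade and
    status are mutually consistent. Covariates (ER/PR/HER2, stage, nodes)
    are sampled independently of the label.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, _STREAM_COHORT]))
    order = rng.permutation(params.n_initial)
    missing_seq = set(order[: params.n_missing_sequences].tolist())
    missing_egfr = set(
        order[
            params.n_missing_sequences : params.n_missing_sequences + params.n_missing_egfr
        ].tolist()
    )
    records = []
    for i in range(params.n_initial):
        pid = f"P{i + 1:04d}"
        has_egfr = i not in missing_egfr
        percent = None
        status = None
        if has_egfr:
            positive = rng.random() < params.prevalence
            percent = float(rng.uniform(0.05, 1.0) if positive else rng.uniform(0.0, 0.05))
            _, status = ihc_to_status(percent)
        covariates = {
            "ER": rng.choice(["+", "-"]),
            "PR": rng.choice(["+", "-"]),
            "HER2": rng.choice(["+", "-"]),
            "stage": rng.choice(["T1", "T2", "T3", "T4"], p=[0.3, 0.4, 0.2, 0.1]),
            "lymphonodus": rng.choice(["N0", "N1", "N2"], p=[0.5, 0.35, 0.15]),
        }
        records.append(
            CohortRecord(
                patient_id=pid,
                has_complete_sequences=i not in missing_seq,
                has_egfr_result=has_egfr,
                ihc_percent_positive=percent,
                egfr_status=status,
                covariates={k: str(v) for k, v in covariates.items()},
            )
        )
    return records


def apply_exclusions(records: list[CohortRecord]) -> list[CohortRecord]:
    """Keep patients with complete imaging and a distinct EGFR result."""
    return [r for r in records if r.usable]


def _effective_axes(params: SynthParams, label: int) -> np.ndarray:
    neg = np.asarray(params.lesion_axes_mm[0], dtype=float)
    pos = np.asarray(params.lesion_axes_mm[1], dtype=float)
    if label == 0:
        return neg
    return neg + min(params.texture_effect, 1.0) * (pos - neg)


def _smooth_unit_field(
    rng: np.random.Generator, shape: tuple[int, ...], sigma_vox
) -> np.ndarray:
    """Gaussian white noise smoothed to correlation length sigma, unit SD."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def simulate_mri_case(
    record: CohortRecord, params: SynthParams
) -> tuple[dict[str, Volume], RoiMask]:
    """One patient's three MRI volumes and the tumour ROI mask.

    The lesion is an ellipsoid (axes per :func:`_effective_axes`, with mild
    per-patient jitter) centred near the field-of-view middle. Inside it the
    intensity is a smoothed Gaussian random field whose correlation length
    and amplitude grow with ``texture_effect`` for positive patients, plus
    unstructured voxel noise; outside, a smoother low-amplitude background.
    The mask is returned on the DWI grid (the sequence the ROI is drawn on).
    """
    if not record.usable:
        raise ParameterError(f"{record.patient_id} is excluded from imaging")
    rng = _rng_for(params, record.patient_id, _STREAM_MRI)
    label = record.label
    effect = params.texture_effect * label

    fov = np.array([60.0, 56.0, 56.0])
    center = fov / 2.0 + rng.uniform(-2.0, 2.0, size=3)
    axes = _effective_axes(params, label) * rng.uniform(0.94, 1.06, size=3)

    base_sigma_mm = 1.5
    sigma_mm = base_sigma_mm * (1.0 + 0.10 * effect)
    amplitude = params.noise_sd * (1.0 + 0.04 * effect)

    volumes: dict[str, Volume] = {}
    mask: RoiMask | None = None
    for seq, (spacing, shape) in SEQUENCES.items():
        spacing_arr = np.asarray(spacing)
        grids = np.meshgrid(
            *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
        )
        inside = (
            sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes)) <= 1.0
        )
        sigma_vox = sigma_mm / spacing_arr
        texture = _smooth_unit_field(rng, shape, sigma_vox)
        background = 0.3 * _smooth_unit_field(rng, shape, 4.0 / spacing_arr)
        voxel_noise = 0.2 * params.noise_sd * rng.standard_normal(shape)
        data = _SEQUENCE_BACKGROUND[seq] + background + voxel_noise
        data[inside] += 2.0 + amplitude * texture[inside]
        volumes[seq] = Volume(data, spacing, sequence=seq)
        if seq == "DWI":
            mask = RoiMask(inside, spacing)
    assert mask is not None
    return volumes, mask


def simulate_he_tile(
    record: CohortRecord,
    params: SynthParams,
    model: StainModel | None = None,
    return_maps: bool = False,
):
    """One patient's RGB H&E tile (values in [0, 1]).

    Hematoxylin and eosin concentration fields are clipped smoothed Gaussian
    random fields whose correlation length grows with ``texture_effect`` for
    positive patients; the tile is their Beer–Lambert composition under the
    reference stain model, so downstream separation is exactly invertible.
    """
    if not record.usable:
        raise ParameterError(f"{record.patient_id} is excluded from pathology")
    model = model or StainModel.reference_he()
    rng = _rng_for(params, record.patient_id, _STREAM_TILE)
    effect = params.texture_effect * record.label
    shape = (params.tile_px, params.tile_px)

    sigma_h = 2.0 * (1.0 + 0.05 * effect)
    sigma_e = 2.0 * (1.0 + 0.05 * effect)
    c_h = np.clip(
        0.7
        + 0.25 * _smooth_unit_field(rng, shape, sigma_h)
        + 0.10 * rng.standard_normal(shape),
        0.0,
        None,
    )
    c_e = np.clip(
        0.45
        + 0.20 * _smooth_unit_field(rng, shape, sigma_e)
        + 0.08 * rng.standard_normal(shape),
        0.0,
        None,
    )
    maps = ConcentrationMaps(c_h, c_e, np.zeros(shape))
    tile = compose_tile(maps, model)
    if return_maps:
        return tile, maps
    return tile
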