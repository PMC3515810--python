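"""Parameter objects shared across the pipeline stages.

Every dataclass here is plain data: serializable to/from the YAML run
config, validated on construction, and safe to hash into a manifest.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

VALID_BIT_DEPTHS = (8, 12, 16)

#: treatment classes a well may carry
TREATMENT_CLASSES = ("vehicle", "positive_control", "sample", "membrane_blank")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Camera/field geometry of the simulated screening microscope.

    Defaults emulate a spinning-disk high-content reader acquiring at
    300 nm effective pixel size (2x2 binned camera), 16-bit depth.
    """

    field_width_px: int = 512
    field_height_px: int = 512
    pixel_size_nm: float = 300.0
    bit_depth: int = 16
    fields_per_well: int = 2

    def __post_init__(self):
        if self.field_width_px < 128 or self.field_height_px < 128:
            raise ValidationError("field dimensions must be >= 128 px")
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be positive")
        if self.bit_depth not in VALID_BIT_DEPTHS:
            raise ValidationError(f"bit_depth must be one of {VALID_BIT_DEPTHS}")
        if self.fields_per_well < 1:
            raise ValidationError("fields_per_well must be >= 1")

    @property
    def saturation_level(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class CellModel:
    """Geometry and brightness of simulated adherent cells.

    Radii are (mean, sd) in pixels; at 300 nm/px the defaults give a
    ~6 um nucleus inside a ~10 um cell footprint.  ``total_gfp`` is the
    summed receptor signal per cell in photon counts (arbitrary units);
    ``shape_irregularity`` perturbs the elliptical outlines.
    """

    nucleus_radius_px: tuple[float, float] = (10.0, 1.0)
    cell_radius_px: tuple[float, float] = (17.0, 1.5)
    total_gfp: tuple[float, float] = (250_000.0, 25_000.0)
    dna_stain_intensity: tuple[float, float] = (400.0, 40.0)
    shape_irregularity: float = 0.08

    def __post_init__(self):
        for name in ("nucleus_radius_px", "cell_radius_px", "total_gfp",
                     "dna_stain_intensity"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValidationError(f"{name} mean must be > 0 and sd >= 0")
        if self.cell_radius_px[0] <= self.nucleus_radius_px[0]:
            raise ValidationError("cell radius must exceed nucleus radius")
        if not 0 <= self.shape_irregularity < 1:
            raise ValidationError("shape_irregularity must lie in [0, 1)")


@dataclass(frozen=True)
class TranslocationModel:
    """Hill-type mapping from treatment dose to nuclear GFP fraction.

    f(d) = f_min + (f_max - f_min) * d^h / (ec50^h + d^h)

    ``ec50`` is in the same units as layout doses (concentration
    multipliers for water samples, nM-equivalents for hormone controls).
    """

    f_min: float = 0.25
    f_max: float = 0.90
    ec50: float = 10.0
    hill: float = 1.5

    def __post_init__(self):
        if not (0 <= self.f_min < 1 and 0 < self.f_max <= 1):
            raise ValidationError("f_min and f_max must lie in [0, 1]")
        if self.f_max <= self.f_min:
            raise ValidationError("f_max must exceed f_min")
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValidationError("ec50 and hill must be positive")

    def fraction(self, dose) -> np.ndarray | float:
        """Nuclear fraction at ``dose`` (scalar or array, dose >= 0)."""
        d = np.asarray(dose, dtype=float)
        if np.any(d < 0):
            raise ValidationError("dose must be non-negative")
        with np.errstate(divide="ignore"):
            dh = np.where(d > 0, d**self.hill, 0.0)
        f = self.f_min + (self.f_max - self.f_min) * dh / (self.ec50**self.hill + dh)
        return float(f) if np.isscalar(dose) else f


@dataclass(frozen=True)
class NoiseModel:
    """Detection noise: Poisson shot noise, Gaussian read noise, Gaussian PSF.

    Each term is independently switchable so tests can walk a ladder from
    the analytic noise-free image to a realistic one.
    """

    background_level: float = 20.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    psf_sigma_px: float = 0.8

    def __post_init__(self):
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValidationError("background_level and read_noise_sd must be >= 0")
        if self.psf_sigma_px < 0:
            raise ValidationError("psf_sigma_px must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(background_level=0.0, read_noise_sd=0.0,
                   shot_noise=False, psf_sigma_px=0.0)


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs for nucleus and cytoplasm segmentation."""

    nucleus_min_area_px: int = 80
    nucleus_max_area_px: int = 2500
    smoothing_sigma_px: float = 1.0
    split_touching: bool = True
    split_min_distance_px: int = 7
    cyto_max_expand_px: int = 12
    border_policy: str = "exclude"

    def __post_init__(self):
        if not 0 < self.nucleus_min_area_px < self.nucleus_max_area_px:
            raise ValidationError("need 0 < nucleus_min_area_px < nucleus_max_area_px")
        if self.smoothing_sigma_px < 0:
            raise ValidationError("smoothing_sigma_px must be >= 0")
        if self.cyto_max_expand_px < 1:
            raise ValidationError("cyto_max_expand_px must be >= 1")
        if self.border_policy not in ("exclude", "keep"):
            raise ValidationError("border_policy must be 'exclude' or 'keep'")


@dataclass(frozen=True)
class QCPolicy:
    """Per-cell quality-control thresholds used by the quantify stage."""

    min_nucleus_area_px: int = 50
    min_cytoplasm_area_px: int = 20
    nucleus_erosion_px: int = 2
    boundary_gap_px: int = 2
    cell_edge_erosion_px: int = 4
    exclude_border: bool = True
    saturation_level: float | None = None
    low_signal_mean: float = 1.0
    background_policy: str = "median"  # 'median' or 'none'

    def __post_init__(self):
        if self.background_policy not in ("median", "none"):
            raise ValidationError("background_policy must be 'median' or 'none'")


def asdict_flat(obj) -> dict:
    """Dataclass -> plain dict (tuples become lists) for YAML round-trip."""
    def conv(v):
        if isinstance(v, tuple):
            return list(v)
        return v
    return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
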