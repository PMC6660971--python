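"""Synthetic CT-like nodule cohorts with known ground truth.

Emulates the data the analysis assumes: sub-2 cm lung nodules on anisotropic
CT grids (in-plane 0.49-0.9 mm, slice 0.625-5 mm), HU-scaled intensities with
ground-glass vs. solid density profiles, a sigmoid margin of configurable
width, spatially correlated intra-nodule texture, class-linked effects on
intensity/margin/texture/size, and a sub-population of very small nodules
that makes neighbourhood-based texture features fail downstream.

All randomness flows through one explicit ``numpy.random.Generator``; the
same seed reproduces a bit-identical cohort.  No attempt is made to simulate
reconstruction kernels, dose, or lung anatomy (vessels, pleura).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from radrep.errors import ConfigError, SizingError
from radrep.io import write_image
from radrep.preprocess import ImageCase

BACKGROUND_HU = -850.0  # aerated lung parenchyma
GGO_CORE_HU = -600.0  # pure ground-glass density
SOLID_CORE_HU = 20.0  # solid soft-tissue density

_SHAPES = ("sphere", "ellipsoid", "lobulated")
_SHELL_FRACTION = 0.35  # GGO shell thickness as a fraction of the radius
_INTERFACE_MM = 0.8  # width of the GGO-to-solid density interface
# ellipsoid semi-axis factors; product 1 so the equivalent diameter is exact
_ELLIPSOID_FACTORS = np.array([1.25, 1.0, 0.8])


@dataclass(frozen=True)
class NoduleSpec:
    """Ground-truth description of one synthetic nodule.

    ``center`` is in physical mm, ``equivalent_diameter`` is the diameter of
    the volume-equivalent sphere (capped at 20 mm: only sub-2 cm nodules are
    in scope), ``core_intensity`` the solid-core HU, ``ggo_fraction`` blends
    the core toward pure ground-glass density, ``margin_width`` the 10-90%
    sigmoid transition width in mm, and ``texture_amplitude`` the SD in HU of
    the correlated intra-nodule texture field.
    """

    center: tuple[float, float, float]
    equivalent_diameter: float
    shape_class: str = "sphere"
    core_intensity: float = SOLID_CORE_HU
    ggo_fraction: float = 0.0
    margin_width: float = 1.0
    texture_amplitude: float = 40.0
    status: str = "benign"

    def __post_init__(self) -> None:
        if not 0.0 < self.equivalent_diameter <= 20.0:
            raise ConfigError(
                f"equivalent_diameter must be in (0, 20] mm, got {self.equivalent_diameter}"
            )
        if self.shape_class not in _SHAPES:
            raise ConfigError(f"unknown shape_class {self.shape_class!r}")
        if not 0.0 <= self.ggo_fraction <= 1.0:
            raise ConfigError("ggo_fraction must be in [0, 1]")
        if self.margin_width < 0 or self.texture_amplitude < 0:
            raise ConfigError("margin_width and texture_amplitude must be >= 0")

    @property
    def core_hu(self) -> float:
        """Density of the solid core (the rim tends to GGO per ggo_fraction)."""
        return self.core_intensity

    @property
    def analytic_volume(self) -> float:
        """Volume (mm^3) of the requested shape at the equivalent diameter."""
        return 4.0 / 3.0 * np.pi * (self.equivalent_diameter / 2.0) ** 3


def _pseudo_distance(spec: NoduleSpec, coords: list[np.ndarray]) -> np.ndarray:
    """Signed distance-like field: positive inside the nodule, in ~mm."""
    r = spec.equivalent_diameter / 2.0
    dx = [c - ctr for c, ctr in zip(coords, spec.center)]
    if spec.shape_class == "sphere":
        rho = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2) / r
    elif spec.shape_class == "ellipsoid":
        a = _ELLIPSOID_FACTORS * r
        rho = np.sqrt((dx[0] / a[0]) ** 2 + (dx[1] / a[1]) ** 2 + (dx[2] / a[2]) ** 2)
    else:  # lobulated: sphere + low-order spherical-harmonic radial perturbation
        dist = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = [np.where(dist > 0, d / np.where(dist > 0, dist, 1.0), 0.0) for d in dx]
        perturb = (
            0.15 * (u[0] ** 2 - u[1] ** 2)
            + 0.12 * 0.5 * (3.0 * u[2] ** 2 - 1.0)
            + 0.10 * 2.0 * u[0] * u[1]
        )
        rho = dist / (r * (1.0 + perturb))
    return (1.0 - rho) * r


def generate_case(
    spec: NoduleSpec,
    spacing,
    grid_shape,
    noise_sd: float = 20.0,
    rng: np.random.Generator | None = None,
    texture_scale_mm: float = 1.5,
    case_id: str = "synthetic",
) -> ImageCase:
    """Rasterize one nodule into a noisy CT-like volume with an exact mask.

    The nodule is part-solid: a solid core of density ``core_intensity``
    surrounded by a homogeneous ground-glass shell whose density is the
    ggo_fraction-weighted blend of solid and pure-GGO values, emulating the
    core-plus-GGO structure of sub-solid lung nodules.  The
    intensity then transitions to lung background through a logistic sigmoid
    in the signed distance to the surface with 10-90% width ``margin_width``;
    correlated texture (Gaussian-smoothed white noise at ``texture_scale_mm``)
    is added inside the nodule, and iid Gaussian noise of ``noise_sd`` HU
    everywhere.

    Raises :class:`SizingError` if the nodule plus a 5 mm margin does not fit
    in the grid.
    """
    rng = np.random.default_rng() if rng is None else rng
    spacing = tuple(float(s) for s in spacing)
    grid_shape = tuple(int(n) for n in grid_shape)
    r_max = spec.equivalent_diameter / 2.0 * float(_ELLIPSOID_FACTORS.max() + 0.2)
    extent = [(n - 1) * s for n, s in zip(grid_shape, spacing)]
    for c, e in zip(spec.center, extent):
        if c - r_max < 5.0 - 1e-9 or c + r_max > e - 5.0 + 1e-9:
            raise SizingError(
                f"nodule (radius ~{r_max:.1f} mm) + 5 mm margin does not fit grid "
                f"extent {extent} mm at center {spec.center}"
            )

    coords = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(grid_shape, spacing)), indexing="ij"
    )
    d = _pseudo_distance(spec, coords)
    mask = d >= 0.0

    if spec.margin_width > 0:
        # logistic with 10-90% transition width = margin_width
        k = 2.0 * np.log(9.0) / spec.margin_width
        w = 1.0 / (1.0 + np.exp(np.clip(-k * d, -500, 500)))
    else:
        w = mask.astype(float)

    # part-solid density profile: a homogeneous ground-glass shell at a
    # case-specific density (set by ggo_fraction) around a solid core, with
    # a narrow interface, so the ROI extremes are tissue plateaus rather
    # than noise extremes
    rim_hu = (1.0 - spec.ggo_fraction) * spec.core_hu + spec.ggo_fraction * GGO_CORE_HU
    shell = _SHELL_FRACTION * spec.equivalent_diameter / 2.0
    interface = np.clip((d - shell) / _INTERFACE_MM, 0.0, 1.0)
    density = rim_hu + (spec.core_hu - rim_hu) * interface
    volume = BACKGROUND_HU + (density - BACKGROUND_HU) * w

    # correlated texture first, then iid noise: fixed draw order for determinism
    if spec.texture_amplitude > 0:
        sigma_vox = [texture_scale_mm / s for s in spacing]
        field = ndimage.gaussian_filter(rng.standard_normal(grid_shape), sigma=sigma_vox)
        sd = field.std()
        if sd > 0:
            volume += spec.texture_amplitude * w * field / sd
    if noise_sd > 0:
        volume += rng.normal(0.0, noise_sd, size=grid_shape)

    return ImageCase(case_id=case_id, volume=volume, mask=mask.astype(np.uint8),
                     spacing=spacing, status=spec.status)


@dataclass
class ClassEffects:
    """Additive malignant-class offsets on the planted nodule parameters."""

    diameter: float = 2.0  # mm
    core_intensity: float = 60.0  # HU
    margin_width: float = -0.6  # mm (malignant margins sharper)
    texture_amplitude: float = 30.0  # HU
    ggo_fraction: float = -0.15


#: strongly separated classes: large planted effects on size, density,
#: margin sharpness and texture, for validation runs where the classifier
#: is expected to succeed
WELL_SEPARATED = ClassEffects(diameter=3.0, core_intensity=120.0,
                              margin_width=-0.8, texture_amplitude=60.0,
                              ggo_fraction=-0.25)


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a small-nodule lung-CT screening cohort: anisotropic
    voxels (in-plane 0.49-0.9 mm, slice 1-2.5 mm), diameters centred near
    12 mm and capped at 20 mm, ~72% malignant prevalence, and a quarter of
    cases drawn very small so neighbourhood texture features fail.
    """

    n_cases: int = 180
    class_balance: float = 129.0 / 180.0  # fraction malignant
    spacing_range_inplane: tuple[float, float] = (0.49, 0.9)
    spacing_range_slice: tuple[float, float] = (1.0, 2.5)
    diameter_mean: float = 12.0
    diameter_sd: float = 3.0
    diameter_bounds: tuple[float, float] = (5.0, 19.5)
    small_nodule_fraction: float = 0.25
    small_diameter_bounds: tuple[float, float] = (3.5, 6.0)
    effects: ClassEffects = field(default_factory=ClassEffects)
    ggo_fraction_mean: float = 0.3
    margin_width_mean: float = 1.5
    texture_amplitude_mean: float = 40.0
    noise_sd: float = 20.0
    texture_scale_mm: float = 1.5
    margin_mm: float = 8.0  # grid padding around the nodule
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.spacing_range_inplane
        if not (0.49 - 1e-9 <= lo <= hi <= 0.9 + 1e-9):
            raise ConfigError("in-plane spacing range must lie within [0.49, 0.9] mm")
        lo, hi = self.spacing_range_slice
        if not (0.625 - 1e-9 <= lo <= hi <= 5.0 + 1e-9):
            raise ConfigError("slice spacing range must lie within [0.625, 5] mm")
        if self.n_cases < 2:
            raise ConfigError("n_cases must be >= 2")
        if 0.0 < self.class_balance < 1.0:
            n_mal = int(round(self.n_cases * self.class_balance))
            if n_mal == 0 or n_mal == self.n_cases:
                raise ConfigError(
                    f"class_balance {self.class_balance} yields a single class at n={self.n_cases}"
                )


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def generate_cohort(config: CohortConfig) -> tuple[list[ImageCase], pd.DataFrame]:
    """Draw a full cohort; returns the cases and a ground-truth table.

    The truth table records every planted nodule parameter (one column per
    :class:`NoduleSpec` field plus spacing and the small-nodule flag) so that
    downstream selections can be compared against the planted effects.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_cases
    n_mal = int(round(n * config.class_balance))
    statuses = np.array(["malignant"] * n_mal + ["benign"] * (n - n_mal))
    rng.shuffle(statuses)
    n_small = int(round(n * config.small_nodule_fraction))
    small = np.zeros(n, dtype=bool)
    small[rng.permutation(n)[:n_small]] = True

    eff = config.effects
    cases: list[ImageCase] = []
    rows = []
    for i in range(n):
        status = str(statuses[i])
        is_mal = status == "malignant"
        sp_in = rng.uniform(*config.spacing_range_inplane)
        sp_sl = rng.uniform(*config.spacing_range_slice)
        spacing = (sp_in, sp_in, sp_sl)

        if small[i]:
            diameter = rng.uniform(*config.small_diameter_bounds)
        else:
            mean_d = config.diameter_mean + (eff.diameter if is_mal else 0.0)
            diameter = _truncated_normal(rng, mean_d, config.diameter_sd,
                                         *config.diameter_bounds)
        core = SOLID_CORE_HU + (eff.core_intensity if is_mal else 0.0) + rng.normal(0, 15)
        ggo = float(np.clip(config.ggo_fraction_mean
                            + (eff.ggo_fraction if is_mal else 0.0)
                            + rng.normal(0, 0.1), 0.0, 1.0))
        margin = max(0.1, config.margin_width_mean
                     + (eff.margin_width if is_mal else 0.0) + rng.normal(0, 0.3))
        texture = max(0.0, config.texture_amplitude_mean
                      + (eff.texture_amplitude if is_mal else 0.0) + rng.normal(0, 8))
        shape_class = _SHAPES[rng.integers(0, 3)] if not small[i] else "sphere"

        r_max = diameter / 2.0 * float(_ELLIPSOID_FACTORS.max() + 0.2)
        half = r_max + config.margin_mm
        grid_shape = tuple(
            int(np.ceil(2 * half / s)) + 1 for s in spacing
        )
        center = tuple(
            (g - 1) * s / 2.0 + rng.uniform(-0.5, 0.5) * s
            for g, s in zip(grid_shape, spacing)
        )
        spec = NoduleSpec(center=center, equivalent_diameter=diameter,
                          shape_class=shape_class, core_intensity=core,
                          ggo_fraction=ggo, margin_width=margin,
                          texture_amplitude=texture, status=status)
        case_id = f"case_{i:04d}"
        case = generate_case(spec, spacing, grid_shape, noise_sd=config.noise_sd,
                             rng=rng, texture_scale_mm=config.texture_scale_mm,
                             case_id=case_id)
        cases.append(case)
        row = {"case_id": case_id, "status": status, "small_nodule": bool(small[i]),
               "spacing_x": spacing[0], "spacing_y": spacing[1], "spacing_z": spacing[2]}
        row.update({k: v for k, v in asdict(spec).items() if k not in ("center", "status")})
        row["center_x"], row["center_y"], row["center_z"] = spec.center
        row["analytic_volume_mm3"] = spec.analytic_volume
        rows.append(row)

    truth = pd.DataFrame(rows).set_index("case_id")
    return cases, truth


def save_cohort(cases: list[ImageCase], truth: pd.DataFrame, out_dir, fmt: str = "nrrd") -> None:
    """Write each case as <id>_image/<id>_mask plus a truth-table CSV."""
    os.makedirs(out_dir, exist_ok=True)
    ext = {"nrrd": ".nrrd", "nifti": ".nii.gz"}[fmt]
    for case in cases:
        write_image(case.volume, case.spacing, os.path.join(out_dir, case.case_id + "_image" + ext))
        write_image(case.mask.astype(np.uint8), case.spacing,
                    os.path.join(out_dir, case.case_id + "_mask" + ext))
    truth.to_csv(os.path.join(out_dir, "truth.csv"))
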