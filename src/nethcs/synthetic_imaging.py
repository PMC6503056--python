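"""Seeded synthetic plates: images plus ground truth for every stage.

No public image data exist for this assay, so the simulator is the
package's benchmark substrate. It emulates the three nuclear phenotypes the
assay discriminates:

* **resting** — 3-5 partially overlapping bright lobes (the neutrophil's
  segmented nucleus);
* **netotic** — a single grossly enlarged, dim, diffuse chromatin region
  with an irregular, filamentous margin (lytic NET formation);
* **apoptotic** — a single small, compact, very bright nucleus (condensed
  chromatin).

and the assay's population-level phenomenology: spontaneous NETosis at
about 1%, stimulus- and time-dependent induction reaching about 70%
(ionomycin fast, ~45-90 min; PMA slow, ~210 min), Hill-type dose-dependent
inhibition by test compounds, a 6-fold cytosolic-ROS rise plateauing in
about an hour under PMA, and TMRM accumulation curves with uncoupler
(CCCP-like) depolarization.

Every preset constant is a named module-level value, not a buried literal,
so downstream recovery checks are auditable. All randomness flows through
``numpy.random.Generator`` seeded explicitly; the same seed and config give
bit-identical images and truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

from nethcs.plate_io import CellRecord, FieldImage, PlateLayout, WellSpec

PHENOTYPES = ("resting", "netotic", "apoptotic")

# --- phenotype rendering calibration ---------------------------------------
# Nuclear areas bracket the human neutrophil nucleus (~30-50 µm²); the
# netotic region is enlarged by CHROMATIN_SPREAD; apoptotic nuclei are
# smaller but brighter than resting ones.
RESTING_AREA_UM2 = 42.0
RESTING_AREA_SD = 6.0
RESTING_PEAK = 2600.0
RESTING_PEAK_SD = 280.0
NETOTIC_SPREAD = 3.0          # netotic mean area = spread x resting mean
NETOTIC_AREA_CV = 0.22
NETOTIC_PEAK = 1100.0
NETOTIC_PEAK_SD = 140.0
APOPTOTIC_AREA_UM2 = 20.0
APOPTOTIC_AREA_SD = 3.0
APOPTOTIC_PEAK = 4400.0
APOPTOTIC_PEAK_SD = 420.0

MASK_LEVEL = 0.12             # profile level defining the ground-truth mask

# --- population / response-law calibration ---------------------------------
BASELINE_NETOTIC_FRAC = 0.01      # spontaneous NETosis (vehicle wells)
BACKGROUND_APOPTOTIC_FRAC = 0.02  # spontaneous apoptosis in every well

# Saturating-exponential induction induced(t) = fmax*(1 - exp(-t/tau)).
# Ionomycin is calibrated to two anchors: ~63% NETotic at 45 min (fast,
# "> 60%") and 70% at the screen's 90-min endpoint. PMA is slow: 70% at the
# 210-min endpoint.
ION_ANCHOR = ((45.0, 0.63), (90.0, 0.70))
_x = ION_ANCHOR[1][1] / ION_ANCHOR[0][1] - 1.0          # exp(-t1/tau)
ION_TAU_MIN = ION_ANCHOR[0][0] / math.log(1.0 / _x)
ION_FMAX = ION_ANCHOR[1][1] / (1.0 - _x**2)
PMA_FMAX = 0.72
PMA_ANCHOR = (210.0, 0.70)
PMA_TAU_MIN = PMA_ANCHOR[0] / math.log(1.0 / (1.0 - PMA_ANCHOR[1] / PMA_FMAX))

# "Capsaicin-like" reference inhibitor: EC50 in the low-micromolar range
# with complete inhibition at 5 µM.
CAPSAICIN_LIKE_EC50_UM = 1.5
CAPSAICIN_LIKE_HILL = 2.0
CAPSAICIN_LIKE_MAX_INHIBITION = 1.0

# Inter-well variability: the well's true NETotic fraction is jittered with
# a Beta distribution of this concentration (larger = tighter).
WELL_JITTER_CONCENTRATION = 1000.0

# --- kinetic presets --------------------------------------------------------
ROS_PMA_PLATEAU_FOLD = 6.0    # peak fold-change of DCF signal under PMA
ROS_PMA_TAU_MIN = 20.0        # 95%-of-plateau time = -tau*ln(0.05) = 59.9 min
ROS_QUIET_PLATEAU_FOLD = 1.1  # vehicle / ionomycin: essentially flat
ROS_QUIET_TAU_MIN = 40.0
ROS_NOISE_SD = 0.15           # additive Gaussian, fold units, per timepoint
ROS_T_MAX_MIN = 120.0

TMRM_PLATEAU_FOLD = 4.0
TMRM_TAU_MIN = 15.0
TMRM_INTACT_D = 1.0           # depolarization scale: 1 = intact mitochondria
TMRM_UNCOUPLED_D = 0.2        # CCCP / ionomycin / alexidine
TMRM_NOISE_SD = 0.12
TMRM_T_MAX_MIN = 60.0


@dataclass(frozen=True)
class PhenotypeParams:
    """Rendering parameters for one nuclear phenotype."""

    phenotype: str
    nucleus_area: float          # mean, µm²
    nucleus_area_sd: float
    peak_intensity: float        # mean, native units above background
    peak_intensity_sd: float
    lobe_count: tuple[int, int] = (3, 5)   # resting only, inclusive range
    chromatin_spread: float = 1.0          # netotic enlargement factor
    texture_granularity: float = 0.25      # speckle contrast inside mask
    texture_scale_px: float = 1.5          # speckle correlation length

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


RESTING_PRESET = PhenotypeParams(
    "resting", RESTING_AREA_UM2, RESTING_AREA_SD, RESTING_PEAK, RESTING_PEAK_SD,
    lobe_count=(3, 5), texture_granularity=0.22, texture_scale_px=1.5,
)
NETOTIC_PRESET = PhenotypeParams(
    "netotic", NETOTIC_SPREAD * RESTING_AREA_UM2,
    NETOTIC_AREA_CV * NETOTIC_SPREAD * RESTING_AREA_UM2,
    NETOTIC_PEAK, NETOTIC_PEAK_SD,
    chromatin_spread=NETOTIC_SPREAD, texture_granularity=0.10,
    texture_scale_px=3.0,
)
APOPTOTIC_PRESET = PhenotypeParams(
    "apoptotic", APOPTOTIC_AREA_UM2, APOPTOTIC_AREA_SD,
    APOPTOTIC_PEAK, APOPTOTIC_PEAK_SD,
    texture_granularity=0.45, texture_scale_px=1.0,
)
DEFAULT_PRESETS: dict[str, PhenotypeParams] = {
    "resting": RESTING_PRESET,
    "netotic": NETOTIC_PRESET,
    "apoptotic": APOPTOTIC_PRESET,
}

# sanity: preset calibration respects the phenotype ordering invariants
assert APOPTOTIC_PRESET.nucleus_area < RESTING_PRESET.nucleus_area < NETOTIC_PRESET.nucleus_area
assert APOPTOTIC_PRESET.peak_intensity > RESTING_PRESET.peak_intensity > NETOTIC_PRESET.peak_intensity


@dataclass(frozen=True)
class InhibitionParams:
    """Hill inhibition of NETosis induction by a test compound."""

    ec50_um: float = CAPSAICIN_LIKE_EC50_UM
    hill_coef: float = CAPSAICIN_LIKE_HILL
    max_inhibition: float = CAPSAICIN_LIKE_MAX_INHIBITION

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_inhibition <= 1.0:
            raise ValueError("max_inhibition must be in [0, 1]")
        if self.ec50_um <= 0:
            raise ValueError("ec50_um must be > 0")

    def inhibition(self, conc_um: float) -> float:
        """Fractional inhibition at concentration ``conc_um`` (µM)."""
        if conc_um < 0:
            raise ValueError("concentration must be >= 0")
        if conc_um == 0:
            return 0.0
        c = conc_um**self.hill_coef
        return self.max_inhibition * c / (c + self.ec50_um**self.hill_coef)


CAPSAICIN_LIKE = InhibitionParams()


@dataclass(frozen=True)
class ResponseLaw:
    """Stimulus-, time-, and dose-dependent true NETotic fraction.

    ``induced_frac(stimulus, t)`` follows a saturating exponential per
    stimulus; a test compound reduces the induced component by its Hill
    inhibition. The well's true fraction is::

        f = baseline + (induced(t) - baseline) * (1 - inhibition(c))
    """

    baseline_frac: float = BASELINE_NETOTIC_FRAC
    pma_fmax: float = PMA_FMAX
    pma_tau: float = PMA_TAU_MIN
    ion_fmax: float = ION_FMAX
    ion_tau: float = ION_TAU_MIN
    t_max: float = 600.0

    def induced_frac(self, stimulus: str, t_min: float) -> float:
        if not 0.0 <= t_min <= self.t_max:
            raise ValueError(f"timepoint {t_min} min outside law domain [0, {self.t_max}]")
        if stimulus == "none":
            return self.baseline_frac
        if stimulus == "PMA":
            fmax, tau = self.pma_fmax, self.pma_tau
        elif stimulus == "ionomycin":
            fmax, tau = self.ion_fmax, self.ion_tau
        else:
            raise ValueError(f"unknown stimulus {stimulus!r}")
        return max(self.baseline_frac, fmax * (1.0 - math.exp(-t_min / tau)))

    def well_fraction(
        self, well: WellSpec, compound_params: Mapping[str, InhibitionParams | None]
    ) -> float:
        """True NETotic fraction for a well given each compound's potency."""
        induced = self.induced_frac(well.stimulus, well.timepoint_min)
        inhibition = 0.0
        if well.compound_id:
            if well.compound_id not in compound_params:
                raise KeyError(f"no inhibition parameters for compound {well.compound_id!r}")
            p = compound_params[well.compound_id]
            if p is not None:
                inhibition = p.inhibition(well.compound_conc)
        return self.baseline_frac + (induced - self.baseline_frac) * (1.0 - inhibition)


DEFAULT_RESPONSE_LAW = ResponseLaw()


@dataclass(frozen=True)
class KineticPreset:
    """Exponential-approach kinetics: fold(t) = 1 + d*(A-1)*(1-exp(-t/tau)).

    ``d`` is the depolarization/attenuation scale (TMRM: 1 = intact,
    0.2 = uncoupled); for ROS presets d is 1.
    """

    plateau_fold: float
    tau_min: float
    d: float = 1.0

    def value(self, t_min):
        t = np.asarray(t_min, dtype=float)
        return 1.0 + self.d * (self.plateau_fold - 1.0) * (1.0 - np.exp(-t / self.tau_min))


ROS_PMA_PRESET = KineticPreset(ROS_PMA_PLATEAU_FOLD, ROS_PMA_TAU_MIN)
ROS_VEHICLE_PRESET = KineticPreset(ROS_QUIET_PLATEAU_FOLD, ROS_QUIET_TAU_MIN)
ROS_IONOMYCIN_PRESET = ROS_VEHICLE_PRESET
TMRM_VEHICLE_PRESET = KineticPreset(TMRM_PLATEAU_FOLD, TMRM_TAU_MIN, d=TMRM_INTACT_D)
TMRM_UNCOUPLED_PRESET = KineticPreset(TMRM_PLATEAU_FOLD, TMRM_TAU_MIN, d=TMRM_UNCOUPLED_D)


@dataclass
class KineticTrace:
    """A sampled kinetic time course (times in minutes, values in fold units)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, density, and noise of simulated fields.

    Defaults: 512x512 px fields at 0.5 µm/px (a 256 µm square field),
    4 fields per well, 16-bit camera with a flat background offset,
    Poisson-like shot noise, and Gaussian read noise.
    """

    field_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.5          # µm / pixel
    fields_per_well: int = 4
    cells_per_field: int = 200
    background: float = 120.0        # camera offset, native units
    photon_gain: float = 4.0         # native units per photon (shot noise)
    read_noise_sd: float = 6.0
    separation_factor: float = 1.05  # min center distance / (r_i + r_j)
    bit_depth: int = 16
    apoptotic_frac: float = BACKGROUND_APOPTOTIC_FRAC
    jitter_concentration: float = WELL_JITTER_CONCENTRATION


DEFAULT_CONFIG = SimulationConfig()


# ---------------------------------------------------------------------------
# Nucleus rendering


def _speckle(shape, granularity, scale_px, rng):
    """Multiplicative chromatin texture: smoothed unit-sd noise, clipped."""
    if granularity <= 0:
        return np.ones(shape)
    noise = ndi.gaussian_filter(rng.standard_normal(shape), scale_px)
    sd = noise.std()
    if sd > 0:
        noise /= sd
    return np.clip(1.0 + granularity * noise, 0.05, None)


def _super_gaussian(rr, cc, center, semi_axes, theta, level=MASK_LEVEL):
    """Flat-topped elliptical profile equal to ``level`` on the ellipse."""
    dr, dc = rr - center[0], cc - center[1]
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    q = (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2
    return np.exp(math.log(level) * q**2)


def render_nucleus(
    params: PhenotypeParams,
    rng: np.random.Generator | int,
    pixel_size: float = DEFAULT_CONFIG.pixel_size,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one nucleus; returns ``(intensity_patch, mask_patch)``.

    The intensity patch is noise-free signal above background (float);
    the boolean mask is the ground-truth object footprint (the profile
    above ``MASK_LEVEL`` of peak, filled).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    area_um2 = max(4.0, rng.normal(params.nucleus_area, params.nucleus_area_sd))
    area_px = area_um2 / pixel_size**2
    peak = max(50.0, rng.normal(params.peak_intensity, params.peak_intensity_sd))

    if params.phenotype == "resting":
        profile = _render_lobed(area_px, params, rng)
    elif params.phenotype == "netotic":
        profile = _render_diffuse(area_px, rng)
    elif params.phenotype == "apoptotic":
        profile = _render_compact(area_px, rng)
    else:  # unreachable: PhenotypeParams validates
        raise ValueError(f"unknown phenotype {params.phenotype!r}")

    mask = profile > MASK_LEVEL
    mask = ndi.binary_fill_holes(mask)
    # keep the largest connected component (filaments may pinch off specks)
    lbl, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum_labels(mask, lbl, index=np.arange(1, n + 1))
        mask = lbl == (1 + int(np.argmax(sizes)))
    # chromatin texture modulates chromatin: the speckle is weighted by the
    # profile so it fades out at the mask boundary and the rendered signal
    # stays consistent with the ground-truth footprint
    speckle = _speckle(profile.shape, params.texture_granularity,
                       params.texture_scale_px, rng)
    weight = np.clip((profile - MASK_LEVEL) / (2.0 * MASK_LEVEL), 0.0, 1.0)
    patch = profile * (1.0 + (speckle - 1.0) * weight)
    patch *= peak / max(patch.max(), 1e-9)
    return patch, mask


def _render_lobed(area_px: float, params: PhenotypeParams, rng) -> np.ndarray:
    """Resting nucleus: 3-5 partially overlapping elongated lobes."""
    lo, hi = params.lobe_count
    k = int(rng.integers(lo, hi + 1))
    # initial lobe size guess; corrected once after measuring the union
    lobe_area = area_px / (0.72 * k)  # overlap eats ~28%
    a = math.sqrt(lobe_area / (math.pi * 0.68))  # semi-major (elong 0.68)
    profile = _compose_lobes(a, k, rng)
    measured = float((profile > MASK_LEVEL).sum())
    if measured > 0:
        a *= math.sqrt(area_px / measured)
        profile = _compose_lobes(a, k, rng, reuse=rng)
    return profile


def _compose_lobes(a: float, k: int, rng, reuse=None) -> np.ndarray:
    # ring radius well under the lobe size keeps the lobe union connected
    # at the mask level for any placement jitter
    elong = 0.68
    ring = 0.78 * a
    half = int(math.ceil(ring + 2.2 * a)) + 2
    n = 2 * half + 1
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    center = (half, half)
    base_angle = rng.uniform(0, 2 * math.pi)
    profile = np.zeros((n, n))
    for i in range(k):
        ang = base_angle + 2 * math.pi * i / k + rng.normal(0, 0.18)
        rad = ring * (1 + rng.normal(0, 0.10))
        cen = (center[0] + rad * math.sin(ang), center[1] + rad * math.cos(ang))
        axes = (a * (1 + rng.normal(0, 0.08)), elong * a * (1 + rng.normal(0, 0.08)))
        theta = ang + math.pi / 2 + rng.normal(0, 0.2)
        amp = 1.0 + rng.normal(0, 0.08)
        profile = np.maximum(profile, amp * _super_gaussian(rr, cc, cen, axes, theta))
    return profile / max(profile.max(), 1e-9)


def _render_diffuse(area_px: float, rng) -> np.ndarray:
    """NETotic chromatin: large dim flat-topped region, irregular
    filamentous margin."""
    r0 = math.sqrt(area_px / math.pi)
    modes = rng.integers(3, 9, size=3)
    amps = rng.uniform(0.04, 0.10, size=3)
    phases = rng.uniform(0, 2 * math.pi, size=3)
    r_margin = r0 * (1 + amps.sum())
    half = int(math.ceil(1.6 * r_margin)) + 3
    n = 2 * half + 1
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    dr, dc = rr - half, cc - half
    r = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    radius = r0 * (1 + sum(a * np.cos(m * theta + p)
                           for a, m, p in zip(amps, modes, phases)))
    profile = np.exp(math.log(MASK_LEVEL) * (r / np.maximum(radius, 1.0)) ** 4)
    # filament strokes reaching outward from the margin
    for _ in range(int(rng.integers(2, 5))):
        ang = rng.uniform(0, 2 * math.pi)
        length = rng.uniform(0.25, 0.5) * r0
        bend = rng.normal(0, 0.5)
        t = np.linspace(0, 1, max(8, int(2 * length)))
        rad_t = 0.92 * r0 + length * t
        ang_t = ang + bend * t**2 * 0.3
        pr = half + rad_t * np.sin(ang_t)
        pc = half + rad_t * np.cos(ang_t)
        stroke = np.zeros((n, n))
        ir, ic = np.round(pr).astype(int), np.round(pc).astype(int)
        ok = (ir >= 0) & (ir < n) & (ic >= 0) & (ic < n)
        stroke[ir[ok], ic[ok]] = 1.0
        stroke = ndi.gaussian_filter(stroke, 1.1)
        if stroke.max() > 0:
            profile = np.maximum(profile, 0.35 * stroke / stroke.max())
    return profile


def _render_compact(area_px: float, rng) -> np.ndarray:
    """Apoptotic nucleus: small, compact, nearly round."""
    r0 = math.sqrt(area_px / math.pi)
    ecc = 1 + abs(rng.normal(0, 0.10))
    axes = (r0 * ecc, r0 / ecc)
    half = int(math.ceil(1.5 * max(axes))) + 2
    n = 2 * half + 1
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    return _super_gaussian(rr, cc, (half, half), axes, rng.uniform(0, math.pi))


# ---------------------------------------------------------------------------
# Field and plate simulation


def _place_cells(radii, shape, halves, sep_factor, rng):
    """Rejection-sample centers so masks stay inside the field and apart.

    Returns centers in placement order. The minimum center distance is
    ``sep_factor * (r_i + r_j) + 2`` px; after repeated failures the factor
    relaxes by 10% per round so dense fields still fill (at the cost of
    closer packing, mimicking real crowding).
    """
    n = len(radii)
    centers = np.empty((n, 2))
    placed_r = np.asarray(radii, dtype=float)
    for i in range(n):
        margin_r, margin_c = halves[i]
        lo_r, hi_r = margin_r, shape[0] - margin_r - 1
        lo_c, hi_c = margin_c, shape[1] - margin_c - 1
        if lo_r >= hi_r or lo_c >= hi_c:
            raise ValueError("field too small for the requested nucleus size")
        factor = sep_factor
        for attempt in range(1200):
            cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
            if i == 0:
                break
            d = np.hypot(centers[:i, 0] - cand[0], centers[:i, 1] - cand[1])
            if np.all(d > factor * (placed_r[:i] + placed_r[i]) + 2):
                break
            if attempt % 200 == 199:
                factor *= 0.9
        centers[i] = cand
    return centers


def simulate_field(
    n_cells: int,
    phenotype_fractions: Sequence[float],
    rng: np.random.Generator | int,
    config: SimulationConfig = DEFAULT_CONFIG,
    presets: Mapping[str, PhenotypeParams] = DEFAULT_PRESETS,
    well_id: str = "",
    field_index: int = 0,
    time_min: float = 0.0,
) -> tuple[FieldImage, list[CellRecord]]:
    """Simulate one nuclear-channel field with ground truth.

    ``phenotype_fractions`` is (resting, netotic, apoptotic) on the
    simplex; each cell's phenotype is an independent draw. Nuclei are
    placed with overlap rejection, entirely inside the field. Noise =
    Poisson-like shot noise (via ``photon_gain``) plus Gaussian read noise
    on top of a flat background offset.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    fr = np.asarray(phenotype_fractions, dtype=float)
    if fr.shape != (3,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("phenotype_fractions must be 3 non-negative values summing to 1")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")

    shape = config.field_shape
    clean = np.zeros(shape)
    records: list[CellRecord] = []
    if n_cells > 0:
        labels = rng.choice(len(PHENOTYPES), size=n_cells, p=fr)
        patches, masks, radii, halves = [], [], [], []
        for lab in labels:
            patch, mask = render_nucleus(presets[PHENOTYPES[lab]], rng, config.pixel_size)
            patches.append(patch)
            masks.append(mask)
            radii.append(math.sqrt(mask.sum() / math.pi))
            halves.append((patch.shape[0] // 2 + 1, patch.shape[1] // 2 + 1))
        # place large objects first: helps packing in dense fields
        order = np.argsort(radii)[::-1]
        centers = _place_cells(
            [radii[i] for i in order], shape, [halves[i] for i in order],
            config.separation_factor, rng,
        )
        for oid, (k, cen) in enumerate(zip(order, centers), start=1):
            patch, mask = patches[k], masks[k]
            r0 = int(round(cen[0])) - patch.shape[0] // 2
            c0 = int(round(cen[1])) - patch.shape[1] // 2
            clean[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] += patch
            records.append(
                CellRecord(
                    well_id=well_id, field_index=field_index, object_id=oid,
                    bbox=(r0, c0), mask=mask, phenotype=PHENOTYPES[labels[k]],
                )
            )

    expected = clean + config.background
    if config.photon_gain > 0:  # photon_gain <= 0 disables shot noise
        noisy = rng.poisson(expected / config.photon_gain) * float(config.photon_gain)
    else:
        noisy = expected
    if config.read_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, config.read_noise_sd, size=shape)
    max_val = 2**config.bit_depth - 1
    pixels = np.clip(np.round(noisy), 0, max_val).astype(
        np.uint16 if config.bit_depth <= 16 else np.uint32
    )
    img = FieldImage(
        pixels=pixels, channel="nuclear", pixel_size=config.pixel_size,
        well_id=well_id, field_index=field_index, time=time_min,
    )
    return img, records


def simulate_secondary_field(
    truth: Sequence[CellRecord],
    rng: np.random.Generator | int,
    config: SimulationConfig = DEFAULT_CONFIG,
    netotic_level: float = 900.0,
    other_level: float = 80.0,
    well_id: str = "",
    field_index: int = 0,
) -> FieldImage:
    """Secondary-antibody (MPO-like) channel: signal decorating NETs.

    Intensity is proportional to the NETotic label (high on netotic masks,
    low elsewhere) plus background and read noise; no staining chemistry is
    modeled.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    clean = np.zeros(config.field_shape)
    for rec in truth:
        level = netotic_level if rec.phenotype == "netotic" else other_level
        r0, c0 = rec.bbox
        h, w = rec.mask.shape
        clean[r0:r0 + h, c0:c0 + w][rec.mask] += level * (1 + rng.normal(0, 0.1))
    clean = ndi.gaussian_filter(clean, 1.0) + config.background
    noisy = clean + rng.normal(0, config.read_noise_sd, size=clean.shape)
    pixels = np.clip(np.round(noisy), 0, 2**config.bit_depth - 1).astype(np.uint16)
    return FieldImage(pixels=pixels, channel="secondary",
                      pixel_size=config.pixel_size, well_id=well_id,
                      field_index=field_index)


@dataclass
class WellTruth:
    """Simulated content of one well: images, ground truth, true fraction."""

    well: WellSpec
    fields: list[FieldImage]
    cells: list[CellRecord]
    true_netotic_frac: float        # law fraction before per-well jitter
    jittered_netotic_frac: float    # fraction actually used for sampling


def simulate_well(
    well: WellSpec,
    netotic_frac: float,
    rng: np.random.Generator | int,
    config: SimulationConfig = DEFAULT_CONFIG,
    presets: Mapping[str, PhenotypeParams] = DEFAULT_PRESETS,
    apply_jitter: bool = True,
    cells_per_field: int | None = None,
    fields_per_well: int | None = None,
) -> WellTruth:
    """Simulate all fields of one well at a given true NETotic fraction."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    f = float(np.clip(netotic_frac, 0.0, 1.0))
    fj = f
    if apply_jitter and 0.0 < f < 1.0 and config.jitter_concentration > 0:
        kappa = config.jitter_concentration
        fj = float(rng.beta(f * kappa, (1.0 - f) * kappa))
    apo = min(config.apoptotic_frac, 1.0 - fj)
    fractions = (1.0 - fj - apo, fj, apo)
    n_fields = config.fields_per_well if fields_per_well is None else fields_per_well
    n_cells = config.cells_per_field if cells_per_field is None else cells_per_field
    fields, cells = [], []
    for fi in range(n_fields):
        img, recs = simulate_field(
            n_cells, fractions, rng, config, presets,
            well_id=well.well_id, field_index=fi, time_min=well.timepoint_min,
        )
        fields.append(img)
        cells.extend(recs)
    return WellTruth(well, fields, cells, f, fj)


def simulate_plate(
    layout: PlateLayout,
    law: ResponseLaw = DEFAULT_RESPONSE_LAW,
    compound_params: Mapping[str, InhibitionParams | None] | None = None,
    rng_seed: int = 0,
    config: SimulationConfig = DEFAULT_CONFIG,
    presets: Mapping[str, PhenotypeParams] = DEFAULT_PRESETS,
    cells_per_field: int | None = None,
    fields_per_well: int | None = None,
) -> dict[str, WellTruth]:
    """Simulate every well of a plate layout under a response law.

    Each well draws from an independent, reproducible stream derived from
    ``rng_seed`` and the well's position in the layout, so results do not
    depend on evaluation order.
    """
    compound_params = compound_params or {}
    out: dict[str, WellTruth] = {}
    for i, well in enumerate(layout):
        f = law.well_fraction(well, compound_params)
        rng = np.random.default_rng([rng_seed, i])
        out[well.well_id] = simulate_well(
            well, f, rng, config, presets,
            cells_per_field=cells_per_field, fields_per_well=fields_per_well,
        )
    return out


# ---------------------------------------------------------------------------
# Kinetic traces


def _simulate_trace(preset, timepoints, noise_sd, rng, t_max, label):
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if t[0] < 0 or t[-1] > t_max:
        raise ValueError(f"timepoints must lie within [0, {t_max}] min")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    values = preset.value(t)
    if noise_sd > 0:
        values = values + rng.normal(0, noise_sd, size=t.shape)
    return KineticTrace(times=t, values=values, label=label)


def simulate_ros_trace(
    preset: KineticPreset,
    timepoints: Sequence[float],
    noise_sd: float = ROS_NOISE_SD,
    rng: np.random.Generator | int = 0,
) -> KineticTrace:
    """Cytosolic-ROS (DCF-like) fold-change trace; domain [0, 120] min."""
    return _simulate_trace(preset, timepoints, noise_sd, rng, ROS_T_MAX_MIN, "ros")


def simulate_tmrm_trace(
    preset: KineticPreset,
    timepoints: Sequence[float],
    noise_sd: float = TMRM_NOISE_SD,
    rng: np.random.Generator | int = 0,
) -> KineticTrace:
    """Mitochondrial TMRM accumulation trace; domain [0, 60] min."""
    return _simulate_trace(preset, timepoints, noise_sd, rng, TMRM_T_MAX_MIN, "tmrm")


# ---------------------------------------------------------------------------
# Layout builders (convenience for screens and tests)


def control_layout(
    n_negative: int,
    n_positive: int,
    stimulus: str = "ionomycin",
    timepoint_min: float | None = None,
) -> PlateLayout:
    """A layout of vehicle negative controls and stimulated positives."""
    if timepoint_min is None:
        timepoint_min = 90.0 if stimulus == "ionomycin" else 210.0
    conc = 5.0 if stimulus == "ionomycin" else 100.0
    wells = []
    for i in range(n_negative):
        wells.append(WellSpec(_well_name(i), "negative_control",
                              timepoint_min=timepoint_min, replicate=i + 1))
    for j in range(n_positive):
        wells.append(WellSpec(_well_name(n_negative + j), "positive_control",
                              stimulus=stimulus, stimulus_conc=conc,
                              timepoint_min=timepoint_min, replicate=j + 1))
    return PlateLayout(wells)


def _well_name(index: int, n_cols: int = 12) -> str:
    row, col = divmod(index, n_cols)
    return f"{chr(ord('A') + row)}{col + 1:02d}"
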