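"""Synthetic leaf-spectra generator for drought-stressed seedlings.

The generator emulates the statistical structure the downstream analysis
relies on, without a radiative-transfer model:

* four drought treatments T1 (most severe) .. T4 (mildest), 25 seedlings
  each by default; treatment Tk carries leaf pairs 1..k (pair 1 = first
  pair of top leaves), two leaves per pair, the lowest pair of T2-T4
  sometimes reduced to a single leaf;
* a fixed piecewise-smooth leaf baseline (low visible reflectance, a red
  edge rising to a NIR plateau, a gradual SWIR decline);
* a chlorophyll-sensitive Gaussian green bump at 550 nm whose amplitude
  strictly decreases with chlorophyll content, so more pigment means a
  lower green peak;
* water-absorption Gaussian troughs at 1440 and 1920 nm whose depths
  strictly increase with leaf water status, so drier leaves reflect more
  in the water bands;
* per-leaf multiplicative scatter plus additive (partly spectrally
  smooth) noise, exactly the effects SNV/MSC are designed to remove;
* chlorophyll and water drawn from treatment- and position-dependent
  normals, with the first top pair spanning the widest chlorophyll range
  (it appears in every treatment) and carrying the noisiest link between
  pigment and spectrum -- young leaves in flux are the hardest to read.

True chlorophyll values are routed through the acetone-extract assay
arithmetic (absorbances -> mg/g), so the emitted metadata follows the
same computation path as a laboratory measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .assay import AssayInput, absorbances_for_content, chlorophyll_total
from .exceptions import ConfigError
from .spectra import RAW_TAG, METADATA_COLUMNS, SpectraSet, TREATMENTS, WavelengthGrid

# Per-treatment chlorophyll baseline (mg/g): severe drought depresses pigment.
_CHL_BASE = {"T1": 6.0, "T2": 10.0, "T3": 14.0, "T4": 18.0}
# Chlorophyll drops by this much per pair position below the apex.
_CHL_POSITION_STEP = 1.5
# Within-(treatment, position) spread; senescing bottom leaves scatter most.
_CHL_SD = {1: 2.0, 2: 2.2, 3: 2.8, 4: 5.0}
# Pigment-to-spectrum link noise (mg/g equivalents); the first top pair,
# present in all four treatments and still developing, has by far the
# loosest link between pigment content and spectral expression.
_LINK_SD = {1: 4.5, 2: 1.2, 3: 0.9, 4: 0.7}
# Water status baseline per treatment and per-position decline (drier below).
# The treatment gradient couples water to chlorophyll (both track drought
# severity) but leaf-to-leaf variation dominates, as in canopy water data.
_WATER_BASE = {"T1": 0.45, "T2": 0.53, "T3": 0.61, "T4": 0.69}
_WATER_POSITION_STEP = 0.10
_WATER_SD = 0.15


def _default_chl_table():
    return {
        (t, pos): (_CHL_BASE[t] - _CHL_POSITION_STEP * (pos - 1), _CHL_SD[pos])
        for t in TREATMENTS
        for pos in range(1, int(t[1]) + 1)
    }


def _default_water_table():
    return {
        (t, pos): (_WATER_BASE[t] - _WATER_POSITION_STEP * (pos - 1), _WATER_SD)
        for t in TREATMENTS
        for pos in range(1, int(t[1]) + 1)
    }


@dataclass(frozen=True)
class BaselineParams:
    """Deterministic leaf-like baseline curve parameters."""

    vis_level: float = 0.08
    nir_level: float = 0.46
    red_edge_center_nm: float = 715.0
    red_edge_width_nm: float = 18.0
    swir_drop: float = 0.45
    swir_center_nm: float = 1650.0
    swir_width_nm: float = 300.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Truth parameters of the synthetic drought-stress study.

    ``chlorophyll_by_position`` and ``water_by_position`` map
    ``(treatment, pair_position)`` to ``(mean, sd)`` in mg/g and on the
    unitless 0-1 water-status scale respectively.
    ``link_noise_by_position`` is the sd (mg/g equivalents) of the jitter
    between a leaf's true chlorophyll and the pigment signal its spectrum
    actually encodes.
    """

    n_seedlings_per_treatment: int = 25
    seed: int = 0
    chlorophyll_by_position: dict = field(default_factory=_default_chl_table)
    water_by_position: dict = field(default_factory=_default_water_table)
    link_noise_by_position: dict = field(default_factory=lambda: dict(_LINK_SD))
    green_peak_center: float = 550.0
    green_peak_width: float = 35.0
    green_amplitude: float = 0.25
    green_chl_scale: float = 12.0  # e-folding of bump amplitude in mg/g
    water_trough_centers: tuple = (1440.0, 1920.0)
    water_trough_widths: tuple = (40.0, 50.0)
    water_trough_depths: tuple = (0.30, 0.26)
    noise_additive_sd: float = 0.003  # smooth component, reflectance units
    noise_white_sd: float = 0.001  # per-band white component
    noise_smooth_length_nm: float = 30.0
    noise_multiplicative_sd: float = 0.02
    single_leaf_prob: float = 0.3  # lowest pair of T2-T4 only
    baseline_params: BaselineParams = field(default_factory=BaselineParams)

    def validate(self) -> None:
        if self.n_seedlings_per_treatment < 1:
            raise ConfigError("need at least one seedling per treatment")
        for (t, pos), (mu, sd) in self.chlorophyll_by_position.items():
            if mu <= 0 or sd < 0:
                raise ConfigError(f"chlorophyll mean/sd invalid for {(t, pos)}")
            if pos > int(t[1]):
                raise ConfigError(f"treatment {t} cannot carry position {pos}")
        for (t, pos), (mu, sd) in self.water_by_position.items():
            if not 0 <= mu <= 1 or sd < 0:
                raise ConfigError(f"water mean/sd invalid for {(t, pos)}")
        for sds in (self.noise_additive_sd, self.noise_white_sd,
                    self.noise_multiplicative_sd):
            if sds < 0:
                raise ConfigError("noise sds must be non-negative")
        if not 0 <= self.single_leaf_prob <= 1:
            raise ConfigError("single_leaf_prob must lie in [0, 1]")


def baseline_spectrum(grid: WavelengthGrid, params: BaselineParams | None = None) -> np.ndarray:
    """Fixed leaf-like baseline: visible floor, red edge, NIR plateau, SWIR decay."""
    p = params or BaselineParams()
    lam = grid.values
    red_edge = expit((lam - p.red_edge_center_nm) / p.red_edge_width_nm)
    base = p.vis_level + (p.nir_level - p.vis_level) * red_edge
    decay = 1.0 - p.swir_drop * expit((lam - p.swir_center_nm) / p.swir_width_nm)
    return base * decay


def _gaussian(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def green_bump_amplitude(chlorophyll: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Green-peak height; strictly decreasing in chlorophyll content."""
    return cfg.green_amplitude * np.exp(-np.asarray(chlorophyll, float) / cfg.green_chl_scale)


def trough_depth(water: np.ndarray, depth: float) -> np.ndarray:
    """Water-trough depth; strictly increasing in water status, so drier
    leaves (low W) reflect more at the water bands."""
    return depth * np.asarray(water, float)


def leaf_layout(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Seedling/leaf bookkeeping: one row per leaf, no spectra yet."""
    rows = []
    for t in TREATMENTS:
        k = int(t[1])
        for s in range(cfg.n_seedlings_per_treatment):
            sid = f"{t}-{s + 1:03d}"
            for pos in range(1, k + 1):
                n_sides = 2
                if pos == k and k > 1 and rng.random() < cfg.single_leaf_prob:
                    n_sides = 1
                for side in range(1, n_sides + 1):
                    rows.append((sid, t, pos, side))
    return pd.DataFrame(rows, columns=["seedling_id", "treatment", "pair_position", "leaf_side"])


def generate_dataset(cfg: GeneratorConfig, grid: WavelengthGrid | None = None):
    """Generate a (SpectraSet, TruthTable) pair; deterministic given cfg.seed.

    The truth table is a DataFrame aligned one-to-one with the spectra
    rows, carrying the true chlorophyll (mg/g), true water status and the
    design factors.
    """
    cfg.validate()
    grid = grid or WavelengthGrid.default()
    rng = np.random.default_rng(cfg.seed)
    layout = leaf_layout(cfg, rng)
    n = len(layout)
    lam = grid.values
    base = baseline_spectrum(grid, cfg.baseline_params)
    bump = _gaussian(lam, cfg.green_peak_center, cfg.green_peak_width)
    troughs = [
        _gaussian(lam, c, w)
        for c, w in zip(cfg.water_trough_centers, cfg.water_trough_widths)
    ]

    chl = np.empty(n)
    water = np.empty(n)
    for i, row in enumerate(layout.itertuples(index=False)):
        cmu, csd = cfg.chlorophyll_by_position[(row.treatment, row.pair_position)]
        wmu, wsd = cfg.water_by_position[(row.treatment, row.pair_position)]
        chl[i] = max(rng.normal(cmu, csd), 0.3)
        water[i] = float(np.clip(rng.normal(wmu, wsd), 0.02, 0.98))

    link_sd = layout["pair_position"].map(cfg.link_noise_by_position).to_numpy(float)
    chl_signal = np.maximum(chl + rng.normal(0.0, 1.0, n) * link_sd, 0.2)

    amp = green_bump_amplitude(chl_signal, cfg)
    clean = base[None, :] + amp[:, None] * bump[None, :]
    for tr, depth in zip(troughs, cfg.water_trough_depths):
        clean = clean - trough_depth(water, depth)[:, None] * tr[None, :]

    m = 1.0 + rng.normal(0.0, cfg.noise_multiplicative_sd, n)
    noisy = m[:, None] * clean
    if cfg.noise_additive_sd > 0:
        sigma_pts = cfg.noise_smooth_length_nm / grid.step_nm
        smooth = gaussian_filter1d(rng.normal(0.0, 1.0, (n, len(grid))), sigma_pts, axis=1)
        # renormalise so the smooth component has the requested sd per band
        smooth /= max(smooth.std(), 1e-12)
        noisy = noisy + cfg.noise_additive_sd * smooth
    if cfg.noise_white_sd > 0:
        noisy = noisy + rng.normal(0.0, cfg.noise_white_sd, (n, len(grid)))
    reflectance = np.clip(noisy, 0.001, 0.999)

    # route truth chlorophyll through the assay arithmetic
    measured = np.empty(n)
    for i, c in enumerate(chl):
        a646, a663 = absorbances_for_content(c)
        measured[i] = chlorophyll_total(AssayInput(A646=a646, A663=a663))

    records = layout.copy()
    records["chlorophyll"] = measured
    spectra = SpectraSet(grid, reflectance, records[list(METADATA_COLUMNS)], RAW_TAG)

    truth = layout.copy()
    truth["chlorophyll_true"] = chl
    truth["water_true"] = water
    truth["chlorophyll_signal"] = chl_signal
    return spectra, truth


def noise_free_config(**overrides) -> GeneratorConfig:
    """Config with every stochastic nuisance switched off (for property tests)."""
    base = dict(
        noise_additive_sd=0.0,
        noise_white_sd=0.0,
        noise_multiplicative_sd=0.0,
        link_noise_by_position={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
        single_leaf_prob=0.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


_FIXTURE_SEEDS = {"tiny": 1317, "study": 20240929 % 2**16}


def make_fixture(size: str = "tiny"):
    """Canonical fixtures: 'tiny' (4 seedlings/treatment, 5 nm grid) for
    fast tests, 'study' (25 seedlings/treatment, full 1 nm grid, ~478
    leaves) matching the modeling-set scale."""
    if size == "tiny":
        cfg = GeneratorConfig(n_seedlings_per_treatment=4, seed=_FIXTURE_SEEDS["tiny"])
        grid = WavelengthGrid.regular(350.0, 2500.0, 5.0)
        return generate_dataset(cfg, grid)
    if size == "study":
        cfg = GeneratorConfig(seed=_FIXTURE_SEEDS["study"])
        return generate_dataset(cfg)
    raise ConfigError(f"unknown fixture size {size!r}")
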