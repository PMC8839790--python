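"""Synthetic honey NIR spectra and HMF tables.

The generator reproduces the structure of the heat-treatment study: three
unifloral honey types (sunflower — fully crystallized, bastard indigo —
mid-crystallized, acacia — liquid), each heated to 40/60/80/100 degC for
60/120/180/240 min plus an untreated control (17 levels), three replicate
bottles per level, and 3 cuvette fills x 5 consecutive scans per sample.

Each clean spectrum is a sum of Gaussian water/sugar absorption bands on a
smooth baseline. Heat exposure is collapsed into a scalar dose that
transfers absorbance mass from the strongly hydrogen-bonded water bands
(~1490, ~1512 nm) to the free-water band (~1412 nm), preserving the total
band mass — the see-saw that drives the aquagram patterns. The transfer is
scaled by the archetype's crystallinity and dose sensitivity, which makes
sunflower models strong and acacia models weak. Measurement artifacts are
layered per fill (multiplicative scatter + additive offset) and per scan
(white noise); replicate bottles get a random effect on the band weights.

HMF follows Arrhenius kinetics with an induction lag and lognormal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DesignError
from .spectra import (
    CONTROL,
    HONEY_TYPES,
    TEMPERATURES,
    TIMES,
    SpectraSet,
    WavelengthGrid,
)

__all__ = [
    "HoneyArchetype",
    "SynthParams",
    "DEFAULT_PARAMS",
    "default_grid",
    "generate_design",
    "heat_dose",
    "generate_spectra",
    "generate_hmf",
]

#: generative band centers (nm); the last one is the sugar band
BAND_CENTERS = (1364.0, 1412.0, 1444.0, 1452.0, 1490.0, 1512.0, 1583.0)
#: Gaussian SD of each band (nm)
BAND_WIDTHS = (14.0, 16.0, 18.0, 14.0, 16.0, 12.0, 22.0)
#: indices of the strongly hydrogen-bonded (donor) bands and the free-water
#: (acceptor) band of the dose-driven transfer
BOUND_BAND_IDX = (4, 5)  # 1490, 1512 nm
FREE_BAND_IDX = 1  # 1412 nm
SUGAR_BAND_IDX = 6  # 1583 nm


def default_grid() -> WavelengthGrid:
    """The instrument grid: 901–1699 nm in 3 nm steps (267 points).

    Both analysis bounds (1300 and 1600 nm) are exact grid points.
    """
    return WavelengthGrid(np.arange(901.0, 1700.0, 3.0))


@dataclass(frozen=True)
class HoneyArchetype:
    """Baseline spectral character of one honey type.

    ``band_weights0`` are the untreated Gaussian band amplitudes (AU) in
    the order of :data:`BAND_CENTERS` (sugar band included).
    ``crystallinity`` in [0, 1] and ``dose_sensitivity`` jointly scale the
    bound-to-free transfer; ``replicate_sd`` is the relative SD of the
    per-bottle random effect on the band weights.
    """

    name: str
    band_weights0: tuple[float, ...]
    crystallinity: float
    dose_sensitivity: float
    replicate_sd: float
    #: relative SD of the per-bottle dose-response multiplier; bottles of
    #: one honey differ in crystallization state, hence in how strongly a
    #: given heat dose remodels their water bands
    dose_response_sd: float = 0.0

    def __post_init__(self):
        if len(self.band_weights0) != len(BAND_CENTERS):
            raise DesignError("band_weights0 must match BAND_CENTERS")
        if any(w < 0 for w in self.band_weights0):
            raise DesignError("band weights must be >= 0")
        if not 0.0 <= self.crystallinity <= 1.0:
            raise DesignError("crystallinity must lie in [0, 1]")

    @property
    def sugar_band_weight0(self) -> float:
        return self.band_weights0[SUGAR_BAND_IDX]


@dataclass(frozen=True)
class SynthParams:
    """All knobs of the generator; one seeded stream per instance."""

    archetypes: tuple[HoneyArchetype, ...]
    band_centers: tuple[float, ...] = BAND_CENTERS
    band_widths: tuple[float, ...] = BAND_WIDTHS
    dose_halftime: float = 120.0  # min; saturation half-time of the dose
    dose_activation: float = 0.04  # 1/K; temperature gain of the dose
    transfer_gain: float = 0.25  # 1/dose; bound->free transfer rate
    sugar_gain: float = 0.08  # relative sugar-band change at full dose
    scatter_sd: float = 0.05  # per-fill multiplicative (lognormal sigma)
    offset_sd: float = 0.01  # AU; per-fill additive offset
    scan_noise_sd: float = 0.002  # AU; per-scan white noise
    baseline_level: float = 0.15  # AU at 901 nm
    baseline_slope: float = 2.5e-4  # AU/nm
    n_fills: int = 3
    n_scans: int = 5
    hmf0: dict = field(
        default_factory=lambda: {
            "sunflower": 18.5,
            "bastard_indigo": 14.7,
            "acacia": 7.0,
        }
    )
    hmf_rate: float = 1.07e-3  # mg/kg/min at the 40 degC (313 K) reference
    hmf_activation: float = 16000.0  # K
    hmf_lag: float = 120.0  # min; induction lag of HMF formation
    hmf_noise_sd: float = 0.08  # lognormal sigma
    seed: int = 0

    def with_seed(self, seed: int) -> "SynthParams":
        return replace(self, seed=seed)

    def archetype(self, honey_type: str) -> HoneyArchetype:
        for a in self.archetypes:
            if a.name == honey_type:
                return a
        raise DesignError(f"no archetype for honey type {honey_type!r}")


def _default_archetypes() -> tuple[HoneyArchetype, ...]:
    # band order: 1364, 1412(free), 1444, 1452, 1490(bound), 1512(bound), 1583(sugar)
    return (
        # fully crystallized: bound-water dominated, strong dose response
        HoneyArchetype(
            "sunflower",
            (0.10, 0.15, 0.50, 0.45, 0.35, 0.30, 0.40),
            crystallinity=1.0,
            dose_sensitivity=1.0,
            replicate_sd=0.04,
            dose_response_sd=0.30,
        ),
        # mid-crystallized
        HoneyArchetype(
            "bastard_indigo",
            (0.12, 0.25, 0.48, 0.42, 0.28, 0.22, 0.38),
            crystallinity=0.55,
            dose_sensitivity=1.0,
            replicate_sd=0.05,
            dose_response_sd=0.40,
        ),
        # liquid: free-water dominated, weak response, heterogeneous bottles
        HoneyArchetype(
            "acacia",
            (0.16, 0.45, 0.46, 0.40, 0.12, 0.08, 0.36),
            crystallinity=0.10,
            dose_sensitivity=0.8,
            replicate_sd=0.12,
            dose_response_sd=0.60,
        ),
    )


DEFAULT_PARAMS = SynthParams(archetypes=_default_archetypes())


# ----------------------------------------------------------------------
# design


def generate_design(
    honey_types=HONEY_TYPES, replicates=("R1", "R2", "R3")
) -> pd.DataFrame:
    """One row per physical sample: the 4x4 factorial plus the control,
    per honey type and replicate bottle (17 levels, 51 samples per type)."""
    rows = []
    levels = [(CONTROL, 0)] + [(t, m) for t in TEMPERATURES for m in TIMES]
    for h in honey_types:
        for temp, time in levels:
            for r in replicates:
                rows.append((h, temp, time, r))
    return pd.DataFrame(
        rows, columns=["honey_type", "temperature_C", "time_min", "replicate"]
    )


def heat_dose(temperature_C, time_min: float, params: SynthParams = DEFAULT_PARAMS) -> float:
    """Scalar heat dose: 0 for the control, saturating in time and
    exponentially increasing in temperature."""
    if temperature_C == CONTROL or time_min == 0:
        return 0.0
    t_term = 1.0 - 2.0 ** (-float(time_min) / params.dose_halftime)
    return t_term * float(np.exp(params.dose_activation * (float(temperature_C) - 40.0)))


# ----------------------------------------------------------------------
# spectra


def clean_spectrum(
    honey_type: str,
    temperature_C,
    time_min: float,
    params: SynthParams = DEFAULT_PARAMS,
    grid: WavelengthGrid | None = None,
    band_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free spectrum of one design cell (no replicate/fill/scan
    effects); exposed for tests of the pre-noise monotonicity."""
    grid = grid or default_grid()
    arch = params.archetype(honey_type)
    dose = heat_dose(temperature_C, time_min, params)
    w0 = np.array(arch.band_weights0) if band_weights is None else np.asarray(band_weights)
    w = _dose_shift(w0, arch, dose, params)
    wl = grid.wavelengths
    spec = params.baseline_level + params.baseline_slope * (wl - wl[0])
    for wgt, c, s in zip(w, params.band_centers, params.band_widths):
        spec = spec + wgt * np.exp(-0.5 * ((wl - c) / s) ** 2)
    return spec


def _dose_shift(w0: np.ndarray, arch: HoneyArchetype, dose: float, params: SynthParams) -> np.ndarray:
    w = np.array(w0, dtype=float)
    phi = 1.0 - np.exp(
        -params.transfer_gain * dose * arch.crystallinity * arch.dose_sensitivity
    )
    moved = 0.0
    for i in BOUND_BAND_IDX:
        moved += w[i] * phi
        w[i] *= 1.0 - phi
    w[FREE_BAND_IDX] += moved
    w[SUGAR_BAND_IDX] *= 1.0 + params.sugar_gain * (1.0 - np.exp(-dose))
    return w


def generate_spectra(
    design: pd.DataFrame,
    params: SynthParams = DEFAULT_PARAMS,
    grid: WavelengthGrid | None = None,
) -> SpectraSet:
    """Simulate the full scan hierarchy for every design row.

    Per sample: ``n_fills`` fills x ``n_scans`` scans. Replicate bottles of
    one honey type share a multiplicative random effect on the untreated
    band weights, so leave-one-replicate-out folds face genuine
    between-bottle variation.
    """
    grid = grid or default_grid()
    rng = np.random.default_rng(params.seed)
    wl = grid.wavelengths

    # per (honey type, replicate) band-weight random effects, drawn once
    rep_ids = sorted(design["replicate"].unique())
    types = sorted(design["honey_type"].unique())
    rep_effect: dict[tuple[str, str], np.ndarray] = {}
    rep_dose: dict[tuple[str, str], float] = {}
    for h in types:
        arch = params.archetype(h)
        for r in rep_ids:
            z = rng.standard_normal(len(params.band_centers))
            rep_effect[(h, r)] = 1.0 + arch.replicate_sd * z
            rep_dose[(h, r)] = float(
                np.exp(arch.dose_response_sd * rng.standard_normal())
            )

    rows = []
    meta_rows = []
    for rec in design.itertuples(index=False):
        arch = params.archetype(rec.honey_type)
        w0 = np.array(arch.band_weights0) * np.clip(
            rep_effect[(rec.honey_type, rec.replicate)], 0.0, None
        )
        dose = heat_dose(rec.temperature_C, rec.time_min, params) * rep_dose[
            (rec.honey_type, rec.replicate)
        ]
        w = _dose_shift(w0, arch, dose, params)
        base = params.baseline_level + params.baseline_slope * (wl - wl[0])
        clean = base.copy()
        for wgt, c, s in zip(w, params.band_centers, params.band_widths):
            clean += wgt * np.exp(-0.5 * ((wl - c) / s) ** 2)
        for fill in range(1, params.n_fills + 1):
            m = float(np.exp(params.scatter_sd * rng.standard_normal())) if params.scatter_sd else 1.0
            a = float(params.offset_sd * rng.standard_normal()) if params.offset_sd else 0.0
            fill_spec = m * clean + a
            for scan in range(1, params.n_scans + 1):
                noise = (
                    params.scan_noise_sd * rng.standard_normal(wl.size)
                    if params.scan_noise_sd
                    else 0.0
                )
                rows.append(fill_spec + noise)
                meta_rows.append(
                    (rec.honey_type, rec.temperature_C, rec.time_min, rec.replicate, fill, scan)
                )
    meta = pd.DataFrame(
        meta_rows,
        columns=["honey_type", "temperature_C", "time_min", "replicate", "fill", "scan"],
    )
    return SpectraSet(grid, np.asarray(rows), meta)


# ----------------------------------------------------------------------
# HMF


def generate_hmf(design: pd.DataFrame, params: SynthParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """HMF (mg/kg) per design row.

    Arrhenius kinetics with an induction lag: the increment is
    ``rate(T) * t_eff`` where ``t_eff = t^2 / (t + lag)`` — early heating
    produces little HMF, matching the published pattern where short
    treatments at 80 degC stay near the control level while longer ones
    rise steeply. Baseline and increment carry lognormal noise; control
    rows get the baseline only.
    """
    rng = np.random.default_rng(params.seed + 1)
    vals = []
    for rec in design.itertuples(index=False):
        h0 = params.hmf0[rec.honey_type]
        base = h0 * float(np.exp(params.hmf_noise_sd * rng.standard_normal())) if params.hmf_noise_sd else h0
        if rec.temperature_C == CONTROL:
            vals.append(base)
            continue
        T_K = float(rec.temperature_C) + 273.15
        rate = params.hmf_rate * float(
            np.exp(params.hmf_activation * (1.0 / 313.15 - 1.0 / T_K))
        )
        t = float(rec.time_min)
        t_eff = t**4 / (t**3 + params.hmf_lag**3) if params.hmf_lag > 0 else t
        inc = rate * t_eff
        if params.hmf_noise_sd:
            inc *= float(np.exp(params.hmf_noise_sd * rng.standard_normal()))
        vals.append(base + inc)
    out = design.copy()
    out["hmf_mg_kg"] = vals
    return out
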