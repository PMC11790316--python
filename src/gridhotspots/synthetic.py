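"""Synthetic multi-year gridded exposure fields with planted hotspot regimes.

Each year's surface is the sum of a constant base level, a linear regional
gradient, spatially correlated noise, and Gaussian source bumps that switch
on and off across years.  The generator emulates the structural features of
an annual fine-scale pollution surface that the hotspot pipeline relies on —
positive spatial autocorrelation, smooth large-scale variation, localized
high-emission areas with year-dependent activity, and a co-registered
population surface — without attempting to model any real region's levels.

Correlated noise is white noise convolved with a Gaussian kernel of scale
``spatial_corr_length`` (periodic boundaries, to keep the field stationary
up to the edges) and rescaled so its empirical SD equals ``noise_sd``
exactly.  Source bumps are Gaussian with scale ``decay``, truncated at
3·decay.  Cells inside ``radius`` of an active source's center form its
geometric *core*; the core's planted regime (consistent / emerging /
declining) is the trend category its active-year pattern would earn under
the two-period rules, which makes recovery of planted structure directly
testable.  Masking (no-data cells) is uniform over non-core cells so the
planted truths survive pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .gistar import AnnualFieldStack
from .lattice import GridLattice
from .trend import PeriodSplit, classify_trend, CAT_INCONSISTENT

__all__ = [
    "SourceSchedule",
    "SimulationConfig",
    "simulate_field_stack",
    "simulate_population",
    "planted_truth",
]

BACKGROUND = "background"


@dataclass(frozen=True)
class SourceSchedule:
    """One localized emission source: where, how strong, and in which years.

    ``active_years`` are 1-based year indices within the study window.
    ``decay`` is the Gaussian scale of the bump in cells; the bump is
    truncated at 3·decay.  ``radius`` (Euclidean, in cells) bounds the core
    used for geometric truth labels.
    """

    center: tuple[int, int]
    radius: int
    amplitude: float
    active_years: frozenset[int]
    decay: float = 1.5

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.radius < 1:
            raise ValueError("radius must be at least 1")
        if self.decay <= 0:
            raise ValueError("decay must be positive")
        object.__setattr__(self, "active_years", frozenset(int(y) for y in self.active_years))

    def core_mask(self, n_rows: int, n_cols: int) -> np.ndarray:
        r0, c0 = self.center
        rr, cc = np.ogrid[:n_rows, :n_cols]
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius**2

    def bump(self, n_rows: int, n_cols: int) -> np.ndarray:
        r0, c0 = self.center
        rr, cc = np.ogrid[:n_rows, :n_cols]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        out = self.amplitude * np.exp(-d2 / (2.0 * self.decay**2))
        out[d2 > (3.0 * self.decay) ** 2] = 0.0
        return out


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic multi-year exposure experiment.

    Defaults describe a 60×60 unit-cell grid observed for 12 years at a base
    level of 40 exposure units with SD-5 noise of correlation length 1 cell —
    a window and noise scale on which a 3×3-neighborhood local statistic has
    realistic, not overwhelming, power.
    """

    n_rows: int = 60
    n_cols: int = 60
    n_years: int = 12
    base_level: float = 40.0
    gradient_vector: tuple[float, float] = (0.0, 0.0)  # units per cell, (row, col)
    spatial_corr_length: float = 1.0
    noise_sd: float = 5.0
    sources: tuple[SourceSchedule, ...] = ()
    mask_fraction: float = 0.0
    population_log_mean: float = 5.0
    population_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("lattice dimensions must be positive")
        if self.n_years < 2:
            raise ValueError("need at least two years")
        if self.n_years % 2 != 0:
            raise ValueError("n_years must be even so the default period split is well defined")
        if not 0.0 <= self.mask_fraction < 0.5:
            raise ValueError("mask_fraction must be in [0, 0.5)")
        if self.spatial_corr_length < 0 or self.noise_sd < 0:
            raise ValueError("spatial_corr_length and noise_sd must be non-negative")
        for s in self.sources:
            bad = {y for y in s.active_years if not 1 <= y <= self.n_years}
            if bad:
                raise ValueError(f"source active_years outside the study window: {sorted(bad)}")
        object.__setattr__(self, "sources", tuple(self.sources))

    def year_labels(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_years + 1))

    def _seed_streams(self) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
        """Independent (noise, mask, population) streams from the master seed."""
        noise_ss, mask_ss, pop_ss = np.random.SeedSequence(self.seed).spawn(3)
        return (
            np.random.default_rng(noise_ss),
            np.random.default_rng(mask_ss),
            np.random.default_rng(pop_ss),
        )


def _correlated_noise(rng: np.random.Generator, shape: tuple[int, int], corr_length: float, sd: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    if sd == 0.0:
        return np.zeros(shape)
    if corr_length > 0:
        smooth = ndimage.gaussian_filter(white, sigma=corr_length, mode="wrap")
    else:
        smooth = white
    emp = smooth.std()
    return smooth / emp * sd if emp > 0 else np.zeros(shape)


def _mask_cells(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Validity mask; exactly round(mask_fraction·n_rows·n_cols) cells removed."""
    n_total = config.n_rows * config.n_cols
    n_mask = int(round(config.mask_fraction * n_total))
    valid = np.ones((config.n_rows, config.n_cols), dtype=bool)
    if n_mask == 0:
        return valid
    protected = np.zeros_like(valid)
    for s in config.sources:
        protected |= s.core_mask(config.n_rows, config.n_cols)
    candidates = np.flatnonzero(~protected.ravel())
    if len(candidates) < n_mask:
        raise ValueError("mask_fraction too large for the non-core area")
    drop = rng.choice(candidates, size=n_mask, replace=False)
    valid.ravel()[drop] = False
    return valid


def simulate_field_stack(config: SimulationConfig) -> tuple[GridLattice, AnnualFieldStack]:
    """Generate the lattice and the per-year exposure fields.

    Each year: base + gradient + fresh correlated noise + the bumps of the
    sources active that year.  The same seed always yields bit-identical
    output (noise, mask and population use separate sub-streams).
    """
    rng_noise, rng_mask, _ = config._seed_streams()
    shape = (config.n_rows, config.n_cols)
    rr, cc = np.meshgrid(np.arange(config.n_rows), np.arange(config.n_cols), indexing="ij")
    gr, gc = config.gradient_vector
    deterministic = config.base_level + gr * rr + gc * cc

    valid = _mask_cells(config, rng_mask)
    lattice = GridLattice(config.n_rows, config.n_cols, valid)

    bumps = [s.bump(*shape) for s in config.sources]
    fields = np.empty((config.n_years, lattice.n_cells))
    flat_idx = lattice.cell_ids
    for t, year in enumerate(config.year_labels()):
        surface = deterministic + _correlated_noise(rng_noise, shape, config.spatial_corr_length, config.noise_sd)
        for s, b in zip(config.sources, bumps):
            if year in s.active_years:
                surface = surface + b
        fields[t] = surface.ravel()[flat_idx]
    return lattice, AnnualFieldStack(years=config.year_labels(), values=fields)


def simulate_population(config: SimulationConfig, lattice: GridLattice) -> pd.DataFrame:
    """Log-normal population per valid cell (persons), seeded from the config.

    Population is drawn independently of exposure so population-weighted
    summaries can be checked against closed forms.
    """
    if lattice.valid.shape != (config.n_rows, config.n_cols):
        raise ValueError("lattice does not match the simulation config")
    _, _, rng_pop = config._seed_streams()
    log_pop = config.population_log_mean + config.population_log_sd * rng_pop.standard_normal(lattice.n_cells)
    return pd.DataFrame({"cell_id": lattice.cell_ids, "population": np.exp(log_pop)})


def planted_truth(config: SimulationConfig) -> pd.DataFrame:
    """Geometric ground-truth regime per cell (cell_id, regime).

    A source's core cells inherit the trend category its active-year pattern
    earns under the two-period rules with the default half split (e.g. active
    all years → "consistent-core"; active only the late half → "emerging-core";
    only the early half → "declining-core").  A pattern mapping to
    "inconsistent" plants nothing.  Overlapping cores with conflicting
    regimes are an error — fixtures must keep sources apart.
    """
    split = PeriodSplit.halves(config.year_labels())
    labels = np.full(config.n_rows * config.n_cols, BACKGROUND, dtype=object)
    for s in config.sources:
        c1 = len(s.active_years & set(split.t1))
        c2 = len(s.active_years & set(split.t2))
        category = classify_trend(c1, c2, split)
        if category == CAT_INCONSISTENT:
            continue
        regime = f"{category}-core"
        core = s.core_mask(config.n_rows, config.n_cols).ravel()
        clash = (labels != BACKGROUND) & core & (labels != regime)
        if clash.any():
            raise ValueError("overlapping source cores with conflicting regimes")
        labels[core] = regime
    return pd.DataFrame(
        {"cell_id": np.arange(config.n_rows * config.n_cols), "regime": labels}
    )
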