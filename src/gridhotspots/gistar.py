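"""Getis-Ord Gi* hotspot statistic with Monte-Carlo permutation inference.

For a spatial unit of ``n`` cells with exposure values ``x_j`` and binary
queen-contiguity weights ``w_ij`` (self-weight included for the star variant),

    Gi* = [ Σ_j w_ij x_j  −  X̄ Σ_j w_ij ]
          / ( S * sqrt( [ n Σ_j w_ij² − (Σ_j w_ij)² ] / (n − 1) ) )

with X̄ = Σ_j x_j / n and S = sqrt(Σ_j x_j² / n − X̄²), both taken over *all*
cells of the spatial unit.  A positive score means the cell and its
neighborhood jointly exceed the unit-wide mean.

Significance uses conditional randomization: the focal value x_i stays
fixed while, for each of ``nsim`` draws, the neighborhood values are
replaced by a without-replacement sample from the remaining n−1 cells and
the statistic is recomputed.  The permutation draws of different cells are
independent.  The one-sided pseudo p-value on the side of the observed
score is (1 + #more-extreme) / (1 + nsim), so with nsim = 99 every p is a
multiple of 1/100 and never 0.  Yearly labels at level ``alpha`` (default
0.05, strict inequality): hotspot if Gi* > 0 and p < alpha, coldspot if
Gi* < 0 and p < alpha, else ns.  Zero-variance fields (S = 0) and cells
whose denominator radical vanishes are flagged degenerate and labeled ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lattice import GridLattice, NeighborWeights

__all__ = [
    "AnnualFieldStack",
    "GiResult",
    "gi_star_scores",
    "mc_pvalues",
    "classify_year",
    "run_yearly",
    "draw_conditional_samples",
]

LABEL_HOT = "hotspot"
LABEL_COLD = "coldspot"
LABEL_NS = "ns"


@dataclass(frozen=True)
class AnnualFieldStack:
    """Cell-aligned exposure values for each year of the study window.

    ``values`` has shape ``(n_years, n_cells)`` in the valid-cell order of the
    lattice the stack was built on; ``years`` are the ordered year labels.
    """

    years: tuple[int, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != len(self.years):
            raise ValueError("values must be (n_years, n_cells) aligned with years")
        if len(self.years) < 1:
            raise ValueError("at least one year required")
        if len(set(self.years)) != len(self.years):
            raise ValueError("duplicate year labels")
        if np.isnan(vals).any():
            raise ValueError("missing values on valid cells")
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "values", vals)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def year(self, label: int) -> np.ndarray:
        return self.values[self.years.index(label)]

    def to_long(self, cell_ids: np.ndarray) -> pd.DataFrame:
        """Long table (cell_id, year, value)."""
        return pd.DataFrame(
            {
                "cell_id": np.tile(cell_ids, self.n_years),
                "year": np.repeat(self.years, self.n_cells),
                "value": self.values.ravel(),
            }
        )

    @classmethod
    def from_long(cls, table: pd.DataFrame, cell_ids: np.ndarray) -> "AnnualFieldStack":
        """Build from a long (cell_id, year, value) table aligned to ``cell_ids``."""
        wide = table.pivot(index="year", columns="cell_id", values="value")
        missing = set(cell_ids) - set(wide.columns)
        if missing:
            raise ValueError(f"stack is missing {len(missing)} lattice cells")
        wide = wide.loc[:, cell_ids]
        return cls(years=tuple(int(y) for y in wide.index), values=wide.to_numpy(float))

    def subset_cells(self, positions: np.ndarray) -> "AnnualFieldStack":
        return AnnualFieldStack(self.years, self.values[:, positions])


@dataclass(frozen=True)
class GiResult:
    """Per cell-year Gi* scores, permutation p-values and yearly labels."""

    table: pd.DataFrame = field(repr=False)  # cell_id, year, gi_score, p_value, label, degenerate

    def year_labels(self, year: int) -> pd.Series:
        sub = self.table[self.table["year"] == year]
        return sub.set_index("cell_id")["label"]

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(int(y) for y in pd.unique(self.table["year"]))


def _field_moments(x: np.ndarray) -> tuple[float, float, int]:
    n = x.size
    xbar = float(x.mean())
    s = float(np.sqrt(max((x * x).mean() - xbar * xbar, 0.0)))
    return xbar, s, n


def gi_star_scores(x: np.ndarray, weights: NeighborWeights) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Gi* scores for one year's field.

    Returns ``(scores, degenerate)``; degenerate cells (S = 0, or a
    neighborhood covering the whole unit) carry NaN scores.
    """
    x = np.asarray(x, dtype=float)
    n = weights.n_cells
    if x.shape != (n,):
        raise ValueError("field is not aligned with the weights lattice")
    if n < 2:
        raise ValueError("need at least two cells")
    xbar, s, _ = _field_moments(x)
    wi = weights.row_sums().astype(float)  # Σ_j w_ij; binary ⇒ also Σ_j w_ij²
    radical = (n * wi - wi * wi) / (n - 1)
    degenerate = np.zeros(n, dtype=bool)
    scores = np.full(n, np.nan)
    if s == 0.0:
        return scores, np.ones(n, dtype=bool)
    degenerate |= radical <= 0
    w = weights.weights_matrix()
    numerator = w @ x - xbar * wi
    ok = ~degenerate
    scores[ok] = numerator[ok] / (s * np.sqrt(radical[ok]))
    return scores, degenerate


def draw_conditional_samples(rng: np.random.Generator, positions: np.ndarray, k: int, nsim: int, n: int) -> np.ndarray:
    """Independent without-replacement index samples for conditional randomization.

    For each focal cell position, draws ``nsim`` samples of ``k`` distinct
    positions from the other ``n − 1`` cells (the focal cell is skipped by
    index shifting).  Duplicates within a draw are rejected and redrawn, so
    every draw is uniform over injective k-tuples.  Exposed separately so a
    reference implementation can replay the exact permutation stream.
    """
    m = len(positions)
    if k > n - 1:
        raise ValueError("neighborhood larger than the candidate pool")
    idx = rng.integers(0, n - 1, size=(m, nsim, k), dtype=np.int64)
    if k > 1:
        while True:
            srt = np.sort(idx, axis=2)
            bad = (srt[:, :, 1:] == srt[:, :, :-1]).any(axis=2)
            if not bad.any():
                break
            idx[bad] = rng.integers(0, n - 1, size=(int(bad.sum()), k), dtype=np.int64)
    # skip the focal cell: indices at or above it shift up by one
    return idx + (idx >= positions[:, None, None])


def mc_pvalues(
    x: np.ndarray,
    weights: NeighborWeights,
    scores: np.ndarray,
    *,
    nsim: int = 99,
    seed: int | np.random.Generator | None = None,
    degenerate: np.ndarray | None = None,
) -> np.ndarray:
    """Conditional-randomization pseudo p-values for observed Gi* scores.

    p = (1 + #{sim ≥ obs}) / (1 + nsim) for non-negative observed scores,
    mirrored with ≤ for negative ones.  Degenerate cells get NaN.
    """
    if nsim < 1:
        raise ValueError("nsim must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    n = weights.n_cells
    xbar, s, _ = _field_moments(x)
    wi = weights.row_sums().astype(float)
    counts = weights.counts

    # denominators are permutation-invariant and positive for non-degenerate
    # cells, so comparing numerators is comparing scores
    obs_num = weights.weights_matrix() @ x - xbar * wi

    if degenerate is None:
        degenerate = np.isnan(scores)
    pvals = np.full(n, np.nan)
    active = ~degenerate
    if s == 0.0 or not active.any():
        return pvals

    exceed = np.zeros(n, dtype=np.int64)
    # group cells by neighbor count so index draws stay rectangular
    for k in np.unique(counts[active]):
        cells = np.flatnonzero(active & (counts == k))
        if k == 0:
            # no neighbors to permute: simulated score equals observed
            exceed[cells] = nsim
            continue
        sampled = draw_conditional_samples(rng, cells, int(k), nsim, n)
        sim_neigh = x[sampled].sum(axis=2)  # (m, nsim)
        sim_num = sim_neigh - xbar * wi[cells, None]
        if weights.include_self:
            sim_num += x[cells, None]
        obs = obs_num[cells, None]
        pos_side = obs_num[cells] >= 0
        ge = (sim_num >= obs).sum(axis=1)
        le = (sim_num <= obs).sum(axis=1)
        exceed[cells] = np.where(pos_side, ge, le)
    pvals[active] = (1.0 + exceed[active]) / (1.0 + nsim)
    return pvals


def classify_year(
    scores: np.ndarray,
    pvalues: np.ndarray,
    *,
    alpha: float = 0.05,
    degenerate: np.ndarray | None = None,
) -> np.ndarray:
    """Yearly hotspot/coldspot/ns labels at significance level ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if degenerate is None:
        degenerate = np.isnan(scores)
    with np.errstate(invalid="ignore"):
        hot = ~degenerate & (scores > 0) & (pvalues < alpha)
        cold = ~degenerate & (scores < 0) & (pvalues < alpha)
    labels = np.full(len(scores), LABEL_NS, dtype=object)
    labels[hot] = LABEL_HOT
    labels[cold] = LABEL_COLD
    return labels


def year_seed(master_seed: int, year_index: int) -> np.random.SeedSequence:
    """Per-year sub-seed: SeedSequence([master, year_index]).

    The counter scheme makes each year's permutation stream a pure function
    of (master seed, year position), independent of execution order.
    """
    return np.random.SeedSequence([int(master_seed), int(year_index)])


def run_yearly(
    stack: AnnualFieldStack,
    weights: NeighborWeights,
    cell_ids: np.ndarray,
    *,
    nsim: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
) -> GiResult:
    """Score, test and label every cell for every year of the stack.

    Each year draws its permutations from a sub-seed derived from the master
    seed and the year's position, so the long table is reproducible and the
    years are mutually independent.
    """
    if stack.n_cells != weights.n_cells:
        raise ValueError("stack is not aligned with the weights lattice")
    frames = []
    for t, year in enumerate(stack.years):
        x = stack.values[t]
        scores, degen = gi_star_scores(x, weights)
        rng = np.random.default_rng(year_seed(seed, t))
        pvals = mc_pvalues(x, weights, scores, nsim=nsim, seed=rng, degenerate=degen)
        labels = classify_year(scores, pvals, alpha=alpha, degenerate=degen)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cell_ids,
                    "year": year,
                    "gi_score": scores,
                    "p_value": pvals,
                    "label": labels,
                    "degenerate": degen,
                }
            )
        )
    return GiResult(table=pd.concat(frames, ignore_index=True))
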