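"""Pipeline orchestration: configuration, CSV/JSON interchange, validation, end-to-end run.

The pipeline chains lattice construction → yearly Gi* labeling → two-period
trend classification → zonal/exposure summaries, writing every intermediate
artifact as CSV with a JSON manifest (config hash, seed, library versions,
per-stage row counts).  Inputs come either from CSV tables on disk or from
the synthetic generator (a ``simulate:`` section in the config).  All floats
are serialized with 10 significant digits and fixed column order, so a rerun
with the same config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gistar, summaries, trend as trend_mod
from .lattice import GridLattice, NeighborWeights, queen_neighbors, prune_empty
from .synthetic import SimulationConfig, SourceSchedule, simulate_field_stack, simulate_population, planted_truth

__all__ = [
    "PipelineConfig",
    "ValidationIssue",
    "validate_inputs",
    "run_pipeline",
    "write_lattice",
    "read_lattice",
    "write_weights",
    "read_weights",
]

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# interchange formats

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_lattice(lattice: GridLattice, outdir: Path) -> None:
    """cells.csv (cell_id,row,col) of valid cells + lattice.json metadata."""
    outdir = Path(outdir)
    rows, cols = lattice.rows_cols()
    _write_csv(pd.DataFrame({"cell_id": lattice.cell_ids, "row": rows, "col": cols}), outdir / "cells.csv")
    meta = {"n_rows": lattice.n_rows, "n_cols": lattice.n_cols, "cell_size": lattice.cell_size}
    (outdir / "lattice.json").write_text(json.dumps(meta, sort_keys=True) + "\n")


def read_lattice(outdir: Path) -> GridLattice:
    outdir = Path(outdir)
    meta = json.loads((outdir / "lattice.json").read_text())
    cells = pd.read_csv(outdir / "cells.csv")
    return GridLattice.from_cell_table(
        cells, n_rows=meta["n_rows"], n_cols=meta["n_cols"], cell_size=meta["cell_size"]
    )


def write_weights(weights: NeighborWeights, lattice: GridLattice, outdir: Path) -> None:
    """Two-column edge list (i,j as cell ids) + JSON header."""
    outdir = Path(outdir)
    coo = weights.graph.tocoo()
    ids = lattice.cell_ids
    _write_csv(pd.DataFrame({"i": ids[coo.row], "j": ids[coo.col]}).sort_values(["i", "j"]), outdir / "edges.csv")
    header = {"include_self": weights.include_self, "n_effective": weights.n_effective}
    (outdir / "weights.json").write_text(json.dumps(header, sort_keys=True) + "\n")


def read_weights(outdir: Path, lattice: GridLattice) -> NeighborWeights:
    import scipy.sparse as sp

    outdir = Path(outdir)
    header = json.loads((outdir / "weights.json").read_text())
    edges = pd.read_csv(outdir / "edges.csv")
    i = lattice.positions_of(edges["i"].to_numpy())
    j = lattice.positions_of(edges["j"].to_numpy())
    n = lattice.n_cells
    graph = sp.csr_matrix((np.ones(len(i), dtype=np.int8), (i, j)), shape=(n, n))
    return NeighborWeights(graph=graph, include_self=bool(header["include_self"]))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Everything a full run needs, loadable from one YAML file.

    Either ``simulate`` holds generator parameters, or ``input_dir`` points
    at a directory with cells.csv/lattice.json/stack.csv/population.csv
    (plus optional units.csv and points.csv).
    """

    output_dir: str = "out"
    seed: int = 0
    nsim: int = 99
    alpha: float = 0.05
    include_self: bool = True
    bin_width: float = 10.0
    exceedance_threshold: float = 40.0
    split_t1: tuple[int, ...] | None = None  # default: first half of the window
    split_t2: tuple[int, ...] | None = None
    thresholds: dict | None = None  # overrides of TrendThresholds fields
    simulate: dict | None = None
    input_dir: str | None = None
    points_radius: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.nsim < 1:
            raise ValueError("nsim must be at least 1")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.simulate is None and self.input_dir is None:
            raise ValueError("config needs either a simulate section or an input_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()

    def simulation_config(self) -> SimulationConfig:
        if self.simulate is None:
            raise ValueError("no simulate section in config")
        params = dict(self.simulate)
        sources = tuple(
            SourceSchedule(
                center=tuple(s["center"]),
                radius=int(s.get("radius", 2)),
                amplitude=float(s["amplitude"]),
                active_years=frozenset(s["active_years"]),
                decay=float(s.get("decay", 1.5)),
            )
            for s in params.pop("sources", [])
        )
        params.setdefault("seed", self.seed)
        if "gradient_vector" in params:
            params["gradient_vector"] = tuple(params["gradient_vector"])
        return SimulationConfig(sources=sources, **params)


@dataclass(frozen=True)
class ValidationIssue:
    level: str  # "fatal" | "warning"
    code: str
    message: str


def _load_inputs(config: PipelineConfig):
    """Return (lattice, stack, population, units, points, truth-or-None)."""
    if config.simulate is not None:
        sim = config.simulation_config()
        lattice, stack = simulate_field_stack(sim)
        population = simulate_population(sim, lattice)
        truth = planted_truth(sim)
        return lattice, stack, population, None, None, truth
    indir = Path(config.input_dir)
    lattice = read_lattice(indir)
    stack_long = pd.read_csv(indir / "stack.csv")
    stack = gistar.AnnualFieldStack.from_long(stack_long, lattice.cell_ids)
    population = pd.read_csv(indir / "population.csv")
    units = pd.read_csv(indir / "units.csv") if (indir / "units.csv").exists() else None
    points = pd.read_csv(indir / "points.csv") if (indir / "points.csv").exists() else None
    return lattice, stack, population, units, points, None


def _resolve_split(config: PipelineConfig, years: tuple[int, ...]) -> trend_mod.PeriodSplit:
    if config.split_t1 is not None and config.split_t2 is not None:
        return trend_mod.PeriodSplit(tuple(config.split_t1), tuple(config.split_t2))
    return trend_mod.PeriodSplit.halves(years)


def validate_inputs(config: PipelineConfig) -> list[ValidationIssue]:
    """Alignment, coverage and sanity checks; fatal issues abort a run."""
    issues: list[ValidationIssue] = []
    try:
        lattice, stack, population, units, points, _ = _load_inputs(config)
    except Exception as exc:  # report load failures as fatal, don't raise
        issues.append(ValidationIssue("fatal", "load-error", str(exc)))
        return issues
    if stack.n_cells != lattice.n_cells:
        issues.append(ValidationIssue("fatal", "misaligned-stack", "stack cell count differs from lattice"))
    pop_ids = set(population["cell_id"])
    if not set(lattice.cell_ids) <= pop_ids:
        issues.append(ValidationIssue("fatal", "misaligned-population", "population does not cover all lattice cells"))
    if (population["population"] < 0).any():
        issues.append(ValidationIssue("fatal", "negative-population", "population values must be non-negative"))
    try:
        split = _resolve_split(config, stack.years)
        missing = set(split.all_years) - set(stack.years)
        if missing:
            issues.append(
                ValidationIssue("fatal", "split-coverage", f"stack missing split years {sorted(missing)}")
            )
    except ValueError as exc:
        issues.append(ValidationIssue("fatal", "bad-split", str(exc)))
    if (stack.values < 0).any():
        issues.append(ValidationIssue("warning", "negative-exposure", "negative exposure values present"))
    if units is not None and not set(lattice.cell_ids) <= set(units["cell_id"]):
        issues.append(ValidationIssue("fatal", "misaligned-units", "unit partition does not cover all lattice cells"))
    if points is not None and not {"x", "y"} <= set(points.columns):
        issues.append(ValidationIssue("fatal", "malformed-points", "points table needs x and y columns"))
    return issues


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute lattice → gistar → trend → summaries, writing all artifacts.

    Returns the in-memory results keyed by stage.  Reruns with identical
    config and seed byte-reproduce every CSV output.
    """
    issues = validate_inputs(config)
    fatal = [i for i in issues if i.level == "fatal"]
    if fatal:
        raise StageError("validate", fatal[0].code, fatal[0].message)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, "stage-failure", str(exc)) from exc
        return deco

    lattice, stack, population, units, points, truth = _load_inputs(config)

    @stage("lattice")
    def lattice_result():
        weights = queen_neighbors(lattice, include_self=config.include_self)
        pruned_weights, pruned_lattice = prune_empty(weights, lattice)
        return pruned_weights, pruned_lattice

    weights, pruned = lattice_result
    if pruned.n_cells != lattice.n_cells:
        keep = pruned.cell_ids
        stack_p = stack.subset_cells(lattice.positions_of(keep))
    else:
        stack_p = stack
    write_lattice(pruned, outdir)
    write_weights(weights, pruned, outdir)
    counts["cells"] = pruned.n_cells
    _write_csv(stack_p.to_long(pruned.cell_ids), outdir / "stack.csv")
    pop = population[population["cell_id"].isin(pruned.cell_ids)].sort_values("cell_id", ignore_index=True)
    _write_csv(pop, outdir / "population.csv")
    if truth is not None:
        _write_csv(truth, outdir / "truth.csv")

    @stage("gistar")
    def gi_result():
        return gistar.run_yearly(
            stack_p, weights, pruned.cell_ids, nsim=config.nsim, alpha=config.alpha, seed=config.seed
        )

    gi = gi_result
    _write_csv(gi.table, outdir / "labels.csv")
    counts["cell_years"] = len(gi.table)

    @stage("trend")
    def trend_result():
        split = _resolve_split(config, stack_p.years)
        thresholds = (
            trend_mod.TrendThresholds(**config.thresholds)
            if config.thresholds
            else trend_mod.TrendThresholds.for_split(split)
        )
        return trend_mod.classify_trends(gi, split, thresholds)

    trend_table = trend_result
    _write_csv(trend_table, outdir / "trend.csv")
    counts["trend_cells"] = len(trend_table)

    @stage("summaries")
    def summary_result():
        ltm = summaries.long_term_average(stack_p, pruned.cell_ids)
        zonal = summaries.zonal_summary(trend_table, pruned, pop, ltm, units)
        bins = summaries.exposure_bins(trend_table, ltm, pop, pruned, bin_width=config.bin_width)
        exceed = summaries.exceedance(ltm, trend_table, pop, threshold=config.exceedance_threshold)
        tagged = (
            summaries.overlay_points(points, trend_table, pruned, radius=config.points_radius)
            if points is not None
            else None
        )
        return ltm, zonal, bins, exceed, tagged

    ltm, zonal, bins, exceed, tagged = summary_result
    _write_csv(ltm, outdir / "long_term.csv")
    _write_csv(zonal, outdir / "zonal.csv")
    _write_csv(bins, outdir / "bins.csv")
    _write_csv(exceed, outdir / "exceedance.csv")
    if tagged is not None:
        _write_csv(tagged, outdir / "points.csv")
    counts["zonal_rows"] = len(zonal)

    from . import __version__

    manifest = {
        "config_hash": config.canonical_hash(),
        "seed": config.seed,
        "versions": {
            "gridhotspots": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "row_counts": counts,
        "warnings": [asdict(i) for i in issues],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "lattice": pruned,
        "weights": weights,
        "stack": stack_p,
        "population": pop,
        "gi": gi,
        "trend": trend_table,
        "long_term": ltm,
        "zonal": zonal,
        "bins": bins,
        "exceedance": exceed,
        "points": tagged,
        "truth": truth,
        "manifest": manifest,
    }
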