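"""Field-trial designs: row-column NVT layouts and BioCal genotype x density trials.

A national variety trial (NVT) replicates each genotype ``n_reps`` times on a
row-column grid.  The companion biomass-calibration (BioCal) trial crosses a
small genotype panel with sowing densities so that destructive biomass cuts
span a wide biomass range.  Two BioCal templates are provided:

* ``biocal_2021_spec`` -- 6 genotypes x 3 densities (75/150/225 plants/m)
  plus one check genotype sown at 150, 187 and 112 plants/m: 21 plots.
* ``biocal_2022_spec`` -- 7 genotypes x 3 densities (75/150/300 plants/m)
  once each, plus a check genotype at all 3 densities twice: 27 plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Plot",
    "TrialDesign",
    "DesignSpec",
    "nvt_spec",
    "biocal_2021_spec",
    "biocal_2022_spec",
    "generate_design",
]


@dataclass(frozen=True)
class Plot:
    plot_id: str
    row: int
    column: int
    genotype: str
    density: float  # plants per metre of row
    replicate: int
    trial_type: str  # "NVT" or "BioCal"


@dataclass
class TrialDesign:
    experiment_id: str
    plots: list[Plot]

    def __post_init__(self) -> None:
        coords = [(p.row, p.column) for p in self.plots]
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate (row, column) positions in design")
        if any(p.row < 1 or p.column < 1 for p in self.plots):
            raise ValueError("rows and columns are 1-based positive integers")

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def genotypes(self) -> list[str]:
        return sorted({p.genotype for p in self.plots})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "experiment": self.experiment_id,
                    "plot_id": p.plot_id,
                    "row": p.row,
                    "column": p.column,
                    "genotype": p.genotype,
                    "density": p.density,
                    "replicate": p.replicate,
                    "trial_type": p.trial_type,
                }
                for p in self.plots
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialDesign":
        exp = str(df["experiment"].iloc[0]) if "experiment" in df else "E?"
        plots = [
            Plot(
                plot_id=str(r.plot_id),
                row=int(r.row),
                column=int(r.column),
                genotype=str(r.genotype),
                density=float(r.density),
                replicate=int(r.replicate),
                trial_type=str(r.trial_type),
            )
            for r in df.itertuples()
        ]
        return cls(experiment_id=exp, plots=plots)


@dataclass
class DesignSpec:
    """Declarative description of a trial; ``entries`` lists one
    (genotype, density, n_replicates) tuple per treatment."""

    trial_type: str
    entries: list[tuple[str, float, int]]
    n_rows: int
    n_cols: int
    label: str = "trial"

    @property
    def n_plots(self) -> int:
        return sum(reps for _, _, reps in self.entries)


def nvt_spec(n_genotypes: int = 30, n_reps: int = 3, n_rows: int | None = None,
             n_cols: int | None = None) -> DesignSpec:
    """Row-column NVT: each genotype in exactly ``n_reps`` plots."""
    n_plots = n_genotypes * n_reps
    if n_rows is None or n_cols is None:
        n_rows = n_reps
        n_cols = int(np.ceil(n_plots / n_rows))
    entries = [(f"G{i + 1:02d}", 150.0, n_reps) for i in range(n_genotypes)]
    return DesignSpec("NVT", entries, n_rows, n_cols, label="NVT")


def biocal_2021_spec() -> DesignSpec:
    """21-plot BioCal: 6 genotypes x {75,150,225} plants/m + check at
    {150,187,112}."""
    entries: list[tuple[str, float, int]] = []
    for i in range(6):
        for d in (75.0, 150.0, 225.0):
            entries.append((f"B{i + 1}", d, 1))
    for d in (150.0, 187.0, 112.0):
        entries.append(("CHECK", d, 1))
    return DesignSpec("BioCal", entries, n_rows=3, n_cols=7, label="BioCal-21")


def biocal_2022_spec() -> DesignSpec:
    """27-plot BioCal: 7 genotypes x {75,150,300} plants/m once each, check
    genotype at all three densities twice (7*3 + 1*3*2 = 27)."""
    entries: list[tuple[str, float, int]] = []
    for i in range(7):
        for d in (75.0, 150.0, 300.0):
            entries.append((f"B{i + 1}", d, 1))
    for d in (75.0, 150.0, 300.0):
        entries.append(("CHECK", d, 2))
    return DesignSpec("BioCal", entries, n_rows=3, n_cols=9, label="BioCal-27")


def generate_design(spec: DesignSpec, seed: int, experiment_id: str = "E1") -> TrialDesign:
    """Assign treatments to randomized grid positions.

    Only plot positions are randomized; the treatment list is fixed by the
    spec.  Deterministic for a given seed.
    """
    n_cells = spec.n_rows * spec.n_cols
    if n_cells < spec.n_plots:
        raise ValueError(
            f"grid {spec.n_rows}x{spec.n_cols} too small for {spec.n_plots} plots"
        )
    rng = np.random.default_rng(seed)
    cells = [(r + 1, c + 1) for r in range(spec.n_rows) for c in range(spec.n_cols)]
    order = rng.permutation(n_cells)[: spec.n_plots]

    treatments: list[tuple[str, float, int]] = []
    for geno, dens, reps in spec.entries:
        for rep in range(1, reps + 1):
            treatments.append((geno, dens, rep))

    plots = []
    for k, (geno, dens, rep) in enumerate(treatments):
        row, col = cells[order[k]]
        plots.append(
            Plot(
                plot_id=f"{experiment_id}-{k + 1:03d}",
                row=row,
                column=col,
                genotype=geno,
                density=dens,
                replicate=rep,
                trial_type=spec.trial_type,
            )
        )
    return TrialDesign(experiment_id=experiment_id, plots=plots)
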