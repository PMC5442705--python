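"""Synthetic time-series scRNA-seq generator with ground-truth labels.

Gene trajectories are drawn from four template "biological process"
functions of a process-time parameter t:

    f1(t) = 5*c1*cos(t/5) + 8 + eps1
    f2(t) = 5*c2*sin(t/5) + 8 + eps2
    f3(t) = c3*(t/10)^2 + eps3 + 5
    f4(t) = 5*log(t + 1) + 8            (no noise terms)

with a trajectory coefficient c_i ~ N(1, 0.01) drawn once per series and
observation noise eps_i ~ N(0, sigma^2) drawn per time point.  t runs
over an equally spaced grid of 314 values from 0 to 10*pi.

A dataset contains two cells (one per time period) and two gene groups:
non-heterogeneous genes follow the same template function in both cells;
heterogeneous genes follow a different template in each cell.  Each
cell's time points are subsampled from the grid — evenly spaced or an
uneven sorted draw without replacement — and the two cells may use
different numbers of points.  Values are floored at 0 to stay on the
expression (FPKM-like) scale.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import ExpressionSeriesSet, GeneTimeSeries
from .exceptions import ValidationError

__all__ = [
    "FAMILIES",
    "GRID_SIZE",
    "SimulationConfig",
    "SimulatedDataset",
    "process_function",
    "time_grid",
    "condition_preset",
    "simulate_dataset",
    "write_truth",
]

FAMILIES = ("f1", "f2", "f3", "f4")
GRID_SIZE = 314
_C_SD = 0.1  # c_i ~ N(1, 0.01)

# Ordered template pairs for the six standard simulation conditions.
# Conditions 1 and 2 are (f2, f3) and (f2, f4); the remaining distinct
# pairs are assigned to 3..6 by declared convention.
_CONDITION_PAIRS = {
    1: ("f2", "f3"),
    2: ("f2", "f4"),
    3: ("f1", "f2"),
    4: ("f1", "f3"),
    5: ("f1", "f4"),
    6: ("f3", "f4"),
}


def time_grid() -> np.ndarray:
    """The canonical process-time grid: 314 equally spaced values, 0 to 10*pi."""
    return np.linspace(0.0, 10.0 * math.pi, GRID_SIZE)


def process_function(
    family: str, t, c: float = 1.0, eps=0.0, *, noisy_f4: bool = False
) -> np.ndarray:
    """Evaluate one template trajectory at process time(s) t.

    ``c`` is the trajectory coefficient, ``eps`` the additive noise
    (scalar or array broadcastable against t).  f4 is deterministic —
    it carries no coefficient or noise term — unless ``noisy_f4`` is
    set, which applies c and eps to it for symmetry experiments.
    """
    t = np.asarray(t, dtype=float)
    if family == "f1":
        return 5.0 * c * np.cos(t / 5.0) + 8.0 + eps
    if family == "f2":
        return 5.0 * c * np.sin(t / 5.0) + 8.0 + eps
    if family == "f3":
        return c * (t / 10.0) ** 2 + eps + 5.0
    if family == "f4":
        base = 5.0 * np.log(t + 1.0) + 8.0
        if noisy_f4:
            return c * base + eps  # symmetry-experiment variant
        return base + np.zeros_like(t)
    raise ValidationError(f"unknown process family {family!r}; expected {FAMILIES}")


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a two-cell, two-group synthetic time course.

    Defaults follow the standard study design: 500 non-heterogeneous +
    500 heterogeneous genes, noise SD sigma = 1, 30 unevenly subsampled
    time points per cell from the 314-point grid.
    """

    n_genes_same: int = 500
    n_genes_diff: int = 500
    family_pair: tuple[str, str] = ("f2", "f3")
    sigma: float = 1.0
    coefficient_sd: float = _C_SD
    points_per_cell: tuple[int, int] = (30, 30)
    sampling: str = "uneven"
    seed: int = 0
    noisy_f4: bool = False

    def __post_init__(self) -> None:
        if self.n_genes_same < 1 or self.n_genes_diff < 1:
            raise ValidationError("gene counts must be >= 1")
        if self.sigma < 0 or self.coefficient_sd < 0:
            raise ValidationError("noise SDs must be >= 0")
        for fam in self.family_pair:
            if fam not in FAMILIES:
                raise ValidationError(f"unknown process family {fam!r}")
        if self.sampling not in ("even", "uneven"):
            raise ValidationError(
                f"unknown sampling {self.sampling!r}; expected 'even' or 'uneven'"
            )
        for k in self.points_per_cell:
            if not 1 <= k <= GRID_SIZE:
                raise ValidationError(
                    f"points_per_cell must be in [1, {GRID_SIZE}], got {k}"
                )


@dataclass(frozen=True)
class SimulatedDataset:
    """Generated series set plus per-gene ground-truth heterogeneity labels."""

    sset: ExpressionSeriesSet
    truth: dict[str, str]  # gene_id -> heterogeneous | non_heterogeneous

    @property
    def truth_binary(self) -> np.ndarray:
        """1 for heterogeneous genes, 0 otherwise, in gene_ids order."""
        return np.array(
            [1 if self.truth[g] == "heterogeneous" else 0 for g in self.sset.gene_ids]
        )


def condition_preset(condition: int, **overrides) -> SimulationConfig:
    """Standard simulation condition 1..6 (template pair per condition);
    remaining fields at their documented defaults unless overridden."""
    if condition not in _CONDITION_PAIRS:
        raise ValidationError(
            f"condition must be in 1..6, got {condition}"
        )
    return replace(
        SimulationConfig(family_pair=_CONDITION_PAIRS[condition]), **overrides
    )


def _subsample(rng: np.random.Generator, k: int, sampling: str) -> np.ndarray:
    if sampling == "even":
        # floor keeps the indices strictly increasing (spacing >= 1)
        return np.linspace(0, GRID_SIZE - 1, k).astype(int)
    return np.sort(rng.choice(GRID_SIZE, size=k, replace=False))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a :class:`SimulatedDataset` according to ``config``.

    Two cells, ``cell1`` (group ``period1``) and ``cell2`` (group
    ``period2``), each with its own time subsample shared by all genes.
    Non-heterogeneous genes draw both series from the first template of
    ``family_pair``; heterogeneous genes draw cell1 from the first and
    cell2 from the second template, with fresh c and eps per series.
    """
    rng = np.random.default_rng(config.seed)
    grid = time_grid()
    idx1 = _subsample(rng, config.points_per_cell[0], config.sampling)
    idx2 = _subsample(rng, config.points_per_cell[1], config.sampling)
    t1, t2 = grid[idx1], grid[idx2]

    fa, fb = config.family_pair
    gene_ids: list[str] = []
    truth: dict[str, str] = {}
    series: dict[tuple[str, str], GeneTimeSeries] = {}

    def draw(family: str, t: np.ndarray) -> np.ndarray:
        c = 1.0 + config.coefficient_sd * rng.standard_normal()
        eps = config.sigma * rng.standard_normal(len(t))
        vals = process_function(family, t, c, eps, noisy_f4=config.noisy_f4)
        return np.maximum(vals, 0.0)  # clip to the expression scale

    width = len(str(config.n_genes_same + config.n_genes_diff))
    for i in range(config.n_genes_same):
        gid = f"gene{i + 1:0{width}d}"
        gene_ids.append(gid)
        truth[gid] = "non_heterogeneous"
        series[(gid, "cell1")] = GeneTimeSeries(gid, "cell1", t1, draw(fa, t1))
        series[(gid, "cell2")] = GeneTimeSeries(gid, "cell2", t2, draw(fa, t2))
    for i in range(config.n_genes_diff):
        gid = f"gene{config.n_genes_same + i + 1:0{width}d}"
        gene_ids.append(gid)
        truth[gid] = "heterogeneous"
        series[(gid, "cell1")] = GeneTimeSeries(gid, "cell1", t1, draw(fa, t1))
        series[(gid, "cell2")] = GeneTimeSeries(gid, "cell2", t2, draw(fb, t2))

    sset = ExpressionSeriesSet(
        gene_ids=gene_ids,
        cell_ids=["cell1", "cell2"],
        group_of_cell={"cell1": "period1", "cell2": "period2"},
        series=series,
    )
    return SimulatedDataset(sset=sset, truth=truth)


def write_truth(dataset: SimulatedDataset, path) -> None:
    """Write the gene_id -> truth table as TSV."""
    import pandas as pd

    pd.DataFrame(
        {
            "gene_id": dataset.sset.gene_ids,
            "truth": [dataset.truth[g] for g in dataset.sset.gene_ids],
        }
    ).to_csv(path, sep="\t", index=False)
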