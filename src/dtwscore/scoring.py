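"""Per-gene heterogeneity scores and the normal threshold model.

A gene's DTWscore D_i is the arithmetic mean of the path-length-normalized
DTW distance gamma(n1,n2)/(n1+n2) over cell pairs: all unordered pairs
(``all_pairs``) or all pairs with one cell from each of two groups
(``cross_group``).  Genes whose temporal trajectories differ between cells
accumulate large warping costs and hence large scores.

Scores across genes are modelled as D_i ~ N(mu, sigma^2) with mu the mean
and sigma^2 the population (divisor-N) variance; the selection threshold is
either mu + k*sigma (default k = 4) or a normal quantile mu + z(q)*sigma
(default q = 0.95).  Genes scoring strictly above the threshold are called
heterogeneous / highly variable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionSeriesSet
from .dtw_core import dtw_distance
from .exceptions import ValidationError

__all__ = [
    "GeneScoreTable",
    "ThresholdModel",
    "score_all",
    "fit_score_distribution",
    "select_heterogeneous_genes",
]


@dataclass(frozen=True)
class GeneScoreTable:
    """Per-gene DTWscores and the number of cell pairs averaged."""

    scores: pd.Series  # index gene_id, values D_i >= 0
    n_pairs: int
    pairing: str
    metric: str

    def __post_init__(self) -> None:
        arr = self.scores.to_numpy()
        if len(arr) == 0:
            raise ValidationError("empty score table")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValidationError("scores must be finite and non-negative")

    def to_frame(self, selected: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"dtwscore": self.scores, "n_pairs": self.n_pairs},
        )
        df.index.name = "gene_id"
        if selected is not None:
            df["selected"] = df.index.isin(selected).astype(int)
        return df


@dataclass(frozen=True)
class ThresholdModel:
    """Fitted normal model of the score distribution and its cut-off.

    ``sd_multiple``: threshold = mu + k * sigma (default k = 4).
    ``normal_quantile``: threshold = mu + z(quantile) * sigma with z the
    standard-normal inverse CDF (default quantile = 0.95).
    """

    mu: float
    sigma: float
    method: str
    k: float
    quantile: float
    threshold: float

    def summary(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "method": self.method,
            "k": self.k,
            "quantile": self.quantile,
            "threshold": self.threshold,
        }


def _cell_pairs(sset: ExpressionSeriesSet, pairing: str) -> list[tuple[str, str]]:
    if pairing == "all_pairs":
        if sset.n_cells < 2:
            raise ValidationError("all_pairs scoring needs at least 2 cells")
        return list(itertools.combinations(sset.cell_ids, 2))
    if pairing == "cross_group":
        groups = sorted(set(sset.group_of_cell.values()))
        if len(groups) != 2:
            raise ValidationError(
                f"cross_group scoring needs exactly 2 groups, found {groups}"
            )
        g1 = [c for c in sset.cell_ids if sset.group_of_cell[c] == groups[0]]
        g2 = [c for c in sset.cell_ids if sset.group_of_cell[c] == groups[1]]
        if not g1 or not g2:
            raise ValidationError("cross_group scoring: a group is empty")
        return [(a, b) for a in g1 for b in g2]
    raise ValidationError(
        f"unknown pairing {pairing!r}; expected 'all_pairs' or 'cross_group'"
    )


def score_all(
    sset: ExpressionSeriesSet,
    pairing: str = "all_pairs",
    metric: str = "euclidean",
    *,
    rescale: bool = False,
) -> GeneScoreTable:
    """Mean normalized DTW distance over cell pairs, per gene.

    Parameters
    ----------
    sset
        Validated expression series set.
    pairing
        ``all_pairs`` (every unordered cell pair) or ``cross_group``
        (one cell from each of two groups).
    metric
        Local distance between scalar expression values.
    rescale
        Optionally min–max rescale the scores to [0, 1] across genes
        (exploratory; off by default — the per-pair path-length
        normalization is the scale the threshold model expects).
    """
    pairs = _cell_pairs(sset, pairing)
    scores = np.zeros(sset.n_genes)
    for i, gene in enumerate(sset.gene_ids):
        total = 0.0
        for ca, cb in pairs:
            a = sset.series[(gene, ca)]
            b = sset.series[(gene, cb)]
            total += dtw_distance(a.values, b.values, metric) / (len(a) + len(b))
        scores[i] = total / len(pairs)
    if rescale:
        lo, hi = scores.min(), scores.max()
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
        else:
            scores = np.zeros_like(scores)
    return GeneScoreTable(
        scores=pd.Series(scores, index=pd.Index(sset.gene_ids, name="gene_id")),
        n_pairs=len(pairs),
        pairing=pairing,
        metric=metric,
    )


def fit_score_distribution(
    table: GeneScoreTable,
    method: str = "sd_multiple",
    k: float = 4.0,
    quantile: float = 0.95,
) -> ThresholdModel:
    """Fit D_i ~ N(mu, sigma^2) and derive the selection threshold.

    mu is the arithmetic mean of the scores and sigma the population
    (divisor-N) standard deviation.  With a single gene the spread is
    degenerate (sigma = 0); a warning is emitted rather than an error.
    """
    arr = table.scores.to_numpy()
    if len(arr) == 1:
        warnings.warn(
            "threshold model fitted on a single gene: sigma is 0 and the "
            "threshold degenerates to the score itself",
            stacklevel=2,
        )
    mu = float(np.mean(arr))
    sigma = float(np.std(arr))  # population SD, divisor N
    if method == "sd_multiple":
        threshold = mu + k * sigma
    elif method == "normal_quantile":
        if not 0.0 < quantile < 1.0:
            raise ValidationError(f"quantile must be in (0, 1), got {quantile}")
        threshold = mu + float(stats.norm.ppf(quantile)) * sigma
    else:
        raise ValidationError(
            f"unknown method {method!r}; expected 'sd_multiple' or 'normal_quantile'"
        )
    return ThresholdModel(
        mu=mu, sigma=sigma, method=method, k=k, quantile=quantile, threshold=threshold
    )


def select_heterogeneous_genes(
    table: GeneScoreTable, model: ThresholdModel
) -> list[str]:
    """Genes scoring strictly above the threshold, sorted by descending score.

    An empty list is a valid result (nothing stands out of the null
    distribution); with sigma = 0 every score equals the threshold and
    nothing is selected.
    """
    above = table.scores[table.scores > model.threshold]
    return list(above.sort_values(ascending=False).index)


def plot_score_distribution(table: GeneScoreTable, path: str) -> None:
    """Histogram + normal Q-Q plot of the scores (diagnostic for the
    normality assumption behind the threshold model)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = table.scores.to_numpy()
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.hist(arr, bins=min(50, max(10, len(arr) // 20)), color="steelblue")
    ax1.set_xlabel("DTWscore")
    ax1.set_ylabel("genes")
    stats.probplot(arr, dist="norm", plot=ax2)
    ax2.set_title("Normal Q-Q")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
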