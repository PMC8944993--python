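"""Feature importance from connection weights (Garson's equation).

For input i and hidden unit j the contribution is
c_ij = |Wi[j, i]| * |Wo[j]|; contributions are normalized within each hidden
unit (share_ij = c_ij / sum_k c_kj), summed over hidden units, and rescaled
so the 14 relative importances add to 100%.  Biases are excluded -- the
classic formulation uses connection weights only -- and signs are discarded,
so importances are magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import NetworkParams
from .panel import FEATURE_NAMES


@dataclass
class ImportanceRanking:
    """Relative importance (percent) of each input feature; sums to 100."""

    feature_names: list[str]
    percents: np.ndarray

    def __post_init__(self) -> None:
        self.percents = np.asarray(self.percents, dtype=float).ravel()
        if len(self.feature_names) != self.percents.size:
            raise ValueError("one percentage per feature required")

    def as_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.percents, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(order) + 1)
        return pd.DataFrame({
            "feature": self.feature_names,
            "percent": self.percents,
            "rank": ranks,
        })

    def to_csv(self, path) -> None:
        self.as_frame().to_csv(path, index=False)


def relative_importance(params: NetworkParams,
                        feature_names: list[str] | None = None
                        ) -> ImportanceRanking:
    """Garson relative importance of every input, in percent.

    A hidden unit whose incoming weights are all zero contributes zero
    shares (it transmits nothing) rather than dividing by zero.
    """
    names = list(feature_names or FEATURE_NAMES[:params.n_inputs])
    if len(names) != params.n_inputs:
        raise ValueError("feature_names length must match the input layer")
    C = np.abs(params.Wi) * np.abs(params.Wo)[:, None]   # (h, n_in)
    col = C.sum(axis=1, keepdims=True)                   # per hidden unit
    shares = np.divide(C, col, out=np.zeros_like(C), where=col > 0)
    totals = shares.sum(axis=0)                          # per input
    grand = totals.sum()
    if grand == 0:
        # every path has zero weight: no information flows, importance is flat
        percents = np.full(params.n_inputs, 100.0 / params.n_inputs)
    else:
        percents = 100.0 * totals / grand
    return ImportanceRanking(feature_names=names, percents=percents)


def rank_features(ranking: ImportanceRanking, top_n: int | None = None
                  ) -> list[tuple[str, float]]:
    """Features in descending importance; ties break by canonical (input)
    order so results are stable across runs.  ``top_n`` beyond the panel
    size is truncated."""
    order = np.argsort(-ranking.percents, kind="stable")
    pairs = [(ranking.feature_names[i], float(ranking.percents[i]))
             for i in order]
    if top_n is not None:
        pairs = pairs[:max(0, min(top_n, len(pairs)))]
    return pairs


def importance_bar_chart(ranking: ImportanceRanking, path,
                         title="Relative importance of maternal features"):
    """Optional artifact: horizontal bar chart of the ranking."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = rank_features(ranking)
    names = [p[0] for p in pairs][::-1]
    vals = [p[1] for p in pairs][::-1]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.barh(names, vals)
    ax.set_xlabel("relative importance (%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
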