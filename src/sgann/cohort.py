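"""Synthetic maternal cohort generation.

Two modes:

``table1``
    Draws SGA and AGA groups whose continuous features follow per-group
    truncated normal distributions with the published means/SDs and whose
    binary multivitamin feature follows the published per-group frequencies
    (SGA 4/14, AGA 24/63).  Features are sampled independently by default;
    an optional user-supplied correlation matrix induces dependence through
    a Gaussian copula.

``oracle``
    Draws the same feature mixture, then produces the codified target from
    a *known* ground-truth 14-h-1 network evaluated on the min-max-scaled
    features, plus optional Gaussian output noise.  The outcome label is the
    interval classification of the noiseless output.  This makes function
    recovery by the trainer a testable property: with zero noise the target
    is exactly reproducible by a forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from . import network as nn
from .panel import (AGA, BINARY, CONTINUOUS, FEATURE_NAMES, SGA, FeatureSpec,
                    table1_panel, validate_panel)
from .preprocessing import fit_normalizer, normalize
from .simulator import ClassificationIntervals

TABLE1 = "table1"
ORACLE = "oracle"


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort draw.

    ``oracle_truth=None`` in oracle mode draws a seeded ground-truth network
    (weights uniform on [-2, 2], hidden size ``oracle_hidden``) and rescales
    its output layer so the noiseless outputs span both classification
    intervals (see :func:`scale_truth_to_intervals`).
    """

    n_sga: int
    n_aga: int
    seed: int = 0
    mode: str = TABLE1
    oracle_truth: "nn.NetworkParams | None" = None
    oracle_noise_sd: float = 0.0
    oracle_hidden: int = 2
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_sga < 0 or self.n_aga < 0:
            raise ValueError("group counts must be nonnegative")
        if self.n_sga + self.n_aga < 2:
            raise ValueError("cohort must contain at least 2 rows")
        if self.mode not in (TABLE1, ORACLE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.oracle_noise_sd < 0:
            raise ValueError("oracle_noise_sd must be >= 0")


def _truncated_normal_rejection(rng: np.random.Generator, mean: float,
                                sd: float, lo: float, hi: float,
                                size: int) -> np.ndarray:
    """Exact truncated-normal draws by rejection from the parent normal."""
    if sd == 0:
        return np.full(size, mean)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=max(size - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def _draw_group(rng: np.random.Generator, panel: list[FeatureSpec],
                group: str, n: int,
                correlation: np.ndarray | None) -> pd.DataFrame:
    """Draw n rows of the 14 features for one outcome group."""
    cols = {}
    if correlation is None:
        for spec in panel:
            if spec.kind == CONTINUOUS:
                mean, sd = spec.group_params(group)
                lo, hi = spec.truncation(group)
                cols[spec.name] = _truncated_normal_rejection(rng, mean, sd, lo, hi, n)
            else:
                rate = spec.group_rate(group)
                cols[spec.name] = (rng.random(n) < rate).astype(float)
    else:
        # Gaussian copula: correlated uniforms pushed through each marginal
        R = np.asarray(correlation, dtype=float)
        if R.shape != (len(panel), len(panel)):
            raise ValueError("correlation matrix must be 14x14")
        L = np.linalg.cholesky(R)
        Z = rng.standard_normal((n, len(panel))) @ L.T
        U = scipy.stats.norm.cdf(Z)
        for j, spec in enumerate(panel):
            if spec.kind == CONTINUOUS:
                mean, sd = spec.group_params(group)
                lo, hi = spec.truncation(group)
                a, b = (lo - mean) / sd, (hi - mean) / sd
                cols[spec.name] = scipy.stats.truncnorm.ppf(
                    U[:, j], a, b, loc=mean, scale=sd)
            else:
                cols[spec.name] = (U[:, j] < spec.group_rate(group)).astype(float)
    return pd.DataFrame(cols)


def generate_table1_cohort(config: CohortConfig,
                           panel: list[FeatureSpec] | None = None) -> pd.DataFrame:
    """Generate a labeled cohort calibrated to the published group statistics.

    Returns a DataFrame with the 14 feature columns in canonical order plus
    ``outcome`` (SGA | AGA) and ``target`` (0.5 | 1.0).  Deterministic given
    ``config.seed``.
    """
    if config.mode != TABLE1:
        raise ValueError("generate_table1_cohort requires mode='table1'")
    panel = panel if panel is not None else table1_panel()
    validate_panel(panel)
    rng = np.random.default_rng(config.seed)
    frames = []
    for group, n in ((SGA, config.n_sga), (AGA, config.n_aga)):
        if n == 0:
            continue
        df = _draw_group(rng, panel, group, n, config.correlation)
        df["outcome"] = group
        df["target"] = 0.5 if group == SGA else 1.0
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[FEATURE_NAMES + ["outcome", "target"]]


def scale_truth_to_intervals(truth: nn.NetworkParams, X_norm: np.ndarray,
                             output_span=(0.48, 0.95),
                             quantiles=(0.10, 0.90)) -> nn.NetworkParams:
    """Affinely rescale a network's output layer so its noiseless outputs
    span both classification intervals on the given (normalized) inputs.

    The pre-sigmoid activation z is mapped so that its ``quantiles`` land on
    logit(output_span); outputs then cover the SGA band (around and below
    0.79) and the AGA band (0.8-1.0) with substantial mass in each.
    """
    a1 = nn.hidden_activations(X_norm, truth)
    z = a1 @ truth.Wo + truth.b2
    z_lo, z_hi = np.quantile(z, quantiles)
    if z_hi - z_lo < 1e-12:
        raise ValueError("degenerate truth: constant pre-sigmoid activation")
    logit = lambda p: float(np.log(p / (1.0 - p)))
    a = (logit(output_span[1]) - logit(output_span[0])) / (z_hi - z_lo)
    c = logit(output_span[0]) - a * z_lo
    return nn.NetworkParams(truth.Wi.copy(), truth.b1.copy(),
                            a * truth.Wo, a * truth.b2 + c,
                            truth.hidden_activation)


def draw_oracle_truth(seed: int, h: int = 2, n_inputs: int = nn.N_INPUTS,
                      scale: float = 2.0) -> nn.NetworkParams:
    """Seeded ground-truth network with all weights/biases uniform on
    [-scale, scale] (before output rescaling)."""
    rng = np.random.default_rng(seed)
    return nn.NetworkParams(
        Wi=rng.uniform(-scale, scale, size=(h, n_inputs)),
        b1=rng.uniform(-scale, scale, size=h),
        Wo=rng.uniform(-scale, scale, size=h),
        b2=rng.uniform(-scale, scale),
    )


def generate_oracle_cohort(config: CohortConfig,
                           panel: list[FeatureSpec] | None = None,
                           intervals: ClassificationIntervals | None = None,
                           return_details: bool = False):
    """Generate a cohort whose targets come from a known ground-truth network.

    Features are drawn exactly as in table1 mode (SGA/AGA mixture given by
    the config counts), min-max scaled on the full cohort, and pushed
    through the truth network; Gaussian noise of sd ``oracle_noise_sd`` is
    added to the codified target (clipped to [0, 1]).  The outcome label is
    the interval classification of the *noiseless* output (an output below
    the AGA band maps to SGA).  Deterministic given ``config.seed``.

    With ``return_details=True`` also returns the (possibly rescaled) truth,
    the fitted normalizer and the noiseless outputs.
    """
    if config.mode != ORACLE:
        raise ValueError("generate_oracle_cohort requires mode='oracle'")
    panel = panel if panel is not None else table1_panel()
    validate_panel(panel)
    intervals = intervals or ClassificationIntervals()

    ss = np.random.SeedSequence(config.seed)
    feat_seed, truth_seed, noise_seed = (int(s) & 0x7FFFFFFF
                                         for s in ss.generate_state(3))
    rng = np.random.default_rng(feat_seed)
    frames = []
    for group, n in ((SGA, config.n_sga), (AGA, config.n_aga)):
        if n:
            frames.append(_draw_group(rng, panel, group, n, config.correlation))
    X = pd.concat(frames, ignore_index=True)[FEATURE_NAMES]

    norm = fit_normalizer(X)
    X_norm = normalize(X, norm)

    truth = config.oracle_truth
    if truth is None:
        truth = scale_truth_to_intervals(
            draw_oracle_truth(truth_seed, config.oracle_hidden), X_norm)
    if truth.n_inputs != len(FEATURE_NAMES):
        raise ValueError(
            f"oracle truth expects {truth.n_inputs} inputs, panel has "
            f"{len(FEATURE_NAMES)}")

    noiseless = np.asarray(nn.forward(X_norm, truth))
    noise_rng = np.random.default_rng(noise_seed)
    if config.oracle_noise_sd > 0:
        target = np.clip(noiseless + noise_rng.normal(
            0.0, config.oracle_noise_sd, size=noiseless.size), 0.0, 1.0)
    else:
        target = noiseless.copy()

    # binary label from the noiseless output: anything below the AGA band is
    # SGA-leaning (the SGA band sits below the AGA band)
    rounded = np.round(noiseless, 2)
    outcome = np.where(rounded < intervals.aga_low, SGA, AGA)

    cohort = X.copy()
    cohort["outcome"] = outcome
    cohort["target"] = target
    if return_details:
        return cohort, truth, norm, noiseless
    return cohort


@dataclass
class CohortSummary:
    """Descriptive summary: per-group and pooled mean +/- SD for continuous
    features, frequencies for binary features and outcome labels."""

    continuous: pd.DataFrame
    frequencies: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (self.continuous.to_string(float_format=lambda v: f"{v:.2f}")
                + "\n\n" + self.frequencies.to_string())


def summarize_cohort(cohort: pd.DataFrame,
                     panel: list[FeatureSpec] | None = None) -> CohortSummary:
    """Mean +/- SD per feature per outcome group plus a pooled column, and
    category frequencies for binary features and the outcome label."""
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    panel = panel if panel is not None else table1_panel()
    groups = {"pooled": cohort}
    for g in (SGA, AGA):
        sub = cohort[cohort["outcome"] == g]
        if len(sub):
            groups[g] = sub

    rows = []
    for spec in panel:
        if spec.kind != CONTINUOUS:
            continue
        row = {"feature": spec.name, "units": spec.units}
        for gname, sub in groups.items():
            vals = sub[spec.name].to_numpy(dtype=float)
            row[f"{gname}_mean"] = float(np.mean(vals))
            row[f"{gname}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    continuous = pd.DataFrame(rows).set_index("feature")

    freq_rows = []
    n = len(cohort)
    for g in (SGA, AGA):
        count = int((cohort["outcome"] == g).sum())
        freq_rows.append({"variable": "outcome", "category": g,
                          "count": count, "percent": 100.0 * count / n})
    for spec in panel:
        if spec.kind != BINARY:
            continue
        for cat, val in (("yes", 1.0), ("no", 0.0)):
            count = int((cohort[spec.name] == val).sum())
            freq_rows.append({"variable": spec.name, "category": cat,
                              "count": count, "percent": 100.0 * count / n})
    frequencies = pd.DataFrame(freq_rows)
    return CohortSummary(continuous=continuous, frequencies=frequencies)


def truncated_moments(spec: FeatureSpec, group: str) -> tuple[float, float]:
    """Analytic mean and SD of the truncated normal actually sampled for a
    continuous feature in ``group`` (uses scipy.stats.truncnorm)."""
    mean, sd = spec.group_params(group)
    if sd == 0:
        return mean, 0.0
    lo, hi = spec.truncation(group)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = scipy.stats.truncnorm(a, b, loc=mean, scale=sd)
    return float(dist.mean()), float(dist.std())
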