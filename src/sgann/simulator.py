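"""What-if scenario engine.

A trained model travels as a portable bundle (weights, biases, per-feature
normalization bounds, output intervals, feature order) in JSON, with a flat
CSV companion for spreadsheet embedding.  A scenario is a named vector of
the 14 raw maternal features; simulation normalizes it, runs the forward
pass, and classifies the output by interval:

    output in [0.4, 0.79]  -> SGA
    output in [0.8, 1.0]   -> AGA
    otherwise              -> indeterminate

Outputs in the two-decimal gap (0.79, 0.8) are resolved by rounding to two
decimals before lookup.  Preset scenarios probe the published what-if axes
for a normal-weight pregnancy (pBMI fixed at 24 kg/m^2): first-trimester
gestational weight gain (adequate 0.5-2.0 kg vs excessive > 2.0 kg),
vitamin D status (deficient < 20 vs adequate > 30 ng/mL), and redox balance
(CP/MDA/TAC at the cohort means vs shifted one SD toward oxidative stress).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network as nn
from .panel import FEATURE_NAMES, POOLED_MEANS, table1_panel
from .preprocessing import NormalizationParams, normalize

INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ClassificationIntervals:
    """Output intervals mapping the network value to a predicted class.
    The SGA band lies strictly below the AGA band."""

    sga_low: float = 0.4
    sga_high: float = 0.79
    aga_low: float = 0.8
    aga_high: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sga_low < self.sga_high < self.aga_low <= self.aga_high):
            raise ValueError("intervals must be ordered: SGA band below AGA band")

    def to_dict(self) -> dict:
        return {"sga_low": self.sga_low, "sga_high": self.sga_high,
                "aga_low": self.aga_low, "aga_high": self.aga_high}


def classify_output(y: float, intervals: ClassificationIntervals | None = None,
                    decimals: int = 2) -> str:
    """Map a network output in [0, 1] to SGA / AGA / indeterminate.

    The output is rounded to ``decimals`` places first, which resolves the
    gap between the two bands (they are stated at two-decimal resolution).
    """
    intervals = intervals or ClassificationIntervals()
    y = float(y)
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"network output must lie in [0, 1], got {y}")
    yr = round(y, decimals)
    if intervals.sga_low <= yr <= intervals.sga_high:
        return "SGA"
    if intervals.aga_low <= yr <= intervals.aga_high:
        return "AGA"
    return INDETERMINATE


@dataclass
class Scenario:
    """A named maternal profile: all 14 raw features plus provenance notes."""

    label: str
    values: dict
    notes: str = ""

    def __post_init__(self) -> None:
        missing = [f for f in FEATURE_NAMES if f not in self.values]
        if missing:
            raise ValueError(f"scenario {self.label!r} missing feature(s): {missing}")

    def vector(self) -> np.ndarray:
        return np.array([float(self.values[f]) for f in FEATURE_NAMES])


def simulate(scenario: Scenario, model: nn.NetworkParams,
             normalizer: NormalizationParams,
             intervals: ClassificationIntervals | None = None
             ) -> tuple[float, str]:
    """Normalize -> forward -> classify; a pure function of its inputs."""
    intervals = intervals or ClassificationIntervals()
    if model.n_inputs != len(normalizer.feature_names):
        raise ValueError("model and normalizer disagree on the feature count")
    x = normalize(scenario.vector(), normalizer)
    y = float(nn.forward(x, model))
    return y, classify_output(y, intervals)


def simulate_table(scenarios: list[Scenario], model, normalizer,
                   intervals=None) -> pd.DataFrame:
    """Run a list of scenarios; one row per scenario with output and class."""
    rows = []
    for sc in scenarios:
        y, cls = simulate(sc, model, normalizer, intervals)
        rows.append({"scenario": sc.label, "output": y, "class": cls,
                     "notes": sc.notes})
    return pd.DataFrame(rows)


# -- preset what-if scenarios ---------------------------------------------

_GWG = {"adequate": 1.5, "excessive": 3.5}          # kg; excessive > 2.0
_VITD = {"adequate": 32.0, "deficient": 15.0}       # ng/mL; deficient < 20
_POOLED_SD = {"cp": 2617.0, "mda": 174.0, "tac": 28.4}


def _redox_values(state: str) -> dict:
    """Balanced: oxidation markers and antioxidant capacity at cohort means.
    Imbalanced: CP and MDA one SD up, TAC one SD down."""
    if state == "balanced":
        return {"cp": POOLED_MEANS["cp"], "mda": POOLED_MEANS["mda"],
                "tac": POOLED_MEANS["tac"]}
    return {"cp": POOLED_MEANS["cp"] + _POOLED_SD["cp"],
            "mda": POOLED_MEANS["mda"] + _POOLED_SD["mda"],
            "tac": max(POOLED_MEANS["tac"] - _POOLED_SD["tac"], 0.0)}


def preset_scenarios(include_obese: bool = False) -> list[Scenario]:
    """The what-if grid for a normal-weight pregnancy (pBMI = 24 kg/m^2):
    every combination of GWG (adequate/excessive), vitamin D status
    (adequate/deficient) and redox balance (balanced/imbalanced), all other
    features at the pooled cohort means.

    ``include_obese=True`` appends exploratory pBMI = 35 variants.
    """
    scenarios = []
    bmis = [("pBMI24", 24.0)] + ([("pBMI35", 35.0)] if include_obese else [])
    for bmi_tag, bmi in bmis:
        for gwg_tag, gwg in _GWG.items():
            for vd_tag, vd in _VITD.items():
                for redox_tag in ("balanced", "imbalanced"):
                    values = dict(POOLED_MEANS)
                    values["pbmi"] = bmi
                    values["gwg"] = gwg
                    values["vit_d"] = vd
                    values.update(_redox_values(redox_tag))
                    label = f"{bmi_tag}/GWG-{gwg_tag}/VitD-{vd_tag}/redox-{redox_tag}"
                    notes = (f"pBMI {bmi}, GWG {gwg} kg ({gwg_tag}), "
                             f"VitD {vd} ng/mL ({vd_tag}), redox {redox_tag}")
                    scenarios.append(Scenario(label, values, notes))
    return scenarios


def scenarios_from_csv(path) -> list[Scenario]:
    """Load scenarios from a CSV with a ``scenario`` column plus the 14
    canonical feature columns; raises naming any missing column."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"scenario file missing column(s): {missing}")
    label_col = "scenario" if "scenario" in df.columns else None
    out = []
    for i, row in df.iterrows():
        label = str(row[label_col]) if label_col else f"scenario_{i}"
        out.append(Scenario(label, {f: float(row[f]) for f in FEATURE_NAMES}))
    return out


# -- portable model bundle -------------------------------------------------

BUNDLE_FORMAT = "sgann-model-bundle-v1"


def export_model(model: nn.NetworkParams, normalizer: NormalizationParams,
                 intervals: ClassificationIntervals | None = None,
                 path=None) -> dict:
    """Serialize model + normalizer + intervals to a portable JSON bundle.

    Returns the bundle dict; writes it to ``path`` when given.  Floats are
    serialized at full precision, so a load/export round-trip reproduces
    forward outputs bit-for-bit.
    """
    intervals = intervals or ClassificationIntervals()
    bundle = {
        "format": BUNDLE_FORMAT,
        "feature_names": list(normalizer.feature_names),
        "normalization": normalizer.to_dict(),
        "network": {
            "hidden_units": model.h,
            "hidden_activation": model.hidden_activation,
            "Wi": model.Wi.tolist(),
            "b1": model.b1.tolist(),
            "Wo": model.Wo.tolist(),
            "b2": model.b2,
        },
        "intervals": intervals.to_dict(),
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(bundle, fh, indent=1)
    return bundle


def load_model(source) -> tuple[nn.NetworkParams, NormalizationParams,
                                ClassificationIntervals]:
    """Load a bundle written by :func:`export_model` (path or dict)."""
    if isinstance(source, dict):
        bundle = source
    else:
        with open(source) as fh:
            bundle = json.load(fh)
    try:
        if bundle.get("format") != BUNDLE_FORMAT:
            raise ValueError(
                f"format: expected {BUNDLE_FORMAT!r}, got {bundle.get('format')!r}")
        net = bundle["network"]
        model = nn.NetworkParams(
            Wi=np.asarray(net["Wi"], dtype=float),
            b1=np.asarray(net["b1"], dtype=float),
            Wo=np.asarray(net["Wo"], dtype=float),
            b2=float(net["b2"]),
            hidden_activation=net.get("hidden_activation", nn.TANSIG),
        )
        normalizer = NormalizationParams.from_dict(bundle["normalization"])
        intervals = ClassificationIntervals(**bundle["intervals"])
    except KeyError as exc:
        raise ValueError(f"corrupt model bundle: missing field {exc}") from exc
    return model, normalizer, intervals


def export_model_csv(model: nn.NetworkParams, normalizer: NormalizationParams,
                     path) -> None:
    """Spreadsheet-oriented flat CSV of the same numbers as the JSON bundle:
    one row per parameter (kind, hidden unit, feature, value)."""
    rows = []
    for j in range(model.h):
        for i, fname in enumerate(normalizer.feature_names):
            rows.append({"kind": "Wi", "hidden_unit": j, "feature": fname,
                         "value": model.Wi[j, i]})
    for j in range(model.h):
        rows.append({"kind": "b1", "hidden_unit": j, "feature": "",
                     "value": model.b1[j]})
    for j in range(model.h):
        rows.append({"kind": "Wo", "hidden_unit": j, "feature": "",
                     "value": model.Wo[j]})
    rows.append({"kind": "b2", "hidden_unit": "", "feature": "", "value": model.b2})
    for i, fname in enumerate(normalizer.feature_names):
        rows.append({"kind": "x_min", "hidden_unit": "", "feature": fname,
                     "value": normalizer.x_min[i]})
        rows.append({"kind": "x_max", "hidden_unit": "", "feature": fname,
                     "value": normalizer.x_max[i]})
    pd.DataFrame(rows).to_csv(path, index=False)
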