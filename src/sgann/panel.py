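"""Canonical 14-feature maternal panel.

The panel mirrors the first-trimester maternal variables used to predict a
small-for-gestational-age (SGA) versus appropriate-for-gestational-age (AGA)
newborn: age, pre-gestational BMI, first-trimester gestational weight gain,
body fat mass, multivitamin use, the serum lipid profile, vitamin D, and the
oxidative-stress markers malondialdehyde (MDA), carbonylated proteins (CP)
and total antioxidant capacity (TAC), plus gestational age at birth.

Each :class:`FeatureSpec` stores the per-group (SGA / AGA) marginal
distribution parameters of the published cohort (n=14 SGA, n=63 AGA) that
the synthetic generator is calibrated to, together with physiological
truncation limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import yaml

CONTINUOUS = "continuous"
BINARY = "binary"

#: outcome labels and their codified network targets
SGA = "SGA"
AGA = "AGA"
TARGET_CODES = {SGA: 0.5, AGA: 1.0}

#: group sizes of the reference cohort (used as default mixture weights)
N_SGA_REF = 14
N_AGA_REF = 63


@dataclass(frozen=True)
class FeatureSpec:
    """Marginal distribution of one maternal feature in the two outcome groups.

    Parameters
    ----------
    name : str
        Canonical column name.
    kind : {"continuous", "binary"}
    units : str
        Clinical units; stored as a label only, never converted.
    sga_mean, sga_sd, aga_mean, aga_sd : float
        Per-group normal parameters (continuous features).
    sga_rate, aga_rate : float
        Per-group probability of "yes" (binary features).
    lower_bound, upper_bound : float
        Hard physiological limits.  The effective truncation window of a
        group is ``[mean - 4*sd, mean + 4*sd]`` intersected with these.
    """

    name: str
    kind: str
    units: str
    sga_mean: float = math.nan
    sga_sd: float = math.nan
    aga_mean: float = math.nan
    aga_sd: float = math.nan
    sga_rate: float = math.nan
    aga_rate: float = math.nan
    lower_bound: float = -math.inf
    upper_bound: float = math.inf

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, BINARY):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == CONTINUOUS:
            if self.sga_sd < 0 or self.aga_sd < 0:
                raise ValueError(f"{self.name}: sd must be >= 0")
        else:
            for rate in (self.sga_rate, self.aga_rate):
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"{self.name}: rate must be in [0, 1]")
        if not self.lower_bound < self.upper_bound:
            raise ValueError(f"{self.name}: lower_bound must be < upper_bound")

    def group_params(self, group: str) -> tuple[float, float]:
        """(mean, sd) for a continuous feature in ``group`` (SGA or AGA)."""
        if group == SGA:
            return self.sga_mean, self.sga_sd
        if group == AGA:
            return self.aga_mean, self.aga_sd
        raise ValueError(f"unknown group {group!r}")

    def group_rate(self, group: str) -> float:
        if group == SGA:
            return self.sga_rate
        if group == AGA:
            return self.aga_rate
        raise ValueError(f"unknown group {group!r}")

    def truncation(self, group: str) -> tuple[float, float]:
        """Effective truncation window of ``group``: mean +/- 4 sd cut to the
        physiological limits."""
        mean, sd = self.group_params(group)
        lo = max(self.lower_bound, mean - 4.0 * sd)
        hi = min(self.upper_bound, mean + 4.0 * sd)
        return lo, hi


def table1_panel() -> list[FeatureSpec]:
    """The canonical 14-feature panel with the published per-group statistics.

    Continuous features carry mean +/- SD per outcome group; the single
    binary feature (multivitamin supplementation, MVI) carries per-group
    "yes" frequencies (SGA 4/14, AGA 24/63).  Gestational age at birth is
    not printed as mean +/- SD in the source table; its parameters are chosen
    so that the preterm (<37 weeks) probability matches the printed
    frequencies (SGA 2/14, AGA 7/63) in expectation.
    """
    return [
        FeatureSpec("age", CONTINUOUS, "years", 29, 4, 28, 5, lower_bound=18),
        FeatureSpec("pbmi", CONTINUOUS, "kg/m^2", 28.2, 8.0, 26.6, 4.9, lower_bound=13),
        FeatureSpec("gwg", CONTINUOUS, "kg", 2.0, 3.1, 1.4, 3.2),
        FeatureSpec("fat_mass", CONTINUOUS, "%", 39.7, 8.9, 38.6, 6.8,
                    lower_bound=0, upper_bound=100),
        FeatureSpec("mvi", BINARY, "no/yes", sga_rate=4 / 14, aga_rate=24 / 63,
                    lower_bound=0, upper_bound=1),
        FeatureSpec("tgl", CONTINUOUS, "mg/dL", 157, 63.4, 132, 41.1, lower_bound=0),
        FeatureSpec("chol", CONTINUOUS, "mg/dL", 201, 32.6, 184, 39.3, lower_bound=0),
        FeatureSpec("hdl_chol", CONTINUOUS, "mg/dL", 59.7, 11.1, 60.7, 12.8, lower_bound=0),
        FeatureSpec("ldl_chol", CONTINUOUS, "mg/dL", 89.9, 27.9, 92.7, 25.3, lower_bound=0),
        FeatureSpec("vit_d", CONTINUOUS, "ng/mL", 19.9, 3.4, 22.0, 7.2, lower_bound=0),
        FeatureSpec("mda", CONTINUOUS, "pmol MDA/mg dry weight", 153, 180, 173, 173,
                    lower_bound=0),
        FeatureSpec("cp", CONTINUOUS, "pmol CP/mg protein", 5710, 2388, 5327, 2679,
                    lower_bound=0),
        FeatureSpec("tac", CONTINUOUS, "pmol Trolox eq/mg protein", 78, 30.7, 81.8, 28,
                    lower_bound=0),
        FeatureSpec("ga_birth", CONTINUOUS, "weeks", 38.5, 1.4, 38.7, 1.4,
                    lower_bound=22, upper_bound=43),
    ]


FEATURE_NAMES: list[str] = [spec.name for spec in table1_panel()]

#: pooled "all women" values used as scenario defaults (MVI defaults to the
#: majority category, no supplementation)
POOLED_MEANS: dict[str, float] = {
    "age": 28.0,
    "pbmi": 26.9,
    "gwg": 1.5,
    "fat_mass": 38.8,
    "mvi": 0.0,
    "tgl": 136.0,
    "chol": 187.0,
    "hdl_chol": 60.5,
    "ldl_chol": 92.1,
    "vit_d": 21.6,
    "mda": 170.0,
    "cp": 5397.0,
    "tac": 81.1,
    "ga_birth": 38.7,
}


def validate_panel(panel: list[FeatureSpec]) -> None:
    """Raise if ``panel`` is not a complete 14-feature canonical panel."""
    names = [spec.name for spec in panel]
    if names != FEATURE_NAMES:
        missing = set(FEATURE_NAMES) - set(names)
        extra = set(names) - set(FEATURE_NAMES)
        raise ValueError(
            "panel must contain exactly the 14 canonical features in order; "
            f"missing={sorted(missing)}, unexpected={sorted(extra)}"
        )


def panel_to_yaml(panel: list[FeatureSpec], path) -> None:
    """Serialize a panel to a YAML file."""
    records = []
    for spec in panel:
        rec = {k: v for k, v in vars(spec).items()}
        records.append(rec)
    with open(path, "w") as fh:
        yaml.safe_dump({"features": records}, fh, sort_keys=False)


def panel_from_yaml(path) -> list[FeatureSpec]:
    """Load a panel from a YAML file written by :func:`panel_to_yaml`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [FeatureSpec(**rec) for rec in doc["features"]]
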