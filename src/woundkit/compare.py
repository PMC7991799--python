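"""Treatment-versus-control comparison of edge velocities.

Velocities measured in the linear window are summarized per condition
and compared as ratios (treated / control, percent) with a two-sample
significance test.  Ratios below 100% mean slowdown; negative ratios
are possible when a treated edge retracts.  Dose series tabulate one
ratio per concentration with the conventional star marks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class ConditionSummary:
    """Replicate velocities of one experimental condition."""

    label: str
    replicate_v: np.ndarray

    def __post_init__(self) -> None:
        self.replicate_v = np.asarray(self.replicate_v, dtype=float)
        if self.replicate_v.size < 1:
            raise ValueError(f"condition {self.label!r} has no replicates")

    @property
    def n(self) -> int:
        return int(self.replicate_v.size)

    @property
    def mean_v_um_per_h(self) -> float:
        return float(self.replicate_v.mean())

    @property
    def sem(self) -> float:
        if self.n < 2:
            return float("nan")
        return float(self.replicate_v.std(ddof=1) / np.sqrt(self.n))


@dataclass
class TreatmentEffect:
    """One treated/control contrast: ratio, p-value, significance."""

    treated: ConditionSummary
    control: ConditionSummary
    ratio_pct: float
    p_value: float
    significant: bool

    @property
    def stars(self) -> str:
        if not np.isfinite(self.p_value):
            return "na"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < ALPHA:
            return "*"
        return "ns"


def velocity_ratio(v_treated: float, v_control: float) -> float:
    """Treated velocity as a percentage of the control velocity.

    May exceed 100 (acceleration) or go negative (edge retraction).
    """
    if v_control == 0:
        raise ValueError("control velocity must be non-zero")
    return 100.0 * v_treated / v_control


def compare_conditions(
    treated: Sequence[float] | ConditionSummary,
    control: Sequence[float] | ConditionSummary,
    test: str = "welch",
) -> TreatmentEffect:
    """Compare replicate velocities of a treated group against control.

    ``test`` selects the standard two-sample routine: ``"welch"``
    (unequal-variance t), ``"student"`` (pooled t) or ``"mannwhitney"``.
    With fewer than 2 replicates in either group only the ratio is
    computed (p = NaN).
    """
    tre = treated if isinstance(treated, ConditionSummary) \
        else ConditionSummary("treated", np.asarray(treated, float))
    ctl = control if isinstance(control, ConditionSummary) \
        else ConditionSummary("control", np.asarray(control, float))

    ratio = velocity_ratio(tre.mean_v_um_per_h, ctl.mean_v_um_per_h)

    if tre.n < 2 or ctl.n < 2:
        p = float("nan")
    elif test == "welch":
        p = float(stats.ttest_ind(tre.replicate_v, ctl.replicate_v,
                                  equal_var=False).pvalue)
    elif test == "student":
        p = float(stats.ttest_ind(tre.replicate_v, ctl.replicate_v,
                                  equal_var=True).pvalue)
    elif test == "mannwhitney":
        p = float(stats.mannwhitneyu(tre.replicate_v, ctl.replicate_v,
                                     alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")

    return TreatmentEffect(
        treated=tre,
        control=ctl,
        ratio_pct=ratio,
        p_value=p,
        significant=bool(np.isfinite(p) and p < ALPHA),
    )


def dose_response_table(
    effects: "Mapping[float, TreatmentEffect] | Sequence[tuple[float, TreatmentEffect]]",
) -> pd.DataFrame:
    """Tabulate one ratio per dose, ascending.

    Accepts a mapping dose -> effect or a sequence of (dose, effect)
    pairs; duplicate dose labels are an error.  No monotonicity is
    imposed — dose–response curves of motility inhibitors are frequently
    non-linear and non-monotonic.
    """
    pairs = list(effects.items()) if isinstance(effects, Mapping) \
        else list(effects)
    doses = [d for d, _ in pairs]
    if len(doses) == 0:
        raise ValueError("at least one dose required")
    if len(set(doses)) != len(doses):
        raise ValueError("duplicate dose labels")
    effects = dict(pairs)
    rows = [
        {
            "dose": dose,
            "ratio_pct": eff.ratio_pct,
            "p_value": eff.p_value,
            "stars": eff.stars,
        }
        for dose, eff in sorted(effects.items(), key=lambda kv: kv[0])
    ]
    return pd.DataFrame(rows, columns=["dose", "ratio_pct", "p_value", "stars"])
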