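"""Metabolite role calls, interaction directions, and tallies.

A metabolite is a *signal* for a strain when it elicits significant
attraction, a *substrate* when it supports significant growth within the
assay window; the four boolean combinations map onto the roles
both / signal / substrate / none.  Pairwise interaction outcomes per strain
are scored detrimental (-), neutral (0) or beneficial (+) by comparing the
strain's chemotactic index within the pair against its index in isolation.
"""
from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .tables_io import RunConfig

__all__ = [
    "RoleCall",
    "RoleTally",
    "InteractionCall",
    "classify_role",
    "tally_roles",
    "classify_interaction",
    "label_pair",
    "display_percent",
    "summarize_pair_outcomes",
]

ROLES = ("both", "signal", "substrate", "none")
DIRECTIONS = ("-", "0", "+")
_DIRECTION_ORDER = {"-": 0, "0": 1, "+": 2}


@dataclasses.dataclass(frozen=True)
class RoleCall:
    strain_id: str
    metabolite: str
    is_signal: bool
    is_substrate: bool

    @property
    def role(self) -> str:
        if self.is_signal and self.is_substrate:
            return "both"
        if self.is_signal:
            return "signal"
        if self.is_substrate:
            return "substrate"
        return "none"


@dataclasses.dataclass(frozen=True)
class RoleTally:
    """Counts and display percentages per role category.

    ``percentages`` is None for an empty tally (the explicit sentinel for
    "no assays scored").
    """

    counts: Mapping[str, int]
    total: int
    percentages: Mapping[str, float] | None

    @property
    def empty(self) -> bool:
        return self.total == 0


@dataclasses.dataclass(frozen=True)
class InteractionCall:
    pair: tuple[str, str]
    metabolite: str
    phase: str
    direction_a: str
    direction_b: str

    @property
    def outcome_label(self) -> str:
        return label_pair(self.direction_a, self.direction_b)


def classify_role(ic, growthrate) -> RoleCall:
    """Combine attraction and growth tests into a role call.

    Accepts the estimate objects from the chemotaxis and growth modules
    (anything exposing ``attracted`` / ``grew`` plus labels).
    """
    strain_ic = ic.strain_set[0] if ic.strain_set else ""
    if growthrate.strain_id and strain_ic and growthrate.strain_id != strain_ic:
        raise ValidationError(
            f"role inputs are for different strains: {strain_ic!r} vs "
            f"{growthrate.strain_id!r}",
            "ARGUMENT",
        )
    met = ic.chemoattractant
    if growthrate.metabolite and met and growthrate.metabolite != met:
        raise ValidationError(
            f"role inputs are for different metabolites: {met!r} vs "
            f"{growthrate.metabolite!r}",
            "ARGUMENT",
        )
    return RoleCall(
        strain_id=strain_ic or growthrate.strain_id,
        metabolite=met or growthrate.metabolite,
        is_signal=bool(ic.attracted),
        is_substrate=bool(growthrate.grew),
    )


def display_percent(value: float) -> float:
    """Percentage at the survey's mixed precision.

    One decimal normally; collapsed to the whole number when the exact value
    lies within 0.15 of it (so 5/56 prints as 9, not 8.9, while 12/56 stays
    21.4).
    """
    nearest = round(value)
    if abs(value - nearest) <= 0.15:
        return float(nearest)
    return round(value, 1)


def tally_roles(calls: Iterable[RoleCall]) -> RoleTally:
    """Tally role categories over an assay grid."""
    counter = Counter(call.role for call in calls)
    counts = {role: counter.get(role, 0) for role in ROLES}
    total = sum(counts.values())
    if total == 0:
        return RoleTally(counts=counts, total=0, percentages=None)
    percentages = {
        role: display_percent(100.0 * n / total) for role, n in counts.items()
    }
    return RoleTally(counts=counts, total=total, percentages=percentages)


def classify_interaction(
    solo,
    paired_ratios: Sequence[float],
    config: RunConfig | None = None,
    method: str = "welch",
) -> str:
    """Direction of a strain's chemotaxis change when paired: -, 0 or +.

    Compares the replicate-level member indices within the pair against the
    strain's solo replicate ratios with a two-sided two-sample test at
    ``config.alpha`` (Welch by default, one-way ANOVA as the alternative).
    """
    config = config or RunConfig()
    solo_ratios = np.asarray(solo.ratios, dtype=float)
    paired = np.asarray(paired_ratios, dtype=float)
    if len(solo_ratios) < 2 or len(paired) < 2:
        raise ValidationError(
            "need >= 2 replicates in both solo and paired sets", "ARGUMENT"
        )
    diff = paired.mean() - solo_ratios.mean()
    if np.std(solo_ratios, ddof=1) == 0 and np.std(paired, ddof=1) == 0:
        p = 1.0 if np.isclose(diff, 0.0) else 0.0
    elif method == "welch":
        p = float(stats.ttest_ind(paired, solo_ratios, equal_var=False).pvalue)
    elif method == "anova":
        p = float(stats.f_oneway(paired, solo_ratios).pvalue)
    else:
        raise ValidationError(f"unknown method {method!r}", "ARGUMENT")
    if p <= config.alpha:
        return "-" if diff < 0 else "+"
    return "0"


def label_pair(direction_a: str, direction_b: str) -> str:
    """Canonical outcome label, worse symbol first (e.g. ``-/0``, ``0/+``)."""
    for d in (direction_a, direction_b):
        if d not in DIRECTIONS:
            raise ValidationError(f"unknown direction symbol {d!r}", "ARGUMENT")
    ordered = sorted((direction_a, direction_b), key=_DIRECTION_ORDER.__getitem__)
    return f"{ordered[0]}/{ordered[1]}"


def summarize_pair_outcomes(
    n_chemotaxis_significant: int,
    n_growth_deviating: int,
    n_experiments: int,
) -> dict[str, float]:
    """Whole-study bookkeeping as integer percentages.

    Reports the share of pair experiments whose pooled chemotaxis differed
    from the null prediction, the share whose final composition deviated by
    more than the threshold, and the complementary share the null model
    matched.
    """
    if n_experiments <= 0:
        raise ValidationError("n_experiments must be > 0", "ARGUMENT")
    for name, n in (
        ("n_chemotaxis_significant", n_chemotaxis_significant),
        ("n_growth_deviating", n_growth_deviating),
    ):
        if not 0 <= n <= n_experiments:
            raise ValidationError(f"{name} out of range", "ARGUMENT")
    return {
        "pct_chemotaxis_different": round(
            100.0 * n_chemotaxis_significant / n_experiments
        ),
        "pct_growth_deviating": round(100.0 * n_growth_deviating / n_experiments),
        "pct_null_matched": round(
            100.0 * (n_experiments - n_growth_deviating) / n_experiments
        ),
    }
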