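"""Chemotactic indices and the independence null for strain pairs.

The chemotactic index I_C of an assay is the cell count recovered from the
metabolite well divided by the count from the seawater control well; 1 means
indifference, > 1 attraction, < 1 repulsion.  For a pair of strains mixed at
fractions f = (f_A, f_B) with control-well entry coefficients r, the null
model of independent chemotaxis predicts

    pooled I_C   = sum_i w_i I_i,          w_i = f_i r_i / sum_j f_j r_j
    well share_i = f_i r_i I_i / sum_j f_j r_j I_j

i.e. the pooled index is the entry-weighted mean of the solo indices and the
within-well composition is tilted toward the stronger chemotaxer.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateCompositionError,
    UndefinedRatioError,
    ValidationError,
)
from .tables_io import RunConfig, parse_strain_set

__all__ = [
    "ChemotaxisIndex",
    "PairChemotaxisPrediction",
    "ComparisonResult",
    "compute_ic",
    "predict_pair_ic",
    "infer_member_ic",
    "compare_pair_ic",
    "compare_pair_ic_anova",
]


@dataclasses.dataclass(frozen=True)
class ChemotaxisIndex:
    """An I_C estimate with its attraction test.

    ``ratios`` keeps the per-replicate metabolite/control ratios so that
    downstream resampling and two-sample tests can reuse them.
    """

    strain_set: tuple[str, ...]
    chemoattractant: str
    ic_mean: float
    ic_sd: float
    n: int
    p_attraction: float
    attracted: bool
    ratios: tuple[float, ...] = ()

    @property
    def se(self) -> float:
        return self.ic_sd / np.sqrt(self.n) if self.n > 0 else np.nan


@dataclasses.dataclass(frozen=True)
class PairChemotaxisPrediction:
    """Null-model pooled index and within-well composition for a pair."""

    strains: tuple[str, ...]
    predicted_ic: float
    weights: np.ndarray
    predicted_well_fractions: np.ndarray


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    """Predicted-vs-observed decision for one pooled index."""

    p_value: float
    significant: bool
    observed_mean: float
    predicted_mean: float
    method: str


def _one_sample_test(values: np.ndarray, popmean: float) -> float:
    """Two-sided one-sample t p-value, degenerate-sd cases handled explicitly."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return float("nan")
    if np.std(values, ddof=1) == 0.0:
        return 1.0 if np.isclose(values.mean(), popmean) else 0.0
    return float(stats.ttest_1samp(values, popmean).pvalue)


def compute_ic(
    counts: pd.DataFrame,
    config: RunConfig | None = None,
    log_scale: bool = False,
) -> ChemotaxisIndex:
    """Chemotactic index for one strain set x chemoattractant slice.

    Computes the per-replicate metabolite/control ratio, summarizes over
    replicates, and tests attraction with a one-sample t-test of the ratios
    against the no-response reference (two-sided on raw ratios by default,
    on log ratios when ``log_scale``).  Attraction is only called when the
    mean exceeds the reference, matching the one-directional reading of
    "significantly greater than 1".
    """
    config = config or RunConfig()
    if counts.empty:
        raise ValidationError("empty measurement slice", "EMPTY_SLICE")
    strain_sets = counts["strain_set"].unique()
    mets = counts["chemoattractant"].unique()
    if len(strain_sets) != 1 or len(mets) != 1:
        raise ValidationError(
            "compute_ic expects a single strain_set x chemoattractant slice",
            "MIXED_SLICE",
        )
    wide = counts.pivot(index="replicate", columns="well_type", values="cells")
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValidationError(
            f"replicates {missing} lack a metabolite or control row",
            "UNPAIRED_WELL",
        )
    zero_ctl = wide.index[wide["control"] == 0].tolist()
    if zero_ctl:
        raise UndefinedRatioError(
            f"control count is 0 in replicate(s) {zero_ctl}; I_C undefined"
        )
    ratios = (wide["metabolite"] / wide["control"]).to_numpy(dtype=float)
    mean = float(ratios.mean())
    sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
    if log_scale:
        if (ratios <= 0).any():
            raise UndefinedRatioError("zero ratio cannot be log-transformed")
        p = _one_sample_test(np.log(ratios), np.log(config.ic_null))
    else:
        p = _one_sample_test(ratios, config.ic_null)
    attracted = bool(
        len(ratios) >= 2 and p <= config.alpha and mean > config.ic_null
    )
    return ChemotaxisIndex(
        strain_set=parse_strain_set(str(strain_sets[0])),
        chemoattractant=str(mets[0]),
        ic_mean=mean,
        ic_sd=sd,
        n=len(ratios),
        p_attraction=float(p),
        attracted=attracted,
        ratios=tuple(float(r) for r in ratios),
    )


def _entry_weights(
    fractions: np.ndarray, entry_rates: Sequence[float] | str
) -> np.ndarray:
    if isinstance(entry_rates, str):
        if entry_rates != "equal":
            raise ValidationError(
                f"entry_rates must be 'equal' or a sequence, got {entry_rates!r}",
                "ARGUMENT",
            )
        r = np.ones_like(fractions)
    else:
        r = np.asarray(entry_rates, dtype=float)
        if (r <= 0).any():
            raise ValidationError("entry rates must be > 0", "ARGUMENT")
    w = fractions * r
    total = w.sum()
    if total <= 0:
        raise ValidationError("fractions x entry rates sum to 0", "ARGUMENT")
    return w / total


def predict_pair_ic(
    solo_a: ChemotaxisIndex | float,
    solo_b: ChemotaxisIndex | float,
    initial_fractions: Sequence[float],
    entry_rates: Sequence[float] | str = "equal",
    strains: tuple[str, str] | None = None,
) -> PairChemotaxisPrediction:
    """Pooled index and well composition for a pair under independence.

    Solo indices may be passed as :class:`ChemotaxisIndex` estimates or bare
    numbers.  ``entry_rates`` defaults to equal random motility; pass the
    per-strain control-well entry coefficients to weight by them.
    """
    ics = []
    labels = []
    for k, solo in enumerate((solo_a, solo_b)):
        if isinstance(solo, ChemotaxisIndex):
            ics.append(solo.ic_mean)
            labels.append(solo.strain_set[0] if solo.strain_set else f"strain{k}")
        else:
            ics.append(float(solo))
            labels.append(f"strain{k}")
    I = np.asarray(ics, dtype=float)
    if not np.isfinite(I).all() or (I < 0).any():
        raise ValidationError("solo indices must be finite and >= 0", "ARGUMENT")
    f = np.asarray(initial_fractions, dtype=float)
    if len(f) != 2 or (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
        raise ValidationError(
            "initial_fractions must be a 2-simplex vector", "ARGUMENT"
        )
    w = _entry_weights(f, entry_rates)
    pooled = float(w @ I)
    numer = w * I
    if numer.sum() == 0:
        raise DegenerateCompositionError(
            "all solo indices are 0: well composition undefined"
        )
    return PairChemotaxisPrediction(
        strains=strains or (labels[0], labels[1]),
        predicted_ic=pooled,
        weights=w,
        predicted_well_fractions=numer / numer.sum(),
    )


def infer_member_ic(
    pooled_met: float,
    pooled_ctl: float,
    fractions_met: Sequence[float],
    fractions_ctl: Sequence[float],
) -> np.ndarray:
    """Per-strain indices of a mixture from pooled counts and ASV fractions.

    Splits the pooled metabolite and control counts by the sequenced strain
    fractions of each well:  I_i = (fm_i * M) / (fc_i * C).  Satisfies the
    pooled identity sum_i fc_i I_i = M / C exactly.
    """
    if pooled_met < 0 or pooled_ctl <= 0:
        raise ValidationError(
            "pooled counts must be positive (control strictly)", "ARGUMENT"
        )
    fm = np.asarray(fractions_met, dtype=float)
    fc = np.asarray(fractions_ctl, dtype=float)
    for name, v in (("fractions_met", fm), ("fractions_ctl", fc)):
        if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
            raise ValidationError(f"{name} must lie on the simplex", "ARGUMENT")
    if (fc == 0).any():
        idx = int(np.flatnonzero(fc == 0)[0])
        raise UndefinedRatioError(
            f"strain {idx} has zero control-well fraction; member index undefined"
        )
    return (fm * pooled_met) / (fc * pooled_ctl)


def empirical_p(draws: np.ndarray, observed: float) -> float:
    """Two-sided empirical p-value of ``observed`` under a draw distribution.

    p = 2 min(F(obs), 1 - F(obs)), floored at 1/n so it is never exactly 0.
    """
    draws = np.asarray(draws, dtype=float)
    n = len(draws)
    if n < 100:
        raise ValidationError(
            "need >= 100 draws for a stable empirical CDF", "ARGUMENT"
        )
    below = np.count_nonzero(draws <= observed)
    above = np.count_nonzero(draws >= observed)
    p = 2.0 * min(below, above) / n
    return float(min(1.0, max(p, 1.0 / n)))


def compare_pair_ic(
    predicted_draws: np.ndarray,
    observed: ChemotaxisIndex,
    config: RunConfig | None = None,
    include_observation_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> ComparisonResult:
    """Test an observed pooled index against the Monte Carlo predictive.

    ``predicted_draws`` is the Monte Carlo distribution of the null-model
    pooled index (solo-measurement uncertainty propagated); the empirical
    two-sided p-value places the mean observed ratio in that distribution.
    ``include_observation_noise`` additionally widens the predictive by the
    observed replicate scatter (t-scaled), which makes the test strictly
    more conservative.
    """
    config = config or RunConfig()
    draws = np.asarray(predicted_draws, dtype=float)
    if include_observation_noise and observed.n >= 2 and observed.ic_sd > 0:
        rng = np.random.default_rng(config.rng_seed) if rng is None else rng
        noise = rng.standard_t(observed.n - 1, size=len(draws))
        draws = draws + noise * observed.ic_sd / np.sqrt(observed.n)
    p = empirical_p(draws, observed.ic_mean)
    return ComparisonResult(
        p_value=p,
        significant=bool(p <= config.alpha),
        observed_mean=observed.ic_mean,
        predicted_mean=float(np.mean(predicted_draws)),
        method="mc_predictive",
    )


def write_ic_table(estimates: Sequence[ChemotaxisIndex], path) -> None:
    """Persist index estimates (replicate ratios kept, ';'-joined)."""
    rows = [
        {
            "strain_set": "+".join(e.strain_set),
            "chemoattractant": e.chemoattractant,
            "ic_mean": e.ic_mean,
            "ic_sd": e.ic_sd,
            "n": e.n,
            "p_attraction": e.p_attraction,
            "attracted": e.attracted,
            "ratios": ";".join(f"{r:.17g}" for r in e.ratios),
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_ic_table(path) -> list[ChemotaxisIndex]:
    frame = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, row in frame.iterrows():
        ratios = (
            tuple(float(x) for x in str(row["ratios"]).split(";"))
            if pd.notna(row.get("ratios")) and str(row["ratios"])
            else ()
        )
        out.append(
            ChemotaxisIndex(
                strain_set=parse_strain_set(str(row["strain_set"])),
                chemoattractant=str(row["chemoattractant"]),
                ic_mean=float(row["ic_mean"]),
                ic_sd=float(row["ic_sd"]),
                n=int(row["n"]),
                p_attraction=float(row["p_attraction"]),
                attracted=bool(row["attracted"]),
                ratios=ratios,
            )
        )
    return out


def compare_pair_ic_anova(
    predicted_replicates: Sequence[float],
    observed: ChemotaxisIndex,
    config: RunConfig | None = None,
) -> ComparisonResult:
    """One-way ANOVA alternative on predicted vs observed replicate sets.

    ``predicted_replicates`` are pooled indices obtained by applying the
    null formula replicate-wise to the solo assays.
    """
    config = config or RunConfig()
    pred = np.asarray(predicted_replicates, dtype=float)
    obs = np.asarray(observed.ratios, dtype=float)
    if len(pred) < 2 or len(obs) < 2:
        raise ValidationError("need >= 2 replicates per group", "ARGUMENT")
    if np.std(pred, ddof=1) == 0 and np.std(obs, ddof=1) == 0:
        p = 1.0 if np.isclose(pred.mean(), obs.mean()) else 0.0
    else:
        p = float(stats.f_oneway(pred, obs).pvalue)
    return ComparisonResult(
        p_value=p,
        significant=bool(p <= config.alpha),
        observed_mean=float(obs.mean()),
        predicted_mean=float(pred.mean()),
        method="anova",
    )
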