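"""Two-strain assembly prediction, deviation statistic, and Monte Carlo.

The null model predicts a pair's community trajectory from isolation
measurements alone.  Chemotaxis phase: the well composition follows the
independence formula (entry-weighted solo indices).  Growth phase: each
strain then grows exponentially at its solo rate for the grow-out time.
The percentage-point deviation between predicted and observed fractions,

    D = 100 * max_i |f_pred_i - f_obs_i|,

flags an inter-species interaction when it exceeds the (conservative) 10
percentage-point threshold.  Monte Carlo propagation resamples the solo
indices, growth rates and initial composition from their sampling
distributions, yielding empirical CDFs, central 95% intervals and
two-sided p-values for every predicted quantity.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon_calibration import CalibrationFit, counts_to_cells
from .chemotaxis import (
    ChemotaxisIndex,
    ComparisonResult,
    compare_pair_ic,
    compute_ic,
    empirical_p,
    infer_member_ic,
    predict_pair_ic,
)
from .classification import classify_interaction
from .errors import ValidationError
from .growth import GrowthRateEstimate, project_growth
from .synthetic_data import PairBundle
from .tables_io import RunConfig

__all__ = [
    "CommunityComposition",
    "AssemblyPrediction",
    "MonteCarloResult",
    "DeviationCall",
    "PairEvaluation",
    "predict_assembly",
    "deviation",
    "monte_carlo",
    "evaluate_pair",
]

STAGES = ("initial", "post_chemotaxis", "post_growth")


@dataclasses.dataclass(frozen=True)
class CommunityComposition:
    """Per-strain make-up of a community at one named stage."""

    stage: str
    strains: tuple[str, ...]
    fractions: np.ndarray
    abundances: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}", "ARGUMENT")
        f = np.asarray(self.fractions, dtype=float)
        if len(f) != len(self.strains):
            raise ValidationError("fractions/strains length mismatch", "ARGUMENT")
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"fractions must lie on the simplex, got {f}", "ARGUMENT"
            )
        object.__setattr__(self, "fractions", f)
        if self.abundances is not None:
            a = np.asarray(self.abundances, dtype=float)
            if (a < 0).any():
                raise ValidationError("abundances must be >= 0", "ARGUMENT")
            object.__setattr__(self, "abundances", a)

    @classmethod
    def from_abundances(
        cls, stage: str, strains: Sequence[str], abundances: Sequence[float]
    ) -> "CommunityComposition":
        a = np.asarray(abundances, dtype=float)
        if a.sum() <= 0:
            raise ValidationError("total abundance must be > 0", "ARGUMENT")
        return cls(stage, tuple(strains), a / a.sum(), a)


@dataclasses.dataclass(frozen=True)
class DeviationCall:
    """Predicted-vs-observed composition mismatch at one stage."""

    stage: str
    deviation: float  # percentage points
    exceeds_threshold: bool
    p_value: float | None = None


@dataclasses.dataclass(frozen=True)
class MonteCarloResult:
    """Empirical distributions of the null model's predicted quantities."""

    draws: int
    seed: int | None
    strains: tuple[str, ...]
    quantities: Mapping[str, np.ndarray]  # sorted draw arrays
    intervals: Mapping[str, tuple[float, float]]

    def cdf(self, name: str, x: float) -> float:
        draws = self.quantities[name]
        return float(np.searchsorted(draws, x, side="right") / len(draws))

    def p_value(self, name: str, observed: float) -> float:
        return empirical_p(self.quantities[name], observed)

    def interval(self, name: str) -> tuple[float, float]:
        return self.intervals[name]


@dataclasses.dataclass(frozen=True)
class AssemblyPrediction:
    """Null-model trajectory with pooled index, MC uncertainty and calls."""

    strains: tuple[str, ...]
    metabolite: str
    trajectory: Mapping[str, CommunityComposition]
    predicted_ic: float
    mc: MonteCarloResult | None = None
    deviations: tuple[DeviationCall, ...] = ()


def _as_ic_mean(value: ChemotaxisIndex | float) -> float:
    return value.ic_mean if isinstance(value, ChemotaxisIndex) else float(value)


def _as_mu_mean(value: GrowthRateEstimate | float) -> float:
    mu = value.mu if isinstance(value, GrowthRateEstimate) else float(value)
    # a non-growing strain's point estimate can dip below 0 from noise;
    # the rate itself is non-negative by definition
    return max(mu, 0.0)


def _lookup(mapping: Mapping[str, object], strains: Sequence[str], what: str):
    out = []
    for s in strains:
        if s not in mapping:
            raise ValidationError(
                f"missing solo {what} for strain {s!r}; provide it before "
                "predicting assembly",
                "MISSING_SOLO",
            )
        out.append(mapping[s])
    return out


def predict_assembly(
    solo_ics: Mapping[str, ChemotaxisIndex | float],
    rates: Mapping[str, GrowthRateEstimate | float],
    initial: CommunityComposition,
    config: RunConfig | None = None,
    metabolite: str = "",
    entry_rates: Sequence[float] | str = "equal",
) -> AssemblyPrediction:
    """Predict the full two-strain trajectory from isolation measurements."""
    config = config or RunConfig()
    if len(initial.strains) != 2:
        raise ValidationError("predict_assembly handles strain pairs", "ARGUMENT")
    ic_a, ic_b = _lookup(solo_ics, initial.strains, "chemotactic index")
    mu_pair = [_as_mu_mean(m) for m in _lookup(rates, initial.strains, "growth rate")]
    pred = predict_pair_ic(
        _as_ic_mean(ic_a),
        _as_ic_mean(ic_b),
        initial.fractions,
        entry_rates,
        strains=(initial.strains[0], initial.strains[1]),
    )
    post_chemo = CommunityComposition(
        "post_chemotaxis", initial.strains, pred.predicted_well_fractions
    )
    _, pg_fractions = project_growth(
        post_chemo.fractions, mu_pair, config.grow_time
    )
    post_growth = CommunityComposition("post_growth", initial.strains, pg_fractions)
    trajectory = {
        "initial": initial,
        "post_chemotaxis": post_chemo,
        "post_growth": post_growth,
    }
    return AssemblyPrediction(
        strains=initial.strains,
        metabolite=metabolite,
        trajectory=trajectory,
        predicted_ic=pred.predicted_ic,
    )


def deviation(
    predicted: CommunityComposition,
    observed: CommunityComposition,
    config: RunConfig | None = None,
    p_value: float | None = None,
) -> DeviationCall:
    """Percentage-point deviation between predicted and observed fractions."""
    config = config or RunConfig()
    if predicted.stage != observed.stage:
        raise ValidationError(
            f"stage mismatch: {predicted.stage} vs {observed.stage}", "ARGUMENT"
        )
    if predicted.strains != observed.strains:
        raise ValidationError(
            "strain order differs between predicted and observed", "ARGUMENT"
        )
    d = 100.0 * float(np.max(np.abs(predicted.fractions - observed.fractions)))
    return DeviationCall(
        stage=predicted.stage,
        deviation=d,
        exceeds_threshold=bool(d > config.deviation_threshold),
        p_value=p_value,
    )


def _draw_nonnegative(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    n: int,
    size: int,
    replicates: Sequence[float] | None,
    mode: str,
) -> np.ndarray:
    """Draws from a sampling distribution of a mean, truncated at 0.

    ``summary`` mode scales a Student-t by the standard error; ``bootstrap``
    resamples replicate values with replacement.  Negatives are rejected
    and redrawn (bounded rounds) so the distribution is properly truncated.
    """
    if mode == "bootstrap" and replicates is not None and len(replicates) >= 2:
        reps = np.asarray(replicates, dtype=float)
        idx = rng.integers(0, len(reps), size=(size, len(reps)))
        draws = reps[idx].mean(axis=1)
        return np.clip(draws, 0.0, None)
    if n < 2 or sd <= 0:
        return np.full(size, max(mean, 0.0))
    se = sd / np.sqrt(n)
    draws = mean + rng.standard_t(n - 1, size=size) * se
    for _ in range(20):
        neg = draws < 0
        if not neg.any():
            break
        draws[neg] = mean + rng.standard_t(n - 1, size=int(neg.sum())) * se
    return np.clip(draws, 0.0, None)


def monte_carlo(
    solo_ics: Mapping[str, ChemotaxisIndex],
    rates: Mapping[str, GrowthRateEstimate],
    initial_reads: Sequence[float],
    config: RunConfig | None = None,
    strains: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "summary",
    entry_rates: Sequence[float] | str = "equal",
    dirichlet: bool = True,
) -> MonteCarloResult:
    """Propagate measurement uncertainty through the null model.

    Per draw: solo indices and growth rates are sampled from their
    (replicate-informed) sampling distributions truncated at 0, the initial
    composition from a Dirichlet with parameters ``initial_reads + 1``
    (a minimal posterior for finite read depth), and the trajectory is
    evaluated in closed form.  Quantities tracked: the pooled index and the
    first strain's fraction at each stage.
    """
    config = config or RunConfig()
    if config.mc_draws < 100:
        raise ValidationError(
            "mc_draws < 100 gives an unstable CDF; refusing", "ARGUMENT"
        )
    if mode not in ("summary", "bootstrap"):
        raise ValidationError(f"unknown mode {mode!r}", "ARGUMENT")
    strains = tuple(strains) if strains is not None else tuple(solo_ics)
    if len(strains) != 2:
        raise ValidationError("monte_carlo handles strain pairs", "ARGUMENT")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    d = config.mc_draws

    ics = _lookup(solo_ics, strains, "chemotactic index")
    mus = _lookup(rates, strains, "growth rate")
    I = np.column_stack(
        [
            _draw_nonnegative(
                rng, ic.ic_mean, ic.ic_sd, ic.n, d, ic.ratios or None, mode
            )
            for ic in ics
        ]
    )
    M = np.column_stack(
        [
            _draw_nonnegative(
                rng, r.mu, r.mu_sd, r.n_replicates, d, r.mu_replicates or None, mode
            )
            for r in mus
        ]
    )
    reads = np.asarray(initial_reads, dtype=float)
    if len(reads) != 2 or (reads < 0).any():
        raise ValidationError("initial_reads must be 2 non-negative counts", "ARGUMENT")
    if dirichlet:
        F = rng.dirichlet(reads + 1.0, size=d)
    else:
        F = np.tile(reads / reads.sum(), (d, 1))

    if isinstance(entry_rates, str):
        r_vec = np.ones(2)
    else:
        r_vec = np.asarray(entry_rates, dtype=float)
    W = F * r_vec
    W /= W.sum(axis=1, keepdims=True)
    pooled = (W * I).sum(axis=1)
    numer = W * I
    denom = numer.sum(axis=1, keepdims=True)
    # a draw where both indices hit 0 has undefined well composition; fall
    # back to the entry weights themselves (no chemotactic tilt)
    bad = denom[:, 0] <= 0
    numer[bad] = W[bad]
    denom = numer.sum(axis=1, keepdims=True)
    pc = numer / denom
    # growth phase in log space: extreme t-tail rate draws would overflow exp
    with np.errstate(divide="ignore"):
        log_pg = np.log(pc) + M * config.grow_time
    log_pg -= log_pg.max(axis=1, keepdims=True)
    pg = np.exp(log_pg)
    pg /= pg.sum(axis=1, keepdims=True)

    quantities = {
        "pooled_ic": np.sort(pooled),
        "frac_initial": np.sort(F[:, 0]),
        "frac_post_chemotaxis": np.sort(pc[:, 0]),
        "frac_post_growth": np.sort(pg[:, 0]),
    }
    intervals = {
        name: (float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975)))
        for name, v in quantities.items()
    }
    return MonteCarloResult(
        draws=d,
        seed=config.rng_seed,
        strains=strains,
        quantities=quantities,
        intervals=intervals,
    )


_STAGE_TO_QUANTITY = {
    "initial": "frac_initial",
    "post_chemotaxis": "frac_post_chemotaxis",
    "post_growth": "frac_post_growth",
}


@dataclasses.dataclass(frozen=True)
class PairEvaluation:
    """Joined prediction, observation and calls for one pair x metabolite."""

    experiment_id: str
    strains: tuple[str, ...]
    metabolite: str
    prediction: AssemblyPrediction
    observed: Mapping[str, CommunityComposition]
    deviations: tuple[DeviationCall, ...]
    observed_ic: ChemotaxisIndex
    ic_comparison: ComparisonResult
    member_ic: Mapping[str, float]
    directions: Mapping[str, str]

    @property
    def interaction_detected(self) -> bool:
        return (
            any(d.exceeds_threshold for d in self.deviations)
            or any(v != "0" for v in self.directions.values())
        )

    def summary(self) -> pd.DataFrame:
        """One row per stage: predicted/observed focal-strain fraction, D, call."""
        mc = self.prediction.mc
        rows = []
        for call in self.deviations:
            stage = call.stage
            lo, hi = (
                mc.interval(_STAGE_TO_QUANTITY[stage]) if mc else (np.nan, np.nan)
            )
            rows.append(
                {
                    "experiment_id": self.experiment_id,
                    "metabolite": self.metabolite,
                    "stage": stage,
                    "focal_strain": self.strains[0],
                    "predicted_fraction": self.prediction.trajectory[stage].fractions[0],
                    "observed_fraction": self.observed[stage].fractions[0],
                    "deviation_pp": call.deviation,
                    "exceeds_threshold": call.exceeds_threshold,
                    "p_value": call.p_value,
                    "ci_lo": lo,
                    "ci_hi": hi,
                }
            )
        return pd.DataFrame(rows)


def _stage_fractions(
    bundle: PairBundle,
    stage: str,
    well: str,
    fits: Mapping[str, CalibrationFit],
    config: RunConfig,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Replicate-mean observed fractions (calibration-corrected) for a stage."""
    asv = bundle.asv
    prefix = f"{bundle.experiment_id}:{stage}:"
    sub = asv[
        asv["sample_id"].str.startswith(prefix)
        & asv["sample_id"].str.endswith(f":{well}")
    ]
    if sub.empty:
        raise ValidationError(
            f"bundle has no ASV samples for stage {stage!r} well {well!r}",
            "MISSING_STAGE",
        )
    per_rep = []
    for _, lib in sub.groupby("sample_id"):
        reads = lib.set_index("strain_id")["reads"].reindex(list(bundle.strains))
        _, fractions = counts_to_cells(reads, fits, config)
        per_rep.append(fractions.to_numpy())
    return np.mean(per_rep, axis=0), per_rep


def evaluate_pair(
    bundle: PairBundle,
    solo_ics: Mapping[str, ChemotaxisIndex],
    rates: Mapping[str, GrowthRateEstimate],
    fits: Mapping[str, CalibrationFit],
    config: RunConfig | None = None,
    rng: np.random.Generator | None = None,
    mc_mode: str = "summary",
    entry_rates: Sequence[float] | str = "equal",
) -> PairEvaluation:
    """Run the full comparison for one pair x metabolite experiment bundle.

    Joins calibration-corrected observed compositions at all three stages
    with the null-model prediction parameterized by the solo measurements,
    attaches Monte Carlo p-values and intervals, tests the pooled index,
    infers member indices from the well amplicons and classifies each
    strain's interaction direction.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    strains = bundle.strains

    obs_initial, _ = _stage_fractions(bundle, "initial", "bulk", fits, config)
    initial = CommunityComposition("initial", strains, obs_initial)
    prediction = predict_assembly(
        solo_ics, rates, initial, config, bundle.metabolite, entry_rates
    )
    mc = monte_carlo(
        solo_ics,
        rates,
        bundle.initial_reads,
        config,
        strains=strains,
        rng=rng,
        mode=mc_mode,
        entry_rates=entry_rates,
    )
    prediction = dataclasses.replace(prediction, mc=mc)

    obs_pc, pc_reps = _stage_fractions(bundle, "post_chemotaxis", "metabolite", fits, config)
    obs_ctl, ctl_reps = _stage_fractions(bundle, "post_chemotaxis", "control", fits, config)
    obs_pg, _ = _stage_fractions(bundle, "post_growth", "metabolite", fits, config)
    observed = {
        "initial": initial,
        "post_chemotaxis": CommunityComposition("post_chemotaxis", strains, obs_pc),
        "post_growth": CommunityComposition("post_growth", strains, obs_pg),
    }

    calls = []
    for stage in STAGES:
        p = mc.p_value(_STAGE_TO_QUANTITY[stage], observed[stage].fractions[0])
        calls.append(
            deviation(prediction.trajectory[stage], observed[stage], config, p)
        )
    prediction = dataclasses.replace(prediction, deviations=tuple(calls))

    observed_ic = compute_ic(bundle.isca.frame, config)
    comparison = compare_pair_ic(
        mc.quantities["pooled_ic"], observed_ic, config, rng=rng
    )

    # member-level indices: split each replicate's pooled counts by the
    # sequenced well compositions, then test against the solo replicates
    wide = bundle.isca.frame.pivot(
        index="replicate", columns="well_type", values="cells"
    )
    member_reps: dict[str, list[float]] = {s: [] for s in strains}
    for k, rep in enumerate(sorted(wide.index)):
        member = infer_member_ic(
            float(wide.loc[rep, "metabolite"]),
            float(wide.loc[rep, "control"]),
            pc_reps[k],
            ctl_reps[k],
        )
        for s, v in zip(strains, member):
            member_reps[s].append(float(v))
    member_mean = {s: float(np.mean(v)) for s, v in member_reps.items()}
    directions = {
        s: classify_interaction(solo_ics[s], member_reps[s], config)
        for s in strains
    }

    return PairEvaluation(
        experiment_id=bundle.experiment_id,
        strains=strains,
        metabolite=bundle.metabolite,
        prediction=prediction,
        observed=observed,
        deviations=tuple(calls),
        observed_ic=observed_ic,
        ic_comparison=comparison,
        member_ic=member_mean,
        directions=directions,
    )
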