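"""Maximum specific growth rates from OD600 curves, and growth projection.

The maximum specific growth rate mu is the steepest slope of the natural-log
transformed OD curve over a sliding window of consecutive time points — the
standard operationalization of "the slope of the linear portion".  Windows
must pass an R-squared gate to count as linear; if none do, the best-R²
window is reported with a quality flag rather than raising.

Community projection through the growth phase is a pure exponential null:
each strain grows independently at its solo rate, n_i(T) = n_i(0) e^{mu_i T}.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .tables_io import RunConfig

__all__ = [
    "GrowthRateEstimate",
    "estimate_max_growth_rate",
    "estimate_rates_table",
    "project_growth",
    "sliding_window_fits",
]


@dataclasses.dataclass(frozen=True)
class GrowthRateEstimate:
    strain_id: str
    metabolite: str
    mu: float
    window: tuple[float, float]
    fit_r2: float
    n_replicates: int
    p_growth: float
    grew: bool
    window_quality_ok: bool = True
    mu_replicates: tuple[float, ...] = ()

    @property
    def mu_sd(self) -> float:
        if len(self.mu_replicates) < 2:
            return 0.0
        return float(np.std(self.mu_replicates, ddof=1))


def sliding_window_fits(
    t: np.ndarray, y: np.ndarray, window_points: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS slope and R² for every consecutive window.

    A window with zero variance in y is a perfect constant fit: slope 0,
    R² defined as 1 so that flat curves are not spuriously rejected.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(t) - window_points + 1
    if n < 1:
        raise ValidationError(
            f"need >= {window_points} points, got {len(t)}", "ARGUMENT"
        )
    idx = np.arange(window_points)[None, :] + np.arange(n)[:, None]
    T, Y = t[idx], y[idx]
    Tc = T - T.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = (Tc**2).sum(axis=1)
    sxy = (Tc * Yc).sum(axis=1)
    syy = (Yc**2).sum(axis=1)
    slope = sxy / sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), 1.0)
    return slope, r2


def _replicate_mu(
    t: np.ndarray, od: np.ndarray, config: RunConfig, blank: float
) -> tuple[float, float, tuple[float, float], bool]:
    """(mu, r2, window, quality_ok) for one replicate curve."""
    keep = od > blank
    t, od = t[keep], od[keep]
    if len(t) < config.window_points:
        raise ValidationError(
            f"only {len(t)} usable points after blank exclusion "
            f"(need {config.window_points})",
            "ARGUMENT",
        )
    y = np.log(od - blank)
    slope, r2 = sliding_window_fits(t, y, config.window_points)
    ok = r2 >= config.fit_r2_min
    if ok.any():
        pick = int(np.flatnonzero(ok)[np.argmax(slope[ok])])
        quality = True
    else:
        pick = int(np.argmax(r2))
        quality = False
    win = (float(t[pick]), float(t[pick + config.window_points - 1]))
    return float(slope[pick]), float(r2[pick]), win, quality


def estimate_max_growth_rate(
    curves: pd.DataFrame,
    config: RunConfig | None = None,
    blank: float | str = 0.0,
) -> GrowthRateEstimate:
    """Estimate mu for one strain x metabolite from replicate OD curves.

    ``curves`` needs columns replicate, time_h, od600 (strain_id/metabolite
    optional, used for labelling).  ``blank`` is subtracted before the log
    transform: a number (default 0 — curves already blank-corrected) or
    ``"first"`` to use each replicate's first reading; points at or below
    the blank are excluded rather than clamped.

    Significant growth is a two-sided one-sample t-test of the replicate mu
    values against 0, called positive only for a positive mean.
    """
    config = config or RunConfig()
    if curves.empty:
        raise ValidationError("empty growth slice", "EMPTY_SLICE")
    strain = str(curves["strain_id"].iloc[0]) if "strain_id" in curves else ""
    met = str(curves["metabolite"].iloc[0]) if "metabolite" in curves else ""

    mus, r2s, wins, quals = [], [], [], []
    for _, rep in curves.groupby("replicate"):
        rep = rep.sort_values("time_h")
        t = rep["time_h"].to_numpy(dtype=float)
        od = rep["od600"].to_numpy(dtype=float)
        b = float(od[0]) if blank == "first" else float(blank)
        mu, r2, win, ok = _replicate_mu(t, od, config, b)
        mus.append(mu)
        r2s.append(r2)
        wins.append(win)
        quals.append(ok)

    mus_arr = np.asarray(mus)
    mean_mu = float(mus_arr.mean())
    if len(mus_arr) >= 2:
        if np.std(mus_arr, ddof=1) == 0.0:
            p = 1.0 if np.isclose(mean_mu, 0.0) else 0.0
        else:
            p = float(stats.ttest_1samp(mus_arr, 0.0).pvalue)
    else:
        p = float("nan")
    # calling growth additionally requires every replicate to contain a
    # genuinely linear log-OD stretch: max-slope selection over noise-only
    # windows is positively biased and would otherwise flag flat curves
    grew = bool(
        len(mus_arr) >= 2 and p <= config.alpha and mean_mu > 0 and all(quals)
    )
    return GrowthRateEstimate(
        strain_id=strain,
        metabolite=met,
        mu=mean_mu,
        window=(min(w[0] for w in wins), max(w[1] for w in wins)),
        fit_r2=float(np.mean(r2s)),
        n_replicates=len(mus),
        p_growth=p,
        grew=grew,
        window_quality_ok=all(quals),
        mu_replicates=tuple(float(m) for m in mus),
    )


def estimate_rates_table(
    curves: pd.DataFrame, config: RunConfig | None = None, blank: float | str = 0.0
) -> list[GrowthRateEstimate]:
    """One estimate per strain x metabolite in a growth-curve table."""
    return [
        estimate_max_growth_rate(sub, config, blank)
        for _, sub in curves.groupby(["strain_id", "metabolite"], sort=True)
    ]


def write_rates_table(estimates: Sequence[GrowthRateEstimate], path) -> None:
    rows = [
        {
            "strain_id": e.strain_id,
            "metabolite": e.metabolite,
            "mu": e.mu,
            "window_start": e.window[0],
            "window_end": e.window[1],
            "fit_r2": e.fit_r2,
            "n_replicates": e.n_replicates,
            "p_growth": e.p_growth,
            "grew": e.grew,
            "window_quality_ok": e.window_quality_ok,
            "mu_replicates": ";".join(f"{m:.17g}" for m in e.mu_replicates),
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_rates_table(path) -> list[GrowthRateEstimate]:
    frame = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, row in frame.iterrows():
        reps = (
            tuple(float(x) for x in str(row["mu_replicates"]).split(";"))
            if pd.notna(row.get("mu_replicates")) and str(row["mu_replicates"])
            else ()
        )
        out.append(
            GrowthRateEstimate(
                strain_id=str(row["strain_id"]),
                metabolite=str(row["metabolite"]),
                mu=float(row["mu"]),
                window=(float(row["window_start"]), float(row["window_end"])),
                fit_r2=float(row["fit_r2"]),
                n_replicates=int(row["n_replicates"]),
                p_growth=float(row["p_growth"]),
                grew=bool(row["grew"]),
                window_quality_ok=bool(row["window_quality_ok"]),
                mu_replicates=reps,
            )
        )
    return out


def project_growth(
    abundances: Sequence[float],
    mus: Sequence[float] | Mapping[str, float],
    hours: float,
    strains: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Project abundances through ``hours`` of independent exponential growth.

    Returns (absolute abundances, renormalized fractions).  With a mapping
    of rates, ``strains`` fixes the order.
    """
    if hours < 0:
        raise ValidationError("hours must be >= 0", "ARGUMENT")
    n0 = np.asarray(abundances, dtype=float)
    if (n0 < 0).any() or n0.sum() <= 0:
        raise ValidationError(
            "abundances must be >= 0 with positive total", "ARGUMENT"
        )
    if isinstance(mus, Mapping):
        if strains is None:
            raise ValidationError(
                "strains order required with a rate mapping", "ARGUMENT"
            )
        mu = np.array([float(mus[s]) for s in strains])
    else:
        mu = np.asarray(mus, dtype=float)
    if len(mu) != len(n0) or not np.isfinite(mu).all() or (mu < 0).any():
        raise ValidationError(
            "rates must be finite, >= 0, one per strain", "ARGUMENT"
        )
    nt = n0 * np.exp(mu * hours)
    return nt, nt / nt.sum()
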