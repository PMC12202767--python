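"""Independent brute-force oracles used to cross-check closed forms.

These deliberately avoid the package's analytic formulas: chemotaxis is
simulated agent by agent (each cell independently enters a well with a
small probability) and growth as a per-cell branching (Yule) process.
"""
from __future__ import annotations

import numpy as np


def agent_chemotaxis(
    fractions: np.ndarray,
    entry_rates: np.ndarray,
    indices: np.ndarray,
    n_cells: int = 1_000_000,
    base_prob: float = 0.01,
    rng: np.random.Generator | None = None,
) -> dict:
    """Agent-level chemotaxis assay for an arbitrary mixture.

    Each of ``n_cells`` cells is assigned a strain by the mixture fractions;
    a strain-``i`` cell enters the control well with probability
    ``base_prob * r_i`` and the metabolite well with probability
    ``base_prob * r_i * I_i`` (independent Bernoulli draws).  Returns the
    realized pooled index and metabolite-well composition with delta-method
    standard errors.
    """
    rng = rng or np.random.default_rng(0)
    r = np.asarray(entry_rates, float) / np.max(entry_rates)
    I = np.asarray(indices, float)
    p_met = base_prob * r * I
    p_ctl = base_prob * r
    if (p_met > 1).any() or (p_ctl > 1).any():
        raise ValueError("entry probabilities exceed 1; lower base_prob")
    counts = rng.multinomial(n_cells, np.asarray(fractions, float))
    met = rng.binomial(counts, p_met)
    ctl = rng.binomial(counts, p_ctl)
    M, C = met.sum(), ctl.sum()
    var_m = (counts * p_met * (1 - p_met)).sum()
    var_c = (counts * p_ctl * (1 - p_ctl)).sum()
    pooled = M / C
    pooled_se = pooled * np.sqrt(var_m / M**2 + var_c / C**2)
    frac = met / M
    var_mi = counts * p_met * (1 - p_met)
    frac_se = np.sqrt(((M - met) ** 2 * var_mi + met**2 * (var_m - var_mi)) / M**4)
    return {
        "pooled_ic": pooled,
        "pooled_se": pooled_se,
        "well_fractions": frac,
        "well_fraction_se": frac_se,
        "met_counts": met,
        "ctl_counts": ctl,
    }


def branching_growth(
    initial_counts: np.ndarray,
    mus: np.ndarray,
    hours: float,
    rng: np.random.Generator | None = None,
) -> dict:
    """Per-cell exponential branching (Yule process) over ``hours``.

    Each founder cell of strain ``i`` leaves a geometric number of
    descendants with mean ``e^{mu_i * T}``; strain totals are therefore
    negative-binomial sums whose expectation matches deterministic
    exponential growth.
    """
    rng = rng or np.random.default_rng(0)
    n0 = np.asarray(initial_counts, int)
    p = np.exp(-np.asarray(mus, float) * hours)  # geometric success prob
    totals = n0 + np.array(
        [rng.negative_binomial(n, pi) if n > 0 else 0 for n, pi in zip(n0, p)]
    )
    totals = totals.astype(float)
    var = n0 * (1 - p) / p**2
    T = totals.sum()
    frac = totals / T
    var_t = var.sum()
    frac_se = np.sqrt(
        ((T - totals) ** 2 * var + totals**2 * (var_t - var)) / T**4
    )
    return {"totals": totals, "fractions": frac, "fraction_se": frac_se}
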