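"""Amplicon library normalization and mock-community cell calibration.

Libraries are normalized to a fixed total (a million reads by default) to
remove library-size differences; per-strain ordinary least squares of
normalized reads on known mock cell counts then yields a calibration line
whose inversion converts sample reads to cell abundances.  16S copy-number
and amplification biases are absorbed into the per-strain slopes — exactly
what the mock-community design measures.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SingularFitError, ValidationError
from .tables_io import RunConfig

__all__ = [
    "CalibrationFit",
    "normalize_library",
    "fit_calibration",
    "counts_to_cells",
]


@dataclasses.dataclass(frozen=True)
class CalibrationFit:
    """Per-strain line: normalized reads = slope * cells + intercept."""

    strain_id: str
    slope: float
    intercept: float
    r2: float
    n_points: int

    @property
    def qc_pass(self) -> bool:
        return self.slope > 0


def normalize_library(
    reads: Sequence[float] | np.ndarray, norm_total: float = 1_000_000.0
) -> np.ndarray:
    """Scale a library's per-strain reads to a fixed total.

    Proportions are preserved exactly; an empty library cannot be scaled.
    """
    r = np.asarray(reads, dtype=float)
    if (r < 0).any():
        raise ValidationError("negative read count", "NEGATIVE_COUNT")
    total = r.sum()
    if total <= 0:
        raise ValidationError("empty library: total reads is 0", "EMPTY_LIBRARY")
    return r * (norm_total / total)


def fit_calibration(
    calibration: pd.DataFrame,
    config: RunConfig | None = None,
    through_origin: bool = False,
) -> dict[str, CalibrationFit]:
    """Fit per-strain calibration lines from a mock-community table.

    Each mock's library is normalized to ``config.library_norm_total`` and
    normalized reads are regressed on the known cell counts (the intercept
    is fitted unless ``through_origin``).  A strain whose cell counts do not
    vary across mocks has no identifiable slope and raises
    :class:`SingularFitError`.
    """
    config = config or RunConfig()
    frame = calibration.copy()
    frame["norm_reads"] = 0.0
    for _, idx in frame.groupby("mock_id").groups.items():
        frame.loc[idx, "norm_reads"] = normalize_library(
            frame.loc[idx, "reads"].to_numpy(), config.library_norm_total
        )
    fits: dict[str, CalibrationFit] = {}
    for strain, sub in frame.groupby("strain_id", sort=True):
        cells = sub["cells"].to_numpy(dtype=float)
        reads = sub["norm_reads"].to_numpy(dtype=float)
        if len(cells) < 2:
            raise ValidationError(
                f"strain {strain!r} has < 2 mock points", "ARGUMENT"
            )
        if np.ptp(cells) == 0:
            raise SingularFitError(
                f"strain {strain!r} has identical cell counts across mocks"
            )
        if through_origin:
            slope = float((cells @ reads) / (cells @ cells))
            intercept = 0.0
            resid = reads - slope * cells
            sst = float(((reads - reads.mean()) ** 2).sum())
            r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 1.0
        else:
            fit = stats.linregress(cells, reads)
            slope, intercept = float(fit.slope), float(fit.intercept)
            r2 = float(fit.rvalue**2)
        fits[str(strain)] = CalibrationFit(
            strain_id=str(strain),
            slope=slope,
            intercept=intercept,
            r2=max(0.0, min(1.0, r2)),
            n_points=len(cells),
        )
    return fits


def write_fits_table(fits: Mapping[str, CalibrationFit], path) -> None:
    rows = [dataclasses.asdict(f) for f in fits.values()]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_fits_table(path) -> dict[str, CalibrationFit]:
    frame = pd.read_csv(path, float_precision="round_trip")
    return {
        str(row["strain_id"]): CalibrationFit(
            strain_id=str(row["strain_id"]),
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            r2=float(row["r2"]),
            n_points=int(row["n_points"]),
        )
        for _, row in frame.iterrows()
    }


def counts_to_cells(
    reads: Mapping[str, float] | pd.Series,
    fits: Mapping[str, CalibrationFit],
    config: RunConfig | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Convert one sample's ASV reads to cell abundances and fractions.

    Inverts each strain's calibration line after normalizing the library;
    estimates below the intercept are clamped to zero with a warning
    (sequencing noise near the detection limit), then fractions are
    renormalized.
    """
    config = config or RunConfig()
    series = pd.Series(reads, dtype=float)
    missing = [s for s in series.index if s not in fits]
    if missing:
        raise ValidationError(
            f"no calibration fit for strain(s) {missing}", "ARGUMENT"
        )
    bad = [s for s in series.index if not fits[s].qc_pass]
    if bad:
        raise ValidationError(
            f"calibration QC failed (non-positive slope) for {bad}", "QC_FAIL"
        )
    norm = normalize_library(series.to_numpy(), config.library_norm_total)
    cells = np.empty_like(norm)
    for k, strain in enumerate(series.index):
        fit = fits[strain]
        cells[k] = (norm[k] - fit.intercept) / fit.slope
    if (cells < 0).any():
        clamped = [s for s, c in zip(series.index, cells) if c < 0]
        warnings.warn(
            f"cell estimate below detection for {clamped}; clamped to 0",
            stacklevel=2,
        )
        cells = np.clip(cells, 0.0, None)
    total = cells.sum()
    if total <= 0:
        raise ValidationError(
            "all cell estimates are zero; composition undefined", "EMPTY_SAMPLE"
        )
    cells_s = pd.Series(cells, index=series.index, name="cells")
    return cells_s, cells_s / total
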