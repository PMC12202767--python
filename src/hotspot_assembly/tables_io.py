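"""On-disk table schemas, validation, and the run configuration.

Every table the pipeline touches is a plain UTF-8 CSV with a mandatory
header row, '.' decimal separator and no quoting of simple labels.  All
downstream modules consume only the validated structures defined here.

Schemas
-------
isca_counts.csv    experiment_id,strain_set,chemoattractant,replicate,well_type,cells
asv_counts.csv     sample_id,strain_id,reads
growth_curves.csv  strain_id,metabolite,replicate,time_h,od600
calibration.csv    mock_id,strain_id,cells,reads

Cell counts are per-millilitre concentrations (flow-cytometry output); the
chemotactic index is a ratio so only within-table consistency matters.
One ISCA row is stored per (device replicate, well type): technical wells
within a device are pooled before they reach these tables.
"""
from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import StructuralError, ValidationError

__all__ = [
    "RunConfig",
    "MeasurementTable",
    "read_config",
    "write_config",
    "read_isca_table",
    "write_isca_table",
    "read_asv_table",
    "write_asv_table",
    "read_growth_table",
    "write_growth_table",
    "read_calibration_table",
    "write_calibration_table",
]

WELL_TYPES = ("metabolite", "control")

ISCA_COLUMNS = [
    "experiment_id",
    "strain_set",
    "chemoattractant",
    "replicate",
    "well_type",
    "cells",
]
ASV_COLUMNS = ["sample_id", "strain_id", "reads"]
GROWTH_COLUMNS = ["strain_id", "metabolite", "replicate", "time_h", "od600"]
CALIBRATION_COLUMNS = ["mock_id", "strain_id", "cells", "reads"]

#: significant digits used when writing floats, so that write->read round-trips
FLOAT_FORMAT = "%.9g"


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Analysis-wide knobs with the study's default values.

    Parameters
    ----------
    alpha:
        Significance level for every hypothesis test (t-tests at P <= 0.05).
    ic_null:
        Reference chemotactic index; 1 means "no different from the seawater
        control".
    deviation_threshold:
        Percentage-point deviation between predicted and observed community
        composition above which an inter-species interaction is called
        (the conservative 10 % rule).
    grow_time:
        Duration of the growth phase following chemotaxis, in hours.
    mc_draws:
        Monte Carlo draws used for uncertainty propagation.
    rng_seed:
        Seed for every stochastic step of a run.
    window_points:
        Number of consecutive time points in the sliding log-linear window
        used to estimate maximum growth rates.
    fit_r2_min:
        Minimum R-squared for a window to count as "the linear portion".
    library_norm_total:
        Total each amplicon library is normalized to (reads).
    """

    alpha: float = 0.05
    ic_null: float = 1.0
    deviation_threshold: float = 10.0
    grow_time: float = 24.0
    mc_draws: int = 10_000
    rng_seed: int = 0
    window_points: int = 5
    fit_r2_min: float = 0.95
    library_norm_total: float = 1_000_000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(
                f"alpha must lie in (0, 1), got {self.alpha}", "CONFIG_RANGE"
            )
        if not self.deviation_threshold > 0:
            raise ValidationError(
                f"deviation_threshold must be > 0, got {self.deviation_threshold}",
                "CONFIG_RANGE",
            )
        if not self.grow_time > 0:
            raise ValidationError(
                f"grow_time must be > 0, got {self.grow_time}", "CONFIG_RANGE"
            )
        if self.mc_draws < 100:
            raise ValidationError(
                f"mc_draws must be >= 100, got {self.mc_draws}", "CONFIG_RANGE"
            )
        if self.window_points < 3:
            raise ValidationError(
                f"window_points must be >= 3, got {self.window_points}",
                "CONFIG_RANGE",
            )
        if not self.library_norm_total > 0:
            raise ValidationError(
                f"library_norm_total must be > 0, got {self.library_norm_total}",
                "CONFIG_RANGE",
            )


_INT_FIELDS = {"mc_draws", "rng_seed", "window_points"}
_CONFIG_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def read_config(path: str | Path) -> RunConfig:
    """Read a flat ``key = value`` config file, applying defaults.

    Unknown keys produce a warning (forward compatibility), malformed lines
    raise a :class:`ValidationError` naming the offending content.
    """
    text = Path(path).read_text(encoding="utf-8")
    values: dict[str, object] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(
                f"config line {lineno} is not 'key = value': {line!r}",
                "CONFIG_PARSE",
            )
        key, _, value = (part.strip() for part in line.partition("="))
        if key not in _CONFIG_FIELDS:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
            continue
        try:
            parsed = int(value) if key in _INT_FIELDS else float(value)
        except ValueError as exc:
            raise ValidationError(
                f"config key {key!r} has unparseable value {value!r}",
                "CONFIG_PARSE",
            ) from exc
        values[key] = parsed
    return RunConfig(**values)  # type: ignore[arg-type]


def write_config(config: RunConfig, path: str | Path) -> None:
    lines = [
        f"{field.name} = {getattr(config, field.name)}"
        for field in dataclasses.fields(RunConfig)
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclasses.dataclass(frozen=True)
class MeasurementTable:
    """Validated ISCA well counts: one metabolite/control pair per replicate."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_isca(self.frame)

    @property
    def n_replicates(self) -> int:
        return self.frame["replicate"].nunique()

    def experiments(self) -> Iterator[tuple[tuple[str, str], pd.DataFrame]]:
        """Iterate over (experiment_id, chemoattractant) slices."""
        for key, sub in self.frame.groupby(
            ["experiment_id", "chemoattractant"], sort=True
        ):
            yield key, sub  # type: ignore[misc]

    def select(
        self, experiment_id: str | None = None, chemoattractant: str | None = None
    ) -> pd.DataFrame:
        sub = self.frame
        if experiment_id is not None:
            sub = sub[sub["experiment_id"] == experiment_id]
        if chemoattractant is not None:
            sub = sub[sub["chemoattractant"] == chemoattractant]
        return sub

    def __eq__(self, other: object) -> bool:  # frame equality, order-insensitive
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        a = self.frame.sort_values(ISCA_COLUMNS[:5]).reset_index(drop=True)
        b = other.frame.sort_values(ISCA_COLUMNS[:5]).reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True


def _require_columns(frame: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise StructuralError(
            f"{what} is missing columns {missing}", "MISSING_COLUMN"
        )


def _validate_isca(frame: pd.DataFrame) -> None:
    _require_columns(frame, ISCA_COLUMNS, "ISCA table")
    if (frame["cells"] < 0).any():
        bad = frame.loc[frame["cells"] < 0].iloc[0]
        raise ValidationError(
            f"negative cell count {bad['cells']} for experiment "
            f"{bad['experiment_id']!r} replicate {bad['replicate']}",
            "NEGATIVE_COUNT",
        )
    unknown = set(frame["well_type"]) - set(WELL_TYPES)
    if unknown:
        raise ValidationError(
            f"unknown well_type values {sorted(unknown)}", "BAD_WELL_TYPE"
        )
    keys = frame[["experiment_id", "chemoattractant", "replicate", "well_type"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise StructuralError(f"duplicate well row for key {dup}", "DUPLICATE_KEY")
    counts = frame.pivot_table(
        index=["experiment_id", "chemoattractant", "replicate"],
        columns="well_type",
        values="cells",
        aggfunc="size",
        fill_value=0,
    )
    for well in WELL_TYPES:
        if well not in counts.columns:
            counts[well] = 0
    orphans = counts[(counts["metabolite"] != 1) | (counts["control"] != 1)]
    if len(orphans):
        raise StructuralError(
            "unpaired wells for keys "
            + ", ".join(str(tuple(k)) for k in orphans.index[:5]),
            "UNPAIRED_WELL",
        )


def _read_csv(path: str | Path, columns: list[str], what: str) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, columns, what)
    return frame[columns]


def _write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_isca_table(path: str | Path) -> MeasurementTable:
    return MeasurementTable(_read_csv(path, ISCA_COLUMNS, "ISCA table"))


def write_isca_table(table: MeasurementTable, path: str | Path) -> None:
    _write_csv(table.frame, path)


def read_asv_table(path: str | Path) -> pd.DataFrame:
    frame = _read_csv(path, ASV_COLUMNS, "ASV table")
    if (frame["reads"] < 0).any():
        raise ValidationError("negative read count in ASV table", "NEGATIVE_COUNT")
    if frame[["sample_id", "strain_id"]].duplicated().any():
        raise StructuralError(
            "duplicate (sample_id, strain_id) row in ASV table", "DUPLICATE_KEY"
        )
    return frame


def write_asv_table(frame: pd.DataFrame, path: str | Path) -> None:
    _write_csv(frame[ASV_COLUMNS], path)


def read_growth_table(path: str | Path) -> pd.DataFrame:
    frame = _read_csv(path, GROWTH_COLUMNS, "growth table")
    if (frame["od600"] < 0).any():
        raise ValidationError("negative OD600 in growth table", "NEGATIVE_COUNT")
    if frame[["strain_id", "metabolite", "replicate", "time_h"]].duplicated().any():
        raise StructuralError(
            "duplicate time point in growth table", "DUPLICATE_KEY"
        )
    return frame


def write_growth_table(frame: pd.DataFrame, path: str | Path) -> None:
    _write_csv(frame[GROWTH_COLUMNS], path)


def read_calibration_table(path: str | Path) -> pd.DataFrame:
    frame = _read_csv(path, CALIBRATION_COLUMNS, "calibration table")
    if (frame["cells"] < 0).any() or (frame["reads"] < 0).any():
        raise ValidationError(
            "negative count in calibration table", "NEGATIVE_COUNT"
        )
    if frame[["mock_id", "strain_id"]].duplicated().any():
        raise StructuralError(
            "duplicate (mock_id, strain_id) row in calibration table",
            "DUPLICATE_KEY",
        )
    return frame


def write_calibration_table(frame: pd.DataFrame, path: str | Path) -> None:
    _write_csv(frame[CALIBRATION_COLUMNS], path)


def strain_set_label(strains: tuple[str, ...] | list[str]) -> str:
    """Serialize an ordered strain set as ``A+B`` for the strain_set column."""
    return "+".join(strains)


def parse_strain_set(label: str) -> tuple[str, ...]:
    return tuple(label.split("+"))
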