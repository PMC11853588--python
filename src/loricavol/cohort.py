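"""Cohort-level statistics over staged specimens.

Given per-specimen records (division stage, lorica-forming-material
volumes, cell dimensions/volumes, lorica wall volume), this module derives
the descriptive quantities of interest for LFM dynamics:

* per-stage summaries of total LFM (n, mean, min, max);
* stage-to-stage increments and their share of the final (VLD) mean;
* occupancy of LFM in the cell volume (%);
* fold ranges (max/min) of within-stage volumes;
* the swelling factor — minimum finished-wall volume over maximum
  intracellular LFM volume, a conservative lower bound on the expansion of
  the secreted material;
* divider-frequency percentages and wall-volume summaries.

No inferential statistics are computed.  Reported values follow fixed
rounding conventions (integer percentages, one-decimal folds); the
unrounded doubles are always retained in machine output.
"""

from __future__ import annotations

import math
import statistics
import warnings
from dataclasses import dataclass, field, fields

import pandas as pd

from .errors import ValidationError
from .staging import DivisionStage, LfmCategory

__all__ = [
    "SpecimenRecord",
    "StageSummary",
    "CSV_COLUMNS",
    "stage_summary",
    "stage_increments",
    "occupancy",
    "swelling_factor",
    "fold_range",
    "stage_frequencies",
    "elongation_percent",
    "wall_summary",
    "records_to_frame",
    "frame_to_records",
    "read_records_csv",
    "write_records_csv",
    "category_table",
]

#: Specimen CSV schema (header order); empty fields are allowed.
CSV_COLUMNS = [
    "id",
    "population",
    "stage",
    "lfm_total_um3",
    "lfm_anterior_um3",
    "lfm_middle_um3",
    "lfm_posterior_um3",
    "category",
    "cell_length_um",
    "cell_width_um",
    "cell_vol_ellipsoid_um3",
    "cell_vol_shape_um3",
    "wall_vol_um3",
]

_VOLUME_FIELDS = [c for c in CSV_COLUMNS if c.endswith("_um3") or c.endswith("_um")]


@dataclass
class SpecimenRecord:
    """One specimen row: stage plus optional volumetric measurements."""

    id: str
    stage: DivisionStage
    population: str = ""
    lfm_total_um3: float | None = None
    lfm_anterior_um3: float | None = None
    lfm_middle_um3: float | None = None
    lfm_posterior_um3: float | None = None
    category: LfmCategory | None = None
    cell_length_um: float | None = None
    cell_width_um: float | None = None
    cell_vol_ellipsoid_um3: float | None = None
    cell_vol_shape_um3: float | None = None
    wall_vol_um3: float | None = None
    portion_sum_rtol: float = field(default=0.02, repr=False)

    def __post_init__(self) -> None:
        for name in _VOLUME_FIELDS:
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
        portions = (
            self.lfm_anterior_um3,
            self.lfm_middle_um3,
            self.lfm_posterior_um3,
        )
        if self.lfm_total_um3 and all(p is not None for p in portions):
            total = sum(portions)
            if not math.isclose(
                total, self.lfm_total_um3,
                rel_tol=self.portion_sum_rtol, abs_tol=1e-9,
            ):
                raise ValidationError(
                    f"specimen {self.id}: portion sum {total:.1f} µm³ deviates "
                    f"from total {self.lfm_total_um3:.1f} µm³ by more than "
                    f"{self.portion_sum_rtol:.0%}"
                )

    @property
    def cell_volume_preferred(self) -> float | None:
        """Shape-function cell volume when available, else the ellipsoid one."""
        if self.cell_vol_shape_um3 is not None:
            return self.cell_vol_shape_um3
        return self.cell_vol_ellipsoid_um3


@dataclass
class StageSummary:
    """Per-stage n / mean / min / max of total LFM (µm³)."""

    stage: DivisionStage
    n: int
    mean: float
    min: float
    max: float
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("a stage summary requires n >= 1")
        if not self.min <= self.mean <= self.max:
            raise ValidationError("summary violates min <= mean <= max")


def stage_summary(records: list[SpecimenRecord]) -> list[StageSummary]:
    """Summarise total LFM per stage, ordered by stage.

    Records without an ``lfm_total_um3`` measurement are skipped and counted
    in the summary's ``n_skipped``; stages with no measured record are
    omitted from the output.
    """
    if not records:
        raise ValidationError("no records supplied")
    out: list[StageSummary] = []
    for stage in sorted({r.stage for r in records}):
        here = [r for r in records if r.stage == stage]
        values = [r.lfm_total_um3 for r in here if r.lfm_total_um3 is not None]
        if not values:
            continue
        out.append(
            StageSummary(
                stage=stage,
                n=len(values),
                mean=statistics.fmean(values),
                min=min(values),
                max=max(values),
                n_skipped=len(here) - len(values),
            )
        )
    return out


def stage_increments(stage_means: list[float]) -> list[dict]:
    """Stage-to-stage LFM increments and their share of the final mean.

    ``stage_means`` are the per-stage mean volumes in divider order
    (ED, EMD, LMD, ELD, VLD); the ED mean is conventionally 0 (onset of
    production).  Each transition i reports the absolute increment
    ``mean_i - mean_{i-1}`` (µm³) and ``100 * increment / final mean``.
    Unrounded increments sum to the final mean exactly and unrounded
    percentages to 100.  Decreasing means (production can pause while
    material is secreted or resorbed) only raise a warning.
    """
    if len(stage_means) < 2:
        raise ValidationError("need at least two stage means")
    final = stage_means[-1]
    if final <= 0:
        raise ValidationError("final stage mean must be > 0")
    if any(b < a for a, b in zip(stage_means, stage_means[1:])):
        warnings.warn("stage means are not monotone non-decreasing", stacklevel=2)
    out = []
    for prev, cur in zip(stage_means, stage_means[1:]):
        inc = cur - prev
        out.append(
            {
                "increment_um3": inc,
                "percent_of_final": 100.0 * inc / final,
                "percent_of_final_rounded": round(100.0 * inc / final),
            }
        )
    return out


def occupancy(lfm_total: float, cell_volume: float) -> float:
    """LFM volume as a percentage of the cell volume.

    By convention the shape-function cell volume is used when both estimates
    exist (see :attr:`SpecimenRecord.cell_volume_preferred`).
    """
    if cell_volume <= 0:
        raise ValidationError(f"cell volume must be > 0 µm³, got {cell_volume}")
    if lfm_total < 0:
        raise ValidationError("LFM volume must be >= 0 µm³")
    return 100.0 * lfm_total / cell_volume


def swelling_factor(min_wall_volume: float, max_lfm_volume: float) -> float:
    """Conservative lower bound on post-secretion swelling of the LFM:
    minimum finished-wall volume over maximum intracellular LFM volume."""
    if max_lfm_volume <= 0:
        raise ValidationError("maximum LFM volume must be > 0 µm³")
    if min_wall_volume < 0:
        raise ValidationError("wall volume must be >= 0 µm³")
    return min_wall_volume / max_lfm_volume


def fold_range(values: list[float]) -> dict:
    """Max/min fold variation of a set of volumes.

    Returns the raw ratio and the one-decimal value used for reporting.
    """
    if len(values) < 2:
        raise ValidationError("fold range requires at least two values")
    lo, hi = min(values), max(values)
    if lo <= 0:
        raise ValidationError("fold range undefined: minimum value is <= 0")
    return {"fold": hi / lo, "fold_rounded": round(hi / lo, 1)}


def stage_frequencies(counts: dict | list[float]) -> dict:
    """Relative class frequencies in percent.

    Accepts a mapping class → count or a plain sequence.  Returns raw and
    integer-rounded percentages; the raw values sum to 100.
    """
    if isinstance(counts, dict):
        keys = list(counts.keys())
        values = [counts[k] for k in keys]
    else:
        values = list(counts)
        keys = list(range(len(values)))
    if any(v < 0 for v in values):
        raise ValidationError("counts must be >= 0")
    total = sum(values)
    if total <= 0:
        raise ValidationError("all counts are zero")
    raw = {k: 100.0 * v / total for k, v in zip(keys, values)}
    return {
        "percent": raw,
        "percent_rounded": {k: round(p) for k, p in raw.items()},
        "n_total": total,
    }


def elongation_percent(length: float, reference_length: float) -> float:
    """Percent elongation of a mean cell length relative to a reference
    stage, ``100 * (L / L_ref - 1)``."""
    if reference_length <= 0:
        raise ValidationError("reference length must be > 0 µm")
    return 100.0 * (length / reference_length - 1.0)


def wall_summary(wall_volumes: list[float]) -> dict:
    """Descriptive summary of lorica-wall volumes (µm³).

    Returns n, mean, median, sample standard deviation (n−1 denominator),
    min and max.  With a single value the SD is omitted (``None``) with a
    warning.
    """
    if not wall_volumes:
        raise ValidationError("no wall volumes supplied")
    if any(v < 0 for v in wall_volumes):
        raise ValidationError("wall volumes must be >= 0 µm³")
    out = {
        "n": len(wall_volumes),
        "mean": statistics.fmean(wall_volumes),
        "median": statistics.median(wall_volumes),
        "min": min(wall_volumes),
        "max": max(wall_volumes),
    }
    if len(wall_volumes) >= 2:
        out["sd"] = statistics.stdev(wall_volumes)
    else:
        warnings.warn("n < 2: sample SD omitted", stacklevel=2)
        out["sd"] = None
    return out


# ---------------------------------------------------------------------------
# tabular round-trips

def records_to_frame(records: list[SpecimenRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {name: getattr(r, name) for name in CSV_COLUMNS
               if name not in ("stage", "category")}
        row["stage"] = r.stage.code
        row["category"] = int(r.category) if r.category is not None else None
        rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[SpecimenRecord]:
    missing = [c for c in ("id", "stage") if c not in frame.columns]
    if missing:
        raise ValidationError(f"specimen table lacks required columns {missing}")
    records = []
    errors = []
    optional = [f.name for f in fields(SpecimenRecord)
                if f.name not in ("id", "stage", "population", "portion_sum_rtol")]
    for i, row in frame.iterrows():
        try:
            kwargs = {}
            for name in optional:
                value = row.get(name)
                if value is None or (isinstance(value, float) and math.isnan(value)):
                    continue
                if name == "category":
                    kwargs[name] = LfmCategory(int(value))
                else:
                    kwargs[name] = float(value)
            records.append(
                SpecimenRecord(
                    id=str(row["id"]),
                    stage=DivisionStage.from_code(str(row["stage"])),
                    population=str(row.get("population", "") or ""),
                    **kwargs,
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(
            "specimen table has invalid rows:\n" + "\n".join(errors)
        )
    if not records:
        raise ValidationError("specimen table contains no records")
    return records


def read_records_csv(path) -> list[SpecimenRecord]:
    return frame_to_records(pd.read_csv(path))


def write_records_csv(records: list[SpecimenRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def category_table(records: list[SpecimenRecord]) -> pd.DataFrame:
    """Stage × LFM-category count table (divider stages as rows, ordinal
    categories 0–3 as columns), the layout of the semi-quantitative
    bar-plot summaries."""
    staged = [r for r in records if r.category is not None]
    if not staged:
        raise ValidationError("no records carry an LFM category")
    table = pd.DataFrame(
        0,
        index=[s.code for s in DivisionStage.dividers()],
        columns=[int(c) for c in LfmCategory],
    )
    for r in staged:
        if r.stage in DivisionStage.dividers():
            table.loc[r.stage.code, int(r.category)] += 1
    return table
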