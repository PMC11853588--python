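"""End-to-end cohort report.

:func:`run_report` reads a specimen CSV, derives every cohort statistic the
package computes (stage table, increments, occupancy, folds, swelling
factor, divider frequencies, wall summary, stage × category table) and
writes a JSON report plus CSV twins.  Every report embeds a provenance
block (configuration echo, seed, package version, input checksum) and is
byte-stable for identical inputs; partial reports are never written.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    SpecimenRecord,
    category_table,
    fold_range,
    occupancy,
    read_records_csv,
    stage_frequencies,
    stage_increments,
    stage_summary,
    swelling_factor,
    wall_summary,
)
from .io import AnalysisConfig, sha256_of
from .staging import DivisionStage

__all__ = ["build_report", "run_report"]


def _divider_means(summaries) -> list[float]:
    """Means for ED..VLD in stage order; the ED baseline is 0 (onset of
    LFM production) and stages without data inherit the previous mean."""
    by_stage = {s.stage: s.mean for s in summaries}
    means = [0.0]
    for stage in DivisionStage.dividers()[1:]:
        means.append(by_stage.get(stage, means[-1]))
    return means


def build_report(records: list[SpecimenRecord], config: AnalysisConfig) -> dict:
    """Compute all cohort statistics for a list of specimen records."""
    report: dict = {}

    summaries = stage_summary(records)
    report["stage_table"] = [
        {
            "stage": s.stage.code,
            "n": s.n,
            "mean_um3": s.mean,
            "min_um3": s.min,
            "max_um3": s.max,
            "n_skipped": s.n_skipped,
        }
        for s in summaries
    ]

    means = _divider_means(summaries)
    if means[-1] > 0:
        transitions = [
            f"{a.code}->{b.code}"
            for a, b in zip(DivisionStage.dividers(), DivisionStage.dividers()[1:])
        ]
        report["increments"] = [
            {"transition": t, **inc}
            for t, inc in zip(transitions, stage_increments(means))
        ]

    occ_rows = []
    for r in records:
        cell_volume = r.cell_volume_preferred
        if r.lfm_total_um3 is not None and cell_volume:
            occ_rows.append(
                {
                    "id": r.id,
                    "stage": r.stage.code,
                    "occupancy_percent": occupancy(r.lfm_total_um3, cell_volume),
                }
            )
    report["occupancy_table"] = occ_rows
    vld_occ = [row["occupancy_percent"] for row in occ_rows
               if row["stage"] == "VLD"]
    if vld_occ:
        report["occupancy_vld"] = {
            "n": len(vld_occ),
            "mean_percent": sum(vld_occ) / len(vld_occ),
            "min_percent": min(vld_occ),
            "max_percent": max(vld_occ),
        }

    report["fold_ranges"] = {}
    for stage in DivisionStage.dividers():
        values = [r.lfm_total_um3 for r in records
                  if r.stage == stage and r.lfm_total_um3]
        if len(values) >= 2:
            report["fold_ranges"][stage.code] = fold_range(values)

    walls = [r.wall_vol_um3 for r in records if r.wall_vol_um3 is not None]
    lfm_positive = [r.lfm_total_um3 for r in records if r.lfm_total_um3]
    if walls:
        report["wall_summary"] = wall_summary(walls)
    if walls and lfm_positive:
        factor = swelling_factor(min(walls), max(lfm_positive))
        report["swelling"] = {
            "min_wall_um3": min(walls),
            "max_lfm_um3": max(lfm_positive),
            "factor": factor,
            "factor_rounded": round(factor, 1),
        }

    counts = {stage.code: sum(1 for r in records if r.stage == stage)
              for stage in DivisionStage}
    counts = {k: v for k, v in counts.items() if v}
    report["stage_frequencies"] = stage_frequencies(counts)

    try:
        report["category_table"] = {
            stage: row.to_dict()
            for stage, row in category_table(records).iterrows()
        }
    except Exception:
        report["category_table"] = None

    report["provenance"] = {
        "package": "loricavol",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "n_records": len(records),
    }
    return report


def run_report(records_csv, config: AnalysisConfig, out_dir=None) -> dict:
    """Read a specimen CSV, build the full report and write it to disk.

    Writes ``report.json`` plus CSV twins of the stage table, the occupancy
    table and the stage × category table into ``out_dir`` (default: the
    configured output directory).  All statistics are computed before any
    file is opened, so a failing input never leaves a partial report.
    """
    records = read_records_csv(records_csv)
    report = build_report(records, config)
    report["provenance"]["input"] = {
        "path": str(records_csv),
        "sha256": sha256_of(records_csv),
    }

    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    pd.DataFrame(report["stage_table"]).to_csv(
        out / "stage_table.csv", index=False
    )
    pd.DataFrame(report["occupancy_table"]).to_csv(
        out / "occupancy_table.csv", index=False
    )
    if report["category_table"] is not None:
        pd.DataFrame(report["category_table"]).T.to_csv(
            out / "category_table.csv"
        )
    return report
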