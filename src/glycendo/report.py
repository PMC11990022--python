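"""End-to-end pipeline: biomarkers -> endotypes -> stratified comparison tables.

``run_pipeline`` computes the biomarker panel for every subject, assigns
endotype labels, and produces the five standard comparison tables:

1. basic characteristics, HS vs control;
2. measured and calculated homeostasis biomarkers, HS vs control;
3. biomarkers within HS, diabetes vs no diabetes;
4. biomarkers within HS, low vs high haptoglobin stratum;
5. biomarkers and severity within HS, antidiabetic treatment vs none.

Each table is written as CSV and as a plain-text rendering; per-subject
figure data (index values with group labels, disposition-plane
coordinates) and a JSON run log complete the bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import (DEFAULT_REFERENCE_RANGES, DEFAULT_SPINA_CONSTANTS,
                         INDEX_NAMES, ReferenceRange, SpinaConstants, panel_frame)
from .cohort import Cohort
from .endotypes import label_frame
from .stats import GroupComparison, compare_table, comparisons_to_frame

logger = logging.getLogger(__name__)

BIOMARKER_VARIABLES = ["glucose", "insulin", "hba1c", *INDEX_NAMES]


@dataclass
class ReportBundle:
    """All computed artefacts of one pipeline run."""

    augmented: pd.DataFrame
    tables: dict[str, list[GroupComparison]] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)
    disposition: pd.DataFrame | None = None
    zones: dict[str, pd.DataFrame] = field(default_factory=dict)


def augment_cohort(cohort: Cohort,
                   constants: SpinaConstants = DEFAULT_SPINA_CONSTANTS) -> pd.DataFrame:
    """Cohort DataFrame with biomarker panel and endotype labels appended."""
    df = panel_frame(cohort, constants=constants)
    return label_frame(cohort, panels_df=df)


def _table1(df: pd.DataFrame) -> list[GroupComparison]:
    d = df.copy()
    d["female"] = d["sex"] == "female"
    variables = ["female", "age", "bmi", "diabetes"]
    severity = ["hurley", "sahs", "exacerbations", "regions", "fistulae",
                "nodules", "abscesses"]
    comps = compare_table(d, variables, "group", ("HS", "control"))
    sev = compare_table(d, severity, "group", ("HS", "control"))
    return comps + sev


def build_tables(df: pd.DataFrame) -> tuple[dict[str, list[GroupComparison]], dict[str, str]]:
    """The five stratified comparison tables; strata that cannot be formed
    (e.g. no HS subjects) are skipped with an explanatory note."""
    tables: dict[str, list[GroupComparison]] = {}
    notes: dict[str, str] = {}

    groups = set(df["group"])
    if groups >= {"HS", "control"}:
        tables["table1_characteristics"] = _table1(df)
        tables["table2_biomarkers"] = compare_table(
            df, BIOMARKER_VARIABLES, "group", ("HS", "control"))
    else:
        notes["table1_characteristics"] = notes["table2_biomarkers"] = (
            f"needs both HS and control subjects; cohort has {sorted(groups)}")

    hs = df[df["group"] == "HS"].copy()
    if hs.empty:
        reason = "no HS subjects in cohort"
        for name in ("table3_diabetes", "table4_haptoglobin", "table5_treatment"):
            notes[name] = reason
        return tables, notes

    strata = [
        ("table3_diabetes", "diabetes", (False, True)),
        ("table4_haptoglobin", "hp_stratum", ("low", "high")),
        ("table5_treatment", "treated", (False, True)),
    ]
    for name, col, values in strata:
        sub = hs[hs[col].isin(values)]
        counts = sub[col].value_counts()
        if any(counts.get(v, 0) == 0 for v in values):
            notes[name] = f"stratum {col} does not split HS into two non-empty groups"
            continue
        variables = list(BIOMARKER_VARIABLES)
        if name == "table5_treatment":
            variables += ["hurley", "sahs", "exacerbations", "regions", "crp", "haptoglobin"]
        tables[name] = compare_table(sub, variables, col, values)
    return tables, notes


def disposition_plane(
    panels: pd.DataFrame,
    ranges: dict[str, ReferenceRange] = DEFAULT_REFERENCE_RANGES,
    gr_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-subject (SPINA-GR, SPINA-GBeta) coordinates and the normal-DI zone.

    Subjects without evaluable SPINA parameters are skipped (their count is
    logged).  The zone of a normal disposition index is bounded by the
    iso-curves GBeta = DI/GR of the DI reference limits, traced over a GR
    grid.
    """
    cols = ["spina_gr", "spina_gbeta"]
    keep = panels.dropna(subset=cols)
    skipped = len(panels) - len(keep)
    if skipped:
        logger.info("disposition plane: skipped %d subjects without evaluable SPINA values", skipped)
    label_cols = [c for c in ("subject_id", "group", "diabetes") if c in keep.columns]
    points = keep[label_cols + cols].reset_index(drop=True)

    di = ranges["spina_di"]
    if gr_grid is None:
        hi = float(keep["spina_gr"].max()) * 1.1 if len(keep) else 10.0
        gr_grid = np.linspace(0.05, max(hi, 1.0), 200)
    zones = {
        "di_lower": pd.DataFrame({"spina_gr": gr_grid, "spina_gbeta": di.lower / gr_grid}),
        "di_upper": pd.DataFrame({"spina_gr": gr_grid, "spina_gbeta": di.upper / gr_grid}),
    }
    return points, zones


def render_table_text(name: str, frame: pd.DataFrame) -> str:
    """Plain-text rendering of a comparison table (variable, groups, p)."""
    labels = [c for c in frame.columns
              if c not in ("variable", "test", "statistic", "p", "p_formatted")
              and not c.startswith("n_")]
    widths = {c: max(len(c), int(frame[c].astype(str).str.len().max() or 0))
              for c in ["variable", *labels, "p_formatted"]}
    header = "  ".join(c.ljust(widths[c]) for c in ["variable", *labels, "p_formatted"])
    lines = [name, "=" * len(header), header, "-" * len(header)]
    for _, row in frame.iterrows():
        lines.append("  ".join(str(row[c]).ljust(widths[c])
                               for c in ["variable", *labels, "p_formatted"]))
    return "\n".join(lines) + "\n"


def run_pipeline(cohort: Cohort, out_dir,
                 constants: SpinaConstants = DEFAULT_SPINA_CONSTANTS,
                 seed: int | None = None,
                 render_figures: bool = False) -> ReportBundle:
    """Run the full analysis on a cohort and write the report bundle.

    Outputs under ``out_dir``: ``cohort_augmented.csv``, the five
    ``table*.csv``/``.txt`` files, ``figure_indices.csv``,
    ``figure_disposition_points.csv`` + zone files, and ``run_log.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    df = augment_cohort(cohort, constants)
    df.to_csv(out / "cohort_augmented.csv", index=False)

    tables, notes = build_tables(df)
    for name, comps in tables.items():
        frame = comparisons_to_frame(comps)
        frame.to_csv(out / f"{name}.csv", index=False)
        (out / f"{name}.txt").write_text(render_table_text(name, frame), encoding="utf-8")
    for name, why in notes.items():
        (out / f"{name}.txt").write_text(f"{name}: not produced — {why}\n", encoding="utf-8")

    fig_cols = ["subject_id", "group", "diabetes", "hp_stratum", "treated", *INDEX_NAMES]
    df[fig_cols].to_csv(out / "figure_indices.csv", index=False)

    points, zones = disposition_plane(df)
    points.to_csv(out / "figure_disposition_points.csv", index=False)
    for name, zone in zones.items():
        zone.to_csv(out / f"figure_disposition_zone_{name}.csv", index=False)
    if render_figures:
        _render_figures(df, points, zones, out)

    log = {
        "version": __version__,
        "seed": seed,
        "provenance": cohort.provenance,
        "n_subjects": len(cohort),
        "n_rejected_rows": len(cohort.rejected_rows),
        "tables_produced": sorted(tables),
        "tables_skipped": notes,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2), encoding="utf-8")

    return ReportBundle(augmented=df, tables=tables, notes=notes,
                        disposition=points, zones=zones)


def _render_figures(df: pd.DataFrame, points: pd.DataFrame,
                    zones: dict[str, pd.DataFrame], out: Path) -> None:
    """Optional matplotlib renderings; the numeric CSVs are the primary output."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, index in zip(axes, ("spina_gr", "spina_gbeta", "spina_di")):
        data = [df.loc[df["group"] == g, index].dropna() for g in ("HS", "control")]
        ax.boxplot(data, tick_labels=["HS", "control"])
        rng = DEFAULT_REFERENCE_RANGES[index]
        ax.axhspan(rng.lower, rng.upper, alpha=0.15)
        ax.set_title(index)
    fig.tight_layout()
    fig.savefig(out / "figure_biomarkers.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    for g, marker in (("HS", "o"), ("control", "s")):
        sub = points[points["group"] == g]
        ax.scatter(sub["spina_gr"], sub["spina_gbeta"], s=12, marker=marker, label=g)
    for zone in zones.values():
        ax.plot(zone["spina_gr"], zone["spina_gbeta"], lw=0.8, color="grey")
    ax.set_xlabel("SPINA-GR (mol/s)")
    ax.set_ylabel("SPINA-GBeta (pmol/s)")
    ax.set_ylim(0, max(1.0, points["spina_gbeta"].quantile(0.99) * 1.2) if len(points) else 1.0)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "figure_disposition.png", dpi=120)
    plt.close(fig)
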