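"""CSV readers/writers and the study report.

CSV is the single tabular interchange format and JSON the structured-result
format.  All readers validate row-by-row and report offending line numbers;
out-of-order times are auto-sorted with a logged warning, structural
problems (missing columns, negative concentrations, duplicate sample times)
abort with an error.  Report output is deterministic: keys are sorted and
numbers are written at fixed reporting precision, so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .binding import BindingMeasurement
from .errors import ValidationError
from .invitro import DepletionAssay
from .nca import REPORT_DECIMALS, ConcentrationTimeProfile, NCAResult, round_half_up
from .paired_stats import PairedPanel, median_range

log = logging.getLogger("koalapk")

__all__ = [
    "read_profiles",
    "write_profiles",
    "read_binding",
    "read_depletion",
    "read_paired",
    "StudyReport",
    "write_report",
]

PROFILE_COLUMNS = ("subject_id", "route", "dose_mg_per_kg", "time_h", "conc_ug_per_ml")


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, columns: Sequence[str], path) -> pd.DataFrame:
    for col in columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValidationError(
                f"{path}: non-numeric value in column {col!r}, line {bad[0] + 2}"
            )
        if parsed.isna().any():
            raise ValidationError(
                f"{path}: empty value in column {col!r}, "
                f"line {df.index[parsed.isna()][0] + 2}"
            )
        df[col] = parsed
    return df


def read_profiles(path, lloq: float = 0.625) -> list[ConcentrationTimeProfile]:
    """Read concentration-time profiles from CSV.

    Required columns: subject_id, route, dose_mg_per_kg, time_h,
    conc_ug_per_ml; optional blq (0/1, derived from ``lloq`` if absent).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, PROFILE_COLUMNS, path)
    df = _numeric(df, ["dose_mg_per_kg", "time_h", "conc_ug_per_ml"], path)
    neg = df.index[df["conc_ug_per_ml"] < 0]
    if len(neg):
        raise ValidationError(
            f"{path}: negative concentration at line {neg[0] + 2}"
        )
    profiles = []
    for subject, grp in df.groupby("subject_id", sort=False):
        if grp["time_h"].duplicated().any():
            t_dup = grp.loc[grp["time_h"].duplicated(), "time_h"].iloc[0]
            raise ValidationError(
                f"{path}: duplicate sample time t={t_dup} for subject {subject}"
            )
        if not grp["time_h"].is_monotonic_increasing:
            log.warning("%s: times out of order for %s; sorting", path, subject)
            grp = grp.sort_values("time_h")
        blq = (
            grp["blq"].astype(int).astype(bool).to_numpy()
            if "blq" in grp.columns
            else None
        )
        profiles.append(
            ConcentrationTimeProfile(
                subject_id=str(subject),
                route=str(grp["route"].iloc[0]),
                dose=float(grp["dose_mg_per_kg"].iloc[0]),
                times=grp["time_h"].to_numpy(),
                concentrations=grp["conc_ug_per_ml"].to_numpy(),
                blq=blq,
                lloq=lloq,
            )
        )
    if not profiles:
        raise ValidationError(f"{path}: no profiles found")
    return profiles


def write_profiles(profiles: Iterable[ConcentrationTimeProfile], path) -> None:
    """Write profiles in the same CSV dialect ``read_profiles`` accepts."""
    rows = []
    for p in profiles:
        for t, c, b in zip(p.times, p.concentrations, p.blq):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "route": p.route,
                    "dose_mg_per_kg": p.dose,
                    "time_h": t,
                    "conc_ug_per_ml": c,
                    "blq": int(b),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_binding(path) -> list[BindingMeasurement]:
    """Columns: nominal_conc_ug_per_ml, matrix, drug_total_ug_per_ml,
    drug_free_ug_per_ml."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = (
        "nominal_conc_ug_per_ml", "matrix",
        "drug_total_ug_per_ml", "drug_free_ug_per_ml",
    )
    _require_columns(df, cols, path)
    df = _numeric(df, [c for c in cols if c != "matrix"], path)
    return [
        BindingMeasurement(
            nominal_conc=row.nominal_conc_ug_per_ml,
            drug_total=row.drug_total_ug_per_ml,
            drug_free=row.drug_free_ug_per_ml,
            matrix=str(row.matrix),
        )
        for row in df.itertuples()
    ]


def read_depletion(path) -> list[DepletionAssay]:
    """Columns: species, replicate, time_min, remaining_percent (or conc),
    protein_mg_per_ml, volume_ul."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("species", "replicate", "time_min"), path)
    value_col = "remaining_percent" if "remaining_percent" in df.columns else "conc"
    _require_columns(df, (value_col, "protein_mg_per_ml", "volume_ul"), path)
    df = _numeric(df, ["replicate", "time_min", value_col, "protein_mg_per_ml", "volume_ul"], path)
    assays = []
    for (species, rep), grp in df.groupby(["species", "replicate"], sort=False):
        grp = grp.sort_values("time_min")
        kwargs = dict(
            species_label=str(species),
            replicate=int(rep),
            times=grp["time_min"].to_numpy(),
            protein_conc=float(grp["protein_mg_per_ml"].iloc[0]),
            incubation_volume=float(grp["volume_ul"].iloc[0]),
        )
        if value_col == "remaining_percent":
            assays.append(DepletionAssay(remaining=grp[value_col].to_numpy(), **kwargs))
        else:
            assays.append(
                DepletionAssay.from_concentrations(
                    concentrations=grp[value_col].to_numpy(),
                    **{k: v for k, v in kwargs.items() if k != "remaining"},
                )
            )
    return assays


def read_paired(path) -> list[PairedPanel]:
    """Columns: analyte, subject_id, value_pre, value_post (optional units)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("analyte", "subject_id", "value_pre", "value_post"), path)
    df = _numeric(df, ["value_pre", "value_post"], path)
    panels = []
    for analyte, grp in df.groupby("analyte", sort=False):
        panels.append(
            PairedPanel(
                analyte=str(analyte),
                units=str(grp["units"].iloc[0]) if "units" in grp.columns else "",
                subjects=tuple(str(s) for s in grp["subject_id"]),
                pre=grp["value_pre"].to_numpy(),
                post=grp["value_post"].to_numpy(),
            )
        )
    return panels


# ---------------------------------------------------------------------------
# study report
# ---------------------------------------------------------------------------


@dataclass
class StudyReport:
    """Everything one analysis run produced, plus provenance."""

    nca_results: list[NCAResult] = field(default_factory=list)
    binding_summary: pd.DataFrame | None = None
    invitro_summary: pd.DataFrame | None = None
    paired_results: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def summary_block(self) -> dict:
        """Median (range) of each index over the NCA results, per route."""
        out: dict = {}
        fields = ["ka", "ke", "t_half", "tmax", "cmax", "auc_0_t", "auc_0_inf", "mrt"]
        for route in sorted({r.route for r in self.nca_results}):
            results = [r for r in self.nca_results if r.route == route]
            block = {}
            for f in fields:
                vals = [getattr(r, f) for r in results if np.isfinite(getattr(r, f))]
                if vals:
                    med, lo, hi = median_range(vals)
                    block[f] = {"median": med, "min": lo, "max": hi, "n": len(vals)}
            out[route] = block
        return out

    def to_dict(self) -> dict:
        d = {
            "package": {"name": "koalapk", "version": __version__},
            "provenance": self.provenance,
            "nca": [r.to_dict() for r in self.nca_results],
            "summary": self.summary_block(),
            "paired_tests": self.paired_results,
        }
        if self.binding_summary is not None:
            d["binding"] = self.binding_summary.to_dict(orient="records")
        if self.invitro_summary is not None:
            d["invitro"] = self.invitro_summary.to_dict(orient="records")
        return d


def _round_tree(obj, decimals: int = 6):
    """Recursively round floats so serialized output is byte-stable."""
    if isinstance(obj, float):
        if not np.isfinite(obj):
            return None
        return round(obj, decimals)
    if isinstance(obj, dict):
        return {k: _round_tree(v, decimals) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_tree(v, decimals) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_tree(float(obj), decimals)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: StudyReport, out_prefix, formats=("json", "csv", "text")) -> list[Path]:
    """Write the report as JSON, a CSV bundle and/or a text summary.

    Returns the paths written.  Output is deterministic for identical
    inputs (sorted keys, fixed decimals, no timestamps).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    payload = _round_tree(report.to_dict())
    if "json" in formats:
        path = out_prefix.with_suffix(".json")
        path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
        written.append(path)
    if "csv" in formats and report.nca_results:
        path = out_prefix.with_suffix(".nca.csv")
        pd.DataFrame([r.to_dict(rounded=True) for r in report.nca_results]).to_csv(
            path, index=False
        )
        written.append(path)
    if "text" in formats:
        path = out_prefix.with_suffix(".txt")
        path.write_text(_text_report(report))
        written.append(path)
    return written


def _text_report(report: StudyReport) -> str:
    lines = [f"koalapk {__version__} study report", ""]
    if report.provenance:
        for k in sorted(report.provenance):
            lines.append(f"  {k}: {report.provenance[k]}")
        lines.append("")
    if report.nca_results:
        lines.append("Per-subject NCA (rounded at reporting precision):")
        df = pd.DataFrame([r.to_dict(rounded=True) for r in report.nca_results])
        lines.append(df.to_string(index=False))
        lines.append("")
        lines.append("Median (range) summaries:")
        for route, block in report.summary_block().items():
            lines.append(f"  route={route}")
            for f, s in block.items():
                nd = REPORT_DECIMALS.get(f, 3)
                lines.append(
                    f"    {f}: {round_half_up(s['median'], nd)} "
                    f"({round_half_up(s['min'], nd)} to {round_half_up(s['max'], nd)}), "
                    f"n={s['n']}"
                )
        lines.append("")
    if report.binding_summary is not None:
        lines += ["Plasma protein binding:", report.binding_summary.to_string(index=False), ""]
    if report.invitro_summary is not None:
        lines += ["In-vitro depletion:", report.invitro_summary.to_string(index=False), ""]
    if report.paired_results:
        lines.append("Paired signed-rank tests:")
        for r in report.paired_results:
            lines.append(
                f"  {r['analyte']}: W+={r['w_plus']}, n={r['n_effective']}, "
                f"p={r['p_two_sided']:.4f} ({r['direction']})"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
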