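"""Run reports and MM-GBSA component-table bookkeeping.

The MM-GBSA part aggregates end-point binding free-energy components into
the theoretical total ``ΔG_bind(T) = ΔE_vdW + ΔE_elec + ΔG_polar +
ΔG_nonpolar − TΔS`` (all kcal/mol; TΔS stored as printed and subtracted).
Model reports serialize a fitted model, its validation battery and its
applicability-domain summary into a versioned JSON plus a human-readable
statistics line.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import pandas as pd

from .exceptions import SchemaError

__all__ = [
    "EnergyComponents",
    "total_binding_energy",
    "mmgbsa_totals",
    "model_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1

MMGBSA_COLUMNS = ("label", "dE_vdw", "dE_elec", "dG_polar", "dG_nonpolar", "TdS")


@dataclass(frozen=True)
class EnergyComponents:
    """One compound's MM-GBSA decomposition (kcal/mol)."""

    label: str
    dE_vdw: float
    dE_elec: float
    dG_polar: float
    dG_nonpolar: float
    TdS: float

    def __post_init__(self):
        for name in ("dE_vdw", "dE_elec", "dG_polar", "dG_nonpolar", "TdS"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise SchemaError(f"{self.label}: non-finite component {name}={v}")


def total_binding_energy(components: EnergyComponents) -> float:
    """Theoretical binding free energy, full precision.

    ``ΔG_bind(T) = ΔE_vdW + ΔE_elec + ΔG_polar + ΔG_nonpolar − TΔS``.
    Report tables round to 2 decimals for display; this function does not.
    """
    c = components
    return c.dE_vdw + c.dE_elec + c.dG_polar + c.dG_nonpolar - c.TdS


def mmgbsa_totals(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``dG_bind`` column (rounded to 2 decimals) to a component table.

    The table must carry exactly the columns
    ``label, dE_vdw, dE_elec, dG_polar, dG_nonpolar, TdS``.
    """
    missing = [c for c in MMGBSA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"MM-GBSA table missing column(s): {missing}")
    out = df.copy()
    totals = [
        total_binding_energy(
            EnergyComponents(
                label=str(row["label"]),
                dE_vdw=float(row["dE_vdw"]),
                dE_elec=float(row["dE_elec"]),
                dG_polar=float(row["dG_polar"]),
                dG_nonpolar=float(row["dG_nonpolar"]),
                TdS=float(row["TdS"]),
            )
        )
        for _, row in df.iterrows()
    ]
    out["dG_bind"] = [round(t, 2) for t in totals]
    return out


def model_report(model, validation, ad_table=None, config=None) -> dict:
    """Assemble a single run's artifacts into one deterministic report dict.

    ``model`` is an MLRModel, ``validation`` a ValidationReport, ``ad_table``
    the Williams-plot DataFrame. Serialization is stable (sorted keys), so
    regenerating from identical inputs is byte-identical.
    """
    if model.schema_version != REPORT_SCHEMA_VERSION:
        raise SchemaError(
            f"model schema v{model.schema_version} != report schema v{REPORT_SCHEMA_VERSION}"
        )
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "model": model.to_dict(),
        "validation": validation.to_dict(),
        "config": config or {},
    }
    if ad_table is not None:
        report["applicability_domain"] = {
            "h_star": ad_table.attrs.get("h_star"),
            "residual_cutoff": ad_table.attrs.get("residual_cutoff"),
            "n_structural_outliers": int(ad_table["structural_outlier"].sum()),
            "n_response_outliers": int(ad_table["response_outlier"].sum()),
            "records": ad_table.drop(columns=[]).to_dict(orient="records"),
        }
    return report


def write_report(report: dict, json_path, summary_path=None, n_train=None, n_test=None) -> None:
    """Write the report JSON (stable ordering) and an optional text summary."""
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if summary_path is not None:
        v = report["validation"]
        lines = ["qsarwb model report", "===================", ""]
        lines.append("Descriptors: " + ", ".join(report["model"]["descriptor_names"]))
        lines.append("")
        for key in sorted(v):
            if key in ("vif", "y_randomization") or v[key] is None:
                continue
            lines.append(f"{key} = {v[key]:.4f}" if isinstance(v[key], float) else f"{key} = {v[key]}")
        if v.get("vif"):
            lines.append("")
            lines.append("VIF per descriptor:")
            for name in sorted(v["vif"]):
                lines.append(f"  {name}: {v['vif'][name]:.3f}")
        if v.get("y_randomization"):
            yr = v["y_randomization"]
            lines.append("")
            lines.append(
                f"Y-randomization ({yr['n_runs']} runs): mean R²_r = "
                f"{yr['mean_r2_randomized']:.4f}, cR_p² = {yr['crp2']:.4f}"
            )
        with open(summary_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def load_report(json_path) -> dict:
    with open(json_path) as fh:
        return json.load(fh)
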