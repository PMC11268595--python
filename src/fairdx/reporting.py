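"""Serialization of audit and fairness reports, with optional boxplots.

Reports are written as nested JSON plus a tidy CSV (comma-separated,
UTF-8, header row, NA literal ``"NA"``); undefined metric values are
explicit NA rows with a reason code, never silently dropped. Every
output file embeds the hash of the run manifest that produced it, so
results can be traced to an exact configuration and master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .audit import AuditReport
from .harness import FairnessReport

__all__ = ["RunManifest", "write_report", "read_fairness_report"]

NA_LITERAL = "NA"


def _package_version() -> str:
    try:
        return version("fairdx")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunManifest:
    """Reproducibility envelope of one pipeline run."""

    seed: int
    parameters: dict = field(default_factory=dict)
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())
    package_version: str = field(default_factory=_package_version)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(
            {"seed": self.seed, "parameters": self.parameters},
            sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "parameters": self.parameters,
            "created": self.created,
            "package_version": self.package_version,
        }


def _validate_fairness(report: FairnessReport) -> None:
    required = {"classifier", "mitigation", "attribute", "repeat", "metric",
                "group", "value", "reason"}
    if report.values.empty:
        raise ValueError("empty fairness report; nothing to write")
    missing = required - set(report.values.columns)
    if missing:
        raise ValueError(f"fairness report missing columns: {sorted(missing)}")


def _validate_audit(report: AuditReport) -> None:
    if report.composition.empty:
        raise ValueError("empty audit report; nothing to write")
    required = {"attribute", "group", "label", "n", "n_positive",
                "selection_rate"}
    missing = required - set(report.composition.columns)
    if missing:
        raise ValueError(f"audit report missing columns: {sorted(missing)}")


def write_report(
    report: FairnessReport | AuditReport,
    out_dir: str | Path,
    stem: str | None = None,
    manifest: RunManifest | None = None,
    plot: bool = False,
) -> list[Path]:
    """Write a report as JSON + tidy CSV (and optionally boxplot PNGs).

    Validates the report against its schema *before* any file is
    created, so a schema violation never leaves partial output. Returns
    the list of written paths.
    """
    out_dir = Path(out_dir)
    manifest = manifest or RunManifest(seed=0)
    if isinstance(report, FairnessReport):
        _validate_fairness(report)
        stem = stem or "fairness"
    elif isinstance(report, AuditReport):
        _validate_audit(report)
        stem = stem or "audit"
    else:
        raise TypeError(f"unsupported report type {type(report)!r}")
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if isinstance(report, FairnessReport):
        payload = {
            "manifest": manifest.to_dict(),
            "delta": report.delta,
            "values": report.values.to_dict(orient="records"),
            "summary": report.summary.to_dict(orient="records"),
        }
        jpath = out_dir / f"{stem}.json"
        jpath.write_text(json.dumps(payload, indent=2, default=_json_default))
        written.append(jpath)
        cpath = out_dir / f"{stem}.csv"
        tidy = report.values.copy()
        tidy.insert(0, "config_hash", manifest.config_hash)
        tidy.to_csv(cpath, index=False, na_rep=NA_LITERAL)
        written.append(cpath)
        if plot:
            written.extend(_boxplots(report, out_dir, stem))
    else:
        jpath = out_dir / f"{stem}.json"
        body = json.loads(report.to_json())
        body["manifest"] = manifest.to_dict()
        jpath.write_text(json.dumps(body, indent=2, default=_json_default))
        written.append(jpath)
        cpath = out_dir / f"{stem}_composition.csv"
        comp = report.composition.copy()
        comp.insert(0, "config_hash", manifest.config_hash)
        comp.to_csv(cpath, index=False, na_rep=NA_LITERAL)
        written.append(cpath)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if obj is pd.NA:
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_fairness_report(path: str | Path) -> FairnessReport:
    """Load a fairness report written by :func:`write_report` (JSON)."""
    data = json.loads(Path(path).read_text())
    return FairnessReport(
        values=pd.DataFrame(data["values"]),
        summary=pd.DataFrame(data["summary"]),
        delta=data["delta"],
    )


def _boxplots(report: FairnessReport, out_dir: Path, stem: str) -> list[Path]:
    """One boxplot per (attribute, metric): center line at the median,
    whiskers at 1.5 IQR, points beyond them drawn as outliers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: list[Path] = []
    vals = report.values[report.values["group"] == ""]
    for (attr, metric), part in vals.groupby(["attribute", "metric"]):
        fig, ax = plt.subplots(figsize=(5, 4))
        data, labels = [], []
        for (clf, mit), sub in part.groupby(["classifier", "mitigation"]):
            data.append(sub["value"].dropna().to_numpy())
            labels.append(f"{clf}\n{mit}")
        ax.boxplot(data, tick_labels=labels, whis=1.5)
        ax.set_title(f"{metric} by {attr}")
        ax.set_ylabel(metric)
        fig.tight_layout()
        path = out_dir / f"{stem}_{attr}_{metric}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
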