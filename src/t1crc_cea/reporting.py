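"""Run manifests and deterministic tabular outputs.

Every analysis run can be written out as CSV tables with a JSON manifest
recording the config digest, seed, package version, and output list, so any
table can be traced back to the exact inputs that produced it. Column order and
formatting are fixed; reruns with identical inputs produce byte-identical CSVs
(the manifest carries a timestamp and is the one non-reproducible file).

Currency and rate units are echoed in CSV headers to prevent silent unit drift.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .cea import ICERTable, OneWayResult, PSAResult, rank_and_icer
from .parameters import ClassId, ParameterSet, Strategy

__all__ = [
    "RunManifest",
    "config_digest",
    "write_base_case",
    "write_icers",
    "write_tornado",
    "write_thresholds",
    "write_psa",
]


def config_digest(params: ParameterSet) -> str:
    """SHA-256 over the canonical serialized config; changes iff the config does."""
    return hashlib.sha256(params.to_yaml().encode()).hexdigest()


@dataclass
class RunManifest:
    command: str
    config_digest: str
    seed: int | None = None
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    package_version: str = __version__
    outputs: list[str] = field(default_factory=list)

    def add(self, path: Path) -> None:
        self.outputs.append(str(path))

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
        return path


def _emit(df: pd.DataFrame, path: Path, manifest: RunManifest | None) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    if manifest is not None:
        manifest.add(path)
    return path


def write_base_case(
    df: pd.DataFrame, out_dir: Path, manifest: RunManifest | None = None
) -> Path:
    out = df.rename(
        columns={
            "life_years": "life_years_undiscounted",
            "qalys": "qalys_discounted",
            "cost": "cost_2019_usd_discounted",
        }
    )
    return _emit(out, Path(out_dir) / "base_case.csv", manifest)


def write_icers(
    tables: Sequence[ICERTable], out_dir: Path, manifest: RunManifest | None = None
) -> Path:
    rows = []
    for table in tables:
        for r in table.rows:
            rows.append(
                {
                    "class": table.class_id.value if table.class_id else "",
                    "strategy": r.strategy.value,
                    "cost_2019_usd": r.cost,
                    "qalys": r.qalys,
                    "status": r.status,
                    "icer_usd_per_qaly": "" if r.icer is None else round(r.icer),
                    "preferred_at_wtp": int(r.strategy is table.preferred),
                    "wtp_usd_per_qaly": table.wtp,
                }
            )
    return _emit(pd.DataFrame(rows), Path(out_dir) / "icers.csv", manifest)


def write_tornado(
    results: Sequence[OneWayResult],
    cls: ClassId,
    out_dir: Path,
    manifest: RunManifest | None = None,
) -> Path:
    df = pd.DataFrame(
        {
            "parameter": [r.parameter for r in results],
            "low": [r.low for r in results],
            "high": [r.high for r in results],
            "icer_at_low_usd_per_qaly": [r.icer_at_low for r in results],
            "icer_at_high_usd_per_qaly": [r.icer_at_high for r in results],
            "base_icer_usd_per_qaly": [r.base_icer for r in results],
            "spread_usd_per_qaly": [r.spread for r in results],
        }
    )
    return _emit(df, Path(out_dir) / f"tornado_{cls.value}.csv", manifest)


def write_thresholds(
    results: Sequence[OneWayResult],
    cls: ClassId,
    out_dir: Path,
    manifest: RunManifest | None = None,
) -> Path:
    rows = []
    for r in results:
        for th in r.thresholds:
            rows.append({"class": cls.value, "parameter": r.parameter,
                         "threshold_value": th})
    df = pd.DataFrame(rows, columns=["class", "parameter", "threshold_value"])
    return _emit(df, Path(out_dir) / "thresholds.csv", manifest)


def write_psa(
    psa: PSAResult, out_dir: Path, manifest: RunManifest | None = None
) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    draws = psa.draws.reset_index().rename(
        columns=lambda c: c.replace("cost_", "cost_2019_usd_")
    )
    p1 = _emit(draws, out_dir / "psa_draws.csv", manifest)
    ceac = psa.ceac.rename(columns={"wtp": "wtp_usd_per_qaly"})
    p2 = _emit(ceac, out_dir / "ceac.csv", manifest)
    return p1, p2
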