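"""Delimited-text I/O for feature tables, lipid libraries, and configs.

All tables are UTF-8, comma- or tab-delimited with a header row.  Retention
times are stored in seconds.  The canonical feature-table columns are
``sample_id, strain, polarity, mz, rt_seconds, intensity``; a ``dialect``
mapping lets callers read tables with different column names.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .masses import monoisotopic_mass
from .model import FeatureObservation, FormatError, LipidRecord, PipelineConfig

FEATURE_COLUMNS = ("sample_id", "strain", "polarity", "mz", "rt_seconds", "intensity")
LIBRARY_COLUMNS = ("name", "subclass", "formula", "monoisotopic_mass")


def _detect_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_feature_table(
    path: str | Path, dialect: dict[str, str] | None = None
) -> list[FeatureObservation]:
    """Read per-run feature observations from a delimited file.

    ``dialect`` maps canonical column names to the file's actual column
    names, e.g. ``{"rt_seconds": "RT"}``.  Row order is preserved; malformed
    rows raise a :class:`FormatError` naming the line.
    """
    path = Path(path)
    dialect = dialect or {}
    colmap = {canon: dialect.get(canon, canon) for canon in FEATURE_COLUMNS}
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    missing = [actual for actual in colmap.values() if actual not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    observations: list[FeatureObservation] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        rec = dict(zip(df.columns, row))
        try:
            observations.append(
                FeatureObservation(
                    sample_id=str(rec[colmap["sample_id"]]),
                    strain=str(rec[colmap["strain"]]),
                    polarity=str(rec[colmap["polarity"]]).strip().lower(),
                    mz=float(rec[colmap["mz"]]),
                    rt=float(rec[colmap["rt_seconds"]]),
                    intensity=float(rec[colmap["intensity"]]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: line {idx}: {exc}") from exc
    return observations


def write_feature_table(
    observations: list[FeatureObservation], path: str | Path, sep: str = ","
) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [o.sample_id for o in observations],
            "strain": [o.strain for o in observations],
            "polarity": [o.polarity for o in observations],
            "mz": [f"{o.mz:.6f}" for o in observations],
            "rt_seconds": [f"{o.rt:.3f}" for o in observations],
            "intensity": [f"{o.intensity:.4f}" for o in observations],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def read_library(path: str | Path) -> list[LipidRecord]:
    """Read a lipid library; mass is derived from the formula when absent."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in ("name", "subclass") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records: list[LipidRecord] = []
    for idx, rec in enumerate(df.to_dict("records"), start=2):
        formula = rec.get("formula", "").strip() or None
        mass_text = rec.get("monoisotopic_mass", "").strip()
        try:
            if mass_text:
                mass = float(mass_text)
            elif formula:
                mass = monoisotopic_mass(formula)
            else:
                raise ValueError("needs a formula or a monoisotopic_mass")
            records.append(LipidRecord(rec["name"], rec["subclass"], formula, mass))
        except ValueError as exc:
            raise FormatError(f"{path}: line {idx}: {exc}") from exc
    return records


def write_library(records: list[LipidRecord], path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(
        {
            "name": [r.name for r in records],
            "subclass": [r.subclass for r in records],
            "formula": [r.formula or "" for r in records],
            "monoisotopic_mass": [f"{r.monoisotopic_mass:.5f}" for r in records],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def read_config(path: str | Path) -> PipelineConfig:
    """Read a flat key-value (YAML) run configuration."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a flat key-value mapping")
    return PipelineConfig.from_dict(data)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
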