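"""Patient-table IO and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import pandas as pd

MANDATORY_COLUMNS = ("patient_id", "area_id", "year")


@dataclass
class ParseReport:
    n_rows: int = 0
    bad_rows: list = field(default_factory=list)  # (line_number, reason)

    @property
    def ok(self) -> bool:
        return not self.bad_rows


def read_patients(path, known_levels: dict | None = None, skip_bad: bool = False):
    """Read a patient CSV into a typed table.

    ``known_levels`` maps covariate column -> allowed category values; rows
    with unknown categories or an unparseable year are collected into the
    parse report with their file line numbers. Unless ``skip_bad`` the
    presence of bad rows raises, with the report attached.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    report = ParseReport(n_rows=len(df))
    year = pd.to_numeric(df["year"], errors="coerce")
    for i in df.index[year.isna()]:
        report.bad_rows.append((int(i) + 2, "unparseable year"))  # +2: header + 1-basing
    if known_levels:
        for col, levels in known_levels.items():
            if col not in df.columns:
                raise ValueError(f"{path}: missing covariate column {col!r}")
            bad = ~df[col].isin([str(l) for l in levels])
            for i in df.index[bad]:
                report.bad_rows.append(
                    (int(i) + 2, f"unknown {col} category {df.loc[i, col]!r}")
                )
    if report.bad_rows and not skip_bad:
        raise ValueError(
            f"{path}: {len(report.bad_rows)} bad row(s), first at line "
            f"{report.bad_rows[0][0]} ({report.bad_rows[0][1]}); pass skip_bad to drop them"
        )
    bad_lines = {ln - 2 for ln, _ in report.bad_rows}
    df = df.drop(index=[i for i in df.index if i in bad_lines])
    df["year"] = pd.to_numeric(df["year"]).astype(int)
    for col in df.columns:
        if col.endswith("_score") or col in (
            "urinary_incontinence", "urinary_irritative", "bowel", "sexual", "hormonal",
        ):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "poor_qol" in df.columns:
        df["poor_qol"] = pd.to_numeric(df["poor_qol"]).astype(int)
    return df.reset_index(drop=True), report


def write_table(df: pd.DataFrame, path):
    """RFC-4180 CSV writer."""
    df.to_csv(path, index=False, lineterminator="\r\n")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seeds, inputs=(), extra: dict | None = None):
    """Atomic JSON run manifest: config hash, seeds, input digests, timestamps."""
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seeds": [int(s) if not hasattr(s, "entropy") else int(s.entropy) for s in seeds],
        "inputs": {str(p): file_digest(p) for p in inputs},
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        manifest.update(extra)
    tmp = str(path) + ".tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    import os

    os.replace(tmp, path)
    return manifest
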