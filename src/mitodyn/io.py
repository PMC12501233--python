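"""CSV/JSON readers and writers for the pipeline's tabular dialects.

Every writer is deterministic (sorted keys, fixed column order, no
timestamps) so identical inputs produce byte-identical outputs, and every
simulation output carries a JSON provenance sidecar from which the run can
be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .proteomics import EnrichmentCall, LfqRecord
from .scores import QpcrPair, XenograftRecord
from .simulate import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "read_lfq_table",
    "write_lfq_table",
    "write_calls",
    "write_enriched_set",
    "read_qpcr_table",
    "write_qpcr_table",
    "read_xenograft_table",
    "write_xenograft_table",
    "load_config",
]

LFQ_COLUMNS = ["protein_id", "ss_1", "ss_2", "ss_3", "s_1", "s_2", "s_3", "peptides", "coverage"]
QPCR_COLUMNS = ["sample_id", "nu_ct_1", "nu_ct_2", "nu_ct_3", "mt_ct_1", "mt_ct_2", "mt_ct_3"]
XENO_COLUMNS = ["group", "pkh_hi", "pkh_lo", "tumor_volume"]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _read_table(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep=_sep_for(path), encoding="utf-8-sig", float_precision="round_trip"
        )
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} (expected {required})")
    return df


def _asdict_clean(obj) -> dict:
    d = dataclasses.asdict(obj)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return d


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write a trajectory CSV (time, n_hu, n_du, n_hf, n_df, atp) plus a
    ``.provenance.json`` sidecar holding scenario, constants and settings."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traj.to_dataframe().to_csv(path, index=False)
    sidecar = {
        "scenario": _asdict_clean(traj.scenario),
        "settings": _asdict_clean(traj.settings),
        "warnings": list(traj.warnings),
    }
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return path


def read_trajectory(path) -> pd.DataFrame:
    return _read_table(path, ["time", "n_hu", "n_du", "n_hf", "n_df", "atp"])


def read_lfq_table(path, *, zero_as_missing: bool = True) -> list[LfqRecord]:
    """Read an LFQ intensity matrix.

    Columns: ``protein_id, ss_1..ss_3, s_1..s_3, peptides, coverage``;
    comma- or tab-separated by extension.  Zeros (and empty cells) are
    missing detections under the default dialect.
    """
    df = _read_table(path, LFQ_COLUMNS)
    records = []
    bad: list[str] = []
    for i, row in df.iterrows():
        try:
            records.append(
                LfqRecord.from_intensities(
                    protein_id=str(row["protein_id"]),
                    intensities_ss=[None if pd.isna(row[c]) else float(row[c]) for c in ("ss_1", "ss_2", "ss_3")],
                    intensities_s=[None if pd.isna(row[c]) else float(row[c]) for c in ("s_1", "s_2", "s_3")],
                    peptides=int(row["peptides"]),
                    coverage=float(row["coverage"]),
                    zero_as_missing=zero_as_missing,
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append(f"row {i}: {exc}")
    if bad:
        raise SchemaError(f"{path}: invalid LFQ rows:\n  " + "\n  ".join(bad))
    return records


def write_lfq_table(records: Iterable[LfqRecord], path) -> Path:
    """Write records in the LFQ dialect; missing detections serialized as 0."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        ss = [0.0 if v is None else v for v in r.intensities_ss]
        s = [0.0 if v is None else v for v in r.intensities_s]
        rows.append([r.protein_id, *ss, *s, r.peptides, r.coverage])
    pd.DataFrame(rows, columns=LFQ_COLUMNS).to_csv(path, sep=_sep_for(path), index=False)
    return path


def write_calls(calls: Iterable[EnrichmentCall], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "qc_pass": c.qc_pass,
                "category": c.category,
                "fold_change": c.fold_change,
                "p_value": c.p_value,
                "reason": c.reason,
            }
            for c in calls
        ]
    ).to_csv(path, index=False)
    return path


def write_enriched_set(ids: Iterable[str], path) -> Path:
    """Plain-text enriched-protein list, one sorted identifier per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{pid}\n" for pid in sorted(ids)))
    return path


def read_qpcr_table(path) -> list[tuple[str, QpcrPair]]:
    """Read qPCR triplicates (``sample_id, nu_ct_1..3, mt_ct_1..3``) and
    aggregate each sample's replicates by mean."""
    df = _read_table(path, QPCR_COLUMNS)
    out = []
    for _, row in df.iterrows():
        pair = QpcrPair.from_triplicates(
            [float(row[c]) for c in ("nu_ct_1", "nu_ct_2", "nu_ct_3")],
            [float(row[c]) for c in ("mt_ct_1", "mt_ct_2", "mt_ct_3")],
        )
        out.append((str(row["sample_id"]), pair))
    return out


def write_qpcr_table(rows: Iterable[tuple[str, Iterable[float], Iterable[float]]], path) -> Path:
    """Write (sample_id, nuclear triplicate, mito triplicate) rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = [[sid, *nu, *mt] for sid, nu, mt in rows]
    pd.DataFrame(data, columns=QPCR_COLUMNS).to_csv(path, index=False)
    return path


def read_xenograft_table(path) -> list[XenograftRecord]:
    df = _read_table(path, XENO_COLUMNS)
    bad: list[str] = []
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                XenograftRecord(
                    group=str(row["group"]),
                    pkh_hi=float(row["pkh_hi"]),
                    pkh_lo=float(row["pkh_lo"]),
                    tumor_volume=float(row["tumor_volume"]),
                )
            )
        except ValueError as exc:
            bad.append(f"row {i}: {exc}")
    if bad:
        raise SchemaError(f"{path}: invalid xenograft rows:\n  " + "\n  ".join(bad))
    return records


def write_xenograft_table(records: Iterable[XenograftRecord], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"group": r.group, "pkh_hi": r.pkh_hi, "pkh_lo": r.pkh_lo, "tumor_volume": r.tumor_volume}
            for r in records
        ]
    ).to_csv(path, index=False)
    return path


def load_config(path) -> dict:
    """Load a JSON or YAML configuration mapping (by file extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return cfg
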