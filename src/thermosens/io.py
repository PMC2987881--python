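"""Readers and writers for the package's plain-text interchange formats.

Constructs travel as JSON ({"id", "length", "sites": [{"role", "factor",
"position"}, ...]}, positions 1-based site centers); concentration/expression
tables and spatial profiles travel as single-header TSV.  Floats are written
at 12 significant digits so reruns can be compared byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .objectives import DataRecord, ExpressionDataset
from .thermo_models import BindingSite, Construct, DistanceBinning

__all__ = [
    "FLOAT_FORMAT",
    "write_constructs_json",
    "read_constructs_json",
    "write_dataset_tsv",
    "read_dataset_tsv",
    "write_profiles_tsv",
    "read_profiles_tsv",
]

FLOAT_FORMAT = "%.12g"


def write_constructs_json(constructs: Sequence[Construct], path: Union[str, Path]) -> None:
    payload = [
        {
            "id": c.id,
            "length": c.length,
            "sites": [
                {"role": s.role, "factor": s.factor, "position": s.position} for s in c.sites
            ],
        }
        for c in constructs
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def read_constructs_json(path: Union[str, Path]) -> list[Construct]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        Construct(
            c["id"],
            [BindingSite(s["role"], s["factor"], int(s["position"])) for s in c["sites"]],
            int(c["length"]),
        )
        for c in payload
    ]


def write_dataset_tsv(dataset: ExpressionDataset, path: Union[str, Path]) -> None:
    factors = sorted({f for r in dataset.records for f in r.concentrations})
    rows = []
    for r in dataset.records:
        row = {"construct_id": getattr(r.element, "id", ""), "condition_id": r.key}
        for f in factors:
            row[f] = r.concentrations.get(f, "")
        row["observed_expression"] = r.observed
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_dataset_tsv(
    path: Union[str, Path],
    constructs: Sequence[Construct],
    binning: DistanceBinning,
) -> ExpressionDataset:
    frame = pd.read_csv(path, sep="\t")
    by_id = {c.id: c for c in constructs}
    meta = {"construct_id", "condition_id", "observed_expression"}
    factors = [c for c in frame.columns if c not in meta]
    records = []
    for _, row in frame.iterrows():
        cid = row["construct_id"]
        if cid not in by_id:
            raise KeyError(f"dataset references unknown construct {cid!r}")
        records.append(
            DataRecord(
                element=by_id[cid],
                key=str(row["condition_id"]),
                concentrations={f: float(row[f]) for f in factors},
                observed=float(row["observed_expression"]),
            )
        )
    return ExpressionDataset(records=records, model_family="fakhouri", binning=binning)


def write_profiles_tsv(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_profiles_tsv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
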