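"""Readers and writers for cell-level and clinical delimited text tables.

Cell table dialect: TSV/CSV with a header naming ``cell_id``, ``sample_id``
and one column per panel chromosome (``X, 4, 6, 10, 14, 17, 18, 21``).
An empty field or a configurable sentinel ("NA") marks a missing FISH
signal in that channel.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .core import DEFAULT_PANEL, CellProfile, ChromosomePanel, SampleRecord

__all__ = ["read_cell_table", "write_cell_table", "read_clinical_table"]

_DEFAULT_SENTINELS = ("", "NA", "na", "NaN", "nan")


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_cell_table(
    path: Union[str, Path],
    panel: ChromosomePanel = DEFAULT_PANEL,
    sentinels: Sequence[str] = _DEFAULT_SENTINELS,
) -> Tuple[List[CellProfile], dict]:
    """Read one cell table; returns (profiles in input order, summary counts).

    Raises ``ValueError`` for chromosome columns not in the panel and for
    negative copy counts (naming the offending row).
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    sentinels = set(sentinels)

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty table")
        cols = [c.strip() for c in reader.fieldnames]
        meta = {"cell_id", "sample_id"}
        chrom_cols = [c for c in cols if c not in meta]
        unknown = [c for c in chrom_cols if c not in panel.labels]
        if unknown:
            raise ValueError(
                f"{path}: unknown chromosome column(s) {unknown}; "
                f"panel is {list(panel.labels)}"
            )
        missing = [c for c in panel.labels if c not in chrom_cols]
        if missing:
            raise ValueError(f"{path}: panel chromosome column(s) {missing} absent")

        profiles: List[CellProfile] = []
        for i, row in enumerate(reader, start=2):
            counts: List[Optional[int]] = []
            for label in panel.labels:
                raw = (row.get(label) or "").strip()
                if raw in sentinels:
                    counts.append(None)
                    continue
                value = int(float(raw))
                if value < 0:
                    raise ValueError(
                        f"{path} row {i} (cell {row.get('cell_id')}): "
                        f"negative count {value} for chr{label}"
                    )
                counts.append(value)
            profiles.append(
                CellProfile(
                    cell_id=str(row.get("cell_id", f"cell{i}")),
                    sample_id=str(row.get("sample_id", "")),
                    counts=tuple(counts),
                    panel=panel,
                )
            )

    n_info = sum(p.informative for p in profiles)
    summary = {
        "n_cells": len(profiles),
        "n_informative": n_info,
        "n_non_informative": len(profiles) - n_info,
    }
    return profiles, summary


def write_cell_table(
    cells: Iterable[CellProfile],
    path: Union[str, Path],
    panel: ChromosomePanel = DEFAULT_PANEL,
    delimiter: str = "\t",
    sentinel: str = "NA",
) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["cell_id", "sample_id", *panel.labels])
        for cell in cells:
            writer.writerow(
                [cell.cell_id, cell.sample_id]
                + [sentinel if c is None else c for c in cell.counts]
            )


_BOOL = {"1": True, "0": False, "true": True, "false": False,
         "yes": True, "no": False, "": None}


def read_clinical_table(path: Union[str, Path]) -> List[SampleRecord]:
    """Read per-sample clinical records.

    Expected columns: ``patient_id, timepoint, outcome, relapse, death,
    time_years, age, sex, wbc, mrd, protocol, karyotype`` (trailing optional
    columns may be absent).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        def get(col: str) -> Optional[str]:
            v = str(row[col]).strip() if col in df.columns else ""
            return v or None

        def get_float(col: str) -> Optional[float]:
            v = get(col)
            return float(v) if v is not None else None

        def get_bool(col: str) -> Optional[bool]:
            v = get(col)
            return _BOOL[v.lower()] if v is not None else None

        records.append(
            SampleRecord(
                patient_id=str(row["patient_id"]),
                timepoint=get("timepoint") or "DX",
                outcome=get("outcome"),
                relapse=get_bool("relapse"),
                death=get_bool("death"),
                time_years=get_float("time_years"),
                age=get_float("age"),
                sex=get("sex"),
                wbc=get_float("wbc"),
                mrd=get("mrd"),
                protocol=get("protocol"),
                karyotype=get("karyotype"),
            )
        )
    return records
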