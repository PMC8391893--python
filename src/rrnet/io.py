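"""File formats: RR-block interchange, ECG CSV loading, fold manifests.

RR cohorts use a diff-friendly line format, one block per line::

    patient_id <TAB> label <TAB> rr1,rr2,... (seconds)

The ECG reader accepts the per-record CSV dialect of the public 12-lead
10 s 500 Hz collection: one CSV file per record with 5000 rows x 12 lead
columns, plus a label table mapping file name to rhythm label. Label
strings vary between releases, so the mapping from raw label to
NSR/AFIB/AFL is configurable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .qrs import ECGRecord
from .synthetic import CLASSES, RRBlock

__all__ = ["save_blocks", "load_blocks", "blocks_to_dataframe",
           "blocks_from_dataframe", "load_chapman", "folds_to_dataframe"]

log = logging.getLogger("rrnet")

DEFAULT_LABEL_MAP = {"SR": "NSR", "NSR": "NSR", "AFIB": "AFIB", "AF": "AFIB",
                     "AFL": "AFL"}


def save_blocks(blocks: list[RRBlock], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for b in blocks:
            rr = ",".join(format(v, ".17g") for v in b.rr)
            fh.write(f"{b.patient_id}\t{b.label}\t{b.duration:.17g}\t{rr}\n")


def load_blocks(path: str | Path) -> list[RRBlock]:
    blocks = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            pid, label, duration, rr = line.split("\t")
            blocks.append(RRBlock(
                patient_id=pid, label=label,
                rr=np.array([float(v) for v in rr.split(",")]),
                duration=float(duration)))
    return blocks


def blocks_to_dataframe(blocks: list[RRBlock]) -> pd.DataFrame:
    """Long-format table: one row per RR interval."""
    return pd.DataFrame({
        "patient_id": np.repeat([b.patient_id for b in blocks],
                                [b.rr.size for b in blocks]),
        "label": np.repeat([b.label for b in blocks],
                           [b.rr.size for b in blocks]),
        "beat": np.concatenate([np.arange(b.rr.size) for b in blocks]),
        "rr_s": np.concatenate([b.rr for b in blocks]),
        "duration_s": np.repeat([b.duration for b in blocks],
                                [b.rr.size for b in blocks]),
    })


def blocks_from_dataframe(df: pd.DataFrame) -> list[RRBlock]:
    blocks = []
    for (pid, label, dur), grp in df.groupby(
            ["patient_id", "label", "duration_s"], sort=False):
        blocks.append(RRBlock(patient_id=str(pid), label=str(label),
                              rr=grp.sort_values("beat")["rr_s"].to_numpy(),
                              duration=float(dur)))
    return blocks


def load_chapman(directory: str | Path, label_table: str | Path | None = None,
                 label_map: dict[str, str] | None = None,
                 fs: float = 500.0, expected_samples: int = 5000,
                 expected_leads: int = 12) -> list[ECGRecord]:
    """Load per-record ECG CSV files filtered to NSR/AFIB/AFL.

    ``label_table`` is a CSV with columns ``FileName`` and ``Rhythm`` (case
    insensitive); ``label_map`` maps raw rhythm strings to canonical class
    names, defaulting to ``DEFAULT_LABEL_MAP``. Records whose CSV does not
    parse to the expected shape are skipped with a warning.
    """
    directory = Path(directory)
    label_map = {k.upper(): v for k, v in (label_map or DEFAULT_LABEL_MAP).items()}
    labels: dict[str, str] = {}
    if label_table is not None:
        tbl = pd.read_csv(label_table)
        cols = {c.lower(): c for c in tbl.columns}
        fcol, rcol = cols.get("filename"), cols.get("rhythm")
        if fcol is None or rcol is None:
            raise ValueError("label table needs FileName and Rhythm columns")
        for _, row in tbl.iterrows():
            labels[str(row[fcol])] = str(row[rcol]).upper()

    records: list[ECGRecord] = []
    for f in sorted(directory.glob("*.csv")):
        raw = labels.get(f.stem, f.stem.split("_")[0].upper())
        cls = label_map.get(raw)
        if cls not in CLASSES:
            continue
        try:
            arr = pd.read_csv(f, header=None).to_numpy(dtype=float)
        except ValueError:
            log.warning("skipping %s: unparseable", f.name)
            continue
        # tolerate a header row of lead names
        if arr.shape[0] == expected_samples + 1:
            arr = arr[1:]
        if arr.shape != (expected_samples, expected_leads):
            log.warning("skipping %s: shape %s != (%d, %d)", f.name,
                        arr.shape, expected_samples, expected_leads)
            continue
        records.append(ECGRecord(patient_id=f.stem, fs=fs, samples=arr.T,
                                 label=cls))
    return records


def folds_to_dataframe(folds) -> pd.DataFrame:
    """Flatten fold specs to one row per vector (fold, split, class, values)."""
    frames = []
    for fold in folds:
        for split, X, y in (("train", fold.train_X, fold.train_y),
                            ("test", fold.test_X, fold.test_y)):
            df = pd.DataFrame(X, columns=[f"v{i:03d}" for i in range(X.shape[1])])
            df.insert(0, "fold", fold.fold_index)
            df.insert(1, "split", split)
            df.insert(2, "label", y)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
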