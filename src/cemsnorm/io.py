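"""Reading and writing peak lists and the reference-dataset archive.

Peak lists are delimited text with header columns ``mz``, ``mt_seconds``,
``intensity`` (``mt`` accepted as a synonym). The reference dataset is a
single zip archive holding JSON metadata and the delimited intensity
matrix; intensities round-trip bit-exactly via 17-significant-digit text.
"""

from __future__ import annotations

import json
import zipfile
from io import StringIO
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .datatypes import FeatureMatrix, PeakList, ReferenceDataset

SCHEMA_VERSION = 1

_FLOAT_FMT = "%.17g"


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_peak_list(path: Union[str, Path],
                   sample_id: Optional[str] = None) -> PeakList:
    """Read one run's peak list from TSV/CSV.

    The sample id defaults to the file stem; a ``sample_id`` column, if
    present, overrides it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = {c.lower(): c for c in df.columns}
    if "mt_seconds" in cols:
        df = df.rename(columns={cols["mt_seconds"]: "mt"})
    elif "mt" in cols:
        df = df.rename(columns={cols["mt"]: "mt"})
    else:
        raise ValueError(f"{path}: no mt_seconds/mt column")
    if sample_id is None:
        if "sample_id" in cols:
            ids = df[cols["sample_id"]].unique()
            if len(ids) != 1:
                raise ValueError(f"{path}: multiple sample ids in one file")
            sample_id = str(ids[0])
        else:
            sample_id = path.stem
    keep = df.loc[:, ["mz", "mt", "intensity"]]
    return PeakList(sample_id, keep)


def write_peak_list(pl: PeakList, path: Union[str, Path]) -> None:
    path = Path(path)
    out = pl.table.rename(columns={"mt": "mt_seconds"})
    out.to_csv(path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT)


def read_peak_list_dir(directory: Union[str, Path]) -> list[PeakList]:
    """Read every .tsv/.csv peak list in a directory, sorted by name."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in (".tsv", ".csv"))
    if not paths:
        raise FileNotFoundError(f"no .tsv/.csv peak lists in {directory}")
    return [read_peak_list(p) for p in paths]


def save_reference(ref: ReferenceDataset, path: Union[str, Path]) -> None:
    """Write a ReferenceDataset to a zip archive (JSON metadata + TSV matrix)."""
    meta = {
        "schema_version": SCHEMA_VERSION,
        "mt_window": list(ref.mt_window),
        "stable": list(ref.stable),
        "provenance": ref.provenance,
        "groups": (ref.matrix.groups.to_dict()
                   if ref.matrix.groups is not None else None),
    }
    buf = StringIO()
    ref.matrix.values.to_csv(buf, sep="\t", float_format=_FLOAT_FMT)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        zf.writestr("matrix.tsv", buf.getvalue())


def load_reference(path: Union[str, Path]) -> ReferenceDataset:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported reference schema {meta.get('schema_version')}")
        mat = pd.read_csv(StringIO(zf.read("matrix.tsv").decode()),
                          sep="\t", index_col=0)
    groups = pd.Series(meta["groups"]) if meta.get("groups") else None
    fm = FeatureMatrix(mat, groups=groups)
    return ReferenceDataset(
        matrix=fm,
        stable=list(meta["stable"]),
        mt_window=tuple(meta["mt_window"]),
        provenance=meta.get("provenance", {}),
    )


def read_labels(path: Union[str, Path]) -> pd.Series:
    """Two-column TSV sample_id -> label (header optional)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    if df.iloc[0, 0].lower() in ("sample_id", "sample"):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values,
                     name="label")
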