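"""TSV reading/writing helpers.

Every emitted table is plain TSV with optional ``#`` comment lines carrying
provenance (package version, seed, parameters).  Floats are written with a
fixed format so identical runs produce byte-identical files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

FLOAT_FORMAT = "%.6g"


def write_tsv(
    frame: pd.DataFrame,
    path: str | Path,
    meta: Optional[Mapping[str, object]] = None,
    index: bool = False,
    index_label: Optional[str] = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    if meta:
        for key, value in meta.items():
            buf.write(f"# {key}: {value}\n")
    frame.to_csv(
        buf,
        sep="\t",
        index=index,
        index_label=index_label,
        float_format=FLOAT_FORMAT,
        lineterminator="\n",
    )
    path.write_text(buf.getvalue())


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read an ASV x sample count table (first column = ASV id)."""
    counts = read_tsv(path, index_col=0)
    return counts


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata in the QIIME2 sample-metadata TSV dialect.

    The first column is ``sample-id``; an optional ``#q2:types`` row is
    treated as a comment.  Returns a frame indexed by sample id.
    """
    meta = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    first = meta.columns[0]
    meta = meta[~meta[first].astype(str).str.startswith("#q2:")]
    return meta.set_index(first)
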