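"""Plain-text outputs with reproducibility metadata headers.

Every CSV the package writes starts with ``#``-prefixed key=value lines
(package version, seed, solver tolerances, parameter hash) so outputs are
diffable and self-describing; readers round-trip the table and the
metadata.  Existing files are never overwritten unless asked.
"""

from __future__ import annotations

import os
from typing import Dict, Tuple

import pandas as pd

from . import __version__

#: deterministic float formatting so identical runs give identical bytes
FLOAT_FORMAT = "%.12g"


def _header_lines(meta: Dict) -> str:
    lines = [f"# phic31rec={__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def write_csv_with_meta(df: pd.DataFrame, path, meta: Dict = None,
                        force: bool = False) -> None:
    if os.path.exists(path) and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    with open(path, "w") as fh:
        fh.write(_header_lines(meta or {}))
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_csv_with_meta(path) -> Tuple[pd.DataFrame, Dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
        df = pd.read_csv(fh)
    return df, meta
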