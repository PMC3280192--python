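"""Tab-separated table IO with reproducibility metadata headers.

All pipeline tables are plain TSV with an optional block of ``# key=value``
comment lines at the top (tool version, rng seed, thresholds, config hash).
Readers skip the metadata; :func:`read_metadata` recovers it.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    metadata: Mapping[str, Any] | None = None,
) -> Path:
    """Write ``frame`` as TSV, preceded by ``# key=value`` metadata lines.

    A ``tool`` line with the package version is always included so any
    output file is traceable to the code that produced it.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"tool": f"carrierscreen {__version__}"}
    if metadata:
        meta.update(metadata)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path, **kwargs: Any) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (metadata lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_metadata(path: str | Path) -> dict[str, str]:
    """Return the ``# key=value`` header block of a pipeline TSV."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def sha256_of(path: str | Path) -> str:
    """Hex SHA-256 of a file's bytes (used for config/fixture hashes)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
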