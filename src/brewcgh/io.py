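"""Headered TSV output helpers.

Every file the pipeline writes starts with comment lines naming the
producing module, the run's config hash and seed, so any artifact can be
traced back to the exact run that made it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = ["config_hash", "write_tsv", "write_text"]


def config_hash(config_dict: dict) -> str:
    """Short stable hash of a JSON-serializable config mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(module: str, cfg_hash: str, seed: int, extra: list[str] | None) -> str:
    lines = [f"# module: {module}", f"# config_hash: {cfg_hash}", f"# seed: {seed}"]
    lines += [f"# {x}" for x in (extra or [])]
    return "\n".join(lines) + "\n"


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    module: str,
    cfg_hash: str,
    seed: int,
    index: bool = True,
    extra_header: list[str] | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(module, cfg_hash, seed, extra_header))
        df.to_csv(fh, sep="\t", index=index)
    return path


def write_text(
    text: str,
    path: str | Path,
    module: str,
    cfg_hash: str,
    seed: int,
    comment_prefix: str = "# ",
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = _header(module, cfg_hash, seed, None)
    if comment_prefix != "# ":
        header = header.replace("# ", comment_prefix)
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(text if text.endswith("\n") else text + "\n")
    return path
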