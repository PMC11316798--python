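"""Deterministic JSON reports and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

SCHEMA_VERSION = "1"


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def write_report(results: dict, path, manifest: Optional[dict] = None) -> None:
    """Write a stable-ordered JSON report.

    Numbers are serialised at full double precision; keys are sorted so
    identical results give byte-identical files.  ``manifest`` (config
    echo, software version, input checksums) is embedded under its own
    key when given.
    """
    doc = {"schema_version": SCHEMA_VERSION, "results": _jsonable(results)}
    if manifest is not None:
        doc["manifest"] = _jsonable(manifest)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
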