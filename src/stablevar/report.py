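"""JSON run reports: everything needed to reproduce a run."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version

__all__ = ["build_report", "write_report", "load_report"]


def _tool_version() -> str:
    try:
        return version("stablevar")
    except PackageNotFoundError:
        return "unknown"


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_report(command: str, inputs: "dict | None" = None,
                 config: "dict | None" = None, **sections) -> dict:
    """Assemble the run record.

    ``inputs`` maps role -> path; each file gets a sha256 digest so a rerun
    can verify it sees the same data.  Extra keyword sections are included
    verbatim (they must be JSON-able).
    """
    rep = {
        "tool": "stablevar",
        "version": _tool_version(),
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            role: {"path": str(p), "sha256": file_digest(p)}
            for role, p in (inputs or {}).items()
        },
        "config": config or {},
    }
    rep.update(sections)
    return rep


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
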