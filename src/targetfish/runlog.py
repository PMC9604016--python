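"""Plain-text run log shared by all pipeline stages.

Every operation that masks, drops or tie-breaks something records a line
here, so a finished run can be audited without re-running it.
"""
from __future__ import annotations

import logging
from pathlib import Path

_logger = logging.getLogger("targetfish")


class RunLog:
    """Accumulates human-readable audit lines; optionally mirrored to ``logging``."""

    def __init__(self) -> None:
        self.lines: list[str] = []

    def record(self, message: str) -> None:
        self.lines.append(message)
        _logger.info(message)

    def extend(self, other: "RunLog") -> None:
        self.lines.extend(other.lines)

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.lines) + ("\n" if self.lines else ""))

    def __iter__(self):
        return iter(self.lines)

    def __len__(self) -> int:
        return len(self.lines)


def get_log(log: RunLog | None) -> RunLog:
    """Return ``log`` or a fresh throwaway log, so callers may pass None."""
    return log if log is not None else RunLog()
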