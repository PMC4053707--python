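"""Tiny shared helper: accept either a path or literal file content."""

from __future__ import annotations

from pathlib import Path


def read_text_or_path(source: str | Path) -> str:
    """Return file content for a path, or the string itself if it is content.

    A string containing a newline is always treated as literal content
    (paths cannot contain newlines); otherwise it is read as a path when
    one exists.
    """
    if isinstance(source, Path):
        return source.read_text()
    if "\n" in source:
        return source
    path = Path(source)
    try:
        if path.exists():
            return path.read_text()
    except OSError:
        pass
    return source
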