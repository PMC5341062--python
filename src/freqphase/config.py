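"""Plain-text ``key = value`` configuration files.

Lines are ``key = value``; blank lines and ``#`` comments are ignored.
Values are coerced: ints, floats, booleans (true/false/yes/no), and
comma-separated lists of numbers or strings.  Keys mirror the fields of
:class:`freqphase.pipeline.SeedConfig`; ``inputs`` may be given as a
comma-separated list of paths.
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["parse_value", "read_config"]

_BOOL = {"true": True, "yes": True, "false": False, "no": False}


def parse_value(raw: str):
    raw = raw.strip()
    if "," in raw:
        return tuple(parse_value(part) for part in raw.split(",") if part.strip())
    low = raw.lower()
    if low in _BOOL:
        return _BOOL[low]
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def read_config(path: str | Path) -> dict:
    cfg: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, raw = stripped.partition("=")
        cfg[key.strip()] = parse_value(raw)
    return cfg
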