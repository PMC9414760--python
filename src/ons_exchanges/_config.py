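"""Tiny ``key = value`` config reader shared by the rule and composition tables."""

from __future__ import annotations

from typing import Dict, TextIO, Union


def read_key_values(source: Union[str, TextIO]) -> Dict[str, str]:
    """Parse ``key = value`` lines; ``#`` starts a comment, blanks ignored."""
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return read_key_values(fh)
    values: Dict[str, str] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        values[key.strip()] = value.strip()
    return values
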