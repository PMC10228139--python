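"""Plain-text readers and writers for .smi and token files.

.smi: one record per line — a SMILES string optionally followed by
whitespace and a name; blank lines and '#'-prefixed comment lines are
ignored. Token files: one molecule per line, tokens separated by single
spaces (no token contains a space, so the format is bit-exact). All text
I/O is UTF-8 with LF line endings.
"""

from __future__ import annotations

from pathlib import Path

from .errors import DataError


def read_smi(path: str | Path) -> list[tuple[str, str]]:
    """Read (smiles, name) records; name is '' when absent."""
    records: list[tuple[str, str]] = []
    text = Path(path).read_text(encoding="utf-8")
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        records.append((parts[0], parts[1].strip() if len(parts) > 1 else ""))
    if not records:
        raise DataError(f"no records in {path}")
    return records


def write_smi(path: str | Path, records: list[tuple[str, str]] | list[str]) -> None:
    lines = []
    for rec in records:
        if isinstance(rec, str):
            lines.append(rec)
        else:
            smiles, name = rec
            lines.append(f"{smiles} {name}" if name else smiles)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_tokens(path: str | Path) -> list[list[str]]:
    """Read one token list per non-empty line."""
    rows = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line:
            rows.append(line.split(" "))
    if not rows:
        raise DataError(f"no token records in {path}")
    return rows


def write_tokens(path: str | Path, rows: list[list[str]]) -> None:
    Path(path).write_text(
        "\n".join(" ".join(r) for r in rows) + "\n", encoding="utf-8")
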