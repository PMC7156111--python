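"""Reading and writing SNP samples in ms format.

The ms text convention: one block per sample, introduced by ``//``,
followed by ``segsites: k``, a ``positions:`` line of unit-interval floats
(omitted when k = 0) and ``n`` rows of 0/1 characters.  Positions
round-trip at the printed precision (6 decimals, as ms prints them).
"""

from __future__ import annotations

from typing import IO, Iterable, List

import numpy as np

from .coalescent import SNPMatrix

__all__ = ["write_ms", "read_ms", "MsParseError"]


class MsParseError(ValueError):
    """Malformed ms block; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def write_ms(samples: Iterable[SNPMatrix], stream: IO[str]) -> None:
    """Write SNP matrices as consecutive ms-format blocks."""
    for sm in samples:
        stream.write("//\n")
        stream.write(f"segsites: {sm.S}\n")
        if sm.S > 0:
            pos = " ".join(f"{p:.6f}" for p in sm.positions)
            stream.write(f"positions: {pos}\n")
            for row in sm.matrix:
                stream.write("".join("1" if x else "0" for x in row) + "\n")


def read_ms(stream: IO[str], species: str = "host") -> List[SNPMatrix]:
    """Parse consecutive ms-format blocks into SNP matrices.

    Lines before the first ``//`` (the ms command-line echo and seeds) are
    skipped, so output of ms-compatible simulators parses directly.
    """
    samples: List[SNPMatrix] = []
    lines = stream.read().splitlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].startswith("//"):
            i += 1
            continue
        i += 1
        while i < n_lines and not lines[i].strip():
            i += 1
        if i >= n_lines or not lines[i].startswith("segsites:"):
            raise MsParseError("expected 'segsites:' after '//'", i + 1)
        try:
            S = int(lines[i].split(":", 1)[1])
        except ValueError as exc:
            raise MsParseError(f"bad segsites value: {exc}", i + 1) from exc
        i += 1
        if S == 0:
            samples.append(
                SNPMatrix(matrix=np.zeros((0, 0), dtype=np.int8),
                          positions=np.zeros(0), species=species)
            )
            continue
        if i >= n_lines or not lines[i].startswith("positions:"):
            raise MsParseError("expected 'positions:' line", i + 1)
        try:
            positions = np.array([float(x) for x in lines[i].split(":", 1)[1].split()])
        except ValueError as exc:
            raise MsParseError(f"bad position value: {exc}", i + 1) from exc
        if len(positions) != S:
            raise MsParseError(
                f"{len(positions)} positions for segsites {S}", i + 1
            )
        i += 1
        rows = []
        while i < n_lines and lines[i].strip() and not lines[i].startswith("//"):
            row = lines[i].strip()
            if not set(row) <= {"0", "1"}:
                raise MsParseError(f"non-binary haplotype row {row!r}", i + 1)
            if len(row) != S:
                raise MsParseError(f"row length {len(row)} != segsites {S}", i + 1)
            rows.append([int(c) for c in row])
            i += 1
        if not rows:
            raise MsParseError("block has no haplotype rows", i + 1)
        samples.append(
            SNPMatrix(
                matrix=np.array(rows, dtype=np.int8),
                positions=positions,
                species=species,
            )
        )
    return samples
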