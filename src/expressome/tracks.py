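"""Strand-specific per-nucleotide coverage tracks with bedGraph I/O.

Coordinates are 0-based half-open throughout, matching the bedGraph
convention; one file per strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class CoverageTrack:
    """Per-nucleotide read counts for one replicon, both strands."""

    replicon: str
    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus)
        self.minus = np.asarray(self.minus)
        if self.plus.shape != self.minus.shape or self.plus.ndim != 1:
            raise ValueError("plus/minus tracks must be 1-D and equal length")
        if (self.plus < 0).any() or (self.minus < 0).any():
            raise ValueError("coverage counts must be >= 0")

    def __len__(self) -> int:
        return self.plus.size

    def strand(self, s: str) -> np.ndarray:
        if s == "+":
            return self.plus
        if s == "-":
            return self.minus
        raise ValueError(f"strand must be '+' or '-', got {s!r}")


def write_bedgraph(values: np.ndarray, replicon: str, path: str | Path) -> None:
    """Write one strand's track as run-length-encoded bedGraph."""
    values = np.asarray(values)
    n = values.size
    if n == 0:
        Path(path).write_text("")
        return
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            v = values[s]
            fh.write(f"{replicon}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path, length: int) -> np.ndarray:
    """Expand a single-strand bedGraph back into a dense array."""
    values = np.zeros(length)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            _, s, e, v = line.split("\t")
            values[int(s):int(e)] = float(v)
    return values


def write_track(track: CoverageTrack, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    plus_path = prefix.with_name(prefix.name + "_plus.bedgraph")
    minus_path = prefix.with_name(prefix.name + "_minus.bedgraph")
    write_bedgraph(track.plus, track.replicon, plus_path)
    write_bedgraph(track.minus, track.replicon, minus_path)
    return plus_path, minus_path


def read_track(prefix: str | Path, replicon: str, length: int) -> CoverageTrack:
    prefix = Path(prefix)
    plus = read_bedgraph(prefix.with_name(prefix.name + "_plus.bedgraph"), length)
    minus = read_bedgraph(prefix.with_name(prefix.name + "_minus.bedgraph"), length)
    return CoverageTrack(replicon=replicon, plus=plus, minus=minus)
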