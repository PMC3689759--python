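"""Secondary-structure content summaries from STRIDE-letter tables.

Assignments are consumed, never computed: the input is a rectangular
whitespace/TSV table, one row per frame and one column per residue, of
STRIDE letters.  Letters group into classes as H/G/I -> helix, E/B/b ->
beta, T -> turn, C -> coil (3-10 and pi helices count as helix, isolated
bridges as beta).  Window boundaries are start-inclusive, end-exclusive
frame indices.  Because whether "coil" should absorb turns is a matter of
convention, window comparisons report both groupings.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SSAssignment", "CLASS_MAP", "parse_assignments", "class_content", "compare_windows"]

CLASS_MAP = {
    "H": "helix",
    "G": "helix",
    "I": "helix",
    "E": "beta",
    "B": "beta",
    "b": "beta",
    "T": "turn",
    "C": "coil",
}
CLASSES = ("helix", "beta", "turn", "coil")


@dataclass
class SSAssignment:
    """Per-frame, per-residue STRIDE letters."""

    letters: np.ndarray  # (n_frames, n_residues) of single characters
    residue_labels: list[str]

    def __post_init__(self):
        self.letters = np.asarray(self.letters, dtype="<U1")
        if self.letters.ndim != 2 or self.letters.shape[0] < 1:
            raise ValueError("need a (n_frames, n_residues) letter table")
        if self.letters.shape[1] != len(self.residue_labels):
            raise ValueError("residue label count must match columns")
        bad = set(self.letters.ravel()) - set(CLASS_MAP)
        if bad:
            raise ValueError(f"unknown secondary-structure letters: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return self.letters.shape[0]

    @property
    def n_residues(self) -> int:
        return self.letters.shape[1]


def parse_assignments(path: str | Path) -> SSAssignment:
    """Read a letters table with a residue-label header row."""
    table = pd.read_csv(path, sep=r"\s+")
    if table.shape[0] < 1 or table.shape[1] < 1:
        raise ValueError(f"empty assignment table {path}")
    letters = table.to_numpy(dtype=str)
    if any(len(x) != 1 for x in letters.ravel()):
        raise ValueError("each cell must hold exactly one letter")
    return SSAssignment(letters=letters, residue_labels=[str(c) for c in table.columns])


def _window_slice(ss: SSAssignment, window: tuple[int, int] | None) -> np.ndarray:
    if window is None:
        window = (0, ss.n_frames)
    start, end = window
    sub = ss.letters[start:end]
    if sub.shape[0] == 0:
        raise ValueError(f"empty frame window {window}")
    return sub


def class_content(
    ss: SSAssignment, window: tuple[int, int] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-residue and overall class percentages within a frame window.

    Returns (per_residue, overall): a residues x classes DataFrame of
    percentages and its residue-mean.  Percentages sum to 100 per residue.
    """
    sub = _window_slice(ss, window)
    n = sub.shape[0]
    data = {}
    for cls in CLASSES:
        letters = [l for l, c in CLASS_MAP.items() if c == cls]
        data[cls] = 100.0 * np.isin(sub, letters).sum(axis=0) / n
    per_residue = pd.DataFrame(data, index=ss.residue_labels)
    return per_residue, per_residue.mean(axis=0)


def compare_windows(
    ss: SSAssignment, window_a: tuple[int, int], window_b: tuple[int, int]
) -> pd.Series:
    """Overall content deltas (window_b minus window_a) per class.

    Includes a combined ``coil+turn`` entry alongside the separate turn
    and coil deltas.
    """
    _, overall_a = class_content(ss, window_a)
    _, overall_b = class_content(ss, window_b)
    delta = overall_b - overall_a
    delta["coil+turn"] = delta["coil"] + delta["turn"]
    return delta
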