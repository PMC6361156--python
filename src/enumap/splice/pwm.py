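"""Position-weight-matrix scoring of splicing-factor binding motifs.

The score of a window is the plain additive PWM score: the sum over
positions of the matrix entry for the base observed at that position (the
"weighted majority vote" style score reported by ESE prediction servers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List

import numpy as np

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_ROWS = "ACGT"


@dataclass(frozen=True)
class WeightMatrix:
    """A 4 x L splicing-factor scoring matrix with a hit threshold."""

    name: str
    scores: np.ndarray  # shape (4, L), rows A/C/G/T
    threshold: float

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[0] != 4 or scores.shape[1] < 1:
            raise ValueError("scores must be a 4 x L matrix with L >= 1")
        object.__setattr__(self, "scores", scores)

    @property
    def width(self) -> int:
        return int(self.scores.shape[1])

    @classmethod
    def from_tsv(cls, path: Path) -> "WeightMatrix":
        """Load a matrix from TSV.

        Format: optional ``#factor:`` and ``#threshold:`` header lines,
        then four rows ``A/C/G/T`` each followed by L tab- or
        space-separated scores.
        """
        name = Path(path).stem
        threshold = -math.inf
        rows = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                key = key.strip().lower()
                if key == "factor":
                    name = value.strip()
                elif key == "threshold":
                    threshold = float(value)
                continue
            parts = line.split()
            if parts[0].upper() in _BASE_INDEX:
                rows[parts[0].upper()] = [float(x) for x in parts[1:]]
        if set(rows) != set(_ROWS):
            raise ValueError(f"matrix file {path} must define rows A, C, G and T")
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise ValueError("all four base rows must have the same width")
        scores = np.array([rows[b] for b in _ROWS], dtype=float)
        return cls(name=name, scores=scores, threshold=threshold)

    def to_tsv(self, path: Path) -> Path:
        lines = [f"#factor: {self.name}", f"#threshold: {self.threshold:g}"]
        for i, base in enumerate(_ROWS):
            lines.append(base + "\t" + "\t".join(f"{x:g}" for x in self.scores[i]))
        Path(path).write_text("\n".join(lines) + "\n")
        return Path(path)


@dataclass(frozen=True)
class EseHit:
    """One scored window: 1-based start in the query, sequence and score."""

    start: int
    window: str
    score: float
    above_threshold: bool


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in sequence.upper()], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"ambiguous or invalid base {exc.args[0]!r} in sequence") from exc


def score_window(window: str, wm: WeightMatrix) -> float:
    """Additive PWM score of one window (must be exactly matrix width)."""
    if len(window) != wm.width:
        raise ValueError(f"window length {len(window)} != matrix width {wm.width}")
    idx = _encode(window)
    return float(wm.scores[idx, np.arange(wm.width)].sum())


def scan_ese(sequence: str, wm: WeightMatrix, report_all: bool = False) -> List[EseHit]:
    """Score every window of ``sequence`` left to right.

    Returns above-threshold hits, or every window when ``report_all``.
    Raises if the sequence is shorter than the matrix.
    """
    if len(sequence) < wm.width:
        raise ValueError("sequence shorter than matrix width")
    idx = _encode(sequence)
    L = wm.width
    n_win = len(sequence) - L + 1
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    scores = wm.scores[windows, np.arange(L)].sum(axis=1)
    hits = []
    for i in range(n_win):
        above = bool(scores[i] > wm.threshold)
        if above or report_all:
            hits.append(
                EseHit(
                    start=i + 1,
                    window=sequence[i : i + L],
                    score=float(scores[i]),
                    above_threshold=above,
                )
            )
    return hits


def compare_alleles(
    context: str,
    offset: int,
    ref: str,
    alt: str,
    wm: WeightMatrix,
):
    """Contrast maximal motif scores of the two alleles at one site.

    Both allelic versions of ``context`` are scored over every matrix-width
    window that overlaps the variant position (1-based ``offset``); the
    maxima and their difference (alt minus ref) are returned as
    ``(ref_max, alt_max, delta)``.
    """
    if not 1 <= offset <= len(context):
        raise ValueError("offset outside context")
    if context[offset - 1].upper() != ref.upper():
        raise ValueError(
            f"reference mismatch at offset {offset}: context has "
            f"{context[offset - 1]!r}, expected {ref!r}"
        )
    alt_context = context[: offset - 1] + alt.upper() + context[offset:]
    L = wm.width
    lo = max(0, offset - L)  # 0-based first window start overlapping the site
    hi = min(len(context) - L, offset - 1)
    if hi < lo:
        return (-math.inf, -math.inf, 0.0)
    ref_max = max(
        score_window(context[i : i + L], wm) for i in range(lo, hi + 1)
    )
    alt_max = max(
        score_window(alt_context[i : i + L], wm) for i in range(lo, hi + 1)
    )
    return (ref_max, alt_max, alt_max - ref_max)
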