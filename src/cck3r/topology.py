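"""Membrane topology assignment for 7-TM receptors.

The default caller is a Kyte–Doolittle hydropathy sliding-window scan:
window means above a threshold seed transmembrane (TM) calls, each call
is extended outward while the per-residue hydropathy stays hydrophobic
(> 0), nearby calls are merged, and short calls discarded.  Residues
between TM segments alternate sides, starting extracellular at the N
terminus by class-A GPCR convention (configurable).

Externally computed per-residue annotations (``E``/``M``/``I`` strings,
e.g. from a dedicated topology predictor) can be supplied instead via
:func:`annotation_from_labels` or a two-column TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import ProteinRecord

#: Kyte & Doolittle (1982) hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


@dataclass
class ScreenConfig:
    """Tunable parameters for topology calling and candidate screening.

    Attributes
    ----------
    window : int
        Hydropathy averaging window in residues (odd, >= 5).
    hydro_threshold : float
        Windowed Kyte–Doolittle mean above which a position seeds a TM call.
    min_tm_length : int
        TM calls shorter than this (after extension/merging) are dropped.
    merge_gap : int
        TM calls separated by fewer residues than this are merged.
    n_term_side : str
        Side of the N terminus, 'E' (default, class-A GPCR) or 'I'.
    similarity_threshold : int
        Screening pass threshold tau on hamming similarity scores.
    threshold_mode : str
        'each' (both reference scores >= tau) or 'sum' (their sum >= tau).
    seed : int
        Seed for any stochastic step (none in the default caller).
    """

    window: int = 19
    hydro_threshold: float = 1.6
    min_tm_length: int = 15
    merge_gap: int = 3
    n_term_side: str = "E"
    similarity_threshold: int = 30
    threshold_mode: str = "each"
    seed: int = 0

    def __post_init__(self):
        if self.window < 5 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 5")
        if self.similarity_threshold < 0:
            raise ValueError("similarity threshold must be >= 0")
        if self.n_term_side not in ("E", "I"):
            raise ValueError("n_term_side must be 'E' or 'I'")
        if self.threshold_mode not in ("each", "sum"):
            raise ValueError("threshold_mode must be 'each' or 'sum'")


@dataclass(frozen=True)
class TopologyAnnotation:
    """Per-residue membrane-side labels and the derived TM intervals.

    ``labels`` is a string over {E, M, I} the same length as the
    annotated sequence; ``tm_segments`` are 0-based half-open intervals,
    sorted and non-overlapping.
    """

    record_id: str
    labels: str
    tm_segments: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if set(self.labels) - set("EMI"):
            raise ValueError("labels must be over {E, M, I}")
        prev_end = 0
        for start, end in self.tm_segments:
            if start < prev_end or end <= start or end > len(self.labels):
                raise ValueError("tm_segments must be sorted, non-overlapping, in range")
            prev_end = end

    @property
    def n_tm(self) -> int:
        return len(self.tm_segments)


def hydropathy_profile(residues: str, window: int) -> np.ndarray:
    """Windowed mean Kyte–Doolittle hydropathy.

    Positions closer than ``window // 2`` to either end (no full window)
    are assigned -inf so they never seed a TM call; TM calls may still
    extend into them.
    """
    values = np.array([KYTE_DOOLITTLE[r] for r in residues], dtype=float)
    n = len(values)
    half = window // 2
    profile = np.full(n, -np.inf)
    if n >= window:
        kernel = np.ones(window) / window
        means = np.convolve(values, kernel, mode="valid")
        profile[half : half + len(means)] = means
    return profile


def _label_sides(n: int, tm: Sequence[tuple[int, int]], n_term_side: str) -> str:
    other = {"E": "I", "I": "E"}
    labels = []
    side = n_term_side
    prev = 0
    for start, end in tm:
        labels.append(side * (start - prev))
        labels.append("M" * (end - start))
        side = other[side]
        prev = end
    labels.append(side * (n - prev))
    return "".join(labels)


def predict_topology(record: ProteinRecord, config: ScreenConfig | None = None) -> TopologyAnnotation:
    """Call TM segments by hydropathy and label extramembrane sides.

    Raises ``ValueError`` if the sequence is shorter than the window.
    A record with no hydrophobic stretch yields zero TM segments and a
    uniform N-terminal-side labeling.
    """
    config = config or ScreenConfig()
    seq = record.residues
    n = len(seq)
    if n < config.window:
        raise ValueError(
            f"record {record.id!r}: sequence length {n} shorter than window {config.window}"
        )
    profile = hydropathy_profile(seq, config.window)
    above = profile >= config.hydro_threshold
    values = np.array([KYTE_DOOLITTLE[r] for r in seq], dtype=float)

    # seed runs of above-threshold window centers
    runs: list[list[int]] = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1

    # window means erode call boundaries; extend while residues stay hydrophobic
    for run in runs:
        while run[0] > 0 and values[run[0] - 1] > 0:
            run[0] -= 1
        while run[1] < n and values[run[1]] > 0:
            run[1] += 1

    # merge overlapping or nearly touching calls
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < config.merge_gap:
            merged[-1][1] = max(merged[-1][1], run[1])
        else:
            merged.append(run)

    tm = tuple(
        (start, end) for start, end in merged if end - start >= config.min_tm_length
    )
    labels = _label_sides(n, tm, config.n_term_side)
    return TopologyAnnotation(record_id=record.id, labels=labels, tm_segments=tm)


def annotation_from_labels(record: ProteinRecord, labels: str) -> TopologyAnnotation:
    """Build an annotation from an externally supplied E/M/I label string."""
    if len(labels) != len(record.residues):
        raise ValueError(
            f"record {record.id!r}: label string length {len(labels)} != "
            f"sequence length {len(record.residues)}"
        )
    tm = []
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] == "M":
            j = i
            while j < n and labels[j] == "M":
                j += 1
            tm.append((i, j))
            i = j
        else:
            i += 1
    return TopologyAnnotation(record_id=record.id, labels=labels, tm_segments=tuple(tm))


def read_topology_tsv(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (record id, E/M/I label string) into a dict."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"expected 2 tab-separated columns, got: {line!r}")
        out[parts[0]] = parts[1]
    return out
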