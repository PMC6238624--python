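"""Sequence-context summarization around site centers.

Windows of 5 nt up- and downstream of each center (transcript orientation)
are summarized as count/frequency matrices with per-column information
content relative to a background composition, with an optional iterative
+-1-base shift alignment.  Full motif discovery is out of scope; FASTA
export keeps the windows usable with external motif tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .coverage import GenomeIndex, reverse_complement
from .sitecalling import SiteCluster

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
WINDOW_WIDTH = 11  # 5 up + site + 5 down
DEFAULT_FLANK = 5


@dataclass(frozen=True)
class SeqWindow:
    replicon: str
    strand: str
    center: int
    sequence: str  # DNA alphabet, transcript orientation
    shift: int = 0

    @property
    def flank(self) -> int:
        return (len(self.sequence) - 1) // 2


def genome_composition(genome: Mapping[str, GenomeIndex]) -> np.ndarray:
    """Mononucleotide background frequencies (A, C, G, T) of a genome."""
    counts = np.zeros(4)
    for g in genome.values():
        for base, i in BASE_INDEX.items():
            counts[i] += g.sequence.count(base)
    total = counts.sum()
    if total == 0:
        raise ValueError("genome contains no unambiguous bases")
    return counts / total


def extract_windows(
    clusters: Sequence[SiteCluster],
    genome: Mapping[str, GenomeIndex],
    flank: int = DEFAULT_FLANK,
) -> tuple[list[SeqWindow], int]:
    """Per-site sequence windows center+-flank in transcript orientation.

    Minus-strand windows are reverse-complemented so index `flank` is always
    the site base.  Centers closer than flank+1 to a replicon edge are
    skipped; the skip count is returned alongside the windows.
    """
    windows = []
    skipped = 0
    for cluster in clusters:
        g = genome[cluster.replicon]
        if cluster.center - flank < 1 or cluster.center + flank > g.length:
            skipped += 1
            continue
        seq = g.sequence[cluster.center - flank - 1 : cluster.center + flank]
        if cluster.strand == "-":
            seq = reverse_complement(seq)
        windows.append(
            SeqWindow(cluster.replicon, cluster.strand, cluster.center, seq.upper())
        )
    return windows, skipped


@dataclass
class MotifMatrix:
    counts: np.ndarray  # 4 x width integer
    frequencies: np.ndarray  # column-stochastic 4 x width
    information_content: np.ndarray  # bits per column
    background: np.ndarray  # 4-vector summing to 1
    n_windows: int = 0
    converged: bool = True
    ic_history: list[float] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def total_ic(self) -> float:
        return float(self.information_content.sum())


def _window_slice(window: SeqWindow, width: int) -> str:
    """Central `width`-mer of the window sequence after applying its shift."""
    offset = window.flank - width // 2 + window.shift
    return window.sequence[offset : offset + width]


def build_matrix(
    windows: Sequence[SeqWindow],
    background: np.ndarray | Sequence[float],
    width: int = WINDOW_WIDTH,
) -> MotifMatrix:
    """Column-wise base counts, frequencies and relative-entropy IC (bits)."""
    if not windows:
        raise ValueError("cannot build a matrix from zero windows")
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or np.any(background <= 0):
        raise ValueError("background must be 4 strictly positive frequencies")
    background = background / background.sum()
    counts = np.zeros((4, width), dtype=int)
    for window in windows:
        seq = _window_slice(window, width)
        if len(seq) != width:
            raise ValueError(
                f"window at {window.replicon}:{window.center} too short for "
                f"width {width} at shift {window.shift}"
            )
        for col, base in enumerate(seq):
            if base in BASE_INDEX:
                counts[BASE_INDEX[base], col] += 1
    col_totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(col_totals > 0, counts / col_totals, 0.25)
    q = np.broadcast_to(background[:, None], freqs.shape)
    terms = np.zeros_like(freqs)
    mask = freqs > 0
    terms[mask] = freqs[mask] * np.log2(freqs[mask] / q[mask])
    ic = terms.sum(axis=0)
    return MotifMatrix(
        counts=counts,
        frequencies=freqs,
        information_content=np.clip(ic, 0.0, None),
        background=background,
        n_windows=len(windows),
    )


def shift_align(
    windows: Sequence[SeqWindow],
    background: np.ndarray | Sequence[float],
    max_shift: int = 1,
    max_iter: int = 20,
    width: int = WINDOW_WIDTH,
) -> tuple[list[SeqWindow], MotifMatrix]:
    """Iteratively realign windows by at most one base against the consensus.

    Each round scores every window's candidate shifts against the current
    frequency matrix (add-one smoothed log-odds vs background) and keeps the
    best; ties prefer the smaller absolute then more negative shift.  Stops
    when no shift changes or after max_iter rounds (flagged on the matrix).
    """
    flank_needed = width // 2 + max_shift
    for w in windows:
        if w.flank < flank_needed:
            raise ValueError(
                f"shift alignment with max_shift={max_shift} needs windows "
                f"extracted with flank >= {flank_needed}"
            )
    current = list(windows)
    matrix = build_matrix(current, background, width=width)
    history = [matrix.total_ic()]
    converged = False
    shifts = sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s))
    for _ in range(max_iter):
        smoothed = (matrix.counts + 1) / (matrix.counts.sum(axis=0) + 4)
        log_odds = np.log2(smoothed / matrix.background[:, None])
        changed = False
        updated = []
        for window in current:
            best_shift, best_score = window.shift, -np.inf
            for s in shifts:
                seq = _window_slice(replace(window, shift=s), width)
                score = sum(
                    log_odds[BASE_INDEX[b], col]
                    for col, b in enumerate(seq)
                    if b in BASE_INDEX
                )
                if score > best_score:
                    best_score, best_shift = score, s
            if best_shift != window.shift:
                changed = True
            updated.append(replace(window, shift=best_shift))
        current = updated
        matrix = build_matrix(current, background, width=width)
        history.append(matrix.total_ic())
        if not changed:
            converged = True
            break
    matrix.converged = converged
    matrix.ic_history = history
    return current, matrix


def au_enrichment(matrix: MotifMatrix) -> "pd.DataFrame":
    """Per-column A+T fraction with a two-sided binomial test vs background."""
    import pandas as pd
    from scipy.stats import binomtest

    q_au = float(matrix.background[BASE_INDEX["A"]] + matrix.background[BASE_INDEX["T"]])
    rows = []
    for col in range(matrix.width):
        au_count = int(
            matrix.counts[BASE_INDEX["A"], col] + matrix.counts[BASE_INDEX["T"], col]
        )
        n = int(matrix.counts[:, col].sum())
        if n > 0:
            frac = au_count / n
            p = binomtest(au_count, n, q_au, alternative="two-sided").pvalue
        else:
            frac, p = float("nan"), 1.0
        rows.append({"column": col, "au_fraction": frac, "p_value": p})
    return pd.DataFrame(rows)


def export_windows_fasta(windows: Sequence[SeqWindow], path: str | Path) -> None:
    """One record per window; headers are replicon:strand:center."""
    with open(path, "w") as fh:
        for window in windows:
            fh.write(f">{window.replicon}:{window.strand}:{window.center}\n")
            fh.write(window.sequence + "\n")


def matrix_to_frame(matrix: MotifMatrix, as_rna: bool = False) -> "pd.DataFrame":
    """Long-format dump of counts, frequencies and per-column IC."""
    import pandas as pd

    rows = []
    for col in range(matrix.width):
        for i, base in enumerate(BASES):
            rows.append(
                {
                    "column": col,
                    "base": "U" if as_rna and base == "T" else base,
                    "count": int(matrix.counts[i, col]),
                    "frequency": float(matrix.frequencies[i, col]),
                    "ic_bits": float(matrix.information_content[col]),
                }
            )
    return pd.DataFrame(rows)


def write_meme_minimal(matrix: MotifMatrix, path: str | Path, name: str = "site") -> None:
    """MEME minimal motif format export of the frequency matrix."""
    bg = matrix.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
        )
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {matrix.width} "
            f"nsites= {matrix.n_windows} E= 0\n"
        )
        for col in range(matrix.width):
            fh.write(
                " ".join(f"{matrix.frequencies[i, col]:.6f}" for i in range(4)) + "\n"
            )
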