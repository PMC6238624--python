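"""Strand-aware single-nucleotide 5'-end (first-base-in-read) coverage.

Coordinates are 1-based inclusive throughout the package; BED export is the
only place where the 0-based half-open convention appears.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-")
CONDITIONS = ("wild_type", "mutant")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeIndex:
    """A single replicon: identifier, length and sequence."""

    replicon_id: str
    length: int
    sequence: str

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError(
                f"replicon {self.replicon_id}: declared length {self.length} "
                f"!= sequence length {len(self.sequence)}"
            )
        if self.length <= 0:
            raise ValueError(f"replicon {self.replicon_id}: empty sequence")


def read_fasta(path: str | Path) -> dict[str, GenomeIndex]:
    """Load a genome FASTA into a mapping replicon_id -> GenomeIndex."""
    genome: dict[str, GenomeIndex] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate replicon id in FASTA: {rec.id}")
        seq = str(rec.seq).upper()
        genome[rec.id] = GenomeIndex(rec.id, len(seq), seq)
    return genome


def write_fasta(genome: Mapping[str, GenomeIndex], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.replicon_id, description="")
        for g in genome.values()
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class AlignedRead:
    """Aligned span of one read (soft-clipping already resolved upstream)."""

    replicon_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid read span {self.start}-{self.end} on {self.replicon_id}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class CoverageTrack:
    """Sparse per-position 5'-end counts for one (library, replicon, strand)."""

    library_id: str
    replicon_id: str
    strand: str
    counts: Counter = field(default_factory=Counter)

    def total(self) -> int:
        return sum(self.counts.values())


def five_prime_coverage(
    reads: Iterable[AlignedRead],
    genome: Mapping[str, GenomeIndex],
    library_id: str = "lib",
) -> dict[tuple[str, str], CoverageTrack]:
    """Count the genomic position of each read's biological 5' end.

    For a ``+`` strand read that is the leftmost aligned base; for a ``-``
    strand read it is the rightmost.  Returns one track per (replicon,
    strand), including empty tracks for strands without reads.
    """
    tracks = {
        (rid, strand): CoverageTrack(library_id, rid, strand)
        for rid in genome
        for strand in STRANDS
    }
    for read in reads:
        if read.replicon_id not in genome:
            raise ValueError(f"read maps to unknown replicon {read.replicon_id!r}")
        length = genome[read.replicon_id].length
        if read.end > length:
            raise ValueError(
                f"read {read.replicon_id}:{read.start}-{read.end} exceeds "
                f"replicon length {length}"
            )
        pos = read.start if read.strand == "+" else read.end
        tracks[(read.replicon_id, read.strand)].counts[pos] += 1
    return tracks


def reads_from_sam(path: str | Path, library_id: str = "lib") -> list[AlignedRead]:
    """Optional SAM/BAM front-end: one AlignedRead per mapped primary record."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            reads.append(
                AlignedRead(
                    replicon_id=rec.reference_name,
                    start=rec.reference_start + 1,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                )
            )
    return reads


# -- wiggle I/O --------------------------------------------------------------

_STRAND_SUFFIX = {"+": "_forward", "-": "_reverse"}
_SUFFIX_STRAND = {v: k for k, v in _STRAND_SUFFIX.items()}


def write_wiggle(tracks: Sequence[CoverageTrack], path: str | Path) -> None:
    """Write tracks of one (library, strand) as variableStep wiggle (span=1)."""
    tracks = list(tracks)
    if tracks:
        libs = {t.library_id for t in tracks}
        strands = {t.strand for t in tracks}
        if len(libs) > 1 or len(strands) > 1:
            raise ValueError("one wiggle file holds a single (library, strand)")
        name = tracks[0].library_id + _STRAND_SUFFIX[tracks[0].strand]
    else:
        name = "empty_forward"
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for track in tracks:
            fh.write(f"variableStep chrom={track.replicon_id} span=1\n")
            for pos in sorted(track.counts):
                count = track.counts[pos]
                if count < 0:
                    raise ValueError(f"negative count at {pos}")
                if count:
                    fh.write(f"{pos} {count}\n")


class WiggleDialectError(ValueError):
    """Raised for wiggle dialects other than variableStep."""


def read_wiggle(path: str | Path, library_id: str | None = None) -> list[CoverageTrack]:
    """Parse a variableStep wiggle file into per-replicon CoverageTracks.

    The strand is recovered from the ``_forward``/``_reverse`` suffix of the
    track name; negative values are interpreted as reverse-strand magnitudes.
    """
    tracks: list[CoverageTrack] = []
    lib = library_id or Path(path).stem
    strand = "+"
    current: CoverageTrack | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("track"):
                name = _parse_track_name(line)
                for suffix, s in _SUFFIX_STRAND.items():
                    if name.endswith(suffix):
                        strand = s
                        if library_id is None:
                            lib = name[: -len(suffix)]
                        break
                continue
            if line.startswith("fixedStep"):
                raise WiggleDialectError(
                    f"{path}:{lineno}: fixedStep wiggle is not supported"
                )
            if line.startswith("variableStep"):
                fields = dict(
                    kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                )
                current = CoverageTrack(lib, fields["chrom"], strand)
                tracks.append(current)
                continue
            parts = line.split()
            if len(parts) != 2 or current is None:
                raise ValueError(f"{path}:{lineno}: malformed wiggle line {line!r}")
            try:
                pos = int(parts[0])
                value = int(float(parts[1]))
                if float(parts[1]) != value:
                    raise ValueError
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer wiggle value {parts[1]!r}"
                ) from None
            if value:
                current.counts[pos] = abs(value)
    return tracks


def _parse_track_name(line: str) -> str:
    if 'name="' in line:
        return line.split('name="', 1)[1].split('"', 1)[0]
    for token in line.split():
        if token.startswith("name="):
            return token[len("name=") :]
    return ""


# -- position table ----------------------------------------------------------

ROW_INDEX_NAMES = ("replicon", "strand", "position")


@dataclass
class PositionTable:
    """Per-(replicon, strand, position) 5'-end counts across libraries.

    ``counts`` is indexed by (replicon, strand, position) with one integer
    column per library; ``conditions`` maps library_id -> condition label.
    """

    counts: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        if list(self.counts.index.names) != list(ROW_INDEX_NAMES):
            raise ValueError(f"index must be {ROW_INDEX_NAMES}")
        if not self.counts.index.is_unique:
            raise ValueError("duplicate row keys in position table")
        unknown = set(self.conditions.values()) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"libraries without condition label: {sorted(missing)}")

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    def libraries_for(self, condition: str) -> list[str]:
        return [c for c in self.counts.columns if self.conditions[c] == condition]

    def __len__(self) -> int:
        return len(self.counts)


def build_position_table(
    tracks_by_library: Mapping[str, Sequence[CoverageTrack]],
    conditions: Mapping[str, str],
) -> PositionTable:
    """Union the nonzero positions of all libraries into one count matrix."""
    library_ids = list(tracks_by_library)
    if len(set(library_ids)) != len(library_ids):
        raise ValueError("duplicate library_id")
    key_sets = {}
    for lib, tracks in tracks_by_library.items():
        keys = [(t.replicon_id, t.strand) for t in tracks]
        if len(set(keys)) != len(keys):
            raise ValueError(f"library {lib}: duplicate (replicon, strand) track")
        key_sets[lib] = set(keys)
    reference = key_sets[library_ids[0]]
    for lib, keys in key_sets.items():
        if keys != reference:
            raise ValueError(
                f"library {lib} covers different (replicon, strand) keys than "
                f"{library_ids[0]}"
            )
    series = {}
    for lib, tracks in tracks_by_library.items():
        data = {
            (t.replicon_id, t.strand, pos): count
            for t in tracks
            for pos, count in t.counts.items()
            if count
        }
        series[lib] = pd.Series(data, dtype="int64")
    counts = pd.DataFrame(series).fillna(0).astype("int64")
    if counts.empty:
        counts = pd.DataFrame(
            columns=library_ids,
            index=pd.MultiIndex.from_tuples([], names=ROW_INDEX_NAMES),
            dtype="int64",
        )
    else:
        counts.index.names = ROW_INDEX_NAMES
        counts = counts.sort_index()
    return PositionTable(counts, dict(conditions))


def write_position_table(table: PositionTable, path: str | Path) -> None:
    """Serialize a PositionTable as TSV with a condition header comment."""
    with open(path, "w") as fh:
        cond = ",".join(f"{k}={v}" for k, v in table.conditions.items())
        fh.write(f"# conditions: {cond}\n")
        table.counts.reset_index().to_csv(fh, sep="\t", index=False)


def read_position_table(path: str | Path) -> PositionTable:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# conditions:"):
            raise ValueError(f"{path}: missing condition header")
        conditions = dict(
            kv.split("=", 1) for kv in header.split(":", 1)[1].strip().split(",")
        )
        df = pd.read_csv(fh, sep="\t")
    df = df.set_index(list(ROW_INDEX_NAMES))
    return PositionTable(df.astype("int64"), conditions)
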