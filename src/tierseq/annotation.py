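"""Assign site clusters to RNA categories and positional statistics.

Sites are matched to features by the cluster center only (strand-aware
containment); overlapping features are resolved by a fixed precedence
putting structural RNAs before coding sequence before UTRs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from urllib.parse import unquote

import numpy as np
import pandas as pd

from .sitecalling import SiteCluster

FEATURE_TYPES = (
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
    "rRNA",
    "tRNA",
    "sRNA",
    "other",
)

# higher wins when a site center sits in several overlapping features
PRECEDENCE = {
    "rRNA": 6,
    "tRNA": 5,
    "sRNA": 4,
    "CDS": 3,
    "five_prime_UTR": 2,
    "three_prime_UTR": 1,
    "other": 0,
}

INTERGENIC = "intergenic"

DEFAULT_TYPE_ALIASES = {
    "5UTR": "five_prime_UTR",
    "3UTR": "three_prime_UTR",
    "5'UTR": "five_prime_UTR",
    "3'UTR": "three_prime_UTR",
    "ncRNA": "sRNA",
    "sRNA": "sRNA",
}


@dataclass(frozen=True)
class Feature:
    replicon: str
    strand: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    type: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature {self.gene_id}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, replicon: str, strand: str, position: int) -> bool:
        return (
            replicon == self.replicon
            and strand == self.strand
            and self.start <= position <= self.end
        )


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        if not chunk or "=" not in chunk:
            continue
        key, value = chunk.split("=", 1)
        attrs[key.strip()] = unquote(value.strip())
    return attrs


def parse_gff(
    path: str | Path,
    type_aliases: Mapping[str, str] | None = None,
) -> list[Feature]:
    """Read GFF3 into typed features; gene ids come from ID or locus_tag.

    Column-3 types outside the known vocabulary fall back to the alias map,
    then to "other".  Raises on malformed lines with the line number.
    """
    aliases = dict(DEFAULT_TYPE_ALIASES)
    if type_aliases:
        aliases.update(type_aliases)
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            replicon, _, ftype, start_s, end_s, _, strand, _, attr_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if end < start:
                raise ValueError(f"{path}:{lineno}: end {end} < start {start}")
            if strand not in "+-":
                # region/unstranded records are irrelevant for site assignment
                continue
            attrs = _parse_attributes(attr_s)
            gene_id = attrs.get("ID") or attrs.get("locus_tag")
            if not gene_id:
                raise ValueError(
                    f"{path}:{lineno}: attributes lack both ID and locus_tag"
                )
            if ftype not in FEATURE_TYPES:
                ftype = aliases.get(ftype, "other")
            features.append(Feature(replicon, strand, start, end, ftype, gene_id))
    return features


def write_gff(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.replicon}\tsim\t{f.type}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.gene_id}\n"
            )


def assign_sites(
    clusters: Sequence[SiteCluster],
    features: Sequence[Feature],
) -> tuple[list[str], Counter]:
    """Per-site category labels (by precedence) and category tallies.

    Every site gets exactly one label; sites matching no feature are
    "intergenic".
    """
    by_key: dict[tuple[str, str], list[Feature]] = {}
    for feature in features:
        by_key.setdefault((feature.replicon, feature.strand), []).append(feature)
    labels = []
    for cluster in clusters:
        hits = [
            f
            for f in by_key.get((cluster.replicon, cluster.strand), [])
            if f.start <= cluster.center <= f.end
        ]
        if hits:
            labels.append(max(hits, key=lambda f: PRECEDENCE[f.type]).type)
        else:
            labels.append(INTERGENIC)
    return labels, Counter(labels)


def site_density(
    clusters: Sequence[SiteCluster],
    features: Sequence[Feature],
) -> pd.DataFrame:
    """Sites-per-kilobase density per feature, zero-site features included.

    A site is counted for every feature containing its center on the same
    strand (density is per-feature, unlike the single-label assignment).
    """
    counts = {id(f): 0 for f in features}
    by_key: dict[tuple[str, str], list[Feature]] = {}
    for feature in features:
        by_key.setdefault((feature.replicon, feature.strand), []).append(feature)
    for cluster in clusters:
        for f in by_key.get((cluster.replicon, cluster.strand), []):
            if f.start <= cluster.center <= f.end:
                counts[id(f)] += 1
    rows = [
        {
            "gene_id": f.gene_id,
            "type": f.type,
            "n_sites": counts[id(f)],
            "length_nt": f.length,
            "density": counts[id(f)] / f.length * 1000.0,
        }
        for f in features
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "type", "n_sites", "length_nt", "density"]
    )


def density_summary(density: pd.DataFrame) -> pd.DataFrame:
    """Box-plot style per-type quartiles plus zero-site gene counts."""
    def q(series, frac):
        return float(np.quantile(series, frac)) if len(series) else float("nan")

    rows = []
    for ftype, group in density.groupby("type", sort=True):
        d = group["density"]
        rows.append(
            {
                "type": ftype,
                "n_features": len(group),
                "n_zero_site": int((group["n_sites"] == 0).sum()),
                "min": q(d, 0.0),
                "q1": q(d, 0.25),
                "median": q(d, 0.5),
                "q3": q(d, 0.75),
                "max": q(d, 1.0),
            }
        )
    return pd.DataFrame(rows)


def codon_relative_frequency(
    clusters: Sequence[SiteCluster],
    cds_features: Sequence[Feature],
    window: int = 100,
) -> tuple[Counter, Counter]:
    """Site-center frequencies by offset from start and stop codon first base.

    Offsets are measured 5'->3' in transcript orientation: 0 is the first
    base of the codon, negative is upstream.  Each (site, CDS) pair within
    +-window contributes one count.
    """
    start_hist: Counter = Counter()
    stop_hist: Counter = Counter()
    by_key: dict[tuple[str, str], list[Feature]] = {}
    for feature in cds_features:
        if feature.type != "CDS":
            continue
        by_key.setdefault((feature.replicon, feature.strand), []).append(feature)
    for cluster in clusters:
        for f in by_key.get((cluster.replicon, cluster.strand), []):
            if f.strand == "+":
                start_codon, stop_codon = f.start, f.end - 2
                start_off = cluster.center - start_codon
                stop_off = cluster.center - stop_codon
            else:
                start_codon, stop_codon = f.end, f.start + 2
                start_off = start_codon - cluster.center
                stop_off = stop_codon - cluster.center
            if abs(start_off) <= window:
                start_hist[start_off] += 1
            if abs(stop_off) <= window:
                stop_hist[stop_off] += 1
    return start_hist, stop_hist


def histogram_frame(hist: Counter, window: int = 100) -> pd.DataFrame:
    offsets = list(range(-window, window + 1))
    return pd.DataFrame(
        {"offset": offsets, "count": [hist.get(o, 0) for o in offsets]}
    )
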