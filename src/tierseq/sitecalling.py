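"""Filter, classify and cluster significant 5' ends into sites.

Cleavage sites are positions depleted in the mutant (positive log2 fold
change, wild type over mutant); enriched sites are the reverse.  Candidates
within 3 nt are merged by single-linkage chaining and represented by a
center position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import PositionTable

CLEAVAGE = "cleavage"
ENRICHED = "enriched"

DEFAULT_MIN_COV = 10
DEFAULT_FC_MIN = 2.0
DEFAULT_ALPHA = 0.05
DEFAULT_PROXIMITY = 3


def filter_low_coverage(table: PositionTable, min_cov: int = DEFAULT_MIN_COV) -> PositionTable:
    """Keep rows with raw count >= min_cov in at least one library."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    keep = table.counts.max(axis=1) >= min_cov
    return PositionTable(table.counts.loc[keep], dict(table.conditions))


def classify_candidates(
    results: pd.DataFrame,
    fc_min: float = DEFAULT_FC_MIN,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Select significant candidate 5' ends and label their class.

    cleavage: log2fc >= log2(fc_min) and padj < alpha (depleted in mutant);
    enriched: log2fc <= -log2(fc_min) and padj < alpha.
    """
    if fc_min <= 1:
        raise ValueError("fc_min must be > 1")
    if "padj" not in results.columns:
        raise ValueError("results lack a padj column")
    lfc_min = math.log2(fc_min)
    significant = results["padj"] < alpha
    cleavage = significant & (results["log2fc"] >= lfc_min)
    enriched = significant & (results["log2fc"] <= -lfc_min)
    out = results.loc[cleavage | enriched].copy()
    out["class"] = np.where(out["log2fc"] > 0, CLEAVAGE, ENRICHED)
    return out


@dataclass(frozen=True)
class SiteCluster:
    replicon: str
    strand: str
    members: tuple[int, ...]  # sorted positions
    center: int
    site_class: str
    padj_min: float
    base_mean_max: float

    @property
    def span(self) -> tuple[int, int]:
        return self.members[0], self.members[-1]


def _pick_center(positions: np.ndarray, base_means: np.ndarray) -> int:
    """Member nearest the arithmetic mean; ties by larger base mean, then left."""
    mean = positions.mean()
    dist = np.abs(positions - mean)
    best = dist == dist.min()
    candidates = positions[best]
    bm = base_means[best]
    top = bm == bm.max()
    return int(candidates[top].min())


def cluster_candidates(
    candidates: pd.DataFrame,
    proximity: int = DEFAULT_PROXIMITY,
) -> list[SiteCluster]:
    """Single-linkage chaining of same-class candidates within `proximity` nt.

    The input must contain candidates of a single class (index: replicon,
    strand, position; columns include class, padj, base_mean).
    """
    if candidates.empty:
        return []
    classes = set(candidates["class"])
    if len(classes) > 1:
        raise ValueError(f"mixed candidate classes in one call: {sorted(classes)}")
    site_class = classes.pop()

    clusters: list[SiteCluster] = []
    frame = candidates.reset_index().sort_values(["replicon", "strand", "position"])
    for (replicon, strand), group in frame.groupby(["replicon", "strand"], sort=True):
        positions = group["position"].to_numpy()
        base_means = group["base_mean"].to_numpy(dtype=float)
        padjs = group["padj"].to_numpy(dtype=float)
        breaks = np.flatnonzero(np.diff(positions) > proximity) + 1
        for chunk in np.split(np.arange(len(positions)), breaks):
            pos = positions[chunk]
            clusters.append(
                SiteCluster(
                    replicon=replicon,
                    strand=strand,
                    members=tuple(int(p) for p in pos),
                    center=_pick_center(pos, base_means[chunk]),
                    site_class=site_class,
                    padj_min=float(padjs[chunk].min()),
                    base_mean_max=float(base_means[chunk].max()),
                )
            )
    return clusters


def call_sites(
    results: pd.DataFrame,
    fc_min: float = DEFAULT_FC_MIN,
    alpha: float = DEFAULT_ALPHA,
    proximity: int = DEFAULT_PROXIMITY,
) -> dict[str, list[SiteCluster]]:
    """Classify and cluster both site classes independently."""
    candidates = classify_candidates(results, fc_min=fc_min, alpha=alpha)
    out = {}
    for site_class in (CLEAVAGE, ENRICHED):
        subset = candidates[candidates["class"] == site_class]
        out[site_class] = cluster_candidates(subset, proximity=proximity)
    return out


def export_sites(clusters: list[SiteCluster], path) -> None:
    """Write one BED6 record per cluster (0-based half-open on the center)."""
    with open(path, "w") as fh:
        for i, cluster in enumerate(clusters):
            if cluster.padj_min > 0:
                score = round(min(1000.0, -10.0 * math.log10(cluster.padj_min)))
            else:
                score = 1000
            name = f"{cluster.site_class}_{i + 1}"
            fh.write(
                f"{cluster.replicon}\t{cluster.center - 1}\t{cluster.center}\t"
                f"{name}\t{score}\t{cluster.strand}\n"
            )


def clusters_to_frame(clusters: list[SiteCluster]) -> pd.DataFrame:
    """Tabular cluster dump with membership (TSV-friendly)."""
    rows = [
        {
            "replicon": c.replicon,
            "strand": c.strand,
            "center": c.center,
            "class": c.site_class,
            "span_start": c.span[0],
            "span_end": c.span[1],
            "n_members": len(c.members),
            "members": ",".join(map(str, c.members)),
            "padj_min": c.padj_min,
            "base_mean_max": c.base_mean_max,
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "replicon", "strand", "center", "class", "span_start", "span_end",
            "n_members", "members", "padj_min", "base_mean_max",
        ],
    )


def frame_to_clusters(frame: pd.DataFrame) -> list[SiteCluster]:
    clusters = []
    for row in frame.to_dict("records"):
        members = tuple(int(x) for x in str(row["members"]).split(","))
        clusters.append(
            SiteCluster(
                replicon=row["replicon"],
                strand=row["strand"],
                members=members,
                center=int(row["center"]),
                site_class=row["class"],
                padj_min=float(row["padj_min"]),
                base_mean_max=float(row["base_mean_max"]),
            )
        )
    return clusters
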