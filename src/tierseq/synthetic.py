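"""Synthetic 5'-end sequencing experiments with known ground truth.

Generates a GC-rich genome, a non-overlapping gene annotation, implanted
wild-type-enriched (cleavage) and mutant-enriched (stabilized) sites, and
negative-binomial per-position count tables — everything needed to exercise
the pipeline end to end and score site recovery, without any downloads.

Counts are simulated directly at the 5'-end position level; read-level
emission is a non-goal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Feature
from .coverage import (
    CoverageTrack,
    GenomeIndex,
    PositionTable,
    ROW_INDEX_NAMES,
    build_position_table,
)
from .sitecalling import CLEAVAGE, ENRICHED, SiteCluster

TRUTH_COLUMNS = ["replicon", "strand", "position", "class", "log2_effect", "site_mean"]


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 200_000
    n_replicons: int = 1
    gc_content: float = 0.688
    n_genes: int = 120
    utr_fraction: float = 0.7  # probability a gene carries each UTR
    n_srna: int = 10
    n_rrna: int = 2
    n_cleavage_sites: int = 200
    n_enriched_sites: int = 200
    cleavage_log2_effect: float = 2.5
    enriched_log2_effect: float = 2.5
    background_rate: float = 0.002  # non-differential 5' ends per nt
    site_mean: float = 80.0  # mean coverage on the high side of a site
    dispersion: float = 0.1  # NB alpha
    n_replicates: int = 3
    size_factors: tuple[float, ...] = (1.0, 1.2, 0.8, 1.1, 0.9, 1.05)
    au_motif_probability: float = 0.8
    min_site_distance: int = 10
    enriched_at_5prime_prob: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in (0, 1]")
        if self.cleavage_log2_effect < 0 or self.enriched_log2_effect < 0:
            raise ValueError("log2 effects must be non-negative")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")

    @property
    def library_ids(self) -> list[str]:
        return [f"wt_{i + 1}" for i in range(self.n_replicates)] + [
            f"mut_{i + 1}" for i in range(self.n_replicates)
        ]

    @property
    def conditions(self) -> dict[str, str]:
        return {
            lib: "wild_type" if lib.startswith("wt_") else "mutant"
            for lib in self.library_ids
        }

    @property
    def library_size_factors(self) -> np.ndarray:
        n = 2 * self.n_replicates
        reps = -(-n // len(self.size_factors))
        return np.array((self.size_factors * reps)[:n], dtype=float)


def simulate_genome(
    config: SimConfig, rng: np.random.Generator
) -> dict[str, GenomeIndex]:
    """i.i.d. sequence with P(G) + P(C) = gc_content, split over replicons."""
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    per = config.genome_length // config.n_replicons
    genome = {}
    for i in range(config.n_replicons):
        length = per if i < config.n_replicons - 1 else (
            config.genome_length - per * (config.n_replicons - 1)
        )
        seq = "".join(rng.choice(list("ACGT"), size=length, p=probs))
        rid = f"repl_{i + 1}"
        genome[rid] = GenomeIndex(rid, length, seq)
    return genome


def simulate_annotation(
    config: SimConfig,
    genome: Mapping[str, GenomeIndex],
    rng: np.random.Generator,
) -> list[Feature]:
    """Non-overlapping genes (optional UTRs), sRNAs and rRNAs on both strands."""
    replicons = list(genome.values())
    units: list[tuple[str, int]] = [("gene", i) for i in range(config.n_genes)]
    units += [("sRNA", i) for i in range(config.n_srna)]
    units += [("rRNA", i) for i in range(config.n_rrna)]
    rng.shuffle(units)

    # round-robin over replicons weighted by length
    total_len = sum(r.length for r in replicons)
    features: list[Feature] = []
    cursors = {r.replicon_id: 1 for r in replicons}
    per_replicon: dict[str, list[tuple[str, int]]] = {r.replicon_id: [] for r in replicons}
    for j, unit in enumerate(units):
        # proportional assignment, deterministic
        weights = np.array([r.length / total_len for r in replicons])
        idx = int(np.argmax(np.cumsum(weights) >= ((j + 0.5) / len(units)) % 1.0))
        per_replicon[replicons[idx].replicon_id].append(unit)

    strand_cycle = ["+", "-"]
    placed_genes = 0
    for r in replicons:
        cursor = cursors[r.replicon_id]
        for kind, i in per_replicon[r.replicon_id]:
            gap = int(rng.integers(20, 200))
            cursor += gap
            if kind == "gene":
                gene_id = f"gene_{i + 1:04d}"
                # deterministic strand for the first two genes, random after,
                # so both strands are always populated
                if placed_genes < 2:
                    strand = strand_cycle[placed_genes]
                else:
                    strand = "+" if rng.random() < 0.5 else "-"
                placed_genes += 1
                has_5utr = rng.random() < config.utr_fraction
                has_3utr = rng.random() < config.utr_fraction
                len_5 = int(rng.integers(30, 81)) if has_5utr else 0
                len_3 = int(rng.integers(30, 81)) if has_3utr else 0
                len_cds = int(rng.integers(100, 301)) * 3
                total = len_5 + len_cds + len_3
                if cursor + total - 1 > r.length:
                    raise ValueError(
                        f"genome too short for requested features on {r.replicon_id}"
                    )
                if strand == "+":
                    pos = cursor
                    if has_5utr:
                        features.append(Feature(r.replicon_id, strand, pos,
                                                pos + len_5 - 1, "five_prime_UTR",
                                                f"{gene_id}_5utr"))
                        pos += len_5
                    features.append(Feature(r.replicon_id, strand, pos,
                                            pos + len_cds - 1, "CDS", gene_id))
                    pos += len_cds
                    if has_3utr:
                        features.append(Feature(r.replicon_id, strand, pos,
                                                pos + len_3 - 1, "three_prime_UTR",
                                                f"{gene_id}_3utr"))
                else:
                    pos = cursor
                    if has_3utr:
                        features.append(Feature(r.replicon_id, strand, pos,
                                                pos + len_3 - 1, "three_prime_UTR",
                                                f"{gene_id}_3utr"))
                        pos += len_3
                    features.append(Feature(r.replicon_id, strand, pos,
                                            pos + len_cds - 1, "CDS", gene_id))
                    pos += len_cds
                    if has_5utr:
                        features.append(Feature(r.replicon_id, strand, pos,
                                                pos + len_5 - 1, "five_prime_UTR",
                                                f"{gene_id}_5utr"))
                cursor += total
            else:
                length = int(rng.integers(60, 201)) if kind == "sRNA" else 1500
                strand = "+" if rng.random() < 0.5 else "-"
                if cursor + length - 1 > r.length:
                    raise ValueError(
                        f"genome too short for requested features on {r.replicon_id}"
                    )
                features.append(Feature(r.replicon_id, strand, cursor,
                                        cursor + length - 1, kind,
                                        f"{kind.lower()}_{i + 1:04d}"))
                cursor += length
    return features


def _transcript_five_prime(feature: Feature) -> int:
    return feature.start if feature.strand == "+" else feature.end


def implant_sites(
    config: SimConfig,
    features: Sequence[Feature],
    genome: dict[str, GenomeIndex],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, GenomeIndex]]:
    """Place ground-truth sites and stamp an AU context into cleavage sites.

    Cleavage sites are uniform within transcribed features; enriched sites
    prefer transcript 5' ends.  All implanted sites keep a minimum pairwise
    distance and stay clear of replicon edges.  The genome is edited so that
    transcript-orientation offsets 0/+1 of a cleavage site carry A/T bases
    with the configured probability (emulating the AU-rich cleavage context
    in a GC-rich background).
    """
    hosts = [f for f in features if f.type in
             ("CDS", "five_prime_UTR", "three_prime_UTR", "sRNA")]
    if not hosts:
        raise ValueError("no features available to host sites")
    lengths = np.array([f.length for f in hosts], dtype=float)
    weights = lengths / lengths.sum()
    edge = 8  # keep flank-6 windows extractable

    taken: dict[str, list[int]] = {rid: [] for rid in genome}
    rows = []

    def place(target_class: str, n_sites: int, effect: float) -> None:
        stale = 0
        placed = 0
        while placed < n_sites:
            stale += 1
            if stale > 5000:
                raise ValueError(
                    "feature space too small for the requested number of sites"
                )
            if target_class == ENRICHED and rng.random() < config.enriched_at_5prime_prob:
                f = hosts[int(rng.integers(len(hosts)))]
                pos = _transcript_five_prime(f)
            else:
                f = hosts[int(rng.choice(len(hosts), p=weights))]
                pos = int(rng.integers(f.start, f.end + 1))
            length = genome[f.replicon].length
            if pos < 1 + edge or pos > length - edge:
                continue
            nearby = taken[f.replicon]
            if any(abs(pos - q) < config.min_site_distance for q in nearby):
                continue
            nearby.append(pos)
            stale = 0
            mean = float(config.site_mean * np.exp(rng.normal(0.0, 0.3)))
            rows.append(
                {
                    "replicon": f.replicon,
                    "strand": f.strand,
                    "position": pos,
                    "class": target_class,
                    "log2_effect": effect,
                    "site_mean": mean,
                }
            )
            placed += 1

    place(CLEAVAGE, config.n_cleavage_sites, config.cleavage_log2_effect)
    place(ENRICHED, config.n_enriched_sites, config.enriched_log2_effect)
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)

    # stamp AU context at offsets 0/+1 (transcript orientation) of cleavage sites
    complement = {"A": "T", "T": "A"}
    editable = {rid: list(g.sequence) for rid, g in genome.items()}
    for row in truth[truth["class"] == CLEAVAGE].itertuples(index=False):
        if rng.random() >= config.au_motif_probability:
            continue
        for offset in (0, 1):
            base = "A" if rng.random() < 0.5 else "T"
            if row.strand == "+":
                editable[row.replicon][row.position - 1 + offset] = base
            else:
                editable[row.replicon][row.position - 1 - offset] = complement[base]
    edited = {
        rid: GenomeIndex(rid, g.length, "".join(editable[rid]))
        for rid, g in genome.items()
    }
    return truth, edited


def _nb_sample(
    rng: np.random.Generator, means: np.ndarray, alpha: float
) -> np.ndarray:
    """NB(mean, dispersion alpha) samples; Poisson in the alpha -> 0 limit."""
    means = np.asarray(means, dtype=float)
    if alpha <= 1e-12:
        return rng.poisson(means)
    n = 1.0 / alpha
    p = n / (n + means)
    return rng.negative_binomial(n, p)


def simulate_counts(
    truth: pd.DataFrame,
    config: SimConfig,
    genome: Mapping[str, GenomeIndex],
    rng: np.random.Generator,
) -> PositionTable:
    """Per-position NB counts for all libraries plus a background scatter.

    Cleavage sites carry the high mean in wild-type libraries and a
    2^-effect reduced mean in the mutant; enriched sites are reversed.
    Background positions are non-differential Poisson 5' ends plus 0-2
    uniform noise counts.
    """
    libs = config.library_ids
    s = config.library_size_factors
    n_libs = len(libs)
    is_wt = np.array([config.conditions[l] == "wild_type" for l in libs])

    records: dict[tuple[str, str, int], np.ndarray] = {}
    if len(truth):
        high = truth["site_mean"].to_numpy(dtype=float)
        low = high * 2.0 ** (-truth["log2_effect"].to_numpy(dtype=float))
        cleavage = (truth["class"] == CLEAVAGE).to_numpy()
        wt_mean = np.where(cleavage, high, low)
        mut_mean = np.where(cleavage, low, high)
        means = np.where(is_wt[None, :], wt_mean[:, None], mut_mean[:, None]) * s[None, :]
        counts = _nb_sample(rng, means, config.dispersion)
        for i, row in enumerate(truth.itertuples(index=False)):
            records[(row.replicon, row.strand, int(row.position))] = counts[i]

    # non-differential background scatter
    truth_pos = {
        rid: set(truth.loc[truth["replicon"] == rid, "position"]) for rid in genome
    }
    for rid, g in genome.items():
        n_bg = int(round(g.length * config.background_rate))
        if n_bg == 0:
            continue
        positions = rng.integers(1, g.length + 1, size=n_bg)
        strands = np.where(rng.random(n_bg) < 0.5, "+", "-")
        bg_means = rng.gamma(shape=1.5, scale=15.0, size=n_bg) + 1.0
        for pos, strand, mu in zip(positions, strands, bg_means):
            pos = int(pos)
            if any(abs(pos - t) < 5 for t in truth_pos[rid]):
                continue
            key = (rid, str(strand), pos)
            if key in records:
                continue
            counts = rng.poisson(mu * s) + rng.integers(0, 3, size=n_libs)
            records[key] = counts

    if not records:
        index = pd.MultiIndex.from_tuples([], names=ROW_INDEX_NAMES)
        return PositionTable(
            pd.DataFrame(columns=libs, index=index, dtype="int64"),
            config.conditions,
        )
    index = pd.MultiIndex.from_tuples(list(records), names=ROW_INDEX_NAMES)
    frame = pd.DataFrame(
        np.vstack(list(records.values())), index=index, columns=libs, dtype="int64"
    )
    frame = frame[frame.sum(axis=1) > 0].sort_index()
    return PositionTable(frame, config.conditions)


@dataclass
class SimBundle:
    config: SimConfig
    genome: dict[str, GenomeIndex]
    features: list[Feature]
    truth: pd.DataFrame
    table: PositionTable


def simulate_experiment(config: SimConfig) -> SimBundle:
    """Run the full generator chain deterministically from config.seed."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    features = simulate_annotation(config, genome, rng)
    truth, genome = implant_sites(config, features, genome, rng)
    table = simulate_counts(truth, config, genome, rng)
    return SimBundle(config, genome, features, truth, table)


def tracks_from_table(
    table: PositionTable, genome: Mapping[str, GenomeIndex]
) -> dict[str, dict[str, list[CoverageTrack]]]:
    """Rebuild per-(library, strand) coverage tracks from a PositionTable."""
    out: dict[str, dict[str, list[CoverageTrack]]] = {}
    for lib in table.library_ids:
        out[lib] = {}
        for strand in "+-":
            tracks = []
            for rid in genome:
                track = CoverageTrack(lib, rid, strand)
                try:
                    sub = table.counts.xs((rid, strand), level=("replicon", "strand"))
                except KeyError:
                    sub = None
                if sub is not None:
                    for pos, count in sub[lib].items():
                        if count:
                            track.counts[int(pos)] = int(count)
                tracks.append(track)
            out[lib][strand] = tracks
    return out


def evaluate_recovery(
    clusters: Sequence[SiteCluster],
    truth: pd.DataFrame,
    tolerance: int = 2,
) -> dict[str, dict]:
    """Greedy one-to-one matching of cluster centers to truth sites per class.

    A truth site is recovered iff a same-class cluster center on the same
    replicon and strand lies within `tolerance` nt.  With zero calls the
    precision denominator is empty; it is reported as 1.0 and flagged.
    """
    report: dict[str, dict] = {}
    for site_class in (CLEAVAGE, ENRICHED):
        truth_rows = truth[truth["class"] == site_class]
        calls = [c for c in clusters if c.site_class == site_class]
        pairs = []
        for ti, row in enumerate(truth_rows.itertuples(index=False)):
            for ci, c in enumerate(calls):
                if c.replicon == row.replicon and c.strand == row.strand:
                    offset = c.center - int(row.position)
                    if abs(offset) <= tolerance:
                        pairs.append((abs(offset), ti, ci, offset))
        pairs.sort()
        matched_truth: set[int] = set()
        matched_calls: set[int] = set()
        offsets = []
        for _, ti, ci, offset in pairs:
            if ti in matched_truth or ci in matched_calls:
                continue
            matched_truth.add(ti)
            matched_calls.add(ci)
            offsets.append(offset)
        n_truth, n_calls = len(truth_rows), len(calls)
        n_matched = len(matched_truth)
        report[site_class] = {
            "n_truth": n_truth,
            "n_called": n_calls,
            "n_matched": n_matched,
            "recall": n_matched / n_truth if n_truth else 0.0,
            "precision": n_matched / n_calls if n_calls else 1.0,
            "precision_undefined": n_calls == 0,
            "offset_histogram": dict(Counter(offsets)),
        }
    return report


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
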