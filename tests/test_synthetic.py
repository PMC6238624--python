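import numpy as np
import pandas as pd
import pytest

from tierseq.annotation import parse_gff, write_gff
from tierseq.coverage import read_fasta, read_wiggle, write_fasta, write_wiggle
from tierseq.sitecalling import SiteCluster
from tierseq.synthetic import (
    SimConfig,
    evaluate_recovery,
    implant_sites,
    simulate_annotation,
    simulate_counts,
    simulate_experiment,
    simulate_genome,
    tracks_from_table,
)


def rng(seed=0):
    return np.random.default_rng(seed)


def call(position, site_class="cleavage", strand="+", replicon="repl_1"):
    return SiteCluster(
        replicon=replicon, strand=strand, members=(position,), center=position,
        site_class=site_class, padj_min=0.001, base_mean_max=40.0,
    )


class TestGenome:
    def test_gc_content(self):
        config = SimConfig(genome_length=100_000)
        genome = simulate_genome(config, rng(1))
        seq = genome["repl_1"].sequence
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.688) < 0.01

    def test_extreme_gc(self):
        config = SimConfig(genome_length=2000, gc_content=1.0)
        seq = simulate_genome(config, rng(2))["repl_1"].sequence
        assert set(seq) <= {"G", "C"}

    def test_determinism(self):
        config = SimConfig(genome_length=5000)
        a = simulate_genome(config, rng(3))["repl_1"].sequence
        b = simulate_genome(config, rng(3))["repl_1"].sequence
        assert a == b

    def test_invalid_gc(self):
        with pytest.raises(ValueError):
            SimConfig(gc_content=1.5)


class TestAnnotation:
    config = SimConfig(genome_length=200_000, n_genes=50)

    def test_gene_count_and_no_overlap(self):
        genome = simulate_genome(self.config, rng(4))
        features = simulate_annotation(self.config, genome, rng(4))
        cds = [f for f in features if f.type == "CDS"]
        assert len(cds) == 50
        ordered = sorted(features, key=lambda f: (f.replicon, f.start))
        for a, b in zip(ordered, ordered[1:]):
            if a.replicon == b.replicon:
                assert a.end < b.start

    def test_both_strands_populated(self):
        genome = simulate_genome(self.config, rng(5))
        features = simulate_annotation(self.config, genome, rng(5))
        strands = {f.strand for f in features if f.type == "CDS"}
        assert strands == {"+", "-"}

    def test_no_utrs_when_fraction_zero(self):
        config = SimConfig(genome_length=200_000, n_genes=30, utr_fraction=0.0)
        genome = simulate_genome(config, rng(6))
        features = simulate_annotation(config, genome, rng(6))
        assert not any("UTR" in f.type for f in features)

    def test_too_short_genome_errors(self):
        config = SimConfig(genome_length=3000, n_genes=50)
        genome = simulate_genome(config, rng(7))
        with pytest.raises(ValueError, match="too short"):
            simulate_annotation(config, genome, rng(7))


class TestImplant:
    def bundle_parts(self, **kw):
        config = SimConfig(genome_length=150_000, n_genes=60, **kw)
        r = rng(config.seed)
        genome = simulate_genome(config, r)
        features = simulate_annotation(config, genome, r)
        truth, edited = implant_sites(config, features, genome, r)
        return config, features, truth, edited

    def test_requested_counts(self):
        _, _, truth, _ = self.bundle_parts(n_cleavage_sites=80, n_enriched_sites=40)
        assert (truth["class"] == "cleavage").sum() == 80
        assert (truth["class"] == "enriched").sum() == 40

    def test_au_stamp_with_probability_one(self):
        _, _, truth, genome = self.bundle_parts(
            n_cleavage_sites=60, n_enriched_sites=0, au_motif_probability=1.0
        )
        for row in truth.itertuples(index=False):
            seq = genome[row.replicon].sequence
            if row.strand == "+":
                pair = seq[row.position - 1 : row.position + 1]
            else:
                pair = seq[row.position - 2 : row.position]
            assert set(pair) <= {"A", "T"}

    def test_min_pairwise_distance(self):
        config, _, truth, _ = self.bundle_parts(
            n_cleavage_sites=100, n_enriched_sites=100
        )
        for _, group in truth.groupby("replicon"):
            pos = np.sort(group["position"].to_numpy())
            assert np.all(np.diff(pos) >= config.min_site_distance)

    def test_sites_inside_features(self):
        _, features, truth, _ = self.bundle_parts(seed=9)
        spans = {}
        for f in features:
            spans.setdefault((f.replicon, f.strand), []).append((f.start, f.end))
        for row in truth.itertuples(index=False):
            assert any(
                s <= row.position <= e
                for s, e in spans[(row.replicon, row.strand)]
            )

    def test_too_many_sites_errors(self):
        with pytest.raises(ValueError, match="too small"):
            self.bundle_parts(n_cleavage_sites=50_000)


class TestCounts:
    def test_effect_size_ratio(self):
        config = SimConfig(seed=21, n_cleavage_sites=150, n_enriched_sites=0)
        bundle = simulate_experiment(config)
        wt = bundle.table.counts[["wt_1", "wt_2", "wt_3"]]
        mut = bundle.table.counts[["mut_1", "mut_2", "mut_3"]]
        keys = pd.MultiIndex.from_frame(
            bundle.truth[["replicon", "strand", "position"]]
        )
        ratio = mut.loc[keys].to_numpy().mean() / wt.loc[keys].to_numpy().mean()
        expected = 2.0 ** (-2.5)
        assert abs(ratio - expected) <= 0.2 * expected

    def test_size_factor_scaling(self):
        config = SimConfig(
            seed=22, n_cleavage_sites=200, n_enriched_sites=200,
            size_factors=(2.0, 1.0, 1.0, 1.0, 1.0, 1.0), background_rate=0.0,
        )
        bundle = simulate_experiment(config)
        totals = bundle.table.counts.sum()
        assert abs(totals["wt_1"] / totals["wt_2"] - 2.0) <= 0.2

    def test_poisson_limit(self):
        config = SimConfig(seed=23, dispersion=0.0, n_cleavage_sites=300,
                           n_enriched_sites=0, background_rate=0.0,
                           size_factors=(1.0,))
        bundle = simulate_experiment(config)
        wt = bundle.table.counts[["wt_1", "wt_2", "wt_3"]].to_numpy(dtype=float)
        # variance-to-mean ratio across sites should hover near 1 (Poisson)
        means = wt.mean(axis=1)
        ok = means > 20
        vmr = (wt.var(axis=1, ddof=1)[ok] / means[ok]).mean()
        assert 0.7 <= vmr <= 1.3

    def test_determinism_byte_identical(self, tmp_path):
        config = SimConfig(seed=31, genome_length=30_000, n_genes=20,
                           n_cleavage_sites=30, n_enriched_sites=30)
        outputs = []
        for run in ("a", "b"):
            bundle = simulate_experiment(config)
            d = tmp_path / run
            d.mkdir()
            write_fasta(bundle.genome, d / "genome.fa")
            write_gff(bundle.features, d / "ann.gff3")
            bundle.truth.to_csv(d / "truth.tsv", sep="\t", index=False)
            tracks = tracks_from_table(bundle.table, bundle.genome)
            write_wiggle(tracks["wt_1"]["+"], d / "wt1_fwd.wig")
            outputs.append(
                tuple((d / n).read_bytes()
                      for n in ("genome.fa", "ann.gff3", "truth.tsv", "wt1_fwd.wig"))
            )
        assert outputs[0] == outputs[1]


class TestInterfaceConformance:
    def test_generated_files_parse_cleanly(self, tmp_path, default_bundle):
        bundle = default_bundle
        write_fasta(bundle.genome, tmp_path / "genome.fa")
        genome = read_fasta(tmp_path / "genome.fa")
        assert genome.keys() == bundle.genome.keys()
        assert genome["repl_1"].sequence == bundle.genome["repl_1"].sequence

        write_gff(bundle.features, tmp_path / "ann.gff3")
        features = parse_gff(tmp_path / "ann.gff3")
        assert features == bundle.features

        tracks = tracks_from_table(bundle.table, bundle.genome)
        write_wiggle(tracks["mut_2"]["-"], tmp_path / "m2.wig")
        (back,) = read_wiggle(tmp_path / "m2.wig")
        assert back.strand == "-"
        assert back.counts == tracks["mut_2"]["-"][0].counts


class TestEvaluateRecovery:
    truth = pd.DataFrame(
        {
            "replicon": ["repl_1"] * 3,
            "strand": ["+", "+", "-"],
            "position": [100, 500, 900],
            "class": ["cleavage", "cleavage", "enriched"],
            "log2_effect": [2.5] * 3,
            "site_mean": [80.0] * 3,
        }
    )

    def test_perfect_calls(self):
        calls = [call(100), call(500), call(900, "enriched", "-")]
        report = evaluate_recovery(calls, self.truth)
        assert report["cleavage"]["precision"] == 1.0
        assert report["cleavage"]["recall"] == 1.0
        assert report["enriched"]["recall"] == 1.0

    def test_no_calls_convention(self):
        report = evaluate_recovery([], self.truth)
        assert report["cleavage"]["recall"] == 0.0
        assert report["cleavage"]["precision"] == 1.0
        assert report["cleavage"]["precision_undefined"] is True

    def test_tolerance_rule(self):
        calls = [call(103), call(503)]
        report = evaluate_recovery(calls, self.truth, tolerance=2)
        assert report["cleavage"]["recall"] == 0.0
        report = evaluate_recovery(calls, self.truth, tolerance=3)
        assert report["cleavage"]["recall"] == 1.0

    def test_one_to_one_matching(self):
        calls = [call(100), call(101)]
        report = evaluate_recovery(calls, self.truth)
        assert report["cleavage"]["n_matched"] == 1
        assert report["cleavage"]["precision"] == 0.5
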