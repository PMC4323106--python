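"""piRNA signatures: upstream motif EM, clustering, ping-pong."""

import numpy as np
import pytest

from nemasrna import pirna, sio
from nemasrna.errors import ContractError


def aln_set(entries, default_seq="U" * 21):
    """entries of (read_id, contig, start, end, strand[, sequence[, count]])."""
    alignments, seqs, counts = [], {}, {}
    for e in entries:
        rid, contig, start, end, strand = e[:5]
        seq = e[5] if len(e) > 5 else default_seq
        count = e[6] if len(e) > 6 else 1
        alignments.append(sio.Alignment(rid, contig, start, end, strand))
        seqs[rid] = sio.rna(seq)
        counts[rid] = count
    return sio.AlignmentSet(alignments, [], seqs, counts)


class TestExtractUpstream:
    GENOME = {"c": "".join("ACGT"[i % 4] for i in range(400))}

    def test_plus_strand_coordinates(self):
        aln = aln_set([("a", "c", 100, 121, "+")])
        ups = pirna.extract_upstream(aln, self.GENOME, window=60,
                                     candidate=lambda a, s: True)
        assert ups.sequences == [self.GENOME["c"][40:100]]

    def test_minus_strand_is_revcomp_downstream(self):
        aln = aln_set([("a", "c", 100, 121, "-")])
        ups = pirna.extract_upstream(aln, self.GENOME, window=60,
                                     candidate=lambda a, s: True)
        assert ups.sequences == [sio.revcomp_dna(self.GENOME["c"][121:181])]

    def test_edge_candidates_skipped(self):
        aln = aln_set([("a", "c", 10, 31, "+"), ("b", "c", 350, 371, "-")])
        ups = pirna.extract_upstream(aln, self.GENOME, window=60,
                                     candidate=lambda a, s: True)
        assert len(ups) == 0
        assert ups.n_skipped == 2

    def test_default_candidate_filter(self):
        aln = aln_set([
            ("u21", "c", 100, 121, "+", "U" * 21),
            ("g21", "c", 100, 121, "+", "G" + "U" * 20),
            ("u22", "c", 100, 122, "+", "U" * 22),
        ])
        ups = pirna.extract_upstream(aln, self.GENOME, window=60)
        assert len(ups) == 1  # only 21 nt 5'U unique


class TestDiscoverMotif:
    MOTIF = "CTGTTTCA"

    def make_upstream(self, n=120, planted_fraction=0.9, window=60, seed=5):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        seqs = []
        for i in range(n):
            s = list("".join(bases[rng.integers(0, 4, size=window)]))
            if rng.random() < planted_fraction:
                # plant at the biological offset: -47..-40 => index 13..20
                s[13:21] = list(self.MOTIF)
            seqs.append("".join(s))
        return pirna.UpstreamSet(window, seqs)

    def test_recovers_planted_motif(self):
        model = pirna.discover_motif(self.make_upstream(), seed=0)
        assert model.consensus_matches(self.MOTIF) >= 7

    def test_deterministic(self):
        ups = self.make_upstream()
        a = pirna.discover_motif(ups, seed=0)
        b = pirna.discover_motif(ups, seed=0)
        assert np.array_equal(a.pwm, b.pwm)
        assert a.log_likelihood == b.log_likelihood

    def test_null_information_below_planted(self):
        planted = pirna.discover_motif(self.make_upstream(), seed=0)
        null = pirna.discover_motif(
            self.make_upstream(planted_fraction=0.0), seed=0
        )
        assert planted.information_content > null.information_content
        assert planted.information_content > 8.0  # strong 8-mer signal

    def test_requires_twenty_sequences(self):
        with pytest.raises(ContractError):
            pirna.discover_motif(self.make_upstream(n=10))

    def test_width_longer_than_window_rejected(self):
        ups = pirna.UpstreamSet(6, ["ACGTAC"] * 25)
        with pytest.raises(ContractError):
            pirna.discover_motif(ups, width=8)

    def test_meme_and_tsv_output(self, tmp_path):
        model = pirna.discover_motif(self.make_upstream(), seed=0)
        pirna.write_motif_meme(model, tmp_path / "m.meme")
        pirna.write_motif_tsv(model, tmp_path / "m.tsv")
        text = (tmp_path / "m.meme").read_text()
        assert "MEME version 4" in text and "w= 8" in text


class TestClusterDensity:
    GENOME = {"c1": "A" * 100_000, "c2": "A" * 100_000}

    def test_uniform_reads_not_flagged(self):
        # one read per 10 kb window
        entries = [
            (f"r{c}{i}", c, i * 10_000 + 5, i * 10_000 + 26, "+")
            for c in ("c1", "c2") for i in range(10)
        ]
        prof = pirna.cluster_density(aln_set(entries), self.GENOME,
                                     window_size=10_000)
        assert prof.flagged_fraction == 0.0
        assert prof.mean_density == 1.0

    def test_concentrated_reads_flagged(self):
        # 95 reads in one window, 5 spread out: mean = 100/20 = 5,
        # threshold 10x mean = 50 < 95
        entries = [(f"h{i}", "c1", 100 + i, 121 + i, "+") for i in range(95)]
        entries += [
            (f"u{i}", "c2", i * 20_000 + 5, i * 20_000 + 26, "+")
            for i in range(5)
        ]
        prof = pirna.cluster_density(aln_set(entries), self.GENOME,
                                     window_size=10_000)
        assert prof.flagged_fraction == pytest.approx(0.95)

    def test_count_weighting(self):
        entries = [("a", "c1", 5, 26, "+", "U" * 21, 90),
                   ("b", "c2", 5, 26, "+", "U" * 21, 10)]
        prof = pirna.cluster_density(aln_set(entries), self.GENOME,
                                     window_size=10_000, weight="count")
        assert prof.window_counts["c1"][0] == 90
        assert prof.total_reads == 100

    def test_order_invariance(self):
        entries = [(f"r{i}", "c1", 100 * i + 5, 100 * i + 26, "+")
                   for i in range(50)]
        a = pirna.cluster_density(aln_set(entries), self.GENOME)
        b = pirna.cluster_density(aln_set(entries[::-1]), self.GENOME)
        assert a.flagged_fraction == b.flagged_fraction
        assert np.array_equal(
            np.sort(a.per_read_densities), np.sort(b.per_read_densities)
        )

    def test_compare_density_identical_and_separated(self):
        uniform = [(f"u{i}", "c1", i * 1000 + 5, i * 1000 + 26, "+")
                   for i in range(100)]
        clustered = [(f"h{i}", "c1", 100 + i, 121 + i, "+")
                     for i in range(100)]
        pu = pirna.cluster_density(aln_set(uniform), self.GENOME,
                                   window_size=10_000)
        pc = pirna.cluster_density(aln_set(clustered), self.GENOME,
                                   window_size=10_000)
        d_same, p_same = pirna.compare_density(pu, pu)
        assert d_same == 0.0 and p_same == 1.0
        d, p = pirna.compare_density(pu, pc)
        assert p < 1e-6

    def test_compare_density_matches_ecdf_oracle(self):
        rng = np.random.default_rng(3)
        uniform = [
            (f"u{i}", "c1", int(p), int(p) + 21, "+")
            for i, p in enumerate(rng.integers(0, 99_000, size=200))
        ]
        clustered = [
            (f"h{i}", "c1", int(p), int(p) + 21, "+")
            for i, p in enumerate(rng.integers(0, 5_000, size=200))
        ]
        pu = pirna.cluster_density(aln_set(uniform), self.GENOME,
                                   window_size=10_000)
        pc = pirna.cluster_density(aln_set(clustered), self.GENOME,
                                   window_size=10_000)
        d, _ = pirna.compare_density(pu, pc)
        # brute-force KS statistic over the pooled support
        x, y = pu.per_read_densities, pc.per_read_densities
        support = np.unique(np.concatenate([x, y]))
        ecdf_d = max(
            abs((x <= v).mean() - (y <= v).mean()) for v in support
        )
        assert d == pytest.approx(ecdf_d)

    def test_generator_21u_clustering(self, aln_indep, clade_v_genome):
        sub = aln_indep.subset(lambda a, s: a.length == 21 and s.startswith("U"))
        # 1 kb windows: sized to the 50 kb fixture contigs the same way
        # the pipeline sizes 2 kb windows to its 100 kb contigs
        prof = pirna.cluster_density(sub, clade_v_genome, window_size=1000,
                                     weight="count")
        assert prof.flagged_fraction > 0.3

    def test_bedgraph_output(self, tmp_path):
        entries = [("a", "c1", 5, 26, "+")]
        prof = pirna.cluster_density(aln_set(entries), self.GENOME,
                                     window_size=50_000)
        pirna.write_bedgraph(prof, self.GENOME, tmp_path / "c.bedgraph")
        lines = (tmp_path / "c.bedgraph").read_text().splitlines()
        assert lines[0] == "c1\t0\t50000\t1"


class TestPingPong:
    def test_ten_overlap_example(self):
        # + 5' at 100, - 5' at 109: k = 109 - 100 + 1 = 10
        aln = aln_set([
            ("p", "c", 100, 121, "+", "U" * 9 + "A" + "U" * 11),
            ("m", "c", 89, 110, "-"),
        ])
        hist = pirna.ping_pong(aln)
        assert hist.counts[10] == 1
        assert hist.counts.drop(10).sum() == 0
        assert hist.tenth_a_fraction == 1.0
        assert hist.n_pairs_10 == 1

    def test_same_strand_gives_nothing(self):
        aln = aln_set([("a", "c", 100, 121, "+"), ("b", "c", 109, 130, "+")])
        hist = pirna.ping_pong(aln)
        assert hist.counts.sum() == 0

    def test_distinct_coordinate_pairs_count_once(self):
        # two + reads sharing one 5' coordinate count as one pair
        aln = aln_set([
            ("p1", "c", 100, 121, "+"),
            ("p2", "c", 100, 122, "+"),
            ("m", "c", 89, 110, "-"),
        ])
        assert pirna.ping_pong(aln).counts[10] == 1

    def test_tenth_a_from_five_prime_most_read(self):
        aln = aln_set([
            ("p", "c", 100, 121, "+", "U" * 9 + "G" + "U" * 11),
            ("m", "c", 89, 110, "-"),
        ])
        assert pirna.ping_pong(aln).tenth_a_fraction == 0.0

    def test_planted_signal_z(self):
        entries = []
        for i in range(30):
            base = 1000 * (i + 1)
            entries.append((f"p{i}", "c", base, base + 21, "+"))
            entries.append((f"m{i}", "c", base - 11, base + 10, "-"))
        hist = pirna.ping_pong(aln_set(entries))
        assert hist.modal_overlap == 10
        assert hist.z_score_10 > 5 or np.isinf(hist.z_score_10)

    def test_null_z_small(self):
        rng = np.random.default_rng(9)
        entries = []
        for i, p in enumerate(rng.integers(0, 80_000, size=400)):
            strand = "+" if i % 2 else "-"
            start = int(p)
            entries.append((f"r{i}", "c", start, start + 21, strand))
        hist = pirna.ping_pong(aln_set(entries))
        assert abs(hist.z_score_10) < 3

    def test_generator_modal_overlap_and_tenth_a(self, aln_indep,
                                                 clade_v_config):
        sub = aln_indep.subset(lambda a, s: a.length == 21)
        hist = pirna.ping_pong(sub)
        assert hist.modal_overlap == 10
        assert hist.z_score_10 > 10
        p = clade_v_config.pingpong_tenth_A_prob
        sd = np.sqrt(p * (1 - p) / hist.n_pairs_10)
        assert abs(hist.tenth_a_fraction - p) < 3 * sd + 0.02
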