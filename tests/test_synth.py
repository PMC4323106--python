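"""Generator contracts: planted structure, class mix, protocol filtering."""

import numpy as np
import pandas as pd
import pytest

from nemasrna import sio, synth
from nemasrna.errors import ParameterError


class TestConfig:
    def test_weights_must_sum_to_one(self):
        cfg = synth.TruthConfig(class_weights={"mirna": 0.5, "background": 0.4})
        with pytest.raises(ParameterError):
            cfg.validate()

    def test_unknown_class_rejected(self):
        cfg = synth.TruthConfig(class_weights={"nope": 1.0})
        with pytest.raises(ParameterError):
            cfg.validate()

    def test_presets_validate(self):
        for preset in (synth.clade_v_config, synth.clade_iii_config,
                       synth.clade_i_config):
            preset(seed=1).validate()

    def test_rng_salting_is_independent(self):
        cfg = synth.TruthConfig(seed=5)
        a = cfg.rng(1).integers(0, 1 << 30, size=4)
        b = cfg.rng(2).integers(0, 1 << 30, size=4)
        assert not np.array_equal(a, b)
        assert np.array_equal(a, cfg.rng(1).integers(0, 1 << 30, size=4))


class TestMakeGenome:
    def test_repeat_copy_counts_and_no_overlap(self, clade_v_genome):
        fams = pd.Series([r.family for r in clade_v_genome.repeats])
        assert fams.value_counts().to_dict() == {"TE1": 20, "TE2": 20}
        by_contig = {}
        for r in clade_v_genome.repeats:
            by_contig.setdefault(r.contig, []).append((r.start, r.end))
        for ivs in by_contig.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_zero_divergence_copies_identical(self):
        cfg = synth.clade_v_config(seed=3)
        genome = synth.make_genome(
            cfg, contig_length=30_000,
            repeat_spec=(("TE1", "LTR", 500, 10, 0.0),),
        )
        seqs = set()
        for r in genome.repeats:
            s = genome.contigs[r.contig][r.start : r.end]
            if r.strand == "-":
                s = synth._revcomp(s)
            seqs.add(s)
        assert len(seqs) == 1

    def test_divergence_rate_recovered(self):
        cfg = synth.clade_v_config(seed=3)
        div = 0.1
        genome = synth.make_genome(
            cfg, contig_length=40_000,
            repeat_spec=(("TE1", "LTR", 1000, 12, div),),
        )
        # consensus unknown; per-site majority across copies approximates it
        copies = []
        for r in genome.repeats:
            s = genome.contigs[r.contig][r.start : r.end]
            if r.strand == "-":
                s = synth._revcomp(s)
            copies.append(s)
        arr = np.array([list(c) for c in copies])
        consensus = np.apply_along_axis(
            lambda col: pd.Series(col).mode()[0], 0, arr
        )
        mismatch = (arr != consensus[None, :]).mean()
        n = arr.size
        sd = np.sqrt(div * (1 - div) / n)
        assert abs(mismatch - div) < 3 * sd + 0.01  # consensus error slack

    def test_pirna_loci_have_5U_and_motif(self, clade_v_genome, clade_v_config):
        motif = clade_v_config.motif
        off = clade_v_config.motif_offset
        for contig, pos, strand in clade_v_genome.pirna_loci[:50]:
            seq = clade_v_genome.contigs[contig]
            if strand == "+":
                assert seq[pos] == "T"
                assert seq[pos + off : pos + off + len(motif)] == motif
            else:
                assert seq[pos] == "A"  # T on the minus strand
                mstart = pos - off - len(motif) + 1
                assert seq[mstart : mstart + len(motif)] == synth._revcomp(motif)

    def test_determinism(self, clade_v_config, clade_v_genome):
        again = synth.make_genome(clade_v_config, n_contigs=2,
                                  contig_length=50_000)
        assert again.contigs == clade_v_genome.contigs
        assert again.repeats == clade_v_genome.repeats

    def test_contig_too_short_for_repeats(self):
        with pytest.raises(ParameterError):
            synth.make_genome(synth.clade_v_config(), contig_length=5_000)


class TestSimulateLibrary:
    def test_dependent_protocol_removes_triphosphate(self, clade_v_libs):
        (lib_dep, truth_dep), _ = clade_v_libs
        assert not (truth_dep.table["phosphate"] == "tri").any()
        assert lib_dep.total_input_count == 40_000

    def test_independent_keeps_class_mix(self, clade_v_libs, clade_v_config):
        _, (lib_indep, truth) = clade_v_libs
        n = lib_indep.total_input_count
        per_class = truth.table.groupby("class")["count"].sum()
        for cls, w in clade_v_config.class_weights.items():
            if w == 0:
                assert cls not in per_class.index
                continue
            sd = np.sqrt(n * w * (1 - w))
            assert abs(per_class[cls] - n * w) <= 3 * sd

    def test_class_defining_reads(self, clade_v_libs):
        _, (lib_indep, truth) = clade_v_libs
        seqs = {r.id: r.sequence for r in lib_indep.reads}
        t = truth.table
        pirna = t[t["class"] == "pirna21U"]
        assert (pirna["read_id"].map(lambda i: len(seqs[i])) == 21).all()
        assert (pirna["read_id"].map(lambda i: seqs[i][0]) == "U").all()
        sirna = t[t["class"] == "sirna22G"]
        assert (sirna["read_id"].map(lambda i: len(seqs[i])) == 22).all()
        assert (sirna["read_id"].map(lambda i: seqs[i][0]) == "G").all()
        assert (sirna["phosphate"] == "tri").all()

    def test_lengths_in_range(self, clade_v_libs):
        _, (lib_indep, _) = clade_v_libs
        assert all(15 <= len(r) <= 33 for r in lib_indep.reads)

    def test_reads_match_genome(self, clade_v_genome, clade_v_libs):
        """Truth coordinates reproduce each read from the genome."""
        _, (lib_indep, truth) = clade_v_libs
        seqs = {r.id: r.sequence for r in lib_indep.reads}
        sample = truth.table.sample(200, random_state=0)
        for _, row in sample.iterrows():
            expected, _, _ = synth._read_at(
                clade_v_genome, row["contig"], row["position"], row["strand"],
                len(seqs[row["read_id"]]),
            )
            assert seqs[row["read_id"]] == expected

    def test_determinism(self, clade_v_genome, clade_v_config, clade_v_libs):
        _, (lib_indep, truth) = clade_v_libs
        lib2, truth2 = synth.simulate_library(
            clade_v_genome, clade_v_config,
            sio.LibraryProtocol(five_prime_dependent=False), 40_000,
        )
        assert lib2.reads == lib_indep.reads
        pd.testing.assert_frame_equal(truth2.table, truth.table)

    def test_periodate_removes_only_unmethylated(self, clade_v_genome,
                                                  clade_v_config):
        lib, truth = synth.simulate_library(
            clade_v_genome, clade_v_config,
            sio.LibraryProtocol(five_prime_dependent=False,
                                treatment="periodate"), 10_000,
        )
        assert truth.table["methyl3p"].all()
        # only methylated classes survive
        assert set(truth.table["class"]) <= {"pirna21U", "pingpong_pair"}

    def test_apply_protocol_idempotent(self, clade_v_genome, clade_v_config):
        protocol = sio.LibraryProtocol(five_prime_dependent=True)
        lib, truth = synth.simulate_library(
            clade_v_genome, clade_v_config,
            sio.LibraryProtocol(five_prime_dependent=False), 10_000,
        )
        once = synth.apply_protocol(lib, truth, protocol)
        twice = synth.apply_protocol(*once, protocol)
        assert twice[0].reads == once[0].reads
        pd.testing.assert_frame_equal(twice[1].table, once[1].table)


class TestSimulateBisulfite:
    def test_row_count_covers_all_cytosines(self, clade_v_genome,
                                            clade_v_config):
        table = synth.simulate_bisulfite(clade_v_genome, clade_v_config)
        n_sites = sum(
            seq.count("C") + seq.count("G")
            for seq in clade_v_genome.contigs.values()
        )
        assert len(table) == n_sites
        assert (table.sites["total"] == clade_v_config.coverage).all()

    def test_zero_levels_give_zero_unconverted(self, clade_v_genome):
        cfg = synth.clade_v_config(
            seed=11, meth_repeat_level=0.0, meth_background_level=0.0
        )
        table = synth.simulate_bisulfite(clade_v_genome, cfg)
        assert (table.sites["unconverted"] == 0).all()

    def test_repeat_sites_near_planted_level(self, clade_v_genome,
                                             clade_v_config):
        table = synth.simulate_bisulfite(clade_v_genome, clade_v_config)
        in_repeat = np.zeros(len(table.sites), dtype=bool)
        pos = table.sites["position"].to_numpy()
        contig = table.sites["contig"].to_numpy()
        for rep in clade_v_genome.repeats:
            in_repeat |= (contig == rep.contig) & (pos >= rep.start) & (
                pos < rep.end
            )
        elevated = in_repeat.copy()  # methylated genes are elevated too
        for g in clade_v_genome.genes:
            if g.methylated:
                elevated |= (contig == g.contig) & (pos >= g.start) & (
                    pos < g.end
                )
        frac = table.sites["unconverted"] / table.sites["total"]
        assert abs(frac[in_repeat].mean() - clade_v_config.meth_repeat_level) < 0.05
        assert frac[~elevated].mean() < 0.1


class TestMakeProteomes:
    def test_zero_distance_identity_and_truth(self):
        cfg = synth.clade_v_config(seed=2)
        proteomes, ancestors, truth = synth.make_proteomes(
            cfg, {"sp1": 0.0}, n_proteins=5, protein_length=60
        )
        for pid, seq in ancestors.items():
            assert proteomes["sp1"][f"sp1_{pid}"] == seq
        assert truth.all().all()

    def test_loss_pattern_and_decoys(self):
        cfg = synth.clade_v_config(seed=2)
        proteomes, _, truth = synth.make_proteomes(
            cfg, {"sp1": 0.1, "sp2": 0.1}, n_proteins=4,
            loss_pattern={("P0002", "sp2"): "absent"},
            n_decoys=3, protein_length=60,
        )
        assert "sp2_P0002" not in proteomes["sp2"]
        assert "sp1_P0002" in proteomes["sp1"]
        assert not truth.loc["P0002", "sp2"]
        assert truth.drop(index="P0002").all().all()
        assert sum(1 for k in proteomes["sp1"] if "decoy" in k) == 3

    def test_unknown_loss_reference_rejected(self):
        cfg = synth.clade_v_config(seed=2)
        with pytest.raises(ParameterError):
            synth.make_proteomes(
                cfg, {"sp1": 0.1}, n_proteins=2,
                loss_pattern={("P0009", "sp1"): "absent"},
            )

    def test_divergence_monotone_in_distance(self):
        cfg = synth.clade_v_config(seed=2)
        proteomes, ancestors, _ = synth.make_proteomes(
            cfg, {"near": 0.1, "far": 1.5}, n_proteins=6, protein_length=200
        )

        def identity(sp):
            vals = []
            for pid, anc in ancestors.items():
                evo = proteomes[sp][f"{sp}_{pid}"]
                vals.append(np.mean([a == b for a, b in zip(anc, evo)]))
            return np.mean(vals)

        assert identity("near") > identity("far")


class TestWriters:
    def test_genome_and_truth_round_trip(self, tmp_path, clade_v_genome,
                                         clade_v_libs):
        from Bio import SeqIO

        synth.write_genome_fasta(clade_v_genome, tmp_path / "g.fa")
        back = {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(tmp_path / "g.fa"), "fasta")
        }
        assert back == clade_v_genome.contigs

        _, (_, truth) = clade_v_libs
        synth.write_truth_tsv(truth, tmp_path / "t.tsv")
        df = pd.read_csv(tmp_path / "t.tsv", sep="\t")
        assert len(df) == len(truth.table)

    def test_bed_to_gff3(self, tmp_path, clade_v_genome):
        synth.write_repeats_bed(clade_v_genome.repeats, tmp_path / "r.bed")
        synth.bed_to_gff3(tmp_path / "r.bed", tmp_path / "r.gff3")
        lines = (tmp_path / "r.gff3").read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        first = lines[1].split("\t")
        rep = clade_v_genome.repeats[0]
        assert int(first[3]) == rep.start + 1 and int(first[4]) == rep.end
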