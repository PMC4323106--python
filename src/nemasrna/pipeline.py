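"""End-to-end orchestration of the synthetic analysis pipeline.

A single run configuration (YAML-friendly mapping) drives the stages in
dependency order: simulate -> trim -> align -> profile / pirna / tesirna
/ meth / homology. Each stage writes its tables under the output
directory and contributes verdicts to a machine-readable summary
(``summary.json``): triphosphate population present?, upstream motif
found (and its consensus), ping-pong z-score, modal duplex overhang,
jackknife p, methylation enrichment p-values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np

from . import homology, meth, mircons, pirna, profiles, sio, synth, tesirna
from .errors import ParameterError

log = logging.getLogger("nemasrna")

ALL_STAGES = ("simulate", "profile", "pirna", "tesirna", "meth", "homology",
              "mircons")

PRESETS = {
    "clade_v": synth.clade_v_config,
    "clade_iii": synth.clade_iii_config,
    "clade_i": synth.clade_i_config,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: Path
    seed: int = 0
    preset: str = "clade_v"
    n_reads: int = 100_000
    stages: Sequence[str] = ALL_STAGES
    n_contigs: int = 2
    contig_length: int = 100_000
    genome_fasta: Optional[Path] = None  # optional external genome input
    reads_fasta: Optional[Path] = None  # optional external library input
    n_proteins: int = 20
    protein_length: int = 200
    species_distances: Dict[str, float] = field(
        default_factory=lambda: {
            "outgroup": 1.0,
            "speciesA": 0.4,
            "speciesB": 0.6,
            "speciesC": 0.8,
        }
    )
    jackknife_reps: int = 2000
    threads: int = 1  # accepted for interface symmetry; results identical

    def validate(self) -> None:
        if self.preset not in PRESETS:
            raise ParameterError(f"unknown preset {self.preset!r}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ParameterError(f"unknown stages {sorted(unknown)}")
        for p in (self.genome_fasta, self.reads_fasta):
            if p is not None and not Path(p).exists():
                raise ParameterError(f"input path does not exist: {p}")
        if self.n_reads < 1:
            raise ParameterError("n_reads must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: Dict, out_dir=None) -> "RunConfig":
        mapping = dict(mapping)
        if out_dir is not None:
            mapping["out_dir"] = out_dir
        mapping["out_dir"] = Path(mapping["out_dir"])
        for key in ("genome_fasta", "reads_fasta"):
            if mapping.get(key):
                mapping[key] = Path(mapping[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown config keys {sorted(unknown)}")
        return cls(**mapping)


def load_config(path, out_dir=None) -> RunConfig:
    import yaml

    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    return RunConfig.from_mapping(mapping, out_dir=out_dir)


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, dict):
        return {k: _jsonify(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonify(v) for v in x]
    return x


def run_pipeline(config: RunConfig) -> Dict:
    """Run all enabled stages and write a summary bundle.

    Returns the summary mapping (also written to ``summary.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO,
        format="%(name)s %(levelname)s %(message)s", force=False,
    )
    summary: Dict = {"seed": config.seed, "preset": config.preset}
    stages = set(config.stages)
    truth_cfg = PRESETS[config.preset](seed=config.seed)

    log.info("[simulate] genome + libraries, seed=%d", config.seed)
    genome = synth.make_genome(
        truth_cfg, n_contigs=config.n_contigs, contig_length=config.contig_length
    )
    protocol_dep = sio.LibraryProtocol(five_prime_dependent=True)
    protocol_indep = sio.LibraryProtocol(five_prime_dependent=False)
    lib_dep, truth_dep = synth.simulate_library(
        genome, truth_cfg, protocol_dep, config.n_reads
    )
    lib_indep, truth_indep = synth.simulate_library(
        genome, truth_cfg, protocol_indep, config.n_reads
    )
    if "simulate" in stages:
        synth.write_genome_fasta(genome, out / "genome.fa")
        synth.write_repeats_bed(genome.repeats, out / "repeats.bed")
        sio.write_fasta_library(lib_dep, out / "library_5p_dependent.fa")
        sio.write_fasta_library(lib_indep, out / "library_5p_independent.fa")
        synth.write_truth_tsv(truth_indep, out / "truth_5p_independent.tsv")

    lib_dep = sio.trim_filter(lib_dep)
    lib_indep = sio.trim_filter(lib_indep)
    index = sio._GenomeIndex(genome.contigs)
    # the generator aggregates duplicate sequences into counted records,
    # so the library aligns at collapsed cost while keeping counts
    aln_indep = sio.align_exact(lib_indep, genome, index)
    sio.write_alignments_tsv(aln_indep, out / "alignments_5p_independent.tsv")

    if "profile" in stages:
        log.info("[profile] length x first-nt tabulation and differencing")
        prof_dep = profiles.length_first_nt(lib_dep)
        prof_indep = profiles.length_first_nt(lib_indep)
        profiles.write_profile_tsv(prof_dep, out / "profile_5p_dependent.tsv")
        profiles.write_profile_tsv(prof_indep, out / "profile_5p_independent.tsv")
        inference = profiles.infer_triphosphate(prof_dep, prof_indep)
        summary["triphosphate_present"] = inference.triphosphate_present
        if inference.triphosphate_present:
            summary["triphosphate_modal_length"] = inference.modal_called_length()

    if "pirna" in stages:
        log.info("[pirna] upstream motif, clusters, ping-pong")
        upstream = pirna.extract_upstream(aln_indep, genome)
        if len(upstream) >= 20:
            motif = pirna.discover_motif(upstream, seed=config.seed)
            pirna.write_motif_tsv(motif, out / "motif_pwm.tsv")
            summary["motif_found"] = True
            summary["motif_consensus"] = motif.consensus
            summary["motif_information_bits"] = motif.information_content
            summary["motif_matches_planted"] = motif.consensus_matches(
                truth_cfg.motif
            )
        else:
            summary["motif_found"] = False
        # 2 kb windows: the analysis default of 100 kb is sized for real
        # genomes; synthetic contigs are two orders of magnitude smaller.
        # Density is computed over the putative piRNA class (21 nt 5'U),
        # read-weighted.
        aln_21u = aln_indep.subset(
            lambda a, s: a.length == 21 and s.startswith("U")
        )
        clusters = pirna.cluster_density(
            aln_21u, genome, window_size=2000, weight="count"
        )
        pirna.write_bedgraph(clusters, genome, out / "clusters.bedgraph")
        summary["cluster_flagged_fraction"] = clusters.flagged_fraction
        # ping-pong candidate set: piRNA-length (21 nt) reads; no 5'U
        # requirement, since the partner of a 10A read starts with the
        # complement of that A by pairing geometry
        pp = pirna.ping_pong(aln_indep.subset(lambda a, s: a.length == 21))
        pp.counts.to_csv(out / "pingpong_histogram.tsv", sep="\t")
        summary["pingpong_z"] = pp.z_score_10
        summary["pingpong_tenth_a_fraction"] = pp.tenth_a_fraction
        summary["pingpong_modal_overlap"] = (
            pp.modal_overlap if pp.counts.sum() else None
        )

    if "tesirna" in stages:
        log.info("[tesirna] repeat assignment, strand bias, overhangs")
        counts = tesirna.assign_repeats(aln_indep, genome.repeats)
        tesirna.write_strand_counts_tsv(counts, out / "strand_counts.tsv")
        sense, anti = counts.totals()
        if sense + anti > 0:
            x2, p = tesirna.strand_bias(sense, anti)
            summary["strand_bias_chi2"] = x2
            summary["strand_bias_p"] = p
            summary["antisense_fraction"] = anti / (sense + anti)
        oh = tesirna.overhang_signature(aln_indep)
        oh.counts.to_csv(out / "overhang_histogram.tsv", sep="\t")
        summary["overhang_mode"] = (
            oh.modal_overhang if oh.counts.sum() else None
        )

    if "meth" in stages:
        log.info("[meth] bisulfite table, enrichment, sRNA association")
        table = synth.simulate_bisulfite(genome, truth_cfg)
        meth.write_methylation_tsv(table, out / "methylation.tsv")
        enr = meth.repeat_enrichment(table, genome.repeats)
        enr.per_class.to_csv(out / "methylation_enrichment.tsv", sep="\t")
        summary["meth_enrichment_p"] = {
            cls: float(row["p"]) for cls, row in enr.per_class.iterrows()
        }
        assoc = meth.srna_association(genome.genes, aln_indep)
        summary["srna_association_p"] = assoc.p_value

    if "homology" in stages:
        log.info("[homology] proteomes, conservation matrix, jackknife")
        proteomes, ancestors, truth = synth.make_proteomes(
            truth_cfg,
            config.species_distances,
            n_proteins=config.n_proteins,
            protein_length=config.protein_length,
        )
        matrix = homology.best_hit_matrix(ancestors, proteomes)
        homology.write_matrix_tsv(matrix, out / "conservation_matrix.tsv")
        binary = homology.binarize(matrix)
        comparison = [s for s in config.species_distances if s != "outgroup"]
        jk = homology.jackknife_incongruity(
            binary, "outgroup", comparison,
            homology.JackknifeConfig(reps=config.jackknife_reps, seed=config.seed),
        )
        summary["jackknife_p"] = jk.p_estimate
        summary["jackknife_p_is_bound"] = jk.p_is_bound

    if "mircons" in stages:
        log.info("[mircons] tiered miRNA conservation in the target library")
        reference = [
            mircons.MatureMiRNA(
                f"mir-{i + 1}",
                synth._read_at(genome, contig, pos, strand,
                               truth_cfg.mirna_length)[0],
            )
            for i, (contig, pos, strand) in enumerate(genome.mirna_loci)
        ]
        call = mircons.call_conservation(reference, lib_indep)
        mircons.write_calls_tsv(call, out / "mirna_conservation.tsv")
        summary["mirna_conserved_fraction"] = {
            str(k): v for k, v in call.fractions.items()
        }

    summary = _jsonify(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", out / "summary.json")
    return summary
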