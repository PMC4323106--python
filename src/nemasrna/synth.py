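"""Ground-truth synthetic data for every analysis stage.

Generates genomes with planted repeat copies, piRNA/miRNA/ping-pong loci
and methylation-flagged genes; class-structured small RNA libraries under
the two library protocols (5'-monophosphate-dependent vs 5'-independent)
and periodate treatment; bisulfite call tables with repeat-elevated
methylation; and divergent proteomes with planted ortholog losses. Every
emitted read carries a truth label (class, 5'-phosphate state, 3'
2'-O-methyl flag, source locus) so detectors can be scored against what
was planted.

Class conventions mirror the small RNA biology being emulated: 21 nt 5'U
monophosphate 2'-O-methylated piRNAs from discrete loci with an upstream
core motif; 22 nt 5'G 5'-triphosphate RdRP-derived siRNAs antisense to
repeats; Dicer siRNA duplexes (23-25 nt) with 2-nt 3' overhangs;
opposite-strand ping-pong pairs with a 10-nt 5' overlap and adenine at
position 10 of the 5'-most read; and uniform genomic background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import homology
from .errors import ContractError, EmptyLibraryError, ParameterError, PlacementError
from .meth import MethylationTable, classify_context
from .sio import LibraryProtocol, Read, SmallRNALibrary, rna
from .tesirna import RepeatAnnotation

CLASSES = ("mirna", "pirna21U", "sirna22G", "dicer_sirna", "pingpong_pair",
           "background")

_DNA = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Gene:
    contig: str
    start: int
    end: int
    strand: str
    methylated: bool


@dataclass
class SyntheticGenome:
    contigs: Dict[str, str]
    repeats: List[RepeatAnnotation] = field(default_factory=list)
    pirna_loci: List[Tuple[str, int, str]] = field(default_factory=list)
    mirna_loci: List[Tuple[str, int, str]] = field(default_factory=list)
    pingpong_loci: List[Tuple[str, int, str]] = field(default_factory=list)
    genes: List[Gene] = field(default_factory=list)

    def contig_length(self, name: str) -> int:
        return len(self.contigs[name])


@dataclass
class TruthConfig:
    """All generator parameters, flowing from one master seed.

    Defaults describe a clade-V-style library: discrete 21 nt 5'U piRNA
    loci with the core upstream motif, a 22 nt 5'G triphosphate siRNA
    class antisense to repeats, ping-pong pairs, and genomic background.
    """

    seed: int = 0
    class_weights: Dict[str, float] = field(
        default_factory=lambda: {
            "mirna": 0.15,
            "pirna21U": 0.35,
            "sirna22G": 0.20,
            "dicer_sirna": 0.0,
            "pingpong_pair": 0.10,
            "background": 0.20,
        }
    )
    pirna_length: int = 21
    sirna22G_length: int = 22
    mirna_length: int = 22
    dicer_len_range: Tuple[int, int] = (23, 25)
    overhang: int = 2
    pingpong_overlap: int = 10
    pingpong_tenth_A_prob: float = 0.8
    antisense_prob: float = 0.8
    motif: str = "CTGTTTCA"
    motif_offset: int = -47  # motif occupies -47..-40 relative to the 5' nt
    meth_repeat_level: float = 0.6
    meth_background_level: float = 0.02
    meth_concentration: float = 30.0  # beta concentration around the means
    # multiplier on the beta mean at CHG sites (CHG methylation runs
    # several-fold below CG genome-wide; 1.0 = no context difference)
    meth_chg_scale: float = 1.0
    coverage: int = 50
    n_pirna_loci: int = 200
    # piRNA loci concentrate in a few genomic clusters (0 = scatter
    # uniformly); each cluster spans pirna_cluster_span nt
    n_pirna_clusters: int = 4
    pirna_cluster_span: int = 2000
    n_mirna_loci: int = 50
    n_pingpong_loci: int = 200
    n_genes: int = 40
    gene_length: int = 1000
    methylated_gene_fraction: float = 0.5
    # sampling-rate multiplier for background reads inside methylated genes
    # (1.0 = uniform background; raised to emulate RNA-directed methylation
    # data where small RNAs concentrate at methylated genes)
    meth_gene_srna_boost: float = 1.0

    def validate(self) -> None:
        unknown = set(self.class_weights) - set(CLASSES)
        if unknown:
            raise ParameterError(f"unknown classes {sorted(unknown)}")
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"class weights sum to {total}, expected 1")
        for L in (self.pirna_length, self.sirna22G_length, self.mirna_length,
                  *self.dicer_len_range):
            if not 15 <= L <= 33:
                raise ParameterError(f"read length {L} outside 15-33")
        for p in (self.pingpong_tenth_A_prob, self.antisense_prob,
                  self.methylated_gene_fraction):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"probability {p} outside [0, 1]")
        if not 0.0 <= self.meth_repeat_level <= 1.0:
            raise ParameterError("meth_repeat_level outside [0, 1]")
        if not 0.0 <= self.meth_background_level <= 1.0:
            raise ParameterError("meth_background_level outside [0, 1]")

    def rng(self, *salt: int) -> np.random.Generator:
        """A generator derived from the master seed and an operation salt."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, *salt]))


def clade_v_config(seed: int = 0, **overrides) -> TruthConfig:
    """Clade-V-like conditions: piRNAs + ping-pong + 22G siRNAs."""
    return TruthConfig(seed=seed, **overrides)


def clade_iii_config(seed: int = 0, **overrides) -> TruthConfig:
    """Clade-III-like conditions: no piRNAs; RdRP 22G class at weight 0.3."""
    weights = {
        "mirna": 0.15,
        "pirna21U": 0.0,
        "sirna22G": 0.30,
        "dicer_sirna": 0.15,
        "pingpong_pair": 0.0,
        "background": 0.40,
    }
    return TruthConfig(seed=seed, class_weights=weights, **overrides)


def clade_i_config(seed: int = 0, **overrides) -> TruthConfig:
    """Clade-I-like conditions: no piRNAs, no triphosphate class; Dicer
    siRNA duplexes dominate and repeats are methylated."""
    weights = {
        "mirna": 0.15,
        "pirna21U": 0.0,
        "sirna22G": 0.0,
        "dicer_sirna": 0.45,
        "pingpong_pair": 0.0,
        "background": 0.40,
    }
    overrides.setdefault("meth_gene_srna_boost", 10.0)
    return TruthConfig(seed=seed, class_weights=weights, **overrides)


@dataclass
class PlantedTruth:
    """Per-read ground truth emitted alongside a simulated library."""

    table: pd.DataFrame  # read_id, class, phosphate, methyl3p, contig, position, strand, count

    def labels(self) -> pd.Series:
        return self.table.set_index("read_id")["class"]

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Genome construction


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_DNA))[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    if divergence <= 0:
        return seq
    chars = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(seq)) < divergence
    for i in np.nonzero(hit)[0]:
        cur = chr(chars[i])
        choices = [b for b in _DNA if b != cur]
        chars[i] = ord(choices[rng.integers(0, 3)])
    return chars.tobytes().decode()


def make_genome(
    config: TruthConfig,
    n_contigs: int = 2,
    contig_length: int = 100_000,
    repeat_spec: Sequence[Tuple[str, str, int, int, float]] = (
        ("TE1", "LTR", 1000, 20, 0.05),
        ("TE2", "DNA", 800, 20, 0.05),
    ),
    max_placement_tries: int = 1000,
) -> SyntheticGenome:
    """Random genome with planted repeats, small RNA loci and genes.

    ``repeat_spec`` rows are (family, class, consensus_length, copies,
    divergence); each copy is the consensus mutated at the divergence
    rate and placed without overlapping other repeat copies (a retry
    budget guards against impossible specs). piRNA and ping-pong loci are
    planted with the class-defining bases (5' T on the locus strand; the
    core motif at -47..-40 of each piRNA locus; an A at position 10 of
    the 5'-most ping-pong read with the configured probability).
    """
    config.validate()
    longest = max((cl for _, _, cl, _, _ in repeat_spec), default=0)
    if longest and contig_length < 10 * longest:
        raise ParameterError("contig_length must be >= 10x the longest consensus")
    rng = config.rng(1)
    names = [f"contig{i + 1}" for i in range(n_contigs)]
    contigs = {n: list(_random_dna(rng, contig_length)) for n in names}
    occupied: Dict[str, List[Tuple[int, int]]] = {n: [] for n in names}

    def _free(contig: str, start: int, end: int) -> bool:
        return all(e <= start or s >= end for s, e in occupied[contig])

    repeats: List[RepeatAnnotation] = []
    for family, rclass, cons_len, copies, divergence in repeat_spec:
        consensus = _random_dna(rng, cons_len)
        for _ in range(copies):
            for attempt in range(max_placement_tries):
                contig = names[rng.integers(0, n_contigs)]
                start = int(rng.integers(0, contig_length - cons_len))
                if _free(contig, start, start + cons_len):
                    break
            else:
                raise PlacementError(
                    f"could not place a copy of {family} within "
                    f"{max_placement_tries} tries"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            copy = _mutate(rng, consensus, divergence)
            if strand == "-":
                copy = _revcomp(copy)
            contigs[contig][start : start + cons_len] = list(copy)
            occupied[contig].append((start, start + cons_len))
            repeats.append(
                RepeatAnnotation(contig, start, start + cons_len, strand, family,
                                 rclass)
            )

    margin = 64  # leave room for the upstream window and the read body

    # positions written by locus planting; later loci must not overwrite
    # them (and must not mutate repeat copies), so truth labels stay exact
    planted: Dict[str, set] = {n: set() for n in names}

    def _writable(contig: str, positions: Sequence[int]) -> bool:
        if any(p in planted[contig] for p in positions):
            return False
        lo, hi = min(positions), max(positions) + 1
        return _free(contig, lo, hi) or all(
            _free(contig, p, p + 1) for p in positions
        )

    def _set_base(contig: str, pos: int, strand: str, base: str) -> None:
        """Set the strand-oriented base at a genomic position."""
        contigs[contig][pos] = base if strand == "+" else base.translate(_COMP)
        planted[contig].add(pos)

    def _place_locus(write_span) -> Tuple[str, int, str]:
        """Random locus whose written positions are still free.

        ``write_span(pos, strand)`` lists the positions the locus would
        write.
        """
        for _ in range(max_placement_tries):
            contig = names[rng.integers(0, n_contigs)]
            pos = int(rng.integers(margin, contig_length - margin))
            strand = "+" if rng.random() < 0.5 else "-"
            if _writable(contig, write_span(pos, strand)):
                return contig, pos, strand
        raise PlacementError("could not place a small RNA locus")

    pirna_loci = []
    motif = config.motif.upper()
    w = len(motif)

    def _pirna_span(pos: int, strand: str) -> List[int]:
        if strand == "+":
            mstart = pos + config.motif_offset
        else:
            mstart = pos - config.motif_offset - w + 1
        return [pos, *range(mstart, mstart + w)]

    cluster_anchors: List[Tuple[str, int]] = []
    span = config.pirna_cluster_span
    for _ in range(config.n_pirna_clusters):
        contig = names[rng.integers(0, n_contigs)]
        anchor = int(rng.integers(margin, contig_length - margin - span))
        cluster_anchors.append((contig, anchor))
    for _ in range(config.n_pirna_loci):
        if cluster_anchors:
            for _try in range(max_placement_tries):
                contig, anchor = cluster_anchors[
                    rng.integers(0, len(cluster_anchors))
                ]
                pos = anchor + int(rng.integers(0, span))
                strand = "+" if rng.random() < 0.5 else "-"
                if _writable(contig, _pirna_span(pos, strand)):
                    break
            else:
                raise PlacementError("could not place a piRNA locus")
        else:
            contig, pos, strand = _place_locus(_pirna_span)
        _set_base(contig, pos, strand, "T")
        # motif occupies positions motif_offset..motif_offset+w-1 relative
        # to the 5' nt (position 1 = first small RNA base)
        if strand == "+":
            mstart = pos + config.motif_offset
            contigs[contig][mstart : mstart + w] = list(motif)
        else:
            mstart = pos - config.motif_offset - w + 1
            contigs[contig][mstart : mstart + w] = list(_revcomp(motif))
        planted[contig].update(range(mstart, mstart + w))
        pirna_loci.append((contig, pos, strand))

    mirna_loci = []
    for _ in range(config.n_mirna_loci):
        contig, pos, strand = _place_locus(lambda p, s: [p])
        _set_base(contig, pos, strand, "T")  # miRNAs emulated with a 5' U bias
        mirna_loci.append((contig, pos, strand))

    pingpong_loci = []
    k = config.pingpong_overlap
    for _ in range(config.n_pingpong_loci):
        contig, pos, _ = _place_locus(lambda p, s: [p, p + k - 1])
        # by convention the locus anchors the plus-strand (5'-most) read
        _set_base(contig, pos, "+", "T")
        if rng.random() < config.pingpong_tenth_A_prob:
            _set_base(contig, pos + k - 1, "+", "A")
        elif contigs[contig][pos + k - 1] == "A":
            _set_base(contig, pos + k - 1, "+", "G")
        else:
            planted[contig].add(pos + k - 1)
        pingpong_loci.append((contig, pos, "+"))

    genes: List[Gene] = []
    for i in range(config.n_genes):
        contig = names[rng.integers(0, n_contigs)]
        start = int(rng.integers(0, contig_length - config.gene_length))
        strand = "+" if rng.random() < 0.5 else "-"
        methylated = rng.random() < config.methylated_gene_fraction
        genes.append(Gene(contig, start, start + config.gene_length, strand,
                          methylated))

    return SyntheticGenome(
        {n: "".join(s) for n, s in contigs.items()},
        repeats, pirna_loci, mirna_loci, pingpong_loci, genes,
    )


# ---------------------------------------------------------------------------
# Library simulation


def _read_at(genome: SyntheticGenome, contig: str, five_prime: int, strand: str,
             length: int) -> Tuple[str, int, int]:
    """Strand-oriented read sequence with 5' nt at the given position.

    Returns (RNA sequence, start, end) with 0-based half-open genomic
    coordinates.
    """
    seq = genome.contigs[contig]
    if strand == "+":
        start, end = five_prime, five_prime + length
        body = seq[start:end]
    else:
        start, end = five_prime - length + 1, five_prime + 1
        body = _revcomp(seq[start:end])
    if start < 0 or end > len(seq):
        raise ContractError("read extends beyond the contig")
    return rna(body), start, end


def _g_candidates(genome: SyntheticGenome, rep: RepeatAnnotation, strand: str,
                  length: int) -> np.ndarray:
    """5' positions inside a repeat whose strand base is G and whose read
    body stays inside the repeat."""
    seq = genome.contigs[rep.contig]
    if strand == "+":
        window = np.frombuffer(
            seq[rep.start : rep.end - length + 1].encode(), dtype=np.uint8
        )
        return rep.start + np.nonzero(window == ord("G"))[0]
    window = np.frombuffer(
        seq[rep.start + length - 1 : rep.end].encode(), dtype=np.uint8
    )
    return rep.start + length - 1 + np.nonzero(window == ord("C"))[0]


def simulate_library(
    genome: SyntheticGenome,
    config: TruthConfig,
    protocol: LibraryProtocol = LibraryProtocol(five_prime_dependent=True),
    n_reads: int = 100_000,
) -> Tuple[SmallRNALibrary, PlantedTruth]:
    """Simulate a class-structured small RNA library under a protocol.

    Read classes are drawn multinomially from ``class_weights``; each
    class is emitted with its defining 5' nt, length, phosphate state and
    3' 2'-O-methyl flag. A 5'-monophosphate-dependent protocol removes
    triphosphate reads before output; periodate treatment removes reads
    lacking the 3' methyl flag. Reads with identical provenance are
    aggregated into counted records; the truth table is emitted
    per record.
    """
    config.validate()
    if n_reads <= 0:
        raise EmptyLibraryError("zero reads requested")
    for cls, weight in config.class_weights.items():
        if weight > 0:
            if cls == "pirna21U" and not genome.pirna_loci:
                raise ContractError("config plants piRNAs but genome has no loci")
            if cls == "mirna" and not genome.mirna_loci:
                raise ContractError("config plants miRNAs but genome has no loci")
            if cls == "pingpong_pair" and not genome.pingpong_loci:
                raise ContractError("config plants ping-pong pairs but genome "
                                    "has no loci")
            if cls in ("sirna22G", "dicer_sirna") and not genome.repeats:
                raise ContractError(f"config plants {cls} but genome has no repeats")
    rng = config.rng(2)
    weights = np.array([config.class_weights.get(c, 0.0) for c in CLASSES])
    counts = rng.multinomial(n_reads, weights)
    contig_names = sorted(genome.contigs)

    # (sequence, class, phosphate, methyl, contig, pos5p, strand) -> count
    emitted: Dict[Tuple, int] = {}

    def emit(seq: str, cls: str, phosphate: str, methyl: bool, contig: str,
             pos: int, strand: str, n: int = 1) -> None:
        key = (seq, cls, phosphate, methyl, contig, pos, strand)
        emitted[key] = emitted.get(key, 0) + n

    n_mirna, n_pirna, n_sirna, n_dicer, n_pp, n_bg = counts

    # miRNA: fixed loci, 5'U, monophosphate, unmethylated 3'
    if n_mirna:
        loci = genome.mirna_loci
        for i in rng.integers(0, len(loci), size=n_mirna):
            contig, pos, strand = loci[i]
            seq, _, _ = _read_at(genome, contig, pos, strand, config.mirna_length)
            emit(seq, "mirna", "mono", False, contig, pos, strand)

    # piRNA: fixed loci, 21 nt, 5'U, monophosphate, 2'-O-methylated
    if n_pirna:
        loci = genome.pirna_loci
        for i in rng.integers(0, len(loci), size=n_pirna):
            contig, pos, strand = loci[i]
            seq, _, _ = _read_at(genome, contig, pos, strand, config.pirna_length)
            emit(seq, "pirna21U", "mono", True, contig, pos, strand)

    # 22G siRNA: repeat-derived, 5'G, triphosphate, antisense with
    # probability antisense_prob
    if n_sirna:
        L = config.sirna22G_length
        cand_cache: Dict[Tuple[int, str], np.ndarray] = {}
        for _ in range(n_sirna):
            for _try in range(100):
                ri = int(rng.integers(0, len(genome.repeats)))
                rep = genome.repeats[ri]
                anti = rng.random() < config.antisense_prob
                strand = (
                    ("-" if rep.strand == "+" else "+") if anti else rep.strand
                )
                key = (ri, strand)
                if key not in cand_cache:
                    cand_cache[key] = _g_candidates(genome, rep, strand, L)
                cands = cand_cache[key]
                if cands.size:
                    pos = int(cands[rng.integers(0, cands.size)])
                    seq, _, _ = _read_at(genome, rep.contig, pos, strand, L)
                    emit(seq, "sirna22G", "tri", False, rep.contig, pos, strand)
                    break
            else:
                raise ContractError("no 5'G positions available in repeats")

    # Dicer siRNA duplexes: both strands, 2-nt 3' overhangs, emitted as
    # two independent reads (detectors must rediscover the pairing)
    if n_dicer:
        lo, hi = config.dicer_len_range
        oh = config.overhang
        n_pairs, extra = divmod(int(n_dicer), 2)
        for j in range(n_pairs + (1 if extra else 0)):
            L = int(rng.integers(lo, hi + 1))
            for _try in range(100):
                rep = genome.repeats[int(rng.integers(0, len(genome.repeats)))]
                if rep.length >= L + oh:
                    break
            else:
                raise ContractError("repeats too short for Dicer duplexes")
            a = int(rng.integers(rep.start + oh, rep.end - L + 1))
            plus_seq, pa, pb = _read_at(genome, rep.contig, a, "+", L)
            emit(plus_seq, "dicer_sirna", "mono", False, rep.contig, a, "+")
            if j < n_pairs or not extra:
                # partner: [a - oh, a + L - oh) on -, 5' at a + L - oh - 1
                minus_fp = a + L - oh - 1
                minus_seq, _, _ = _read_at(genome, rep.contig, minus_fp, "-", L)
                emit(minus_seq, "dicer_sirna", "mono", False, rep.contig,
                     minus_fp, "-")

    # ping-pong pairs: opposite strands, 5'-5' overlap k, 5'-most read
    # carries the position-10 adenine bias planted in the genome
    if n_pp:
        k = config.pingpong_overlap
        L = config.pirna_length
        loci = genome.pingpong_loci
        n_pairs, extra = divmod(int(n_pp), 2)
        for j in range(n_pairs + (1 if extra else 0)):
            contig, pos, _ = loci[int(rng.integers(0, len(loci)))]
            plus_seq, _, _ = _read_at(genome, contig, pos, "+", L)
            emit(plus_seq, "pingpong_pair", "mono", True, contig, pos, "+")
            if j < n_pairs or not extra:
                minus_fp = pos + k - 1
                minus_seq, _, _ = _read_at(genome, contig, minus_fp, "-", L)
                emit(minus_seq, "pingpong_pair", "mono", True, contig,
                     minus_fp, "-")

    # background: random genomic fragments, 15-33 nt; uniform when
    # meth_gene_srna_boost is 1, otherwise methylated-gene segments are
    # sampled at boost x the rate of the rest of the genome
    if n_bg:
        segments: List[Tuple[str, int, int, float]] = []
        boost = config.meth_gene_srna_boost
        for contig in contig_names:
            clen = len(genome.contigs[contig])
            if boost == 1.0:
                segments.append((contig, 0, clen, 1.0))
                continue
            meth_ivs = sorted(
                (g.start, g.end) for g in genome.genes
                if g.methylated and g.contig == contig
            )
            merged: List[List[int]] = []
            for s, e in meth_ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            prev = 0
            for s, e in merged:
                if s > prev:
                    segments.append((contig, prev, s, 1.0))
                segments.append((contig, s, e, boost))
                prev = e
            if prev < clen:
                segments.append((contig, prev, clen, 1.0))
        weights_seg = np.array([(e - s) * w for _, s, e, w in segments])
        weights_seg /= weights_seg.sum()
        seg_choice = rng.choice(len(segments), size=n_bg, p=weights_seg)
        for si in seg_choice:
            contig, seg_start, seg_end, _ = segments[si]
            L = int(rng.integers(15, 34))
            strand = "+" if rng.random() < 0.5 else "-"
            clen = len(genome.contigs[contig])
            start = int(rng.integers(seg_start, seg_end))
            start = min(start, clen - L)
            fp = start if strand == "+" else start + L - 1
            seq, _, _ = _read_at(genome, contig, fp, strand, L)
            emit(seq, "background", "mono", False, contig, fp, strand)

    # protocol filtering
    reads: List[Read] = []
    truth_rows = []
    idx = 0
    for (seq, cls, phosphate, methyl, contig, pos, strand), count in sorted(
        emitted.items()
    ):
        if protocol.five_prime_dependent and phosphate == "tri":
            continue
        if protocol.treatment == "periodate" and not methyl:
            continue
        idx += 1
        rid = f"r{idx:07d}"
        reads.append(Read(rid, seq, count))
        truth_rows.append((rid, cls, phosphate, methyl, contig, pos, strand, count))
    library = SmallRNALibrary(reads, protocol, total_input_count=n_reads)
    truth = PlantedTruth(
        pd.DataFrame(
            truth_rows,
            columns=["read_id", "class", "phosphate", "methyl3p", "contig",
                     "position", "strand", "count"],
        )
    )
    return library, truth


def apply_protocol(
    library: SmallRNALibrary,
    truth: PlantedTruth,
    protocol: LibraryProtocol,
) -> Tuple[SmallRNALibrary, PlantedTruth]:
    """Re-apply protocol filtering to an already-simulated library.

    Idempotent: filtering twice equals filtering once.
    """
    info = truth.table.set_index("read_id")
    keep_ids = []
    for r in library.reads:
        row = info.loc[r.id]
        if protocol.five_prime_dependent and row["phosphate"] == "tri":
            continue
        if protocol.treatment == "periodate" and not row["methyl3p"]:
            continue
        keep_ids.append(r.id)
    keep = set(keep_ids)
    reads = [r for r in library.reads if r.id in keep]
    table = truth.table[truth.table["read_id"].isin(keep)].reset_index(drop=True)
    return (
        SmallRNALibrary(reads, protocol, library.total_input_count),
        PlantedTruth(table),
    )


# ---------------------------------------------------------------------------
# Bisulfite table simulation


def simulate_bisulfite(
    genome: SyntheticGenome, config: TruthConfig
) -> MethylationTable:
    """Per-cytosine bisulfite call table over both strands.

    Unconverted counts are binomial draws at a per-site methylation level
    drawn from a beta distribution whose mean is ``meth_repeat_level``
    inside repeats and methylated genes and ``meth_background_level``
    elsewhere.
    """
    config.validate()
    if config.coverage < 1:
        raise ParameterError("coverage must be >= 1")
    rng = config.rng(3)

    elevated: Dict[str, np.ndarray] = {
        name: np.zeros(len(seq), dtype=bool) for name, seq in genome.contigs.items()
    }
    for rep in genome.repeats:
        elevated[rep.contig][rep.start : rep.end] = True
    for gene in genome.genes:
        if gene.methylated:
            elevated[gene.contig][gene.start : gene.end] = True

    def _level(mean: float, size: int) -> np.ndarray:
        if mean <= 0:
            return np.zeros(size)
        if mean >= 1:
            return np.ones(size)
        kappa = config.meth_concentration
        return rng.beta(mean * kappa, (1 - mean) * kappa, size=size)

    rows = []
    for name in sorted(genome.contigs):
        seq = genome.contigs[name]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for strand, base in (("+", ord("C")), ("-", ord("G"))):
            positions = np.nonzero(arr == base)[0]
            if positions.size == 0:
                continue
            hot = elevated[name][positions]
            contexts = [
                classify_context(genome, name, int(pos), strand)
                for pos in positions
            ]
            chg = np.array([c == "CHG" for c in contexts])
            levels = np.empty(positions.size)
            for is_hot, mean in ((True, config.meth_repeat_level),
                                 (False, config.meth_background_level)):
                for is_chg in (False, True):
                    mask = (hot == is_hot) & (chg == is_chg)
                    m = mean * (config.meth_chg_scale if is_chg else 1.0)
                    levels[mask] = _level(min(m, 1.0), int(mask.sum()))
            unconverted = rng.binomial(config.coverage, levels)
            for pos, ctx, unc in zip(positions, contexts, unconverted):
                rows.append(
                    (name, int(pos), strand, ctx, config.coverage, int(unc))
                )
    frame = pd.DataFrame(
        rows,
        columns=["contig", "position", "strand", "context", "total",
                 "unconverted"],
    ).sort_values(["contig", "position", "strand"], kind="stable")
    return MethylationTable(frame.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Proteome simulation


def make_proteomes(
    config: TruthConfig,
    distances: Mapping[str, float],
    n_proteins: int = 100,
    loss_pattern: Optional[Mapping[Tuple[str, str], str]] = None,
    n_decoys: int = 0,
    protein_length: int = 400,
) -> Tuple[Dict[str, Dict[str, str]], Dict[str, str], pd.DataFrame]:
    """Divergent proteomes with planted ortholog losses.

    An ancestor set of ``n_proteins`` random proteins (WAG equilibrium
    composition) is evolved independently to each species' distance
    (substitutions/site); proteins marked absent in ``loss_pattern`` are
    deleted from that species, and ``n_decoys`` unrelated random proteins
    are added per species. Returns (species -> proteome, ancestor set,
    presence truth matrix).
    """
    loss_pattern = dict(loss_pattern or {})
    for d in distances.values():
        if d < 0:
            raise ParameterError("distances must be >= 0")
    ancestor_ids = [f"P{i + 1:04d}" for i in range(n_proteins)]
    for (pid, sp) in loss_pattern:
        if pid not in ancestor_ids or sp not in distances:
            raise ParameterError(f"loss pattern references unknown ({pid}, {sp})")
    model = homology.default_model()
    rng = config.rng(4)
    ancestors = {
        pid: homology.random_protein(protein_length, rng, model)
        for pid in ancestor_ids
    }
    proteomes: Dict[str, Dict[str, str]] = {}
    truth = pd.DataFrame(True, index=ancestor_ids, columns=list(distances))
    for sp, d in distances.items():
        proteome = {}
        for pid, seq in ancestors.items():
            if loss_pattern.get((pid, sp)) == "absent":
                truth.loc[pid, sp] = False
                continue
            evo_seed = int(rng.integers(0, 2**31 - 1))
            proteome[f"{sp}_{pid}"] = homology.evolve_sequence(
                seq, d, model, seed=evo_seed
            )
        for j in range(n_decoys):
            proteome[f"{sp}_decoy{j + 1:03d}"] = homology.random_protein(
                protein_length, rng, model
            )
        proteomes[sp] = proteome
    return proteomes, ancestors, truth


# ---------------------------------------------------------------------------
# File writers


def write_genome_fasta(genome: SyntheticGenome, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome.contigs):
            fh.write(f">{name}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_repeats_bed(repeats: Sequence[RepeatAnnotation], path) -> None:
    """BED6, 0-based half-open, ``family#class`` in the name column."""
    with open(path, "w") as fh:
        for rep in repeats:
            fh.write(
                f"{rep.contig}\t{rep.start}\t{rep.end}\t{rep.family}#{rep.rclass}"
                f"\t0\t{rep.strand}\n"
            )


def bed_to_gff3(bed_path, gff_path, source: str = "nemasrna",
                feature: str = "dispersed_repeat") -> None:
    """Convert BED6 (0-based half-open) to GFF3 (1-based closed)."""
    with open(bed_path) as src, open(gff_path, "w") as dst:
        dst.write("##gff-version 3\n")
        for line in src:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, start, end, name, score, strand = line.split("\t")[:6]
            dst.write(
                f"{contig}\t{source}\t{feature}\t{int(start) + 1}\t{end}\t"
                f"{score}\t{strand.strip()}\t.\tName={name}\n"
            )


def write_truth_tsv(truth: PlantedTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)
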