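"""Small RNA read handling, size selection, and perfect-match alignment.

Reads are stored RNA-style (U internally; T accepted on input). Alignment
is exact-match only, reporting a single best placement per read under a
deterministic tie-break, mirroring the one-best perfect-match policy
(``bowtie -v 0 -k 1 --best``) used for small RNA mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from Bio import SeqIO

from .errors import ContractError, ParameterError

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# minimum seed length for the k-mer index; reads shorter than this fall
# back to a direct scan
_SEED = 15


def rna(seq: str) -> str:
    """Normalize a sequence to uppercase RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def dna(seq: str) -> str:
    """Normalize a sequence to uppercase DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """A counted small RNA sequence (RNA alphabet, U internally)."""

    id: str
    sequence: str
    count: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise ContractError(f"read {self.id!r} has an empty sequence")
        if self.count < 1:
            raise ContractError(f"read {self.id!r} has count {self.count} < 1")
        object.__setattr__(self, "sequence", rna(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def first_nt(self) -> str:
        return self.sequence[0]


@dataclass(frozen=True)
class LibraryProtocol:
    """Library preparation metadata.

    ``five_prime_dependent`` — adapter ligation captures only
    5'-monophosphate RNAs (polyphosphatase omitted); ``treatment`` —
    chemical pre-treatment of the RNA (periodate oxidation destroys 3'
    ends lacking 2'-O-methylation).
    """

    five_prime_dependent: bool = True
    treatment: str = "none"  # none | periodate | control

    def __post_init__(self):
        if self.treatment not in ("none", "periodate", "control"):
            raise ParameterError(f"unknown treatment {self.treatment!r}")


@dataclass
class SmallRNALibrary:
    reads: List[Read]
    protocol: LibraryProtocol = field(default_factory=LibraryProtocol)
    # total read count before any collapsing, kept through collapse_unique
    total_input_count: Optional[int] = None

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


@dataclass(frozen=True)
class Alignment:
    """A perfect-match placement: 0-based half-open, stranded.

    The 5' genomic coordinate is ``start`` on + and ``end - 1`` on -.
    ``n_occurrences`` counts all perfect-match placements of the read on
    both strands (the reported placement is the tie-break winner).
    """

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    n_occurrences: int = 1

    def __post_init__(self):
        if self.strand not in "+-":
            raise ContractError(f"invalid strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ContractError(f"invalid interval [{self.start}, {self.end})")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentSet:
    """Placements plus the read sequences/counts they came from."""

    alignments: List[Alignment]
    unaligned: List[str]
    sequences: Dict[str, str]  # read_id -> RNA sequence
    counts: Dict[str, int]  # read_id -> library count

    def __len__(self) -> int:
        return len(self.alignments)

    def __iter__(self):
        return iter(self.alignments)

    def subset(self, predicate) -> "AlignmentSet":
        """Alignments for which ``predicate(alignment, sequence)`` holds."""
        kept = [
            a for a in self.alignments if predicate(a, self.sequences[a.read_id])
        ]
        ids = {a.read_id for a in kept}
        return AlignmentSet(
            kept,
            list(self.unaligned),
            {i: self.sequences[i] for i in ids},
            {i: self.counts[i] for i in ids},
        )


def trim_filter(
    library: SmallRNALibrary, min_len: int = 15, max_len: int = 33
) -> SmallRNALibrary:
    """Size-select reads to ``min_len..max_len`` nt inclusive."""
    if min_len > max_len:
        raise ParameterError(f"min_len {min_len} > max_len {max_len}")
    kept = [r for r in library.reads if min_len <= len(r) <= max_len]
    return SmallRNALibrary(kept, library.protocol, library.total_input_count)


def collapse_unique(library: SmallRNALibrary) -> SmallRNALibrary:
    """Collapse to one count-1 read per distinct sequence.

    The original total read count is retained as ``total_input_count``
    so RPM-style quantities remain computable after collapsing.
    """
    seen: Dict[str, str] = {}
    for r in library.reads:
        if r.sequence not in seen:
            seen[r.sequence] = r.id
    reads = [Read(rid, seq, 1) for seq, rid in seen.items()]
    total = library.total_input_count
    if total is None:
        total = library.total_count
    return SmallRNALibrary(reads, library.protocol, total)


def _contig_map(genome) -> Mapping[str, str]:
    contigs = getattr(genome, "contigs", genome)
    if not isinstance(contigs, Mapping):
        raise ContractError("genome must be a mapping of contig name -> sequence")
    return contigs


class _GenomeIndex:
    """Seed-length k-mer index over the forward strands of a genome."""

    def __init__(self, contigs: Mapping[str, str], seed: int = _SEED):
        self.seed = seed
        self.contigs = {name: dna(seq) for name, seq in contigs.items()}
        self.index: Dict[str, List[Tuple[str, int]]] = {}
        for name in sorted(self.contigs):
            seq = self.contigs[name]
            for i in range(len(seq) - seed + 1):
                self.index.setdefault(seq[i : i + seed], []).append((name, i))

    def occurrences(self, read_seq_dna: str) -> List[Tuple[str, int, str]]:
        """All perfect-match placements (contig, start, strand), both strands."""
        hits: List[Tuple[str, int, str]] = []
        L = len(read_seq_dna)
        for strand, query in (("+", read_seq_dna), ("-", revcomp_dna(read_seq_dna))):
            if L >= self.seed:
                for name, i in self.index.get(query[: self.seed], ()):
                    if self.contigs[name][i : i + L] == query:
                        hits.append((name, i, strand))
            else:  # short query: direct scan
                for name in sorted(self.contigs):
                    seq = self.contigs[name]
                    j = seq.find(query)
                    while j != -1:
                        hits.append((name, j, strand))
                        j = seq.find(query, j + 1)
        return hits


def _tie_break_key(hit: Tuple[str, int, str]) -> Tuple[str, int, int]:
    contig, start, strand = hit
    return (contig, start, 0 if strand == "+" else 1)


def align_exact(
    library: SmallRNALibrary, genome, index: Optional[_GenomeIndex] = None
) -> AlignmentSet:
    """Perfect-match one-best alignment of every read against a genome.

    A read is reported iff its sequence (U->T) occurs exactly in the
    genome on either strand. Among multiple placements the
    lexicographically smallest (contig, start, strand with + < -) wins.
    Unaligned read ids are listed separately.
    """
    contigs = _contig_map(genome)
    if not contigs:
        raise ContractError("genome is empty")
    if index is None:
        index = _GenomeIndex(contigs)
    alignments: List[Alignment] = []
    unaligned: List[str] = []
    sequences: Dict[str, str] = {}
    counts: Dict[str, int] = {}
    for read in library.reads:
        hits = index.occurrences(dna(read.sequence))
        if not hits:
            unaligned.append(read.id)
            continue
        contig, start, strand = min(hits, key=_tie_break_key)
        alignments.append(
            Alignment(read.id, contig, start, start + len(read), strand, len(hits))
        )
        sequences[read.id] = read.sequence
        counts[read.id] = read.count
    return AlignmentSet(alignments, unaligned, sequences, counts)


# ---------------------------------------------------------------------------
# File formats


def _parse_count(description: str) -> int:
    for token in description.split():
        if token.startswith("count="):
            return int(token[6:])
    return 1


def read_fasta_library(
    path, protocol: Optional[LibraryProtocol] = None
) -> SmallRNALibrary:
    """Read a FASTA small RNA library; counts from ``count=N`` header tokens."""
    reads = [
        Read(rec.id, str(rec.seq), _parse_count(rec.description))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return SmallRNALibrary(reads, protocol or LibraryProtocol())


def read_fastq_library(
    path, protocol: Optional[LibraryProtocol] = None
) -> SmallRNALibrary:
    reads = [
        Read(rec.id, str(rec.seq), _parse_count(rec.description))
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    return SmallRNALibrary(reads, protocol or LibraryProtocol())


def write_fasta_library(library: SmallRNALibrary, path) -> None:
    with open(path, "w") as fh:
        for r in library.reads:
            fh.write(f">{r.id} count={r.count}\n{r.sequence}\n")


def write_alignments_bed(alignments: Iterable[Alignment], path) -> None:
    """BED6: contig, start, end, read_id, score 0, strand."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(f"{a.contig}\t{a.start}\t{a.end}\t{a.read_id}\t0\t{a.strand}\n")


def write_alignments_tsv(aln_set: AlignmentSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcontig\tstart\tend\tstrand\tn_occurrences\n")
        for a in aln_set.alignments:
            fh.write(
                f"{a.read_id}\t{a.contig}\t{a.start}\t{a.end}\t{a.strand}"
                f"\t{a.n_occurrences}\n"
            )
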