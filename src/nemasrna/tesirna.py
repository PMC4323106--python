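"""Transposon-derived siRNA statistics.

Small RNAs aligned to the genome are intersected with repeat annotations
(e.g. RepeatMasker output consumed as BED); strand bias relative to the
annotated element strand is tested by chi-squared, two read classes are
compared in a Yates-corrected 2x2, and overlapping sense/antisense pairs
are examined for the 2-nt 3' overhang characteristic of Dicer cleavage
of double-stranded RNA.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, ParameterError
from .sio import AlignmentSet

REPEAT_CLASSES = ("LTR", "DNA", "LINE", "SINE", "BEL/PAO", "RC", "Unknown")


@dataclass(frozen=True)
class RepeatAnnotation:
    """A repeat copy on the genome (0-based half-open, stranded)."""

    contig: str
    start: int
    end: int
    strand: str
    family: str
    rclass: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ContractError(f"invalid repeat interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ContractError(f"invalid repeat strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_repeats_bed(path) -> List[RepeatAnnotation]:
    """BED6 with ``family#class`` (RepeatMasker convention) or ``family`` in col 4."""
    repeats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, start, end, name, _score, strand = line.split("\t")[:6]
            family, _, rclass = name.partition("#")
            repeats.append(
                RepeatAnnotation(
                    contig, int(start), int(end), strand.strip(), family,
                    rclass or "Unknown",
                )
            )
    return repeats


def read_repeatmasker_out(path) -> List[RepeatAnnotation]:
    """Parse the standard RepeatMasker ``.out`` column layout."""
    repeats = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) < 11 or not fields[0].isdigit():
                continue
            contig = fields[4]
            start = int(fields[5]) - 1  # .out is 1-based closed
            end = int(fields[6])
            strand = "+" if fields[8] == "+" else "-"
            family, rclass = fields[9], fields[10].split("/")[0]
            repeats.append(RepeatAnnotation(contig, start, end, strand, family, rclass))
    return repeats


@dataclass
class ReadAssignment:
    read_id: str
    repeat: RepeatAnnotation
    orientation: str  # sense | antisense
    overlap: int


@dataclass
class StrandCounts:
    """Sense/antisense tallies per repeat class and family."""

    per_class: pd.DataFrame  # index class, columns sense/antisense
    per_family: pd.DataFrame
    assignments: List[ReadAssignment]

    def totals(self) -> Tuple[int, int]:
        return int(self.per_class["sense"].sum()), int(
            self.per_class["antisense"].sum()
        )


def assign_repeats(
    alignments: AlignmentSet,
    repeats: Iterable[RepeatAnnotation],
    min_overlap_fraction: float = 0.5,
    weight: str = "unique",
) -> StrandCounts:
    """Assign aligned reads to repeats and tally sense/antisense counts.

    A read is assigned iff it overlaps a repeat by at least
    ``min_overlap_fraction`` of the read length; among several qualifying
    repeats the largest overlap wins (ties broken by the repeat with the
    lexicographically smallest (contig, start, strand), + before -).
    Orientation is sense iff read strand equals the repeat's annotated
    strand. ``weight='unique'`` counts each distinct read once (collapsed
    mode, the default); ``weight='count'`` weights by library counts.
    """
    if weight not in ("unique", "count"):
        raise ParameterError(f"unknown weight mode {weight!r}")
    by_contig: Dict[str, List[RepeatAnnotation]] = defaultdict(list)
    for rep in repeats:
        by_contig[rep.contig].append(rep)
    starts: Dict[str, List[int]] = {}
    max_len: Dict[str, int] = {}
    for contig, reps in by_contig.items():
        reps.sort(key=lambda r: (r.start, r.end))
        starts[contig] = [r.start for r in reps]
        max_len[contig] = max(r.length for r in reps)

    assignments: List[ReadAssignment] = []
    class_counts: Dict[Tuple[str, str], float] = defaultdict(float)
    family_counts: Dict[Tuple[str, str], float] = defaultdict(float)
    for aln in alignments.alignments:
        reps = by_contig.get(aln.contig)
        if not reps:
            continue
        # candidate repeats start within max repeat length upstream
        lo = bisect_left(starts[aln.contig], aln.start - max_len[aln.contig])
        hi = bisect_right(starts[aln.contig], aln.end)
        best: Optional[Tuple[int, Tuple, RepeatAnnotation]] = None
        for rep in reps[lo:hi]:
            ov = min(aln.end, rep.end) - max(aln.start, rep.start)
            if ov < aln.length * min_overlap_fraction:
                continue
            key = (rep.contig, rep.start, 0 if rep.strand == "+" else 1)
            if best is None or ov > best[0] or (ov == best[0] and key < best[1]):
                best = (ov, key, rep)
        if best is None:
            continue
        ov, _, rep = best
        orient = "sense" if aln.strand == rep.strand else "antisense"
        assignments.append(ReadAssignment(aln.read_id, rep, orient, ov))
        w = 1.0 if weight == "unique" else float(alignments.counts[aln.read_id])
        class_counts[(rep.rclass, orient)] += w
        family_counts[(rep.family, orient)] += w

    def _frame(d: Dict[Tuple[str, str], float]) -> pd.DataFrame:
        keys = sorted({k for k, _ in d})
        return pd.DataFrame(
            {
                "sense": [d.get((k, "sense"), 0.0) for k in keys],
                "antisense": [d.get((k, "antisense"), 0.0) for k in keys],
            },
            index=keys,
        )

    return StrandCounts(_frame(class_counts), _frame(family_counts), assignments)


def strand_bias(sense: float, antisense: float) -> Tuple[float, float]:
    """1-df chi-squared of (sense, antisense) against an even split."""
    n = sense + antisense
    if n <= 0:
        raise ContractError("strand_bias requires sense + antisense > 0")
    e = n / 2.0
    x2 = (sense - e) ** 2 / e + (antisense - e) ** 2 / e
    return x2, float(stats.chi2.sf(x2, 1))


def class_bias_2x2(
    a_sense: float, a_anti: float, b_sense: float, b_anti: float
) -> Tuple[float, float]:
    """2x2 chi-squared with Yates continuity correction.

    X^2 = N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    a, b, c, d = a_sense, a_anti, b_sense, b_anti
    n = a + b + c + d
    for margin in (a + b, c + d, a + c, b + d):
        if margin <= 0:
            raise ContractError("class_bias_2x2 requires all marginals > 0")
    corr = max(abs(a * d - b * c) - n / 2.0, 0.0)
    x2 = n * corr**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return x2, float(stats.chi2.sf(x2, 1))


@dataclass
class OverhangHistogram:
    """Signed 3' overhang counts pooled over both duplex ends.

    Positive = protruding 3' end (Dicer-like), negative = recessed.
    """

    counts: pd.Series  # index -10..10
    n_pairs: int

    @property
    def modal_overhang(self) -> int:
        return int(self.counts.idxmax())


def overhang_signature(
    alignments: AlignmentSet, min_body_overlap: int = 15, max_overhang: int = 10
) -> OverhangHistogram:
    """3' overhang histogram of rediscovered sense/antisense duplexes.

    For every +/- pair of alignments on one contig overlapping by at
    least ``min_body_overlap`` nt, the two 3' overhangs are ``b - d``
    (plus-read 3' end, intervals [a,b) on + and [c,d) on -) and
    ``a - c`` (minus-read 3' end). Distinct coordinate pairs count once.
    """
    plus: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    minus: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for aln in alignments.alignments:
        if aln.strand not in "+-":
            raise ContractError("overhang_signature requires stranded alignments")
        (plus if aln.strand == "+" else minus)[aln.contig].append(
            (aln.start, aln.end)
        )
    overhangs = np.arange(-max_overhang, max_overhang + 1)
    counts = np.zeros(overhangs.size, dtype=np.int64)
    n_pairs = 0
    for contig, plus_ivs in plus.items():
        minus_ivs = sorted(set(minus.get(contig, ())))
        if not minus_ivs:
            continue
        m_starts = [iv[0] for iv in minus_ivs]
        m_maxlen = max(d - c for c, d in minus_ivs)
        for a, b in sorted(set(plus_ivs)):
            lo = bisect_left(m_starts, a - m_maxlen)
            hi = bisect_right(m_starts, b - min_body_overlap)
            for c, d in minus_ivs[lo:hi]:
                if min(b, d) - max(a, c) < min_body_overlap:
                    continue
                n_pairs += 1
                for oh in (b - d, a - c):
                    if -max_overhang <= oh <= max_overhang:
                        counts[oh + max_overhang] += 1
    return OverhangHistogram(pd.Series(counts, index=overhangs), n_pairs)


def write_strand_counts_tsv(counts: StrandCounts, path) -> None:
    counts.per_class.rename_axis("class").to_csv(path, sep="\t")
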