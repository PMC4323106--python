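"""RNA-directed DNA methylation analysis.

Per-cytosine bisulfite call tables (total vs unconverted read counts) are
classified by sequence context (CG/CHG/CHH), summarized as per-site
methylation fractions, tested for repeat-class enrichment of methylated
sites against the genome-wide rate (chi-squared), and related to small
RNA densities at methylated vs unmethylated genes (one-sided
Mann-Whitney). Under bisulfite chemistry a methylated cytosine resists
conversion, so the methylation fraction at a site is
unconverted / total.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .sio import AlignmentSet
from .tesirna import RepeatAnnotation

CONTEXTS = ("CG", "CHG", "CHH")


def classify_context(genome, contig: str, position: int, strand: str) -> str:
    """Cytosine context (CG/CHG/CHH) read 5'->3' on the site's strand.

    On + the site base must be C; on - it must be G (a C on the minus
    strand). Sites within 2 nt of the contig end on their strand fall
    back to CHH by truncation.
    """
    contigs = getattr(genome, "contigs", genome)
    seq = contigs[contig]
    if strand == "+":
        if seq[position] != "C":
            raise ContractError(f"{contig}:{position}+ is not a C")
        nxt = seq[position + 1] if position + 1 < len(seq) else None
        nxt2 = seq[position + 2] if position + 2 < len(seq) else None
    elif strand == "-":
        if seq[position] != "G":
            raise ContractError(f"{contig}:{position}- is not a C on the minus strand")
        # downstream on the minus strand = upstream on plus, complemented;
        # a G on the minus strand is a C on plus
        nxt = "G" if position - 1 >= 0 and seq[position - 1] == "C" else (
            None if position - 1 < 0 else "H"
        )
        nxt2 = "G" if position - 2 >= 0 and seq[position - 2] == "C" else (
            None if position - 2 < 0 else "H"
        )
    else:
        raise ContractError(f"invalid strand {strand!r}")
    if nxt == "G":
        return "CG"
    if nxt is None or nxt2 is None:
        return "CHH"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


@dataclass(frozen=True)
class CSite:
    contig: str
    position: int  # 0-based position of the C on its strand
    strand: str
    context: str
    total: int
    unconverted: int

    def __post_init__(self):
        if self.unconverted > self.total:
            raise ContractError("unconverted exceeds total")
        if self.context not in CONTEXTS:
            raise ContractError(f"unknown context {self.context!r}")


@dataclass
class MethylationTable:
    """Per-cytosine bisulfite calls as a DataFrame.

    Columns: contig, position, strand, context, total, unconverted.
    """

    sites: pd.DataFrame

    def __len__(self) -> int:
        return len(self.sites)

    def fractions(self) -> pd.Series:
        covered = self.sites["total"] > 0
        out = pd.Series(np.nan, index=self.sites.index)
        out[covered] = (
            self.sites.loc[covered, "unconverted"] / self.sites.loc[covered, "total"]
        )
        return out

    def genome_wide_proportion(
        self, cutoff: float = 0.05, contexts: Sequence[str] = ("CG", "CHG")
    ) -> float:
        """Fraction of covered sites (in the given contexts) with
        methylation strictly above the cutoff."""
        sub = self.sites[
            self.sites["context"].isin(contexts) & (self.sites["total"] > 0)
        ]
        if len(sub) == 0:
            raise ContractError("no covered sites in the requested contexts")
        frac = sub["unconverted"] / sub["total"]
        return float((frac > cutoff).mean())


def site_fraction(site: CSite) -> float:
    """Methylation fraction at one site: unconverted / total."""
    if site.total <= 0:
        raise ContractError("site has no coverage")
    return site.unconverted / site.total


def read_methylation_tsv(path) -> MethylationTable:
    df = pd.read_csv(path, sep="\t")
    df.columns = ["contig", "position", "strand", "context", "total", "unconverted"]
    return MethylationTable(df)


def write_methylation_tsv(table: MethylationTable, path) -> None:
    table.sites.to_csv(path, sep="\t", index=False)


@dataclass
class EnrichmentResult:
    per_class: pd.DataFrame  # observed, total, expected, chi2, p per repeat class
    genome_wide_proportion: float
    cutoff: float


def repeat_enrichment(
    table: MethylationTable,
    repeats: Iterable[RepeatAnnotation],
    cutoff: float = 0.05,
    contexts: Sequence[str] = ("CG", "CHG"),
) -> EnrichmentResult:
    """Repeat-class enrichment of methylated sites.

    Per class: observed = covered sites inside the class's intervals with
    methylation fraction strictly > cutoff; expected = class site total x
    genome-wide proportion of sites above the cutoff; significance from a
    two-cell 1-df chi-squared (above-cutoff vs not). Classes with zero
    covered sites are omitted.
    """
    gw = table.genome_wide_proportion(cutoff, contexts)
    sub = table.sites[
        table.sites["context"].isin(contexts) & (table.sites["total"] > 0)
    ].copy()
    sub["meth"] = sub["unconverted"] / sub["total"] > cutoff

    by_contig: Dict[str, List[RepeatAnnotation]] = defaultdict(list)
    for rep in repeats:
        by_contig[rep.contig].append(rep)

    rows = {}
    for contig, reps in by_contig.items():
        csites = sub[sub["contig"] == contig]
        if len(csites) == 0:
            continue
        pos = csites["position"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order].tolist()
        meth_sorted = csites["meth"].to_numpy()[order]
        for rep in reps:
            lo = bisect_left(pos_sorted, rep.start)
            hi = bisect_left(pos_sorted, rep.end)
            n_tot = hi - lo
            n_obs = int(meth_sorted[lo:hi].sum())
            cur = rows.setdefault(rep.rclass, [0, 0])
            cur[0] += n_obs
            cur[1] += n_tot

    records = []
    for rclass in sorted(rows):
        obs, tot = rows[rclass]
        if tot == 0:
            continue  # class with no covered sites: omitted
        exp = tot * gw
        if exp == 0 or exp == tot:
            x2, p = np.nan, np.nan
        else:
            x2 = (obs - exp) ** 2 / exp + ((tot - obs) - (tot - exp)) ** 2 / (tot - exp)
            p = float(stats.chi2.sf(x2, 1))
        records.append((rclass, obs, tot, exp, x2, p))
    frame = pd.DataFrame(
        records, columns=["class", "observed", "total", "expected", "chi2", "p"]
    ).set_index("class")
    return EnrichmentResult(frame, gw, cutoff)


@dataclass
class SrnaAssociation:
    densities: pd.DataFrame  # per gene: contig, start, end, methylated, density
    u_statistic: float
    p_value: float
    curves: Dict[str, Tuple[np.ndarray, np.ndarray]]  # group -> (grid, density)


def srna_association(
    genes: Sequence,
    alignments: AlignmentSet,
    weight: str = "count",
) -> SrnaAssociation:
    """Small RNA density at methylated vs unmethylated genes.

    Genes are (contig, start, end, strand, methylated) records (the
    generator's Gene type or equivalent tuples). Density = overlapping
    read count per kb of gene length. Tests methylated > unmethylated by
    one-sided Mann-Whitney U; returns kernel density curves of
    log10(density + 0.1) per group for plotting.
    """
    gene_list = []
    for g in genes:
        if hasattr(g, "contig"):
            gene_list.append((g.contig, g.start, g.end, bool(g.methylated)))
        else:
            contig, start, end = g[0], g[1], g[2]
            gene_list.append((contig, start, end, bool(g[-1])))
    n_meth = sum(1 for g in gene_list if g[3])
    if n_meth < 3 or len(gene_list) - n_meth < 3:
        raise ContractError("need at least 3 genes in each methylation group")

    by_contig: Dict[str, List[Tuple[int, int, int]]] = defaultdict(list)
    for aln in alignments.alignments:
        w = 1 if weight == "unique" else alignments.counts[aln.read_id]
        by_contig[aln.contig].append((aln.start, aln.end, w))
    for lst in by_contig.values():
        lst.sort()

    rows = []
    for contig, start, end, methylated in gene_list:
        reads = by_contig.get(contig, ())
        total = 0
        if reads:
            starts = [r[0] for r in reads]
            maxlen = max(r[1] - r[0] for r in reads)
            lo = bisect_left(starts, start - maxlen)
            hi = bisect_right(starts, end)
            for a, b, w in reads[lo:hi]:
                if min(b, end) - max(a, start) > 0:
                    total += w
        density = total / ((end - start) / 1000.0)
        rows.append((contig, start, end, methylated, density))
    frame = pd.DataFrame(
        rows, columns=["contig", "start", "end", "methylated", "density"]
    )
    meth = frame.loc[frame["methylated"], "density"].to_numpy()
    unmeth = frame.loc[~frame["methylated"], "density"].to_numpy()
    u, p = stats.mannwhitneyu(meth, unmeth, alternative="greater")

    curves = {}
    for label, values in (("methylated", meth), ("all_unmethylated", unmeth)):
        logv = np.log10(values + 0.1)
        grid = np.linspace(logv.min() - 1, logv.max() + 1, 256)
        if np.ptp(logv) == 0:
            dens = np.zeros_like(grid)
        else:
            dens = stats.gaussian_kde(logv)(grid)
        curves[label] = (grid, dens)
    return SrnaAssociation(frame, float(u), float(p), curves)
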