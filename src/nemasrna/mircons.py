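"""miRNA conservation calling and cross-species correlations.

Reference mature miRNAs are searched for in a target species' expressed
small RNA library at three nested stringencies combining sequence
conservation with an expression floor: tier 3 requires a near-exact copy
(Hamming distance <= 1 over the full mature sequence), tier 2 an
identical seed (nucleotides 2-8) with at most 3 mismatches overall, and
tier 1 an identical seed. Calls are cumulative (a tier-3 call satisfies
the tier-2 and tier-1 conditions by construction) so the per-tier
conserved fractions are non-increasing with stringency. Conserved
fractions can be correlated against phylogenetic distance, and
developmental (adult vs larva) expression fold-changes against those of
the homologous reference miRNAs, both by Spearman rank correlation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, UndefinedCorrelationError
from .sio import SmallRNALibrary, rna


@dataclass(frozen=True)
class MatureMiRNA:
    name: str
    sequence: str  # mature sequence, RNA alphabet
    family: Optional[str] = None  # shared-seed family id

    def __post_init__(self):
        object.__setattr__(self, "sequence", rna(self.sequence))
        if not 18 <= len(self.sequence) <= 26:
            raise ContractError(
                f"mature miRNA {self.name!r} length {len(self.sequence)} "
                "outside 18-26"
            )

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 of the mature sequence."""
        return self.sequence[1:8]


def read_mature_fasta(path) -> List[MatureMiRNA]:
    from Bio import SeqIO

    return [
        MatureMiRNA(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def assign_families(mirnas: List[MatureMiRNA]) -> List[MatureMiRNA]:
    """Group miRNAs into shared-seed families."""
    seeds: Dict[str, str] = {}
    out = []
    for mi in mirnas:
        fam = seeds.setdefault(mi.seed, f"fam-{mi.seed}")
        out.append(MatureMiRNA(mi.name, mi.sequence, fam))
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class ConservationCall:
    """Per-reference tiers and supporting expression in one target library."""

    calls: pd.DataFrame  # index reference name; tier (0-3), rpm
    fractions: Dict[int, float]  # tier -> conserved fraction

    def tier(self, name: str) -> int:
        return int(self.calls.loc[name, "tier"])


def call_conservation(
    reference: List[MatureMiRNA],
    target: SmallRNALibrary,
    min_rpm: float = 1.0,
) -> ConservationCall:
    """Tiered conservation calls of reference miRNAs in a target library.

    Expression (reads per million, using the library's pre-collapse total
    when available) of all qualifying target sequences must reach
    ``min_rpm`` for a call at any tier. Tiers are cumulative: a reference
    is called at tier k iff the conditions of all tiers <= k hold for
    some qualifying expression-supported sequence set.
    """
    if not reference:
        raise ContractError("empty reference miRNA set")
    total = target.total_input_count or target.total_count
    if total == 0:
        raise ContractError("target library is empty")
    # index target sequences by seed for tier-1/2 lookups
    by_seed: Dict[str, List[Tuple[str, float]]] = defaultdict(list)
    for r in target.reads:
        if len(r) >= 8:
            by_seed[r.sequence[1:8]].append((r.sequence, r.count / total * 1e6))

    rows = []
    for ref in reference:
        cands = by_seed.get(ref.seed, ())
        tier1_rpm = sum(rpm for _, rpm in cands)
        tier2_rpm = sum(
            rpm
            for seq, rpm in cands
            if len(seq) == len(ref.sequence) and _hamming(seq, ref.sequence) <= 3
        )
        tier3_rpm = sum(
            rpm
            for seq, rpm in cands
            if len(seq) == len(ref.sequence) and _hamming(seq, ref.sequence) <= 1
        )
        tier = 0
        rpm = 0.0
        if tier1_rpm >= min_rpm:
            tier, rpm = 1, tier1_rpm
            if tier2_rpm >= min_rpm:
                tier, rpm = 2, tier2_rpm
                if tier3_rpm >= min_rpm:
                    tier, rpm = 3, tier3_rpm
        rows.append((ref.name, tier, rpm))
    calls = pd.DataFrame(rows, columns=["name", "tier", "rpm"]).set_index("name")
    fractions = {
        k: float((calls["tier"] >= k).mean()) for k in (1, 2, 3)
    }
    return ConservationCall(calls, fractions)


def distance_correlation(
    fractions: Mapping[str, float], distances: Mapping[str, float]
) -> Tuple[float, float]:
    """Spearman correlation of conserved fraction against distance.

    Species present in both mappings are used; at least 4 are required.
    The sign is reported as-is (negative when conservation falls with
    distance).
    """
    shared = sorted(set(fractions) & set(distances))
    if len(shared) < 4:
        raise ContractError("distance correlation requires >= 4 shared species")
    f = np.array([fractions[s] for s in shared], dtype=float)
    d = np.array([distances[s] for s in shared], dtype=float)
    if np.ptp(f) == 0 or np.ptp(d) == 0:
        raise UndefinedCorrelationError("constant input")
    rho, p = stats.spearmanr(f, d)
    return float(rho), float(p)


def _rpm_map(library: SmallRNALibrary) -> Tuple[Dict[str, float], float]:
    total = library.total_input_count or library.total_count
    out: Dict[str, float] = defaultdict(float)
    for r in library.reads:
        out[r.sequence] += r.count / total * 1e6
    return out, total


def dev_expression_correlation(
    adult: SmallRNALibrary,
    larva: SmallRNALibrary,
    homolog_map: Mapping[str, str],
    reference_foldchanges: Mapping[str, float],
) -> Tuple[pd.Series, float, float]:
    """Developmental fold-change correlation against a reference species.

    Per shared miRNA, log2((adult RPM + 1) / (larva RPM + 1)) is computed
    for the target sequence named in ``homolog_map`` (reference miRNA ->
    target library sequence) and rank-correlated against the reference
    species' fold-changes. At least 5 shared miRNAs are required.
    """
    adult_rpm, _ = _rpm_map(adult)
    larva_rpm, _ = _rpm_map(larva)
    rows = {}
    for ref_name, target_seq in homolog_map.items():
        if ref_name not in reference_foldchanges:
            continue
        seq = rna(target_seq)
        a = adult_rpm.get(seq, 0.0)
        l = larva_rpm.get(seq, 0.0)
        if a == 0.0 and l == 0.0:
            continue
        rows[ref_name] = np.log2((a + 1.0) / (l + 1.0))
    if len(rows) < 5:
        raise ContractError(
            "developmental correlation requires >= 5 shared expressed miRNAs"
        )
    fc = pd.Series(rows, name="log2_fold_change").sort_index()
    ref = np.array([reference_foldchanges[n] for n in fc.index])
    rho, p = stats.spearmanr(fc.to_numpy(), ref)
    return fc, float(rho), float(p)


def write_calls_tsv(call: ConservationCall, path) -> None:
    call.calls.to_csv(path, sep="\t")
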