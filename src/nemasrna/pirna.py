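"""piRNA diagnostics: upstream motif, genomic clustering, ping-pong.

Putative piRNAs (21 nt, 5' U, uniquely aligned by default) are
characterized by three genomic signatures: a conserved core motif in the
sequence upstream of their 5' ends (found here by a ZOOPS-style EM motif
finder over a fixed upstream window), concentration of reads into dense
genomic clusters (100 kb windows; the cumulative read-density curve is
compared across species by a two-sample KS test), and the ping-pong
amplification signature (opposite-strand pairs whose 5' ends overlap by
10 nt, with adenine enriched at position 10 of the 5'-most read).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .sio import Alignment, AlignmentSet, revcomp_dna

DNA_NTS = "ACGT"


@dataclass
class UpstreamSet:
    """Strand-corrected upstream windows adjacent to small RNA 5' ends.

    Position ``window`` of each sequence abuts the small RNA's first
    base; sequences are written 5'->3' on the small RNA's strand.
    """

    window: int
    sequences: List[str]
    n_skipped: int = 0

    def __post_init__(self):
        for s in self.sequences:
            if len(s) != self.window:
                raise ContractError("upstream sequence length != window")

    def __len__(self) -> int:
        return len(self.sequences)


def default_pirna_candidate(aln: Alignment, sequence: str) -> bool:
    """Length 21, first nucleotide U, uniquely aligned."""
    return aln.length == 21 and sequence.startswith("U") and aln.n_occurrences == 1


def extract_upstream(
    alignments: AlignmentSet,
    genome,
    window: int = 60,
    candidate: Optional[Callable[[Alignment, str], bool]] = None,
) -> UpstreamSet:
    """Upstream windows of candidate piRNA alignments.

    For + alignments [a, b): genomic [a - window, a); for -: the reverse
    complement of genomic [b, b + window). Candidates within ``window``
    of a contig edge are skipped and counted.
    """
    contigs = getattr(genome, "contigs", genome)
    if candidate is None:
        candidate = default_pirna_candidate
    sequences: List[str] = []
    skipped = 0
    for aln in alignments.alignments:
        if not candidate(aln, alignments.sequences[aln.read_id]):
            continue
        seq = contigs[aln.contig]
        if aln.strand == "+":
            if aln.start < window:
                skipped += 1
                continue
            sequences.append(seq[aln.start - window : aln.start])
        else:
            if aln.end + window > len(seq):
                skipped += 1
                continue
            sequences.append(revcomp_dna(seq[aln.end : aln.end + window]))
    return UpstreamSet(window, sequences, skipped)


@dataclass
class MotifModel:
    """Fixed-width PWM with a 0-order background."""

    width: int
    pwm: np.ndarray  # width x 4, columns sum... rows are positions, cols ACGT
    background: np.ndarray  # 4 probabilities
    log_likelihood: float
    occurrence_prior: float  # fitted ZOOPS gamma

    @property
    def consensus(self) -> str:
        return "".join(DNA_NTS[j] for j in self.pwm.argmax(axis=1))

    @property
    def information_content(self) -> float:
        """Total KL information (bits) of the PWM against the background."""
        p = np.clip(self.pwm, 1e-12, None)
        return float(np.sum(p * np.log2(p / self.background[None, :])))

    def consensus_matches(self, motif: str) -> int:
        """Number of consensus positions matching a reference motif."""
        motif = motif.upper()
        return sum(a == b for a, b in zip(self.consensus, motif))


def _encode(sequences: List[str]) -> np.ndarray:
    lookup = np.full(128, -1, dtype=np.int8)
    for j, nt in enumerate(DNA_NTS):
        lookup[ord(nt)] = j
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    codes = lookup[arr].reshape(len(sequences), -1)
    if (codes < 0).any():
        # non-ACGT characters: assign uniformly at random-free choice A
        codes = np.where(codes < 0, 0, codes)
    return codes.astype(np.int64)


def discover_motif(
    upstream: UpstreamSet,
    width: int = 8,
    n_starts: int = 50,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> MotifModel:
    """ZOOPS EM motif discovery over the upstream windows.

    The model allows zero or one motif occurrence per sequence with prior
    gamma, uniform over positions given occurrence, and a 0-order
    background elsewhere. Restarts are seeded from the ``n_starts`` most
    over-represented width-mers (observed/expected under the background);
    the highest-likelihood fitted model is returned. Deterministic given
    the seed.
    """
    if len(upstream) < 20:
        raise ContractError("motif discovery requires at least 20 sequences")
    if upstream.window < width:
        raise ContractError("sequences shorter than the motif width")
    codes = _encode(upstream.sequences)
    n, W = codes.shape
    m = W - width + 1
    # sliding windows view: n x m x width
    windows = np.lib.stride_tricks.sliding_window_view(codes, width, axis=1)

    background = np.bincount(codes.ravel(), minlength=4).astype(float)
    background /= background.sum()

    # rank width-mers by observed / expected under the background
    kmer_counts: Dict[Tuple[int, ...], int] = defaultdict(int)
    flat = windows.reshape(-1, width)
    for row in map(tuple, flat):
        kmer_counts[row] += 1
    log_bg = np.log(background)

    def over_representation(kmer: Tuple[int, ...]) -> float:
        expected = math.exp(sum(log_bg[c] for c in kmer)) * flat.shape[0]
        return kmer_counts[kmer] / expected

    ranked = sorted(
        kmer_counts, key=lambda k: (-over_representation(k), k)
    )[:n_starts]

    rng = np.random.default_rng(seed)
    best: Optional[MotifModel] = None
    bg_ll_window = log_bg[windows].sum(axis=2)  # n x m, log P(window | bg)
    for kmer in ranked:
        pwm = np.full((width, 4), 0.1)
        for i, c in enumerate(kmer):
            pwm[i, c] = 0.7
        # tiny seeded jitter breaks symmetry between equivalent starts
        pwm += rng.random((width, 4)) * 1e-4
        pwm /= pwm.sum(axis=1, keepdims=True)
        gamma = 0.5
        prev_ll = -np.inf
        for _ in range(max_iter):
            log_pwm = np.log(np.clip(pwm, 1e-12, None))
            # per-window motif log-prob: sum over positions of log_pwm[k, base]
            motif_ll = np.zeros((n, m))
            for k in range(width):
                motif_ll += log_pwm[k, windows[:, :, k]]
            log_ratio = motif_ll - bg_ll_window
            ratio = np.exp(np.clip(log_ratio, -700, 700))
            # posterior over positions and the no-occurrence event
            w_pos = (gamma / m) * ratio  # n x m
            denom = (1.0 - gamma) + w_pos.sum(axis=1)  # n
            z = w_pos / denom[:, None]
            q = z.sum(axis=1)  # P(sequence has an occurrence)
            # M-step
            new_pwm = np.full((width, 4), 0.25)  # Dirichlet(0.25) smoothing
            for k in range(width):
                for c in range(4):
                    new_pwm[k, c] += z[windows[:, :, k] == c].sum()
            new_pwm /= new_pwm.sum(axis=1, keepdims=True)
            gamma = float(np.clip(q.mean(), 1e-6, 1 - 1e-6))
            pwm = new_pwm
            # full log-likelihood: sum_i log((1-gamma) + (gamma/m) sum_j ratio_ij)
            # + log P(seq_i | background), the latter constant across models
            seq_bg_ll = log_bg[codes].sum(axis=1)
            ll = float(np.sum(np.log(denom) + seq_bg_ll))
            if abs(ll - prev_ll) < tol * max(1.0, abs(prev_ll)):
                prev_ll = ll
                break
            prev_ll = ll
        model = MotifModel(width, pwm, background, prev_ll, gamma)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Cluster density


@dataclass
class ClusterProfile:
    """Read density in fixed genomic windows.

    ``window_counts`` maps contig -> per-window read counts; densities
    are counts per window. ``per_read_densities`` holds, for every read
    (weighted by count), the density of the window it falls in — the
    sample the cross-species KS test is computed on.
    """

    window_size: int
    window_counts: Dict[str, np.ndarray]
    threshold_factor: float
    mean_density: float
    flagged_fraction: float  # fraction of reads in windows > factor x mean
    per_read_densities: np.ndarray
    cumulative_curve: pd.DataFrame  # density, fraction of reads at >= density

    @property
    def total_reads(self) -> float:
        return float(self.per_read_densities.size)


def cluster_density(
    alignments: AlignmentSet,
    genome,
    window_size: int = 100_000,
    threshold_factor: float = 10.0,
    weight: str = "unique",
) -> ClusterProfile:
    """Bin reads into fixed windows and measure clustering.

    Reads are assigned to the window containing their 5' end. The mean
    density is taken over all windows of the genome (including empty
    ones); the flagged fraction is the fraction of reads residing in
    windows with density strictly greater than threshold_factor x mean.
    """
    contigs = getattr(genome, "contigs", genome)
    window_counts: Dict[str, np.ndarray] = {}
    for name in sorted(contigs):
        n_windows = max(1, -(-len(contigs[name]) // window_size))
        window_counts[name] = np.zeros(n_windows)
    per_read: List[Tuple[str, int, int]] = []  # contig, window index, weight
    for aln in alignments.alignments:
        w = 1 if weight == "unique" else alignments.counts[aln.read_id]
        idx = min(aln.five_prime // window_size,
                  window_counts[aln.contig].size - 1)
        window_counts[aln.contig][idx] += w
        per_read.append((aln.contig, idx, w))

    all_counts = np.concatenate(list(window_counts.values()))
    mean_density = float(all_counts.mean())
    densities = np.concatenate(
        [np.repeat(window_counts[c][i], w) for c, i, w in per_read]
    ) if per_read else np.array([])
    total = densities.size
    if total:
        flagged = float(
            (densities > threshold_factor * mean_density).sum() / total
        )
        uniq = np.unique(densities)
        frac_ge = [(densities >= d).sum() / total for d in uniq]
        curve = pd.DataFrame({"density": uniq, "fraction_reads_ge": frac_ge})
    else:
        flagged = 0.0
        curve = pd.DataFrame(columns=["density", "fraction_reads_ge"])
    return ClusterProfile(
        window_size, window_counts, threshold_factor, mean_density, flagged,
        densities, curve,
    )


def compare_density(a: ClusterProfile, b: ClusterProfile) -> Tuple[float, float]:
    """Two-sample KS test on per-read window densities."""
    if a.per_read_densities.size == 0 or b.per_read_densities.size == 0:
        raise ContractError("both cluster profiles must contain reads")
    res = stats.ks_2samp(a.per_read_densities, b.per_read_densities)
    return float(res.statistic), float(res.pvalue)


def write_bedgraph(profile: ClusterProfile, genome, path) -> None:
    contigs = getattr(genome, "contigs", genome)
    with open(path, "w") as fh:
        for name in sorted(profile.window_counts):
            counts = profile.window_counts[name]
            clen = len(contigs[name])
            for i, c in enumerate(counts):
                start = i * profile.window_size
                end = min(start + profile.window_size, clen)
                fh.write(f"{name}\t{start}\t{end}\t{c:g}\n")


# ---------------------------------------------------------------------------
# Ping-pong


@dataclass
class OverlapHistogram:
    """5'-5' overlap histogram of opposite-strand alignment pairs."""

    counts: pd.Series  # index overlap 1..30
    z_score_10: float
    tenth_a_fraction: float  # among 10-overlap pairs, A at position 10
    n_pairs_10: int

    @property
    def modal_overlap(self) -> int:
        return int(self.counts.idxmax())


def ping_pong(alignments: AlignmentSet, max_overlap: int = 30) -> OverlapHistogram:
    """Ping-pong 5' overlap signature.

    For every +/- alignment pair on one contig with 5' overlap
    k = 5'(-) - 5'(+) + 1 in 1..max_overlap, counts[k] is incremented
    once per distinct (5'+, 5'-) coordinate pair. The z-score compares
    counts[10] with the mean and SD of the other overlaps; among
    10-overlap pairs the fraction of 5'-most (smaller 5' coordinate)
    reads with adenine at position 10 is reported.
    """
    plus5: Dict[str, Dict[int, str]] = defaultdict(dict)  # contig -> 5' -> read_id
    minus5: Dict[str, set] = defaultdict(set)
    for aln in alignments.alignments:
        if aln.strand == "+":
            plus5[aln.contig].setdefault(aln.five_prime, aln.read_id)
        elif aln.strand == "-":
            minus5[aln.contig].add(aln.five_prime)
        else:
            raise ContractError("ping_pong requires stranded alignments")
    counts = np.zeros(max_overlap + 1, dtype=np.int64)  # index 0 unused
    tenth_a = 0
    tenth_total = 0
    for contig, p5map in plus5.items():
        m5 = minus5.get(contig)
        if not m5:
            continue
        for fp, read_id in p5map.items():
            for k in range(1, max_overlap + 1):
                if fp + k - 1 in m5:
                    counts[k] += 1
                    if k == 10:
                        # 5'-most read is the plus read (its 5' coordinate
                        # is smaller for any positive overlap)
                        seq = alignments.sequences[read_id]
                        if len(seq) >= 10:
                            tenth_total += 1
                            tenth_a += seq[9] == "A"
    others = counts[1:][np.arange(1, max_overlap + 1) != 10]
    sd = float(others.std(ddof=1))
    if sd == 0:
        z = 0.0 if counts[10] == others.mean() else float("inf")
    else:
        z = float((counts[10] - others.mean()) / sd)
    frac = tenth_a / tenth_total if tenth_total else float("nan")
    series = pd.Series(counts[1:], index=pd.Index(range(1, max_overlap + 1),
                                                  name="overlap"))
    return OverlapHistogram(series, z, frac, tenth_total)


# ---------------------------------------------------------------------------
# Motif output formats


def write_motif_meme(model: MotifModel, path, name: str = "motif1") -> None:
    """Minimal MEME-format text block."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{nt} {p:.4f}" for nt, p in zip(DNA_NTS, model.background))
            + "\n\n"
        )
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {model.width}\n"
        )
        for row in model.pwm:
            fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")


def write_motif_tsv(model: MotifModel, path) -> None:
    pd.DataFrame(model.pwm, columns=list(DNA_NTS)).rename_axis("position").to_csv(
        path, sep="\t"
    )
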