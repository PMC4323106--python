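"""Protein conservation scoring and the jackknife incongruity test.

Conservation of a query proteome across species is summarized as the
best local-alignment hit per (query, species), scored in bits and
normalized by query length — a more stable measure than the e-value for
cross-species comparison. The normalized matrix is binarized at a
presence threshold and resampled (jackknife) to ask how often a
designated outgroup ranks above every species in a comparison set, which
quantifies how unusual a single protein's loss pattern is against the
proteome-wide background. A sequence-evolution simulator (WAG model)
supports spike-in detectability tests: evolve a query to a given
distance, hide it in a decoy proteome, and check it still scores far
above the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from scipy.linalg import expm

from .errors import ContractError, ParameterError

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

# Karlin-Altschul constants for gapped BLOSUM62 with open 11 / extend 1
LAMBDA_GAPPED = 0.267
K_GAPPED = 0.041


def _blosum62_x_zero():
    """BLOSUM62 with X scored 0 against everything (incl. itself)."""
    m = substitution_matrices.load("BLOSUM62")
    arr = np.array(m)
    alpha = m.alphabet
    xi = alpha.index("X")
    arr[xi, :] = 0.0
    arr[:, xi] = 0.0
    out = substitution_matrices.Array(alphabet=alpha, dims=2, data=arr)
    return out


_MATRIX = _blosum62_x_zero()


def _make_aligner(gap_open: int = 11, gap_extend: int = 1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _MATRIX
    # a gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class ScoredHit:
    query_id: str
    target_id: str
    raw: float
    bitscore: float
    evalue: float
    normalized: float  # bitscore / query length


def bit_score(raw: float, lam: float = LAMBDA_GAPPED, k: float = K_GAPPED) -> float:
    return (lam * raw - math.log(k)) / math.log(2.0)


def e_value(bitscore: float, m: int, n: int) -> float:
    return m * n * 2.0 ** (-bitscore)


def _validate_protein(seq: str, label: str) -> str:
    if not seq:
        raise ContractError(f"{label}: empty protein sequence")
    seq = seq.upper()
    bad = set(seq) - set(AA_ALPHABET + "X")
    if bad:
        raise ContractError(f"{label}: invalid residues {sorted(bad)}")
    return seq


def local_align_score(
    query: str,
    target: str,
    query_id: str = "query",
    target_id: str = "target",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> ScoredHit:
    """Smith-Waterman local alignment score with affine gaps.

    Raw score uses BLOSUM62 (X scored 0) with a gap of length k costing
    ``gap_open + k * gap_extend``. Bit score and e-value use the standard
    gapped Karlin-Altschul constants; e-value = m * n * 2**(-bits).
    """
    q = _validate_protein(query, query_id)
    t = _validate_protein(target, target_id)
    if gap_open == 11 and gap_extend == 1:
        aligner = _DEFAULT_ALIGNER
    else:
        aligner = _make_aligner(gap_open, gap_extend)
    raw = float(aligner.score(q, t))
    raw = max(raw, 0.0)
    bits = bit_score(raw)
    return ScoredHit(
        query_id, target_id, raw, bits, e_value(bits, len(q), len(t)), bits / len(q)
    )


@dataclass
class ConservationMatrix:
    """Queries x species matrix of length-normalized best-hit bit scores."""

    scores: pd.DataFrame  # index query ids, columns species

    def log_display(self, floor: float = 1e-3) -> pd.DataFrame:
        return np.log10(self.scores.clip(lower=floor))


def best_hit_matrix(
    queries: Mapping[str, str],
    species: Mapping[str, Mapping[str, str]],
    min_raw: float = 0.0,
) -> ConservationMatrix:
    """Best-hit conservation matrix: entry (q, s) = max bitscore / len(q).

    A species entry is 0 when no target alignment scores above ``min_raw``
    raw (absence). Empty proteomes yield a column of zeros.
    """
    if not species:
        raise ContractError("at least one species proteome is required")
    names = list(species)
    data = np.zeros((len(queries), len(names)))
    for qi, (qid, qseq) in enumerate(queries.items()):
        for si, sname in enumerate(names):
            best = 0.0
            for tid, tseq in species[sname].items():
                hit = local_align_score(qseq, tseq, qid, tid)
                if hit.raw > min_raw and hit.normalized > best:
                    best = hit.normalized
            data[qi, si] = best
    return ConservationMatrix(pd.DataFrame(data, index=list(queries), columns=names))


def binarize(matrix: ConservationMatrix, threshold: float = 0.18) -> pd.DataFrame:
    """Presence/absence calls: present iff normalized score >= threshold."""
    return matrix.scores >= threshold


@dataclass(frozen=True)
class JackknifeConfig:
    threshold: float = 0.18
    removal_fraction: float = 0.10
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.removal_fraction < 1.0:
            raise ParameterError("removal fraction must be in (0, 1)")
        if self.reps < 1:
            raise ParameterError("reps must be >= 1")


@dataclass(frozen=True)
class JackknifeResult:
    reps: int
    hits: int
    p_estimate: float  # hits/reps, or 1/reps bound when hits == 0
    p_is_bound: bool

    def __str__(self) -> str:
        if self.p_is_bound:
            return f"p < {1.0 / self.reps:g} ({self.hits}/{self.reps} resamples)"
        return f"p = {self.p_estimate:g} ({self.hits}/{self.reps} resamples)"


def jackknife_incongruity(
    binary: pd.DataFrame,
    outgroup: str,
    comparison: Sequence[str],
    config: JackknifeConfig = JackknifeConfig(),
) -> JackknifeResult:
    """Jackknife test of outgroup-ranks-above-all incongruity.

    Each of ``config.reps`` resamples drops a uniformly random
    ``floor(removal_fraction * n)`` subset of the proteins and counts
    presences per species on the remainder. A hit is a resample in which
    the outgroup's presence count strictly exceeds every comparison
    species' count (ties are not hits). Reported p is hits/reps, stated
    as the bound 1/reps when no hit occurs.
    """
    comparison = list(comparison)
    if outgroup in comparison:
        raise ParameterError("outgroup must not be in the comparison set")
    n = binary.shape[0]
    if n < 10:
        raise ContractError("jackknife requires at least 10 proteins")
    n_drop = int(config.removal_fraction * n)
    if n_drop < 1:
        raise ParameterError("removal fraction leaves no protein to drop")
    cols = [outgroup] + comparison
    presence = binary[cols].to_numpy(dtype=np.float64)
    rng = np.random.default_rng(config.seed)
    hits = 0
    # Chunked vectorization: each rep keeps n - n_drop random proteins.
    chunk = max(1, min(config.reps, 64_000_000 // max(n, 1)))
    done = 0
    while done < config.reps:
        m = min(chunk, config.reps - done)
        keep = np.ones((m, n), dtype=np.float64)
        # random subset of size n_drop per row, without replacement
        order = rng.random((m, n)).argsort(axis=1)[:, :n_drop]
        np.put_along_axis(keep, order, 0.0, axis=1)
        counts = keep @ presence  # m x (1 + n_comparison)
        hits += int(np.sum(counts[:, 0] > counts[:, 1:].max(axis=1)))
        done += m
    if hits == 0:
        return JackknifeResult(config.reps, 0, 1.0 / config.reps, True)
    return JackknifeResult(config.reps, hits, hits / config.reps, False)


# ---------------------------------------------------------------------------
# Protein sequence evolution (WAG model)


@dataclass
class EvolutionModel:
    """Continuous-time amino acid substitution model.

    ``exchangeabilities`` is the symmetric rate-multiplier matrix S and
    ``frequencies`` the equilibrium distribution pi; the generator is
    Q_ij = S_ij * pi_j (i != j), diagonal set so rows sum to 0, scaled to
    one expected substitution per site per unit distance.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alphabet: str = AA_ALPHABET
    rate_matrix: np.ndarray = field(init=False)

    def __post_init__(self):
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (20, 20) or not np.allclose(s, s.T):
            raise ParameterError("exchangeability matrix must be symmetric 20x20")
        pi = pi / pi.sum()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.dot(pi, np.diag(q))  # expected substitutions per site
        self.rate_matrix = q / scale
        self.frequencies = pi

    def transition_matrix(self, d: float) -> np.ndarray:
        """P(d) = exp(Q d); rows sum to 1."""
        if d < 0:
            raise ParameterError("distance must be >= 0")
        return expm(self.rate_matrix * d)


def load_wag() -> EvolutionModel:
    """The WAG model (Whelan & Goldman 2001) shipped with the package."""
    text = (
        resources.files("nemasrna").joinpath("data/wag.txt").read_text().splitlines()
    )
    rows = [ln for ln in text if ln and not ln.startswith("#")]
    alphabet = "".join(rows[0].split())
    s = np.array([[float(x) for x in ln.split()] for ln in rows[1:21]])
    pi = np.array([float(x) for x in rows[21].split()])
    # reorder from the file's PAML order into AA_ALPHABET order
    idx = [alphabet.index(a) for a in AA_ALPHABET]
    return EvolutionModel(s[np.ix_(idx, idx)], pi[idx])


_WAG: Optional[EvolutionModel] = None


def default_model() -> EvolutionModel:
    global _WAG
    if _WAG is None:
        _WAG = load_wag()
    return _WAG


def evolve_sequence(
    seq: str,
    d: float,
    model: Optional[EvolutionModel] = None,
    seed: int = 0,
) -> str:
    """Evolve a protein to distance ``d`` substitutions/site (no indels).

    Each site is independently replaced by a draw from the transition
    distribution P(d) conditioned on its current residue.
    """
    if d < 0:
        raise ParameterError("distance must be >= 0")
    model = model or default_model()
    seq = _validate_protein(seq, "evolve_sequence")
    if "X" in seq:
        raise ContractError("cannot evolve sequences containing X")
    if d == 0:
        return seq
    p = model.transition_matrix(d)
    rng = np.random.default_rng(seed)
    aa_index = {a: i for i, a in enumerate(model.alphabet)}
    states = np.fromiter((aa_index[a] for a in seq), dtype=np.int64, count=len(seq))
    u = rng.random(len(seq))
    cdf = np.cumsum(p, axis=1)
    new_states = (u[:, None] > cdf[states]).sum(axis=1)
    return "".join(model.alphabet[i] for i in new_states)


def random_protein(length: int, rng: np.random.Generator,
                   model: Optional[EvolutionModel] = None) -> str:
    """A random protein drawn from the model's equilibrium frequencies."""
    model = model or default_model()
    states = rng.choice(20, size=length, p=model.frequencies)
    return "".join(model.alphabet[i] for i in states)


@dataclass
class SpikeInResult:
    evolved_evalues: np.ndarray  # per-rep best-hit e-value of the evolved copy
    best_decoy_evalue: float
    distance: float

    @property
    def max_evolved_evalue(self) -> float:
        return float(self.evolved_evalues.max())

    @property
    def separated(self) -> bool:
        """True when even the weakest evolved hit beats every decoy."""
        return self.max_evolved_evalue < self.best_decoy_evalue


def spike_in_test(
    query: str,
    d: float,
    decoys: Mapping[str, str],
    reps: int = 1000,
    seed: int = 0,
    model: Optional[EvolutionModel] = None,
) -> SpikeInResult:
    """Evolution spike-in detectability test.

    Per rep, the query is evolved to distance ``d`` and spiked into the
    decoy proteome; the e-value of the query's hit to its evolved copy is
    recorded. Separately, the best (smallest) e-value of the query
    against the decoys alone is computed once. Detectability holds when
    the worst evolved-copy e-value over all reps is still below the best
    decoy e-value.
    """
    if not decoys:
        raise ContractError("decoy proteome must be non-empty")
    model = model or default_model()
    best_decoy = min(
        local_align_score(query, t, target_id=tid).evalue
        for tid, t in decoys.items()
    )
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(reps)
    evalues = np.empty(reps)
    for i in range(reps):
        evolved = evolve_sequence(query, d, model, seed=int(child_seeds[i]))
        evalues[i] = local_align_score(query, evolved, target_id=f"rep{i}").evalue
    return SpikeInResult(evalues, best_decoy, d)


# ---------------------------------------------------------------------------
# File formats


def read_proteome_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_proteome_fasta(proteome: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteome.items():
            fh.write(f">{pid}\n{seq}\n")


def read_blast_tabular(path) -> List[ScoredHit]:
    """12-column blastp tabular adapter (qseqid..bitscore); normalized
    score requires query lengths, so it is left 0 and filled by callers."""
    hits = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            bits = float(f[11])
            hits.append(ScoredHit(f[0], f[1], 0.0, bits, float(f[10]), 0.0))
    return hits


def write_matrix_tsv(matrix: ConservationMatrix, path) -> None:
    matrix.scores.rename_axis("query").to_csv(path, sep="\t")
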