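"""Length x first-nucleotide profiles and 5'-triphosphate inference.

A small RNA library is tabulated as a 15-33 nt x {A,C,G,U} count matrix.
Comparing the composition of a 5'-monophosphate-dependent library with a
5'-independent library from the same sample reveals 5'-triphosphate
populations (RdRP products such as 22G-RNAs): cells enriched in the
5'-independent protocol relative to the dependent one are called as
triphosphate-bearing. Periodate protection is scored as the ratio of a
selector class's frequency in treated vs control libraries (3'
2'-O-methylated classes survive oxidation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np
import pandas as pd

from .errors import ContractError, UndefinedRatioError
from .sio import SmallRNALibrary

LENGTHS = range(15, 34)
NUCLEOTIDES = ("A", "C", "G", "U")


@dataclass
class LengthNtProfile:
    """Counts over read length 15..33 x first nucleotide."""

    counts: pd.DataFrame  # index length, columns A C G U

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def frequencies(self) -> pd.DataFrame:
        total = self.total
        if total == 0:
            raise ContractError("profile is empty")
        return self.counts / total

    def modes(self) -> list:
        """All (length, nt) cells achieving the maximum count."""
        arr = self.counts.to_numpy()
        mx = arr.max()
        out = []
        for i, j in zip(*np.nonzero(arr == mx)):
            out.append((int(self.counts.index[i]), self.counts.columns[j]))
        return out

    def mode(self) -> Tuple[int, str]:
        return self.modes()[0]

    def modal_length(self) -> int:
        by_len = self.counts.sum(axis=1)
        return int(by_len.idxmax())


def empty_profile() -> pd.DataFrame:
    return pd.DataFrame(
        0, index=pd.Index(list(LENGTHS), name="length"), columns=list(NUCLEOTIDES)
    )


def length_first_nt(library: SmallRNALibrary) -> LengthNtProfile:
    """Tabulate length x first nucleotide, weighted by read counts.

    Reads must already be size-selected to 15-33 nt (run trim_filter
    first); an out-of-range read raises a contract error naming it.
    """
    counts = empty_profile()
    arr = counts.to_numpy()
    nt_index = {nt: j for j, nt in enumerate(NUCLEOTIDES)}
    for read in library.reads:
        L = len(read)
        if not 15 <= L <= 33:
            raise ContractError(
                f"read {read.id!r} has length {L} outside 15-33; run trim_filter"
            )
        arr[L - 15, nt_index[read.first_nt]] += read.count
    counts.iloc[:, :] = arr
    return LengthNtProfile(counts)


@dataclass
class PhosphateInference:
    """Per-cell protocol comparison and triphosphate calls.

    ``cells`` holds, per (length, first nt): frequency in the dependent
    and independent libraries, the pseudocount-regularized enrichment
    ratio (f_indep + eps) / (f_dep + eps), and the call flag.
    """

    cells: pd.DataFrame  # columns freq_dep, freq_indep, enrichment, called
    epsilon: float
    min_enrich: float
    min_frac: float

    @property
    def triphosphate_present(self) -> bool:
        return bool(self.cells["called"].any())

    def called_cells(self) -> pd.DataFrame:
        return self.cells[self.cells["called"]]

    def modal_called_length(self) -> int:
        """Length of the highest-frequency (5'-independent) called cell."""
        called = self.called_cells()
        if called.empty:
            raise ContractError("no cells were called triphosphate-enriched")
        top = called["freq_indep"].idxmax()
        return int(top[0])


def infer_triphosphate(
    dep: LengthNtProfile,
    indep: LengthNtProfile,
    epsilon: float = 1e-3,
    min_enrich: float = 2.0,
    min_frac: float = 0.01,
) -> PhosphateInference:
    """Call 5'-triphosphate-enriched cells by protocol differencing.

    Frequencies (not raw counts) are compared since the two libraries
    differ in depth. A cell is called iff its enrichment
    (f_indep + eps)/(f_dep + eps) >= min_enrich and f_indep >= min_frac;
    the library-level verdict is "triphosphate population present" iff
    any cell is called.
    """
    if dep.total == 0 or indep.total == 0:
        raise ContractError("both profiles must be non-empty")
    f_dep = dep.frequencies().stack()
    f_indep = indep.frequencies().stack()
    enrichment = (f_indep + epsilon) / (f_dep + epsilon)
    called = (enrichment >= min_enrich) & (f_indep >= min_frac)
    cells = pd.DataFrame(
        {
            "freq_dep": f_dep,
            "freq_indep": f_indep,
            "enrichment": enrichment,
            "called": called,
        }
    )
    cells.index.names = ["length", "first_nt"]
    return PhosphateInference(cells, epsilon, min_enrich, min_frac)


def protection_ratio(
    control: SmallRNALibrary,
    treated: SmallRNALibrary,
    selector: Callable[[int, str], bool],
    protected_threshold: float = 0.5,
) -> Tuple[float, bool]:
    """Periodate-protection ratio for a (length, first nt) selector class.

    ratio = selector-class frequency in treated / frequency in control;
    the class is classified protected iff ratio >= protected_threshold.
    """
    if treated.protocol.treatment != "periodate":
        raise ContractError("treated library must have periodate treatment")
    if control.protocol.treatment not in ("control", "none"):
        raise ContractError("control library must be an untreated control")

    def class_freq(lib: SmallRNALibrary) -> float:
        total = lib.total_count
        if total == 0:
            raise ContractError("library is empty")
        sel = sum(r.count for r in lib.reads if selector(len(r), r.first_nt))
        return sel / total

    f_control = class_freq(control)
    if f_control == 0:
        raise UndefinedRatioError("selector matches nothing in the control library")
    ratio = class_freq(treated) / f_control
    return ratio, ratio >= protected_threshold


def write_profile_tsv(profile: LengthNtProfile, path) -> None:
    profile.counts.to_csv(path, sep="\t")


def read_profile_tsv(path) -> LengthNtProfile:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "length"
    return LengthNtProfile(df[list(NUCLEOTIDES)].astype(int))


def plot_profile(profile: LengthNtProfile, ax=None, title: str = ""):
    """Stacked barplot (length on x, first-nt colors), mirroring the
    standard small RNA class figure. Requires matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    bottom = np.zeros(len(profile.counts))
    for nt, color in zip(NUCLEOTIDES, ("#e41a1c", "#377eb8", "#4daf4a", "#984ea3")):
        vals = profile.counts[nt].to_numpy()
        ax.bar(profile.counts.index, vals, bottom=bottom, label=nt, color=color)
        bottom += vals
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("reads")
    ax.set_title(title)
    ax.legend(title="5' nt")
    return ax
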