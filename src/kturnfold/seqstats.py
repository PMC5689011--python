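"""Positional nucleotide statistics over aligned k-turn sets.

Sets of k-turn sequences are anchored on the conserved (1b,1n,2b,2n)
G•A/A•G core by the annotator, so every member shares the label
vocabulary -1b..4n.  From an aligned set the module computes per-position
nucleotide frequencies, joint distributions of paired positions, and
sequence-logo matrices (per-column information content in bits, WebLogo
convention: IC = 2 - H2, letter height = frequency * IC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptySet
from .motif import CORE_LABELS, KTurnAnnotation, KTurnDuplex, annotate_kturn

BASES = ("A", "C", "G", "U")

#: archaeal box C/D -1b:-1n pair frequencies (database survey fixture).
#: The itemized pairs sum to 0.8847; the residual mass is spread uniformly
#: over the unlisted canonical (WC + wobble) pairs, here U:A alone.
ARCHAEAL_BOXCD_MINUS1_PAIRS: dict[str, float] = {
    "C:G": 0.3942,
    "G:C": 0.2308,
    "A:U": 0.1154,
    "U:U": 0.0721,
    "G:U": 0.0433,
    "U:G": 0.0289,
    "U:A": 1.0 - 0.8847,
}

#: bacterial ribosomal k-turn -1b:-1n pair frequencies (survey fixture).
BACTERIAL_RIBOSOMAL_MINUS1_PAIRS: dict[str, float] = {
    "C:G": 0.943,
    "G:C": 0.030,
    "U:A": 0.017,
    "U:G": 0.008,
    "A:U": 0.002,
}


@dataclass(frozen=True)
class AlignedKTurnSet:
    """Annotated members sharing the -1b..4n label frame, plus rejects."""

    members: tuple[KTurnAnnotation, ...]
    ids: tuple[str, ...]
    rejects: tuple[tuple[str, str], ...] = ()

    def __len__(self) -> int:
        return len(self.members)


def align_kturn_set(
    duplexes, require_core: bool = True
) -> AlignedKTurnSet:
    """Annotate each duplex; members share the core-anchored label frame.

    Inputs failing annotation are listed as rejects with the error text.
    Raises :class:`EmptySet` when no input is given.
    """
    duplexes = list(duplexes)
    if not duplexes:
        raise EmptySet("no sequences to align")
    members, ids, rejects = [], [], []
    for dup in duplexes:
        try:
            members.append(annotate_kturn(dup, require_core=require_core))
            ids.append(dup.id)
        except Exception as exc:  # noqa: BLE001 - reason goes in the report
            rejects.append((dup.id, f"{type(exc).__name__}: {exc}"))
    return AlignedKTurnSet(tuple(members), tuple(ids), tuple(rejects))


@dataclass(frozen=True)
class PositionFrequencyTable:
    """Per-label nucleotide frequencies over {A,C,G,U}; inosine counts as G."""

    frequencies: pd.DataFrame  # index: labels, columns: BASES
    n: int


def position_frequency_table(aligned: AlignedKTurnSet) -> PositionFrequencyTable:
    if not aligned.members:
        raise EmptySet("aligned set has no members")
    counts = pd.DataFrame(0.0, index=list(CORE_LABELS), columns=list(BASES))
    for ann in aligned.members:
        for label in CORE_LABELS:
            res = ann.residue(label)
            counts.loc[label, "G" if res == "I" else res] += 1.0
    freqs = counts / len(aligned.members)
    return PositionFrequencyTable(frequencies=freqs, n=len(aligned.members))


@dataclass(frozen=True)
class PairDistribution:
    """Joint distribution of an ordered position pair, descending."""

    pair: tuple[str, str]
    frequencies: pd.Series  # index "X:Y", values sum to 1, descending
    n: int


def pair_distribution(
    aligned: AlignedKTurnSet, pair: tuple[str, str]
) -> PairDistribution:
    if not aligned.members:
        raise EmptySet("aligned set has no members")
    counts: dict[str, int] = {}
    for ann in aligned.members:
        key = f"{ann.residue(pair[0])}:{ann.residue(pair[1])}"
        counts[key] = counts.get(key, 0) + 1
    series = pd.Series(counts, dtype=float) / len(aligned.members)
    # descending by frequency, then lexicographic for determinism
    series = series.sort_index().sort_values(ascending=False, kind="stable")
    return PairDistribution(pair=pair, frequencies=series, n=len(aligned.members))


def logo_matrix(
    table: PositionFrequencyTable, small_sample_correction: bool = False
) -> pd.DataFrame:
    """Letter heights in bits per label, WebLogo convention.

    IC = 2 - H2(column) (0 log 0 := 0); height = frequency * IC.  The
    optional small-sample correction subtracts e(n) = 3 / (2 ln2 n) from
    each column's IC (floored at 0).
    """
    freqs = table.frequencies[list(BASES)]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = 2.0 - entropy
    if small_sample_correction:
        ic = np.maximum(ic - 3.0 / (2.0 * np.log(2) * table.n), 0.0)
    heights = freqs.mul(ic, axis=0)
    heights = heights.copy()
    heights["IC"] = ic
    return heights


def sample_pair(rng: np.random.Generator, distribution: dict[str, float]) -> str:
    """Draw one 'X:Y' pair key from a frequency dict."""
    keys = sorted(distribution)
    probs = np.array([distribution[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


# ---------------------------------------------------------------------------
# TSV interfaces

def frequency_table_tsv(table: PositionFrequencyTable, path) -> None:
    out = table.frequencies.copy()
    out.index.name = "label"
    out.to_csv(path, sep="\t")


def logo_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "label"
    out.to_csv(path, sep="\t")


def rejects_tsv(aligned: AlignedKTurnSet, path) -> None:
    pd.DataFrame(aligned.rejects, columns=["duplex_id", "reason"]).to_csv(
        path, sep="\t", index=False
    )
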