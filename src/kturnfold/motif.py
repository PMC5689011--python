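"""Annotation of standard kink-turns in two-strand RNA duplexes.

A standard k-turn is a 3-nucleotide bulge followed on its 3' side by tandem
trans sugar-Hoogsteen G•A and A•G base pairs.  The bulge separates a
canonical (C) helix from the non-canonical (NC) helix that carries the G•A
pairs.  Positions are labelled outward from the bulge: ``-1b:-1n`` is the
last C-helix pair, ``L1``-``L3`` the bulge ("loop") nucleotides on the
bulged strand, and ``1b:1n`` .. ``4b:4n`` the first four NC-helix pairs,
where the ``b``/``n`` suffix names the bulged / non-bulged strand.

The annotator slides the two strands against each other looking for the
unique registration that places a 3-nt bulge immediately 5' of a G•A/A•G
core.  Within a registration the labelled core pairs are part of their helix
span by definition; the spans extend outward through Watson-Crick and G:U
wobble pairs (inosine pairs as G, DNA thymine as uracil) and stop at the
first other apposition or at a strand end.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping

from .errors import AmbiguousKTurn, NoKTurnFound, UnknownLabel

RNA_ALPHABET = frozenset("ACGUI")
#: thymine is accepted only at positions tagged as DNA chemistry
DNA_ALPHABET = frozenset("ACGT")

#: Watson-Crick plus G:U wobble, after canonicalization (I->G, T->U).
_PAIRED = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: the public position vocabulary, 5'->3' along the bulged strand
CORE_LABELS = (
    "-1b", "-1n",
    "L1", "L2", "L3",
    "1b", "1n", "2b", "2n", "3b", "3n", "4b", "4n",
)

_LOOP_LABELS = ("L1", "L2", "L3")


def canonical_residue(residue: str) -> str:
    """Map a residue to its pairing equivalent (I pairs as G, T as U)."""
    return {"I": "G", "T": "U"}.get(residue, residue)


def residues_pair(a: str, b: str) -> bool:
    """True when two residues form a Watson-Crick or G:U wobble pair."""
    return (canonical_residue(a), canonical_residue(b)) in _PAIRED


@dataclass(frozen=True)
class Strand:
    """A single oligonucleotide written 5'->3'.

    ``chemistry`` optionally tags each residue as RNA (``R``) or DNA
    (``D``); ``None`` means all-RNA.  The 5' fluorophore is metadata only
    and never affects annotation.
    """

    id: str
    residues: str
    chemistry: str | None = None
    fluorophore: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"strand {self.id!r} is empty")
        chem = self.chemistry
        if chem is not None and len(chem) != len(self.residues):
            raise ValueError("chemistry mask length != sequence length")
        for i, res in enumerate(self.residues):
            allowed = DNA_ALPHABET if (chem and chem[i] == "D") else RNA_ALPHABET
            if res not in allowed:
                raise ValueError(
                    f"strand {self.id!r}: residue {res!r} at {i} not in alphabet"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def rna_core(self) -> str:
        """The RNA portion of a chimeric strand (whole sequence if all-RNA)."""
        if self.chemistry is None:
            return self.residues
        return "".join(
            r for r, c in zip(self.residues, self.chemistry) if c == "R"
        )


@dataclass(frozen=True)
class KTurnDuplex:
    """Two annealed strands; ``bulged`` carries the 3-nt loop."""

    bulged: Strand
    nonbulged: Strand

    @property
    def id(self) -> str:
        return self.bulged.id

    def sha256(self) -> str:
        digest = hashlib.sha256()
        digest.update(self.bulged.residues.encode())
        digest.update(b"/")
        digest.update(self.nonbulged.residues.encode())
        return digest.hexdigest()


class ElementId(str, Enum):
    """The four exchangeable sequence elements of a standard k-turn."""

    MINUS1_PAIR = "MINUS1_PAIR"
    LOOP = "LOOP"
    PAIR_3 = "PAIR_3"
    PAIR_4 = "PAIR_4"

    @property
    def labels(self) -> tuple[str, ...]:
        return _ELEMENT_LABELS[self]


_ELEMENT_LABELS: dict[ElementId, tuple[str, ...]] = {
    ElementId.MINUS1_PAIR: ("-1b", "-1n"),
    ElementId.LOOP: ("L1", "L2", "L3"),
    ElementId.PAIR_3: ("3b", "3n"),
    ElementId.PAIR_4: ("4b", "4n"),
}


@dataclass(frozen=True)
class Position:
    """One labelled position: which strand, 0-based index, residue."""

    strand: str  # "bulged" | "nonbulged"
    index: int
    residue: str


@dataclass(frozen=True)
class KTurnAnnotation:
    """A registered standard k-turn over a duplex.

    ``bulge_start`` is the 0-based index of L1 on the bulged strand.  Helix
    spans are half-open 0-based index ranges on each strand; ``c_bp`` /
    ``nc_bp`` are their paired lengths.
    """

    duplex: KTurnDuplex
    bulge_start: int
    positions: Mapping[str, Position]
    c_helix: tuple[tuple[int, int], tuple[int, int]]
    nc_helix: tuple[tuple[int, int], tuple[int, int]]
    c_bp: int
    nc_bp: int
    core_intact: bool

    def strands(self) -> KTurnDuplex:
        """The duplex this annotation was derived from, exactly."""
        return self.duplex

    def residue(self, label: str) -> str:
        try:
            return self.positions[label].residue
        except KeyError as exc:
            raise UnknownLabel(label) from exc

    def pair(self, b_label: str, n_label: str) -> str:
        return f"{self.residue(b_label)}:{self.residue(n_label)}"

    def loop(self) -> str:
        return "".join(self.residue(lbl) for lbl in _LOOP_LABELS)

    def element_residues(self, element: ElementId) -> tuple[str, ...]:
        return tuple(self.residue(lbl) for lbl in element.labels)

    def element_summary(self) -> dict[str, str]:
        """One-line summary of the four exchangeable elements."""
        return {
            "-1b:-1n": self.pair("-1b", "-1n"),
            "loop": self.loop(),
            "3b:3n": self.pair("3b", "3n"),
            "4b:4n": self.pair("4b", "4n"),
        }


def _label_index_map(j: int, len_n: int) -> dict[str, tuple[str, int]]:
    """Map labels to (strand, index) for bulge start j on the bulged strand."""
    out: dict[str, tuple[str, int]] = {"-1b": ("bulged", j - 1)}
    for k, lbl in enumerate(_LOOP_LABELS):
        out[lbl] = ("bulged", j + k)
    for k in range(1, 5):
        out[f"{k}b"] = ("bulged", j + 2 + k)
    out["-1n"] = ("nonbulged", len_n - j)
    for k in range(1, 5):
        out[f"{k}n"] = ("nonbulged", len_n - j - k)
    return out


def _span_lengths(b: str, n: str, j: int) -> tuple[int, int]:
    """C and NC paired lengths for registration j (core pairs always count)."""
    len_b, len_n = len(b), len(n)
    c_bp = 1  # the -1 pair belongs to the C helix by definition
    k = 2
    while j - k >= 0 and len_n - j + k - 1 < len_n and residues_pair(
        b[j - k], n[len_n - j + k - 1]
    ):
        c_bp += 1
        k += 1
    nc_bp = 4  # labelled pairs 1..4 tile the NC side of the core
    k = 5
    while j + 2 + k < len_b and len_n - j - k >= 0 and residues_pair(
        b[j + 2 + k], n[len_n - j - k]
    ):
        nc_bp += 1
        k += 1
    return c_bp, nc_bp


def _registration_score(b: str, n: str, j: int) -> int:
    """Total WC/wobble-paired appositions under registration j."""
    len_n = len(n)
    score = 0
    # C side: b[j-1-t] vs n[len_n-j+t]
    for t in range(j):
        if residues_pair(b[j - 1 - t], n[len_n - j + t]):
            score += 1
    # NC side: b[j+3+t] vs n[len_n-j-1-t]
    for t in range(len_n - j):
        if residues_pair(b[j + 3 + t], n[len_n - j - 1 - t]):
            score += 1
    return score


def _candidate_registrations(
    duplex: KTurnDuplex, require_core: bool
) -> list[tuple[int, int]]:
    b = duplex.bulged.residues
    n = duplex.nonbulged.residues
    len_b, len_n = len(b), len(n)
    candidates: list[tuple[int, int]] = []
    # need -1b (j >= 1) and labels 1..4 on both strands
    for j in range(1, len_b - 6):
        if len_n - j - 4 < 0:
            break
        if require_core:
            core = (
                canonical_residue(b[j + 3]),
                canonical_residue(n[len_n - j - 1]),
                canonical_residue(b[j + 4]),
                canonical_residue(n[len_n - j - 2]),
            )
            if core != ("G", "A", "A", "G"):
                continue
        c_bp, nc_bp = _span_lengths(b, n, j)
        # >=1 flanking WC/wobble pair on each side of the bulge
        c_flank = any(
            residues_pair(b[j - 1 - t], n[len_n - j + t]) for t in range(c_bp)
        )
        nc_flank = any(
            residues_pair(b[j + 2 + k], n[len_n - j - k])
            for k in range(3, nc_bp + 1)
        )
        if not (c_flank and nc_flank):
            continue
        candidates.append((j, _registration_score(b, n, j)))
    return candidates


def annotate_kturn(duplex: KTurnDuplex, require_core: bool = True) -> KTurnAnnotation:
    """Locate and annotate the single standard k-turn in a duplex.

    Parameters
    ----------
    duplex:
        The annealed pair of strands; the bulged strand must be exactly
        three residues longer than its partner.
    require_core:
        When True (default) a registration must place (G,A,A,G) at
        (1b,1n,2b,2n).  Disabling the check lets core-mutant controls be
        registered far enough to report their elements.

    Raises
    ------
    NoKTurnFound
        when no registration satisfies the k-turn geometry.
    AmbiguousKTurn
        when two registrations tie on total paired positions.
    """
    b = duplex.bulged.residues
    n = duplex.nonbulged.residues
    if len(b) != len(n) + 3:
        raise NoKTurnFound(
            f"{duplex.id!r}: bulged strand must exceed non-bulged by exactly "
            f"3 nt (got {len(b)} vs {len(n)})"
        )
    candidates = _candidate_registrations(duplex, require_core)
    if not candidates:
        raise NoKTurnFound(f"{duplex.id!r}: no standard k-turn registration")
    best = max(score for _, score in candidates)
    winners = [j for j, score in candidates if score == best]
    if len(winners) > 1:
        # secondary tie-break: closest core to canonical (G,A,A,G); only
        # discriminates when core checking is off (e.g. mutant controls)
        len_n = len(n)

        def core_similarity(j: int) -> int:
            observed = (b[j + 3], n[len_n - j - 1], b[j + 4], n[len_n - j - 2])
            return sum(x == y for x, y in zip(observed, ("G", "A", "A", "G")))

        top = max(core_similarity(j) for j in winners)
        winners = [j for j in winners if core_similarity(j) == top]
    if len(winners) > 1:
        raise AmbiguousKTurn(
            f"{duplex.id!r}: registrations at bulge offsets {winners} tie"
        )
    j = winners[0]
    len_n = len(n)
    positions = {}
    for lbl, (strand_name, idx) in _label_index_map(j, len_n).items():
        seq = b if strand_name == "bulged" else n
        positions[lbl] = Position(strand_name, idx, seq[idx])
    c_bp, nc_bp = _span_lengths(b, n, j)
    annotation = KTurnAnnotation(
        duplex=duplex,
        bulge_start=j,
        positions=positions,
        c_helix=((j - c_bp, j), (len_n - j, len_n - j + c_bp)),
        nc_helix=((j + 3, j + 3 + nc_bp), (len_n - j - nc_bp, len_n - j)),
        c_bp=c_bp,
        nc_bp=nc_bp,
        core_intact=(
            tuple(positions[x].residue for x in ("1b", "1n", "2b", "2n"))
            == ("G", "A", "A", "G")
        ),
    )
    return annotation


def helix_lengths(annotation: KTurnAnnotation) -> tuple[int, int]:
    """Paired lengths (C helix, NC helix) of an annotation."""
    return annotation.c_bp, annotation.nc_bp


def _edit_duplex(
    target: KTurnAnnotation, edits: Mapping[str, str], new_id: str | None = None
) -> KTurnDuplex:
    dup = target.duplex
    b = list(dup.bulged.residues)
    n = list(dup.nonbulged.residues)
    for label, residue in edits.items():
        if label not in target.positions:
            raise UnknownLabel(label)
        if residue not in RNA_ALPHABET:
            raise ValueError(f"residue {residue!r} not in alphabet")
        pos = target.positions[label]
        (b if pos.strand == "bulged" else n)[pos.index] = residue
    suffix = new_id or "variant"
    return KTurnDuplex(
        bulged=replace(dup.bulged, id=f"{dup.bulged.id}|{suffix}", residues="".join(b)),
        nonbulged=replace(
            dup.nonbulged, id=f"{dup.nonbulged.id}|{suffix}", residues="".join(n)
        ),
    )


def exchange_element(
    target: KTurnAnnotation, element: ElementId, source: KTurnAnnotation
) -> KTurnDuplex:
    """Replace one sequence element of ``target`` with ``source``'s.

    Both strands are edited for pair elements; L1-L3 for the loop.  The
    product differs from the target duplex only at the element's labelled
    positions.
    """
    edits = {lbl: source.residue(lbl) for lbl in element.labels}
    return _edit_duplex(target, edits, new_id=f"{element.value}<-{source.duplex.id}")


def substitute(target: KTurnAnnotation, label: str, residue: str) -> KTurnDuplex:
    """Point-substitute a single labelled position."""
    return _edit_duplex(target, {label: residue}, new_id=f"{label}{residue}")


def substitute_many(target: KTurnAnnotation, edits: Mapping[str, str]) -> KTurnDuplex:
    """Apply several point substitutions in one pass (no re-annotation between)."""
    return _edit_duplex(target, dict(edits), new_id="+".join(
        f"{lbl}{res}" for lbl, res in edits.items()
    ))


# ---------------------------------------------------------------------------
# FASTA / TSV interfaces

def read_duplexes_fasta(path) -> Iterator[KTurnDuplex]:
    """Read duplexes from FASTA: records in bulged, non-bulged order."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2:
        raise ValueError(f"{path}: odd number of FASTA records ({len(records)})")
    for i in range(0, len(records), 2):
        bulged, nonbulged = records[i], records[i + 1]
        yield KTurnDuplex(
            bulged=Strand(bulged.id, str(bulged.seq).upper().replace("T", "U")),
            nonbulged=Strand(nonbulged.id, str(nonbulged.seq).upper().replace("T", "U")),
        )


def write_duplexes_fasta(duplexes: Iterable[KTurnDuplex], path) -> None:
    with open(path, "w") as fh:
        for dup in duplexes:
            fh.write(f">{dup.bulged.id}\n{dup.bulged.residues}\n")
            fh.write(f">{dup.nonbulged.id}\n{dup.nonbulged.residues}\n")


def annotation_table(annotations: Mapping[str, KTurnAnnotation]):
    """Long-format annotation table: duplex_id, label, strand, index, residue."""
    import pandas as pd

    rows = [
        {
            "duplex_id": dup_id,
            "label": lbl,
            "strand": pos.strand,
            "index": pos.index,
            "residue": pos.residue,
        }
        for dup_id, ann in annotations.items()
        for lbl, pos in ann.positions.items()
    ]
    return pd.DataFrame(rows, columns=["duplex_id", "label", "strand", "index", "residue"])


def summary_table(annotations: Mapping[str, KTurnAnnotation]):
    """Per-duplex element summary plus helix lengths."""
    import pandas as pd

    rows = []
    for dup_id, ann in annotations.items():
        row = {"duplex_id": dup_id, **ann.element_summary()}
        row["c_bp"], row["nc_bp"] = helix_lengths(ann)
        row["core_intact"] = ann.core_intact
        rows.append(row)
    return pd.DataFrame(rows)
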