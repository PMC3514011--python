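"""Aligned COI sequence handling and haplotype collapsing.

The unit of every sequence statistic in this package is an
:class:`AlignedSeqSet`: equal-length nucleotide sequences with unique labels
and an optional population assignment per record.  Identical sequences are
collated into a :class:`HaplotypeTable` with per-population frequency
bookkeeping, mirroring the haplotype-collapser step of a standard barcoding
pipeline.

Alignment columns are 0-based and windows are half-open, ``[start, end)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, DataError

#: Unambiguous nucleotide states used by every statistic in the package.
CANONICAL_BASES = ("A", "C", "G", "T")

#: IUPAC ambiguity codes plus gap and N; gaps are treated as ambiguity
#: symbols throughout (COI is protein-coding, indels are not expected).
AMBIGUOUS_SYMBOLS = frozenset("RYSWKMBDHVN-")

_VALID_SYMBOLS = frozenset(CANONICAL_BASES) | AMBIGUOUS_SYMBOLS


@dataclass(frozen=True)
class SeqEntry:
    """One aligned record: label, population assignment and sequence."""

    label: str
    population: str
    sequence: str


@dataclass
class AlignedSeqSet:
    """Equal-length nucleotide sequences with unique labels.

    Parameters
    ----------
    records
        Iterable of :class:`SeqEntry` (or ``(label, population, sequence)``
        triples).  Sequences are upper-cased on construction and validated
        against the nucleotide alphabet (ACGT, IUPAC ambiguity codes, ``-``
        and ``N``).

    Raises
    ------
    AlignmentError
        If sequences do not share one length (offending labels are named).
    DataError
        If the set is empty, labels repeat, or a symbol is not nucleotide.
    """

    records: list[SeqEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        normalized: list[SeqEntry] = []
        for rec in self.records:
            if not isinstance(rec, SeqEntry):
                rec = SeqEntry(*rec)
            normalized.append(
                SeqEntry(rec.label, rec.population, rec.sequence.upper())
            )
        self.records = normalized
        if not self.records:
            raise DataError("empty sequence set: no records")
        labels = [r.label for r in self.records]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise DataError(f"duplicate labels: {dupes}")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            ref = len(self.records[0].sequence)
            offending = [r.label for r in self.records if len(r.sequence) != ref]
            raise AlignmentError(
                "sequences are not aligned to one length; offending labels: "
                f"{offending}"
            )
        for rec in self.records:
            bad = set(rec.sequence) - _VALID_SYMBOLS
            if bad:
                raise DataError(
                    f"record {rec.label!r} contains non-nucleotide symbols {sorted(bad)}"
                )

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def populations(self) -> list[str]:
        return [r.population for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def to_matrix(self) -> np.ndarray:
        """Return the alignment as a ``(n, length)`` array of byte codes."""
        return np.frombuffer(
            "".join(r.sequence for r in self.records).encode("ascii"),
            dtype=np.uint8,
        ).reshape(self.n, self.length)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class Haplotype:
    haplotype_id: str
    sequence: str
    total_count: int
    counts_by_population: Mapping[str, int]


@dataclass
class HaplotypeTable:
    """Unique sequences with total and per-population frequencies."""

    haplotypes: list[Haplotype]
    length: int

    @property
    def k(self) -> int:
        """Number of haplotypes (K of the diversity-index table)."""
        return len(self.haplotypes)

    @property
    def total(self) -> int:
        return sum(h.total_count for h in self.haplotypes)

    def expand(self) -> AlignedSeqSet:
        """Inverse of collapsing: one record per counted colony."""
        records = []
        for h in self.haplotypes:
            i = 0
            for pop, cnt in sorted(h.counts_by_population.items()):
                for _ in range(cnt):
                    records.append(
                        SeqEntry(f"{h.haplotype_id}_{i}", pop, h.sequence)
                    )
                    i += 1
        return AlignedSeqSet(records)

    def write_csv(self, path: str | Path) -> None:
        """Write haplotype_id, sequence, total_count plus one column per
        population."""
        pops = sorted({p for h in self.haplotypes for p in h.counts_by_population})
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["haplotype_id", "sequence", "total_count", *pops])
            for h in self.haplotypes:
                writer.writerow(
                    [h.haplotype_id, h.sequence, h.total_count]
                    + [h.counts_by_population.get(p, 0) for p in pops]
                )


def read_fasta(
    path: str | Path, metadata: Mapping[str, str] | None = None
) -> AlignedSeqSet:
    """Read an aligned FASTA file into an :class:`AlignedSeqSet`.

    ``metadata`` maps record labels to population names; unlisted labels get
    population ``"unassigned"``.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    metadata = dict(metadata or {})
    records = [
        SeqEntry(rec.id, metadata.get(rec.id, "unassigned"), str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise DataError(f"empty FASTA: {path}")
    return AlignedSeqSet(records)


def write_fasta(seqs: AlignedSeqSet, path: str | Path) -> None:
    """Write the set as FASTA, wrapped at 70 columns."""
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.label, description="") for r in seqs),
        str(path),
        "fasta",
    )


def trim_to_window(seqs: AlignedSeqSet, start: int, end: int) -> AlignedSeqSet:
    """Cut every sequence to alignment columns ``[start, end)`` (0-based).

    The analysed fragment of a barcoding alignment is usually a fixed-length
    window determined by the shortest deposited sequences (here 489 or 388
    sites); this is the operation that applies such a window.
    """
    if not (0 <= start < end <= seqs.length):
        raise AlignmentError(
            f"window [{start}, {end}) outside alignment of length {seqs.length} "
            "(or empty)"
        )
    return AlignedSeqSet(
        [SeqEntry(r.label, r.population, r.sequence[start:end]) for r in seqs]
    )


def ambiguous_columns(seqs: AlignedSeqSet) -> np.ndarray:
    """Boolean mask of columns containing any ambiguity/gap/N in any record."""
    mat = seqs.to_matrix()
    ok = np.zeros(mat.shape, dtype=bool)
    for b in CANONICAL_BASES:
        ok |= mat == ord(b)
    return ~ok.all(axis=0)


def collapse_haplotypes(
    seqs: AlignedSeqSet, ambiguity_policy: str = "mask"
) -> HaplotypeTable:
    """Collate identical sequences into haplotypes with frequency counts.

    Under ``mask`` (default), columns containing any ambiguity symbol, gap or
    N in *any* record are excluded set-wide before identity comparison — the
    behaviour of common haplotype collapsers.  Under ``strict``, any ambiguity
    symbol raises :class:`DataError` listing the offending positions.

    Haplotypes are ordered by descending frequency (ties by first occurrence)
    and labelled ``H1, H2, ...``.  Counts are conserved: the haplotype counts
    sum to ``seqs.n``.
    """
    if ambiguity_policy not in ("mask", "strict"):
        raise ValueError(f"unknown ambiguity_policy: {ambiguity_policy!r}")
    mask = ambiguous_columns(seqs)
    if ambiguity_policy == "strict" and mask.any():
        positions = np.flatnonzero(mask).tolist()
        raise DataError(
            f"ambiguity symbols present at alignment columns {positions} "
            "(strict policy)"
        )
    keep = ~mask
    groups: dict[str, list[SeqEntry]] = {}
    order: list[str] = []
    for rec in seqs:
        key = "".join(
            ch for ch, k in zip(rec.sequence, keep) if k
        )
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    # descending count, first occurrence breaks ties (stable sort)
    order.sort(key=lambda k: -len(groups[k]))
    haplotypes = []
    for i, key in enumerate(order, start=1):
        members = groups[key]
        by_pop: dict[str, int] = {}
        for rec in members:
            by_pop[rec.population] = by_pop.get(rec.population, 0) + 1
        haplotypes.append(
            Haplotype(
                haplotype_id=f"H{i}",
                sequence=members[0].sequence,
                total_count=len(members),
                counts_by_population=by_pop,
            )
        )
    return HaplotypeTable(haplotypes=haplotypes, length=seqs.length)


def base_composition(seqs: AlignedSeqSet) -> dict[str, float]:
    """Fractions of A/C/G/T over unambiguous calls only (sum to 1)."""
    mat = seqs.to_matrix()
    counts = {b: int((mat == ord(b)).sum()) for b in CANONICAL_BASES}
    total = sum(counts.values())
    if total == 0:
        raise DataError("no unambiguous bases in the set")
    return {b: c / total for b, c in counts.items()}
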