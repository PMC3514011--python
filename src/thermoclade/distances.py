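"""Kimura 2-parameter distances and clade divergence summaries.

The K2P model separates transitions (purine<->purine, pyrimidine<->pyrimidine)
from transversions.  With P the transition fraction and Q the transversion
fraction over pairwise-complete sites,

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)

in expected substitutions per site.  Ambiguous sites (anything outside ACGT in
either sequence) are excluded pairwise (pairwise deletion), which maximises
usable signal and matches the behaviour of standard distance tools.

Net divergence between two groups subtracts mean within-group diversity from
the mean between-group distance, correcting for ancestral polymorphism:

    d_net = d_between - (d_within_X + d_within_Y) / 2
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import DataError, PartitionError, SaturationError
from .seq_core import AlignedSeqSet

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.all(np.diag(self.values) == 0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < 0).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Strict lower triangle as a flat vector (row-major)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["", *self.labels])
            for label, row in zip(self.labels, self.values):
                writer.writerow([label, *row.tolist()])

    @classmethod
    def read_csv(cls, path: str | Path) -> "DistanceMatrix":
        """Read a square labelled CSV; PHYLIP square format also accepted."""
        path = Path(path)
        with open(path) as fh:
            first = fh.readline().split()
            if len(first) == 1 and first[0].isdigit():
                # PHYLIP square: first line is n, then label + n values per row
                n = int(first[0])
                labels, rows = [], []
                for line in fh:
                    parts = line.split()
                    if not parts:
                        continue
                    labels.append(parts[0])
                    rows.append([float(x) for x in parts[1:]])
                if len(labels) != n:
                    raise DataError(f"PHYLIP matrix promises {n} rows, found {len(labels)}")
                return cls(labels, np.array(rows))
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            labels = header[1:]
            rows = [[float(x) for x in row[1:]] for row in reader]
        return cls(labels, np.array(rows))


@dataclass(frozen=True)
class DivergenceSummary:
    """Within/between/net K2P divergence for a two-group partition."""

    d_within_x: float
    d_within_y: float
    d_between: float

    @property
    def d_net(self) -> float:
        return self.d_between - (self.d_within_x + self.d_within_y) / 2.0


def _classify(a: str, b: str) -> str:
    if a == b:
        return "same"
    if (a in _PURINES) == (b in _PURINES):
        return "ts"
    return "tv"


def k2p_distance(a: str, b: str) -> float:
    """K2P distance between two equal-length sequences (subs/site).

    Sites where either sequence is not a plain A/C/G/T are excluded
    (pairwise deletion).
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise DataError(f"unequal sequence lengths: {len(a)} vs {len(b)}")
    usable = ts = tv = 0
    acgt = frozenset("ACGT")
    for x, y in zip(a, b):
        if x in acgt and y in acgt:
            usable += 1
            kind = _classify(x, y)
            if kind == "ts":
                ts += 1
            elif kind == "tv":
                tv += 1
    if usable == 0:
        raise DataError("no comparable unambiguous sites")
    p = ts / usable
    q = tv / usable
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P distance undefined (saturation): P={p:.4f}, Q={q:.4f}"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def pairwise_k2p(seqs: AlignedSeqSet) -> DistanceMatrix:
    """All-pairs K2P distances as a :class:`DistanceMatrix`.

    Vectorised over sites; any saturated pair raises
    :class:`SaturationError` naming the pair (no silent NaN).
    """
    mat = seqs.to_matrix()
    n, _ = mat.shape
    acgt = np.zeros(mat.shape, dtype=bool)
    for b in "ACGT":
        acgt |= mat == ord(b)
    purine = (mat == ord("A")) | (mat == ord("G"))
    out = np.zeros((n, n))
    for i in range(n):
        both = acgt[i] & acgt[i + 1:]
        usable = both.sum(axis=1).astype(float)
        if (usable == 0).any():
            j = i + 1 + int(np.flatnonzero(usable == 0)[0])
            raise DataError(
                f"no comparable sites between {seqs.labels[i]!r} and "
                f"{seqs.labels[j]!r}"
            )
        diff = (mat[i] != mat[i + 1:]) & both
        ts = (diff & (purine[i] == purine[i + 1:])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        p = ts / usable
        q = tv / usable
        w1 = 1.0 - 2.0 * p - q
        w2 = 1.0 - 2.0 * q
        bad = (w1 <= 0) | (w2 <= 0)
        if bad.any():
            j = i + 1 + int(np.flatnonzero(bad)[0])
            raise SaturationError(
                f"K2P distance undefined (saturation) for pair "
                f"({seqs.labels[i]!r}, {seqs.labels[j]!r})"
            )
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        out[i, i + 1:] = d
        out[i + 1:, i] = d
    return DistanceMatrix(list(seqs.labels), out)


def net_divergence(
    seqs: AlignedSeqSet,
    partition: Mapping[str, str],
    dist: DistanceMatrix | None = None,
) -> DivergenceSummary:
    """Within-, between- and net divergence for a two-group label partition.

    ``partition`` maps every label to one of exactly two group names.  The
    within-group mean over a singleton group is defined as 0 (the convention
    needed to report net divergence for clades represented by one sequence).
    ``dist`` may supply a precomputed matrix; by default K2P distances are
    computed from ``seqs``.
    """
    groups = sorted(set(partition.values()))
    if len(groups) != 2:
        raise PartitionError(f"partition must define exactly 2 groups, got {groups}")
    missing = [l for l in seqs.labels if l not in partition]
    if missing:
        raise PartitionError(f"labels missing from partition: {missing}")
    if dist is None:
        dist = pairwise_k2p(seqs)
    gx, gy = groups
    ix = [k for k, l in enumerate(dist.labels) if partition[l] == gx]
    iy = [k for k, l in enumerate(dist.labels) if partition[l] == gy]
    if not ix or not iy:
        raise PartitionError("both groups must be non-empty")

    def within(idx: list[int]) -> float:
        if len(idx) < 2:
            return 0.0
        sub = dist.values[np.ix_(idx, idx)]
        m = len(idx)
        return float(sub.sum() / (m * (m - 1)))  # mean over unordered pairs

    d_between = float(dist.values[np.ix_(ix, iy)].mean())
    return DivergenceSummary(
        d_within_x=within(ix), d_within_y=within(iy), d_between=d_between
    )
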