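"""Concatenated five-gene MLSA sequences and Kimura two-parameter distances.

The multilocus scheme concatenates pre-aligned, pre-trimmed, in-frame
fragments of five housekeeping genes head-to-tail in the fixed order
*atpD, gyrB, recA, rpoB, trpB*.  Pairwise evolutionary distance is the
Kimura (1980) two-parameter estimate

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

where P and Q are the proportions of compared sites differing by a
transition (A<->G, C<->T) and a transversion respectively.  Sites where
either sequence carries a gap or any symbol other than A/C/G/T (U counts
as T) are excluded pairwise.

This module validates its inputs rather than aligning them: alignment and
trimming happen upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "GENE_ORDER",
    "GeneAlignmentSet",
    "SiteComparison",
    "DistanceMatrix",
    "AlignmentError",
    "FrameError",
    "MembershipError",
    "NoOverlapError",
    "SaturationError",
    "load_gene_fastas",
    "concatenate",
    "classify_sites",
    "k2p_distance",
    "k2p_from_proportions",
    "mlsa_distance_matrix",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_phylip_lower",
]

GENE_ORDER = ("atpD", "gyrB", "recA", "rpoB", "trpB")


class AlignmentError(ValueError):
    """Sequences within one gene alignment have unequal lengths."""


class FrameError(ValueError):
    """A gene alignment length is not a multiple of 3 (out of frame)."""


class MembershipError(ValueError):
    """A strain is present in some gene files but not all."""


class NoOverlapError(ValueError):
    """No unambiguously comparable sites between two sequences."""


class SaturationError(ValueError):
    """Divergence too high for the two-parameter correction (log arg <= 0)."""


@dataclass(frozen=True)
class SiteComparison:
    """Per-site classification summary for one aligned sequence pair."""

    compared: int
    transitions: int
    transversions: int
    excluded: int

    def __post_init__(self) -> None:
        if self.transitions + self.transversions > self.compared:
            raise ValueError("more mismatches than compared sites")

    def __add__(self, other: "SiteComparison") -> "SiteComparison":
        return SiteComparison(
            self.compared + other.compared,
            self.transitions + other.transitions,
            self.transversions + other.transversions,
            self.excluded + other.excluded,
        )

    @property
    def p(self) -> float:
        """Transition proportion P among compared sites."""
        return self.transitions / self.compared

    @property
    def q(self) -> float:
        """Transversion proportion Q among compared sites."""
        return self.transversions / self.compared


@dataclass
class GeneAlignmentSet:
    """Per-gene aligned nucleotide sequences keyed by strain id."""

    genes: dict[str, dict[str, str]]
    gene_order: tuple[str, ...] = GENE_ORDER

    def __post_init__(self) -> None:
        missing = [g for g in self.gene_order if g not in self.genes]
        if missing:
            raise MembershipError(f"missing gene alignment(s): {missing}")
        strain_sets = {g: set(seqs) for g, seqs in self.genes.items()}
        reference = strain_sets[self.gene_order[0]]
        for gene, strains in strain_sets.items():
            if strains != reference:
                raise MembershipError(
                    f"gene {gene!r}: strain set differs from "
                    f"{self.gene_order[0]!r} "
                    f"(only-in-{gene}={sorted(strains - reference)}, "
                    f"missing={sorted(reference - strains)})"
                )
        for gene in self.gene_order:
            seqs = self.genes[gene]
            lengths = {s: len(v) for s, v in seqs.items()}
            if len(set(lengths.values())) > 1:
                raise AlignmentError(
                    f"gene {gene!r}: unequal aligned lengths {lengths}"
                )
            length = next(iter(lengths.values()), 0)
            if length % 3 != 0:
                raise FrameError(
                    f"gene {gene!r}: aligned length {length} is not a "
                    "multiple of 3 (expected in-frame alignment)"
                )

    @property
    def strains(self) -> list[str]:
        return sorted(self.genes[self.gene_order[0]])

    def gene_length(self, gene: str) -> int:
        seqs = self.genes[gene]
        return len(next(iter(seqs.values()))) if seqs else 0


def load_gene_fastas(
    paths: Mapping[str, Union[str, Path]],
    gene_order: Sequence[str] = GENE_ORDER,
) -> GeneAlignmentSet:
    """Load one aligned FASTA per gene; record ids are strain ids."""
    expected = set(gene_order)
    if set(paths) != expected:
        raise MembershipError(
            f"need exactly one path per gene {sorted(expected)}, "
            f"got {sorted(paths)}"
        )
    genes: dict[str, dict[str, str]] = {}
    for gene in gene_order:
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(paths[gene]), "fasta"):
            if rec.id in seqs:
                raise MembershipError(
                    f"gene {gene!r}: duplicate strain id {rec.id!r}"
                )
            seqs[rec.id] = str(rec.seq)
        genes[gene] = seqs
    return GeneAlignmentSet(genes=genes, gene_order=tuple(gene_order))


def concatenate(aln: GeneAlignmentSet, strain: str) -> str:
    """Head-to-tail concatenation in the fixed gene order for one strain."""
    if strain not in aln.genes[aln.gene_order[0]]:
        raise KeyError(f"unknown strain {strain!r}")
    return "".join(aln.genes[g][strain] for g in aln.gene_order)


# Byte-level classification tables over ASCII codes; U/u are folded to T.
_CODE = np.zeros(256, dtype=np.uint8)  # 0 = not an unambiguous base
for i, base in enumerate("ACGT", start=1):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i
_CODE[ord("U")] = _CODE[ord("T")]
_CODE[ord("u")] = _CODE[ord("T")]
# Purines A(1) G(3); pyrimidines C(2) T(4): transition iff both purine or
# both pyrimidine.
_IS_PURINE = np.array([False, True, False, True, False])


def classify_sites(seq_a: str, seq_b: str) -> SiteComparison:
    """Classify each aligned site as match, transition, transversion or
    excluded (pairwise deletion of gaps/ambiguities)."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a = _CODE[np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)]
    b = _CODE[np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)]
    ok = (a > 0) & (b > 0)
    compared = int(ok.sum())
    excluded = len(seq_a) - compared
    diff = ok & (a != b)
    same_class = _IS_PURINE[a] == _IS_PURINE[b]
    transitions = int((diff & same_class).sum())
    transversions = int(diff.sum()) - transitions
    return SiteComparison(compared, transitions, transversions, excluded)


def k2p_from_proportions(p: float, q: float) -> float:
    """Two-parameter distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"distance undefined at P={p:.4g}, Q={q:.4g}: "
            "sequences too diverged for the two-parameter correction"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(comparison: SiteComparison) -> float:
    """Kimura two-parameter distance for one compared pair."""
    if comparison.compared == 0:
        raise NoOverlapError("no unambiguously comparable sites")
    return k2p_from_proportions(comparison.p, comparison.q)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over an ordered strain list.

    Pairs where the two-parameter correction is undefined (saturated) are
    flagged in ``failures`` and hold NaN; they are never silently dropped.
    """

    ids: list[str]
    values: np.ndarray
    failures: dict[tuple[str, str], str]

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.values[i, j])


def mlsa_distance_matrix(aln: GeneAlignmentSet) -> DistanceMatrix:
    """All pairwise K2P distances on the concatenated five-gene sequences."""
    ids = aln.strains
    if len(ids) < 2:
        raise ValueError("need at least 2 strains for a distance matrix")
    concat = {s: concatenate(aln, s) for s in ids}
    n = len(ids)
    values = np.zeros((n, n))
    failures: dict[tuple[str, str], str] = {}
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = k2p_distance(classify_sites(concat[ids[i]], concat[ids[j]]))
            except (SaturationError, NoOverlapError) as exc:
                failures[(ids[i], ids[j])] = str(exc)
                d = math.nan
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=ids, values=values, failures=failures)


def write_distance_matrix(
    matrix: DistanceMatrix, path: Union[str, Path]
) -> Path:
    """Square TSV with strain ids in the first row and column, 6 dp."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(matrix.ids) + "\n")
        for sid, row in zip(matrix.ids, matrix.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    return path


def read_distance_matrix(path: Union[str, Path]) -> DistanceMatrix:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    ids = lines[0].split("\t")[1:]
    values = np.array(
        [[float(v) for v in line.split("\t")[1:]] for line in lines[1:]]
    )
    return DistanceMatrix(ids=ids, values=values, failures={})


def write_phylip_lower(
    matrix: DistanceMatrix, path: Union[str, Path]
) -> Path:
    """Lower-triangle PHYLIP-style distance matrix, 6 dp."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(matrix.ids)}\n")
        for i, sid in enumerate(matrix.ids):
            cells = "  ".join(f"{matrix.values[i, j]:.6f}" for j in range(i))
            fh.write(f"{sid:<12s}{('  ' + cells) if cells else ''}\n".rstrip() + "\n")
    return path
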