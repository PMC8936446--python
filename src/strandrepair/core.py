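"""Shared containers and sequence utilities.

Coordinate conventions used throughout the package:

* All genomic coordinates are 0-based; intervals are half-open ``[start, end)``.
* A lesion (cyclobutane pyrimidine dimer, CPD) spans a dinucleotide on one
  strand and is keyed by the genomic position of the 5'-most base of that
  dinucleotide *on the damaged strand*.  On the minus strand the 5'-most base
  is the one with the *higher* genomic coordinate.
* For a gene, the transcribed strand (TS, the template read by RNA
  polymerase) is the strand **opposite** the annotated mRNA-coding strand;
  the non-transcribed strand (NTS) is the coding strand itself.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np

PYRIMIDINE_DINUCS = ("TT", "TC", "CT", "CC")

# base -> code: A=0, C=1, G=2, T=3; anything else (N, gaps) = 4.
# Complement of a code c in 0..3 is 3 - c.
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "a": "t", "c": "g", "g": "c", "t": "a", "n": "n"}


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


@dataclass
class GeneModel:
    """A gene interval with the covariates used for stratified repair analysis.

    ``tss``/``tes`` are the transcription start site and the transcription end
    site (polyadenylation site).  For a minus-strand gene ``tss > tes``.  The
    gene body in transcription orientation is ``[tss, tes)``; genomically this
    is ``[tss, tes)`` for a plus-strand gene and ``[tes + 1, tss + 1)`` for a
    minus-strand gene.
    """

    gene_id: str
    chrom: str
    strand: str  # mRNA-coding strand
    tss: int
    tes: int
    transcription_rate: Optional[float] = None
    expr_log2fc: Optional[float] = None
    srat_class: str = "none"  # none | polyA | all

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.body_length <= 0:
            raise ValueError(f"gene {self.gene_id}: body length must be > 0")

    @property
    def body_length(self) -> int:
        return abs(self.tes - self.tss)

    @property
    def body_start(self) -> int:
        """Genomic start (inclusive) of the gene body."""
        return self.tss if self.strand == "+" else self.tes + 1

    @property
    def body_end(self) -> int:
        """Genomic end (exclusive) of the gene body."""
        return self.tes if self.strand == "+" else self.tss + 1

    @property
    def ts_strand(self) -> str:
        return "-" if self.strand == "+" else "+"

    @property
    def nts_strand(self) -> str:
        return self.strand

    @property
    def is_srat(self) -> bool:
        return self.srat_class != "none"


class LesionTrack:
    """Strand-specific sparse per-position CPD counts for one sample/timepoint.

    Internally each (chrom, strand) holds a pair of parallel arrays
    (sorted positions, positive counts); region sums use a cached cumulative
    sum so that interval queries are O(log n).
    """

    def __init__(self, sample_id: str = "", timepoint: float = 0.0,
                 provenance: str = "raw") -> None:
        self.sample_id = sample_id
        self.timepoint = timepoint
        self.provenance = provenance
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        self._cumsum: dict[tuple[str, str], np.ndarray] = {}

    # -- construction -----------------------------------------------------
    def set_counts(self, chrom: str, strand: str,
                   positions: np.ndarray, counts: np.ndarray) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.int64)
        keep = counts > 0
        positions, counts = positions[keep], counts[keep]
        order = np.argsort(positions, kind="stable")
        positions, counts = positions[order], counts[order]
        if positions.size and np.any(np.diff(positions) == 0):
            # collapse duplicates
            uniq, inv = np.unique(positions, return_inverse=True)
            summed = np.zeros(uniq.size, dtype=np.int64)
            np.add.at(summed, inv, counts)
            positions, counts = uniq, summed
        key = (chrom, strand)
        if positions.size:
            self._data[key] = (positions, counts)
        else:
            self._data.pop(key, None)
        self._cumsum.pop(key, None)

    @classmethod
    def from_dict(cls, mapping: Mapping[tuple[str, str], Mapping[int, int]],
                  **kwargs) -> "LesionTrack":
        track = cls(**kwargs)
        for (chrom, strand), posmap in mapping.items():
            pos = np.fromiter(posmap.keys(), dtype=np.int64, count=len(posmap))
            cnt = np.fromiter(posmap.values(), dtype=np.int64, count=len(posmap))
            track.set_counts(chrom, strand, pos, cnt)
        return track

    def add_records(self, records: Iterable[tuple[str, str, int, int]]) -> None:
        """Accumulate (chrom, strand, position, count) tuples."""
        from collections import defaultdict
        acc: dict[tuple[str, str], dict[int, int]] = defaultdict(dict)
        for chrom, strand, pos, count in records:
            d = acc[(chrom, strand)]
            d[pos] = d.get(pos, 0) + count
        for (chrom, strand), posmap in acc.items():
            base = dict(zip(*[a.tolist() for a in self.get(chrom, strand)])) \
                if (chrom, strand) in self._data else {}
            for p, c in posmap.items():
                base[p] = base.get(p, 0) + c
            pos = np.fromiter(base.keys(), dtype=np.int64, count=len(base))
            cnt = np.fromiter(base.values(), dtype=np.int64, count=len(base))
            self.set_counts(chrom, strand, pos, cnt)

    # -- access -----------------------------------------------------------
    def keys(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self._data))

    def chroms(self) -> list[str]:
        return sorted({c for c, _ in self._data})

    def get(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        pos, cnt = self._data.get((chrom, strand),
                                  (np.empty(0, np.int64), np.empty(0, np.int64)))
        return pos, cnt

    @property
    def total_count(self) -> int:
        return int(sum(int(c.sum()) for _, c in self._data.values()))

    @property
    def n_positions(self) -> int:
        return int(sum(p.size for p, _ in self._data.values()))

    def region_sum(self, chrom: str, strand: str, start: int, end: int) -> int:
        """Total lesion count in [start, end) on one strand."""
        key = (chrom, strand)
        if key not in self._data:
            return 0
        pos, cnt = self._data[key]
        cs = self._cumsum.get(key)
        if cs is None:
            cs = np.concatenate([[0], np.cumsum(cnt)])
            self._cumsum[key] = cs
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return int(cs[hi] - cs[lo])

    def to_dense(self, chrom: str, strand: str, length: int) -> np.ndarray:
        arr = np.zeros(length, dtype=np.int64)
        pos, cnt = self.get(chrom, strand)
        if pos.size:
            arr[pos] = cnt
        return arr

    def same_counts(self, other: "LesionTrack") -> bool:
        if set(self._data) != set(other._data):
            return False
        for key in self._data:
            p1, c1 = self._data[key]
            p2, c2 = other._data[key]
            if not (np.array_equal(p1, p2) and np.array_equal(c1, c2)):
                return False
        return True

    def copy(self, **overrides) -> "LesionTrack":
        track = LesionTrack(sample_id=overrides.get("sample_id", self.sample_id),
                            timepoint=overrides.get("timepoint", self.timepoint),
                            provenance=overrides.get("provenance", self.provenance))
        for (chrom, strand), (pos, cnt) in self._data.items():
            track.set_counts(chrom, strand, pos.copy(), cnt.copy())
        return track

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"LesionTrack(sample_id={self.sample_id!r}, "
                f"timepoint={self.timepoint}, total={self.total_count}, "
                f"positions={self.n_positions})")
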