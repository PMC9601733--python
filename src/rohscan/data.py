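"""Core in-memory containers: the SNP coordinate map and the genotype matrix.

Genotypes are coded as the count of the counted (ALT) allele: 0, 1, 2, with
``MISSING`` (-1) as the missing sentinel. Coordinates are 1-based inclusive
throughout the package; conversion to 0-based half-open happens only at the
BED boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING: int = -1

_VALID_CALLS = frozenset({-1, 0, 1, 2})


@dataclass
class SNPMap:
    """Ordered genomic positions of biallelic SNPs.

    Parameters
    ----------
    chrom
        Chromosome label per SNP (opaque strings; autosomes expected).
        Each chromosome must occupy one contiguous block.
    pos
        1-based positions, strictly increasing within each chromosome.
    ids
        SNP identifiers; synthesized as ``"<chrom>:<pos>"`` when omitted.
    freq
        Optional frequency of the counted allele per SNP.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray | None = None
    freq: np.ndarray | None = None
    _slices: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.chrom.shape != self.pos.shape:
            raise ValueError("chrom and pos must have the same length")
        if self.ids is None:
            self.ids = np.array(
                [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)], dtype=object
            )
        else:
            self.ids = np.asarray(self.ids, dtype=object)
        if self.freq is not None:
            self.freq = np.asarray(self.freq, dtype=float)
            if self.freq.shape != self.pos.shape:
                raise ValueError("freq must align with pos")
        self._build_slices()

    def _build_slices(self) -> None:
        slices: dict[str, slice] = {}
        n = len(self.pos)
        i = 0
        while i < n:
            c = self.chrom[i]
            j = i
            while j < n and self.chrom[j] == c:
                j += 1
            if c in slices:
                raise ValueError(f"chromosome {c!r} is not a contiguous block")
            block = self.pos[i:j]
            if len(block) > 1 and not np.all(np.diff(block) > 0):
                k = i + int(np.argmax(np.diff(block) <= 0)) + 1
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c!r} "
                    f"at record {c}:{self.pos[k]}"
                )
            slices[c] = slice(i, j)
            i = j
        self._slices = slices

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        return list(self._slices.keys())

    def chrom_slice(self, chrom) -> slice:
        return self._slices[chrom]

    def index_range(self, chrom, start_bp: int, end_bp: int) -> tuple[int, int]:
        """Half-open global index range [lo, hi) of SNPs within a bp span."""
        sl = self._slices[chrom]
        block = self.pos[sl]
        lo = int(np.searchsorted(block, start_bp, side="left"))
        hi = int(np.searchsorted(block, end_bp, side="right"))
        return sl.start + lo, sl.start + hi

    def subset(self, keep: np.ndarray) -> "SNPMap":
        keep = np.asarray(keep)
        return SNPMap(
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            ids=self.ids[keep],
            freq=None if self.freq is None else self.freq[keep],
        )


@dataclass
class GenotypeMatrix:
    """Per-individual, per-SNP diploid calls: 0/1/2 ALT-allele counts, -1 missing."""

    individuals: list
    calls: np.ndarray  # (n_individuals, n_snps), int8

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-dimensional")
        if self.calls.shape[0] != len(self.individuals):
            raise ValueError("rows of calls must match the individual list")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype calls must be in {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.individuals), self.calls.copy())

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.individuals), self.calls[:, keep])
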