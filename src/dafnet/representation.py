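"""Sample-size-invariant window representation for sweep classification.

A genomic window is held as an N x W ternary SNP matrix (rows = haplotype
samples, columns = loci; states ancestral / derived / missing).  For
classification it is collapsed to a 2 x W feature matrix that is invariant
to the sample size N: one row of per-locus derived allele frequencies
(DAF) and one row of distances between neighbouring SNPs.  The DAF row
carries the site-frequency-spectrum signature of a hard sweep; the
distance row carries the local reduction of polymorphism (SNP density).
Using inter-SNP distances rather than absolute positions makes the
representation translation invariant, so a window yields the same
features wherever it sits on the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: allele state codes in :class:`SNPMatrix` arrays
ANCESTRAL = 0
DERIVED = 1
MISSING = -1


class RepresentationError(ValueError):
    """Raised for invalid SNP matrices or feature inputs."""


@dataclass
class SNPMatrix:
    """An N x W window of ternary allele states with per-SNP positions.

    Parameters
    ----------
    alleles
        ``int8`` array of shape ``(N, W)`` with values ``0`` (ancestral),
        ``1`` (derived) or ``-1`` (missing).
    positions
        Nondecreasing coordinates of the W loci.  Fractional in ``[0, 1]``
        for coalescent simulator output, 1-based base pairs for VCF input.
    label
        Optional class label, ``"neutral"`` or ``"sweep"``.
    scenario_id
        Optional tag of the simulation scenario the window came from.
    chrom
        Contig name for empirical data.
    """

    alleles: np.ndarray
    positions: np.ndarray
    label: Optional[str] = None
    scenario_id: Optional[str] = None
    chrom: Optional[str] = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.alleles.ndim != 2:
            raise RepresentationError("alleles must be a 2-D (N, W) array")
        n, w = self.alleles.shape
        if n < 1 or w < 1:
            raise RepresentationError("need N >= 1 samples and W >= 1 loci")
        if self.positions.shape != (w,):
            raise RepresentationError(
                f"positions length {self.positions.shape} does not match W={w}"
            )
        if np.any(np.diff(self.positions) < 0):
            raise RepresentationError("positions must be nondecreasing")
        bad = ~np.isin(self.alleles, (ANCESTRAL, DERIVED, MISSING))
        if bad.any():
            raise RepresentationError("allele states must be in {0, 1, -1}")
        if self.label is not None and self.label not in ("neutral", "sweep"):
            raise RepresentationError(f"unknown label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.alleles == MISSING).any())

    def with_rows(self, order: np.ndarray) -> "SNPMatrix":
        """Return a copy with sample rows reordered (positions untouched)."""
        return replace(self, alleles=self.alleles[np.asarray(order)])


@dataclass
class FeatureMatrix:
    """The fused 2 x W classifier input: DAF row and distance row."""

    daf: np.ndarray
    dist: np.ndarray
    label: Optional[str] = None
    scenario_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.daf = np.asarray(self.daf, dtype=np.float32)
        self.dist = np.asarray(self.dist, dtype=np.float32)
        if self.daf.ndim != 1 or self.daf.shape != self.dist.shape:
            raise RepresentationError("daf and dist must be 1-D and equally long")
        if self.daf.size < 1:
            raise RepresentationError("need W >= 1")
        if np.any(self.daf < 0) or np.any(self.daf > 1):
            raise RepresentationError("DAF values must lie in [0, 1]")
        if np.any(self.dist < 0):
            raise RepresentationError("distances must be nonnegative")
        if self.dist[-1] != 0:
            raise RepresentationError("last distance entry must be 0")

    @property
    def width(self) -> int:
        return self.daf.size

    def as_array(self) -> np.ndarray:
        """Stack into the ``(2, W)`` float32 network input."""
        return np.stack([self.daf, self.dist]).astype(np.float32)


def compute_daf(matrix: SNPMatrix) -> np.ndarray:
    """Per-locus derived allele frequency.

    The frequency at a locus is the derived-allele count divided by the
    number of non-missing alleles at that locus, i.e. missing entries
    shrink the denominator rather than counting as ancestral.
    """
    derived = (matrix.alleles == DERIVED).sum(axis=0)
    called = (matrix.alleles != MISSING).sum(axis=0)
    empty = np.flatnonzero(called == 0)
    if empty.size:
        raise RepresentationError(
            f"locus {int(empty[0])} has no called alleles (all missing)"
        )
    return (derived / called).astype(np.float64)


def compute_distances(positions: np.ndarray) -> np.ndarray:
    """Distances to the next SNP; the last locus gets distance 0.

    ``D[i] = P[i+1] - P[i]`` for all but the final locus.  Adding any
    constant to every position leaves the result unchanged.
    """
    positions = np.asarray(positions, dtype=np.float64)
    if positions.ndim != 1 or positions.size < 1:
        raise RepresentationError("positions must be a non-empty 1-D vector")
    diffs = np.diff(positions)
    if np.any(diffs < 0):
        raise RepresentationError("positions must be nondecreasing")
    return np.concatenate([diffs, [0.0]])


def featurize(matrix: SNPMatrix, scale: Optional[float] = None) -> FeatureMatrix:
    """Collapse an N x W SNP matrix to its 2 x W feature matrix.

    Parameters
    ----------
    scale
        Optional divisor applied to the distance row.  Simulator output
        already uses fractional coordinates in ``[0, 1]`` and needs no
        scaling; base-pair coordinates from a VCF should be divided by
        the span (in bp) of the regions the classifier was trained on so
        that train and scan distance scales match.
    """
    daf = compute_daf(matrix)
    dist = compute_distances(matrix.positions)
    if scale is not None:
        if scale <= 0:
            raise RepresentationError("scale must be positive")
        dist = dist / scale
    return FeatureMatrix(
        daf=daf, dist=dist, label=matrix.label, scenario_id=matrix.scenario_id
    )


def center_window_start(n_snps: int, width: int) -> int:
    """0-based start of the width-W window centred on the SNP midpoint.

    The window whose centre index is closest to ``n_snps / 2`` is chosen;
    ties go to the lower start index.
    """
    if width < 1:
        raise RepresentationError("width must be >= 1")
    if n_snps < width:
        raise RepresentationError(
            f"window of {width} SNPs requested but only {n_snps} available"
        )
    return (n_snps - width + 1) // 2


def extract_center_window(matrix: SNPMatrix, width: int) -> SNPMatrix:
    """Cut the central ``width``-SNP window out of a longer replicate."""
    start = center_window_start(matrix.n_snps, width)
    return replace(
        matrix,
        alleles=matrix.alleles[:, start : start + width],
        positions=matrix.positions[start : start + width],
    )
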