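"""Sliding-window genome scanning with a trained 1-D classifier.

Windows of a fixed SNP count slide along a chromosome at a small SNP
step; each window's 2 x W feature matrix is classified and the softmax
probability of the sweep class is reported per window.  Because the
features are built from inter-SNP distances, every window produces
identical features wherever the region sits on the chromosome, and the
per-locus DAF and distance values shared by overlapping windows can be
computed once and reused without changing any output bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .representation import SNPMatrix, compute_daf, compute_distances, featurize
from .training import Checkpoint, restore

logger = logging.getLogger(__name__)


@dataclass
class ScanRecord:
    """One scanned window: coordinates plus sweep probability."""

    window_index: int
    snp_start: int  # 0-based, half-open
    snp_end: int
    p_sweep: float
    chrom: Optional[str] = None
    bp_start: Optional[int] = None  # 1-based inclusive, when bp positions exist
    bp_end: Optional[int] = None


def sliding_windows(
    matrix: SNPMatrix, width: int, step: int
) -> Iterator[Tuple[int, SNPMatrix]]:
    """Yield (snp_start, window) at offsets 0, step, 2*step, ...

    Only complete ``width``-SNP windows are produced; a chromosome with
    fewer SNPs than ``width`` yields nothing (with a warning).
    """
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    if matrix.n_snps < width:
        logger.warning(
            "chromosome has %d SNPs < window width %d; empty scan",
            matrix.n_snps,
            width,
        )
        return
    from dataclasses import replace

    for start in range(0, matrix.n_snps - width + 1, step):
        yield start, replace(
            matrix,
            alleles=matrix.alleles[:, start : start + width],
            positions=matrix.positions[start : start + width],
        )


def scan(
    checkpoint: Checkpoint,
    matrix: SNPMatrix,
    width: int = 128,
    step: int = 32,
    reuse: bool = True,
) -> List[ScanRecord]:
    """Classify every sliding window and report sweep probabilities.

    With ``reuse=True`` the per-locus DAF and distance vectors are
    computed once for the whole chromosome and sliced per window
    (bit-identical to the per-window path, which recomputes them).
    """
    spec_width = checkpoint["model_meta"]["spec"].get("input_width")
    if spec_width != width:
        raise ValueError(
            f"checkpoint expects {spec_width}-SNP windows, scan requested {width}"
        )
    model = restore(checkpoint)
    scale = checkpoint.get("feature_scale")

    starts = list(range(0, max(matrix.n_snps - width + 1, 0), step)) if (
        matrix.n_snps >= width
    ) else []
    if not starts:
        logger.warning("no complete %d-SNP window; empty scan", width)
        return []

    if reuse:
        daf_all = compute_daf(matrix)
        dist_all = compute_distances(matrix.positions)
        if scale:
            dist_all = dist_all / scale
        feats = np.empty((len(starts), 2, width), dtype=np.float32)
        for i, s in enumerate(starts):
            feats[i, 0] = daf_all[s : s + width]
            feats[i, 1, : width - 1] = dist_all[s : s + width - 1]
            feats[i, 1, width - 1] = 0.0
    else:
        feats = np.stack(
            [
                featurize(win, scale=scale).as_array()
                for _, win in sliding_windows(matrix, width, step)
            ]
        )

    records: List[ScanRecord] = []
    bp = matrix.positions if matrix.chrom is not None else None
    for i in range(0, len(starts), 64):
        probs = nn.softmax(model.forward(feats[i : i + 64]))[:, 1]
        for j, p in enumerate(probs):
            k = i + j
            s = starts[k]
            records.append(
                ScanRecord(
                    window_index=k,
                    snp_start=s,
                    snp_end=s + width,
                    p_sweep=float(p),
                    chrom=matrix.chrom,
                    bp_start=int(bp[s]) if bp is not None else None,
                    bp_end=int(bp[s + width - 1]) if bp is not None else None,
                )
            )
    return records


def write_scan_tsv(records: Sequence[ScanRecord], path: str) -> None:
    """Tab-separated scan output, one row per window, 6-decimal probabilities."""
    with open(path, "w") as fh:
        fh.write("chrom\tbp_start\tbp_end\tsnp_start\tsnp_end\tp_sweep\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.chrom or ".",
                        str(r.bp_start) if r.bp_start is not None else ".",
                        str(r.bp_end) if r.bp_end is not None else ".",
                        str(r.snp_start),
                        str(r.snp_end),
                        f"{r.p_sweep:.6f}",
                    ]
                )
                + "\n"
            )


def read_scan_tsv(path: str) -> List[ScanRecord]:
    """Parse a scan TSV back into records (inverse of write_scan_tsv)."""
    records: List[ScanRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"not a scan TSV: {path}")
        for i, line in enumerate(fh):
            chrom, bps, bpe, ss, se, p = line.rstrip("\n").split("\t")
            records.append(
                ScanRecord(
                    window_index=i,
                    snp_start=int(ss),
                    snp_end=int(se),
                    p_sweep=float(p),
                    chrom=None if chrom == "." else chrom,
                    bp_start=None if bps == "." else int(bps),
                    bp_end=None if bpe == "." else int(bpe),
                )
            )
    return records
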