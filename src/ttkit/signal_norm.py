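"""Reference-set renormalization of mNET-seq/ChIP-seq tracks and 3'-end extraction.

mNET-seq reads sequence the RNA 3' end held in the polymerase active site;
from a properly-paired alignment the single-nucleotide signal is the 3'-most
aligned base of the second mate, placed on the transcript strand inferred
from the first mate's orientation (opposite of mate1's alignment strand for
dUTP-style libraries; a flag covers the other convention).

Because a global transcription change shifts all of a library's signal,
between-condition comparisons need renormalization to genes known to be
unaffected: the factor is the average (geometric by default) control/treated
fold change over the reference gene bodies, applied multiplicatively to the
treated track.  Histone genes — whose transcription is insensitive to the
inhibition — serve the same role for CTD-phosphorylation signal, using full
TU spans since histone genes are short.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomicWindow
from .tracks import StrandedTrack

logger = logging.getLogger(__name__)

__all__ = [
    "PairedAlignment",
    "RenormFactor",
    "nascent_3prime_signal",
    "renorm_factor",
    "apply_factor",
    "rpkm_scale",
    "read_pairs_tsv",
    "read_pairs_sam",
]


@dataclass(frozen=True)
class PairedAlignment:
    """A properly-paired fragment: (chrom, start, end, strand) per mate."""

    chrom: str
    mate1_start: int
    mate1_end: int
    mate1_strand: str
    mate2_start: int
    mate2_end: int
    mate2_strand: str
    properly_paired: bool = True
    mate2_chrom: str | None = None  # None: same chromosome

    def __post_init__(self) -> None:
        if self.mate1_start >= self.mate1_end or self.mate2_start >= self.mate2_end:
            raise ValueError("mate intervals must have start < end")


@dataclass
class RenormFactor:
    """A multiplicative track renormalization factor with its audit trail."""

    value: float
    reference_set: list[str]
    method: str
    per_gene_ratios: pd.DataFrame

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("renormalization factor must be positive")
        if not self.reference_set:
            raise ValueError("reference set must be non-empty")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# factor\t{self.value:.10g}\tmethod\t{self.method}\n")
        self.per_gene_ratios.to_csv(path, sep="\t", index=False, mode="a")


def nascent_3prime_signal(
    alignments: Iterable[PairedAlignment],
    chrom_sizes: dict[str, int] | None = None,
    flip_strand: bool = True,
) -> tuple[StrandedTrack, dict[str, int]]:
    """Single-nucleotide 3'-end track from paired alignments.

    For each accepted pair, +1 at the genomic coordinate of mate2's 3'-most
    aligned base (highest coordinate for a + mate2, lowest for -), on the
    transcript strand derived from mate1 (opposite of mate1's strand when
    ``flip_strand``, the dUTP convention).  Improper pairs and
    cross-chromosome pairs are skipped and counted.

    Returns (track, stats) where stats counts accepted / improper / chimeric.
    """
    track = StrandedTrack(chrom_sizes)
    counts = {"accepted": 0, "improper": 0, "chimeric": 0}
    buf: dict[tuple[str, str], dict[int, float]] = {}
    for aln in alignments:
        if not aln.properly_paired:
            counts["improper"] += 1
            continue
        if aln.mate2_chrom is not None and aln.mate2_chrom != aln.chrom:
            counts["chimeric"] += 1
            continue
        pos = aln.mate2_end - 1 if aln.mate2_strand == "+" else aln.mate2_start
        strand = aln.mate1_strand
        if flip_strand:
            strand = "-" if strand == "+" else "+"
        key = (aln.chrom, strand)
        buf.setdefault(key, {}).setdefault(pos, 0.0)
        buf[key][pos] += 1.0
        counts["accepted"] += 1
    for (chrom, strand), positions in buf.items():
        pos = np.array(sorted(positions))
        vals = np.array([positions[p] for p in pos])
        for p, v in zip(pos, vals):
            track.add_values(chrom, strand, int(p), np.array([v]))
    track.consolidate()
    if counts["improper"] or counts["chimeric"]:
        logger.warning("3'-end extraction skipped %d improper and %d chimeric pairs",
                       counts["improper"], counts["chimeric"])
    return track, counts


def renorm_factor(
    treated: StrandedTrack,
    control: StrandedTrack,
    reference_windows: list[GenomicWindow],
    method: str = "geometric",
    ids: list[str] | None = None,
) -> RenormFactor:
    """Renormalization factor from control/treated fold changes on reference windows.

    Per window g the ratio r_g = control_sum/treated_sum over the window; the
    factor is the geometric (default) or arithmetic mean of the r_g.
    Multiplying the treated track by the factor equalizes average
    reference-set signal between conditions.
    """
    if method not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown method {method!r}")
    if not reference_windows:
        raise ValueError("reference window set is empty")
    ids = ids or [w.label or f"window_{k}" for k, w in enumerate(reference_windows)]
    rows, offenders = [], []
    for wid, w in zip(ids, reference_windows):
        c = control.window_sum(w.chrom, w.strand, w.start, w.end)
        t = treated.window_sum(w.chrom, w.strand, w.start, w.end)
        if c <= 0 or t <= 0:
            offenders.append(wid)
            continue
        rows.append((wid, c, t, c / t))
    if offenders:
        raise ValueError(f"reference windows with zero signal: {offenders}")
    table = pd.DataFrame(rows, columns=["id", "control_sum", "treated_sum", "ratio"])
    value = (stats.gmean(table["ratio"]) if method == "geometric"
             else float(table["ratio"].mean()))
    return RenormFactor(float(value), list(table["id"]), method, table)


def apply_factor(track: StrandedTrack, factor: RenormFactor | float) -> StrandedTrack:
    """Multiply every track value by the factor (exactly invertible)."""
    value = factor.value if isinstance(factor, RenormFactor) else float(factor)
    if value <= 0:
        raise ValueError("factor must be positive")
    return track.scale(value)


def rpkm_scale(track: StrandedTrack, total_mapped: int, bin_bp: int = 1) -> StrandedTrack:
    """RPKM-style scaling: values multiplied by 1e9 / (total_mapped * bin_bp)."""
    if total_mapped <= 0 or bin_bp <= 0:
        raise ValueError("total_mapped and bin_bp must be positive")
    return track.scale(1e9 / (total_mapped * bin_bp))


# ---------------------------------------------------------------------------
# input readers
# ---------------------------------------------------------------------------

PAIRS_COLUMNS = ["chrom", "mate1_start", "mate1_end", "mate1_strand",
                 "mate2_start", "mate2_end", "mate2_strand", "properly_paired"]


def read_pairs_tsv(path: str) -> Iterator[PairedAlignment]:
    """Portable paired-interval table (TSV with the PAIRS_COLUMNS header)."""
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        yield PairedAlignment(
            chrom=str(row.chrom),
            mate1_start=int(row.mate1_start), mate1_end=int(row.mate1_end),
            mate1_strand=str(row.mate1_strand),
            mate2_start=int(row.mate2_start), mate2_end=int(row.mate2_end),
            mate2_strand=str(row.mate2_strand),
            properly_paired=bool(getattr(row, "properly_paired", True)),
        )


def write_pairs_tsv(pairs: Iterable[PairedAlignment], path: str) -> None:
    rows = [(p.chrom, p.mate1_start, p.mate1_end, p.mate1_strand,
             p.mate2_start, p.mate2_end, p.mate2_strand, p.properly_paired)
            for p in pairs]
    pd.DataFrame(rows, columns=PAIRS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pairs_sam(path: str) -> Iterator[PairedAlignment]:
    """Paired alignments from SAM/BAM; mate1/mate2 are the read1/read2 of a pair.

    Pairs are matched by query name on the first two primary records seen;
    unmatched or unmapped records are dropped.
    """
    import pysam

    pending: dict[str, object] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            r1, r2 = (rec, mate) if rec.is_read1 else (mate, rec)
            yield PairedAlignment(
                chrom=r1.reference_name,
                mate1_start=r1.reference_start, mate1_end=r1.reference_end,
                mate1_strand="-" if r1.is_reverse else "+",
                mate2_start=r2.reference_start, mate2_end=r2.reference_end,
                mate2_strand="-" if r2.is_reverse else "+",
                properly_paired=r1.is_proper_pair and r2.is_proper_pair,
                mate2_chrom=r2.reference_name,
            )
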