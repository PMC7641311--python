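"""Anchored, scaled, binned metagene profiles and per-TU signal ratios.

A metagene profile averages per-base signal over many transcription units
after anchoring each at its TSS and pA site: unscaled flank bins outside the
anchors, and a gene body rescaled to a common number of bins by
length-weighted (area-preserving) averaging, so a constant-valued gene stays
exactly constant and the profile is linear in the track.  Minus-strand genes
are reflected so every profile reads TSS -> pA left to right.

Uncertainty bands are nonparametric bootstrap percentile intervals over
genes (resampling genes with replacement and recomputing the per-bin mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import TranscriptionUnit, assign_length_class
from .tracks import StrandedTrack

logger = logging.getLogger(__name__)

__all__ = [
    "MetageneProfile",
    "resample_body",
    "tu_profile",
    "scaled_metagene",
    "ratio_profile",
    "tb_ratio",
    "bootstrap_band",
]


@dataclass
class MetageneProfile:
    """Binned average profile with layout (flank | scaled body | flank)."""

    values: np.ndarray
    flank_bins: int
    body_bins: int
    bin_bp: int
    n_genes: int
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = 2 * self.flank_bins + self.body_bins
        if self.values.shape != (expected,):
            raise ValueError(f"values must have {expected} bins")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")

    @property
    def layout(self) -> tuple[int, int, int]:
        return (self.flank_bins, self.body_bins, self.flank_bins)

    def to_frame(self) -> pd.DataFrame:
        n = self.values.size
        df = pd.DataFrame({"bin": np.arange(n), "value": self.values})
        df["segment"] = (
            ["upstream"] * self.flank_bins
            + ["body"] * self.body_bins
            + ["downstream"] * self.flank_bins
        )
        if self.lower is not None:
            df["lower"] = self.lower
            df["upper"] = self.upper
        return df

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def resample_body(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Rescale a per-base signal to ``n_bins`` by area-preserving averaging.

    Bin i's value is the mean of the signal over the i-th of ``n_bins`` equal
    sub-intervals of [0, len(values)), computed from the linear interpolant of
    the cumulative sum — exact for piecewise-constant per-base signal, so a
    constant input returns that constant in every bin.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0 or n_bins <= 0:
        raise ValueError("need non-empty values and positive n_bins")
    cum = np.concatenate([[0.0], np.cumsum(values)])
    edges = np.linspace(0.0, values.size, n_bins + 1)
    cum_at_edges = np.interp(edges, np.arange(values.size + 1), cum)
    widths = np.diff(edges)
    return np.diff(cum_at_edges) / widths


def _bin_means(values: np.ndarray, bin_bp: int) -> np.ndarray:
    """Non-overlapping fixed-width bin means (length must be a multiple)."""
    return values.reshape(-1, bin_bp).mean(axis=1)


def tu_profile(
    track: StrandedTrack,
    tu: TranscriptionUnit,
    bin_bp: int = 10,
    body_bins: int = 100,
    flank_bp: int = 0,
) -> np.ndarray:
    """Single-TU profile: flank bins (bin_bp each) + scaled body bins + flank bins.

    Flanks extending past chromosome bounds (when the track carries
    ``chrom_sizes``) are clipped with a warning: out-of-bounds bases read 0.
    """
    if tu.length_bp <= 2 * bin_bp:
        raise ValueError(f"TU {tu.gene_id} shorter than two bins")
    if flank_bp % bin_bp:
        raise ValueError("flank_bp must be a multiple of bin_bp")
    chrom_size = track.chrom_sizes.get(tu.chrom)
    lo, hi = tu.start - flank_bp, tu.end + flank_bp
    pad_left = max(0, -lo)
    pad_right = 0 if chrom_size is None else max(0, hi - chrom_size)
    if pad_left or pad_right:
        logger.warning("TU %s: flank clipped at chromosome bounds", tu.gene_id)
    vals = track.window_values(tu.chrom, tu.strand, max(lo, 0),
                               hi if chrom_size is None else min(hi, chrom_size))
    if pad_left or pad_right:
        vals = np.concatenate([np.zeros(pad_left), vals, np.zeros(pad_right)])
    if tu.strand == "-":
        vals = vals[::-1]
    n_flank_bins = flank_bp // bin_bp
    up = vals[:flank_bp]
    body = vals[flank_bp : flank_bp + tu.length_bp]
    down = vals[flank_bp + tu.length_bp :]
    parts = []
    if n_flank_bins:
        parts.append(_bin_means(up, bin_bp))
    parts.append(resample_body(body, body_bins))
    if n_flank_bins:
        parts.append(_bin_means(down, bin_bp))
    return np.concatenate(parts)


def scaled_metagene(
    track: StrandedTrack,
    tus: list[TranscriptionUnit],
    bin_bp: int = 10,
    body_bins: int = 100,
    flank_bp: int = 0,
    band: bool = False,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> MetageneProfile:
    """Average anchored/scaled profile over a TU set (arithmetic mean over TUs)."""
    if not tus:
        raise ValueError("empty TU set")
    per_gene = np.stack(
        [tu_profile(track, tu, bin_bp, body_bins, flank_bp) for tu in tus]
    )
    profile = MetageneProfile(
        values=per_gene.mean(axis=0),
        flank_bins=flank_bp // bin_bp,
        body_bins=body_bins,
        bin_bp=bin_bp,
        n_genes=len(tus),
    )
    if band:
        profile.lower, profile.upper = bootstrap_band(per_gene, n_boot, level, seed)
    return profile


def ratio_profile(
    num: MetageneProfile, den: MetageneProfile, floor: float = 1e-6
) -> MetageneProfile:
    """Bin-wise ratio num/(den + floor); e.g. kinase-treated over control, or
    a CTD-phosphorylation mark over total polymerase.

    Bands, when both inputs carry one, are propagated as the ratio of bounds
    (indicative only, not a formal interval).  Bins where the denominator is
    at or below the floor are effectively flagged by their very large values.
    """
    if num.layout != den.layout or num.bin_bp != den.bin_bp:
        raise ValueError("profile layouts differ")
    if floor <= 0:
        raise ValueError("floor must be positive")
    out = MetageneProfile(
        values=num.values / (den.values + floor),
        flank_bins=num.flank_bins,
        body_bins=num.body_bins,
        bin_bp=num.bin_bp,
        n_genes=min(num.n_genes, den.n_genes),
    )
    if num.lower is not None and den.lower is not None:
        out.lower = num.lower / (den.upper + floor)
        out.upper = num.upper / (den.lower + floor)
    return out


def tb_ratio(
    track_treated: StrandedTrack,
    track_control: StrandedTrack,
    tus: list[TranscriptionUnit],
    length_breaks=None,
) -> pd.DataFrame:
    """Per-TU ratio of transcribed bases: treated sum / control sum over the TU span.

    Both tracks must already be on a common scale (antisense-corrected,
    depth-normalized).  TUs with zero control signal are dropped with a
    warning.  The result carries a length-class column for box-plot style
    stratification.
    """
    rows = []
    n_dropped = 0
    for tu in tus:
        ctrl = track_control.window_sum(tu.chrom, tu.strand, tu.start, tu.end)
        if ctrl <= 0:
            n_dropped += 1
            continue
        trt = track_treated.window_sum(tu.chrom, tu.strand, tu.start, tu.end)
        cls_label = (assign_length_class(tu, length_breaks) if length_breaks is not None
                     else assign_length_class(tu))
        rows.append((tu.gene_id, tu.length_bp, trt / ctrl, cls_label))
    if n_dropped:
        logger.warning("tb_ratio: dropped %d TUs with zero control signal", n_dropped)
    if not rows:
        raise ValueError("no TU with nonzero control signal")
    return pd.DataFrame(rows, columns=["gene_id", "length_bp", "ratio", "length_class"])


def bootstrap_band(
    per_gene_profiles: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap interval for the per-bin mean over genes.

    ``per_gene_profiles``: array (n_genes, n_bins).  Genes are resampled with
    replacement ``n_boot`` times; the (1-level)/2 and 1-(1-level)/2 percentiles
    of the resampled means form the band.  Deterministic given ``seed``.
    """
    profiles = np.asarray(per_gene_profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise ValueError("need a (n_genes >= 2, n_bins) array")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    n_genes = profiles.shape[0]
    idx = rng.integers(0, n_genes, size=(n_boot, n_genes))
    boot_means = profiles[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(boot_means, alpha, axis=0)
    upper = np.quantile(boot_means, 1.0 - alpha, axis=0)
    return lower, upper
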