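"""Spike-in based global normalization for TT-seq count data.

RNA spike-ins of known identity (labeled and unlabeled members) added before
library prep allow estimation of three per-sample global parameters:

* sigma_j  — sequencing depth scale, median over labeled spike-ins of
  count/length (reads per base);
* c_j      — antisense bias ratio, the fraction of spurious opposite-strand
  reads introduced by reverse transcription, median over spike-ins of
  antisense/sense counts;
* epsilon_j — cross-contamination rate, the proportion of unlabeled RNA
  carried through the 4sU purification, median over unlabeled spike-ins of
  count/length divided by sigma_j.

Observed sense/antisense counts follow the mixing model
``S = s + c*a``, ``A = a + c*s`` for true quantities (s, a); the antisense
bias correction ``s = (S - c*A)/(1 - c**2)`` inverts it exactly.

On top of the spike-in parameters, reference-set size factors (median-of-
ratios) balance residual library-size variation between replicates, computed
on a non-differentially-expressed subset of long, expressed transcription
units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeInSet",
    "NormalizationParams",
    "antisense_bias",
    "sequencing_depth",
    "cross_contamination",
    "estimate_params",
    "antisense_correct",
    "rpk",
    "rpk_to_coverage",
    "select_expressed",
    "select_reference_non_de",
    "size_factors",
    "depth_normalize",
    "SpikeInNormalizer",
]

SPIKEIN_COLUMNS = ["spikein_id", "length", "labeled", "sample", "sense", "antisense"]


@dataclass
class SpikeInSet:
    """Long-format spike-in counts: one row per (spike-in, sample).

    ``data`` columns: spikein_id, length, labeled (bool), sample, sense,
    antisense.  ``k_ij`` in the depth/cross-contamination formulas is the
    sense-assigned count.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SPIKEIN_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"spike-in table missing columns: {sorted(missing)}")
        df = self.data
        if (df["length"] <= 0).any():
            raise ValueError("spike-in lengths must be positive")
        if (df[["sense", "antisense"]] < 0).to_numpy().any():
            raise ValueError("spike-in counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data["sample"]))

    def sample_rows(self, sample: str) -> pd.DataFrame:
        rows = self.data[self.data["sample"] == sample]
        if rows.empty:
            raise KeyError(f"no spike-in rows for sample {sample!r}")
        return rows

    @classmethod
    def from_tsv(cls, path: str) -> "SpikeInSet":
        df = pd.read_csv(path, sep="\t")
        df["labeled"] = df["labeled"].astype(bool)
        return cls(df)

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class NormalizationParams:
    """Per-sample global normalization parameters."""

    sigma: pd.Series
    c: pd.Series
    epsilon: pd.Series
    size_factor: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive")
        if ((self.c < 0) | (self.c >= 1)).any():
            raise ValueError("antisense bias c must lie in [0, 1)")
        if (self.epsilon < 0).any():
            raise ValueError("cross-contamination epsilon must be >= 0")
        if self.size_factor is None:
            self.size_factor = pd.Series(1.0, index=self.sigma.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sigma": self.sigma, "c": self.c, "epsilon": self.epsilon,
             "size_factor": self.size_factor}
        ).rename_axis("sample")

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str) -> "NormalizationParams":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        return cls(df["sigma"], df["c"], df["epsilon"], df["size_factor"])


# ---------------------------------------------------------------------------
# per-sample parameter estimators
# ---------------------------------------------------------------------------


def antisense_bias(spikeins: SpikeInSet, sample: str) -> float:
    """Antisense bias ratio c_j = median_i(antisense_ij / sense_ij).

    Spike-ins with zero sense count are excluded (with a warning); at least
    one usable spike-in is required.
    """
    rows = spikeins.sample_rows(sample)
    usable = rows[rows["sense"] > 0]
    n_dropped = len(rows) - len(usable)
    if n_dropped:
        logger.warning("sample %s: %d spike-ins with zero sense count excluded from c",
                       sample, n_dropped)
    if usable.empty:
        raise ValueError(f"sample {sample!r}: no spike-in with positive sense count")
    return float(np.median(usable["antisense"] / usable["sense"]))


def sequencing_depth(spikeins: SpikeInSet, sample: str) -> float:
    """Depth scale sigma_j = median over LABELED spike-ins of k_ij / l_i."""
    rows = spikeins.sample_rows(sample)
    labeled = rows[rows["labeled"]]
    if labeled.empty or not (labeled["sense"] > 0).any():
        raise ValueError(f"sample {sample!r}: no labeled spike-in with counts")
    return float(np.median(labeled["sense"] / labeled["length"]))


def cross_contamination(spikeins: SpikeInSet, sample: str, sigma: float) -> float:
    """Cross-contamination epsilon_j = median over UNLABELED spike-ins of (k/l) / sigma_j."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rows = spikeins.sample_rows(sample)
    unlabeled = rows[~rows["labeled"]]
    if unlabeled.empty:
        raise ValueError(f"sample {sample!r}: no unlabeled spike-in")
    return float(np.median(unlabeled["sense"] / unlabeled["length"]) / sigma)


def estimate_params(spikeins: SpikeInSet, rescale_sigma: bool = True) -> NormalizationParams:
    """Estimate (sigma, c, epsilon) for every sample in the set.

    With ``rescale_sigma`` the sigma vector is divided by its geometric mean
    so that factors average to 1 across samples (relative depths are what
    matter downstream).
    """
    samples = spikeins.samples
    sigma = pd.Series({j: sequencing_depth(spikeins, j) for j in samples})
    c = pd.Series({j: antisense_bias(spikeins, j) for j in samples})
    eps = pd.Series({j: cross_contamination(spikeins, j, sigma[j]) for j in samples})
    if rescale_sigma:
        sigma = sigma / stats.gmean(sigma)
    return NormalizationParams(sigma=sigma, c=c, epsilon=eps)


# ---------------------------------------------------------------------------
# corrections
# ---------------------------------------------------------------------------


def antisense_correct(S, A, c: float, floor: bool = True):
    """Invert the antisense mixing model: s = (S - c*A) / (1 - c**2).

    Works elementwise on scalars or arrays.  Negative corrected values are
    floored at zero (counts are physical); the number of floored cells is
    logged so a mis-estimated c is detectable.
    """
    if not 0 <= c < 1:
        raise ValueError(f"antisense bias c must lie in [0, 1), got {c}")
    S = np.asarray(S, dtype=float)
    A = np.asarray(A, dtype=float)
    s = (S - c * A) / (1.0 - c * c)
    if floor:
        n_neg = int(np.sum(s < 0))
        if n_neg:
            logger.warning("antisense correction floored %d negative cells at 0", n_neg)
        s = np.maximum(s, 0.0)
    return s if s.ndim else float(s)


def rpk(count, length_bp):
    """Reads per kilobase: count / (length_bp / 1000). Elementwise."""
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("length_bp must be positive")
    out = np.asarray(count, dtype=float) / (length_bp / 1000.0)
    return out if out.ndim else float(out)


def rpk_to_coverage(rpk_value: float, mean_fragment_bp: int = 200, n_replicates: int = 2) -> float:
    """Approximate per-sample coverage for an RPK value.

    With the default 200 bp mean fragment size and two summed replicates an
    RPK of 100 corresponds to a coverage of about 10 per sample, and an RPK
    of 20 to a coverage of about 2.
    """
    if mean_fragment_bp <= 0 or n_replicates <= 0:
        raise ValueError("fragment size and replicate count must be positive")
    if rpk_value < 0:
        raise ValueError("rpk must be non-negative")
    return rpk_value * mean_fragment_bp / 1000.0 / n_replicates


# ---------------------------------------------------------------------------
# reference sets and size factors
# ---------------------------------------------------------------------------


def select_expressed(
    rpk_by_tu: pd.DataFrame,
    threshold: float = 100.0,
    summarize: list[str] | None = None,
) -> pd.Index:
    """TUs whose RPK summed over the named replicate columns meets the threshold.

    ``rpk_by_tu``: rows TUs, columns samples, values antisense-corrected RPK.
    ``summarize`` names the replicate columns to sum (default: all columns).
    Threshold presets: 100 (reference-set path), 20 (plotting path); the
    boundary is inclusive.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    cols = list(rpk_by_tu.columns) if summarize is None else list(summarize)
    unknown = set(cols) - set(rpk_by_tu.columns)
    if unknown:
        raise KeyError(f"unknown sample columns: {sorted(unknown)}")
    summed = rpk_by_tu[cols].sum(axis=1)
    return rpk_by_tu.index[summed >= threshold]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style) on a reference count matrix.

    factor_j = median over TUs i of k_ij / geomean_j'(k_ij'); TUs containing
    a zero in any sample are excluded from the median.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("every reference TU contains a zero count in some sample")
    mat = mat[nonzero]
    log_geomean = np.log(mat).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(mat) - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns)


def depth_normalize(values, sigma):
    """t_ij = s_ij / sigma_j: divide each sample column by its depth scale.

    ``values`` may be a scalar with scalar sigma, or a DataFrame with a
    per-column sigma Series.
    """
    if np.ndim(values) == 0:
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        return float(values) / float(sigma)
    values = pd.DataFrame(values)
    sigma = pd.Series(sigma)
    if (sigma <= 0).any():
        raise ValueError("sigma must be positive")
    missing = set(values.columns) - set(sigma.index)
    if missing:
        raise KeyError(f"no sigma for samples: {sorted(missing)}")
    return values.div(sigma[values.columns], axis=1)


def select_reference_non_de(
    counts: pd.DataFrame,
    lengths: pd.Series,
    contrasts: dict[str, tuple[list[str], list[str]]],
    expressed: pd.Index | None = None,
    min_length_bp: int = 50_000,
    log2fc_tolerance: float = 0.25,
    sigma: pd.Series | None = None,
    alpha: float | None = None,
) -> pd.Index:
    """Select a non-differentially-expressed reference TU set.

    Among TUs in ``expressed`` (default: all) longer than ``min_length_bp``,
    keeps those whose |log2 fold change| between control and treated mean
    counts is within ``log2fc_tolerance`` at EVERY contrast (time point).
    Counts are depth-normalized by ``sigma`` when given, then balanced by
    median-of-ratios size factors WITHIN each replicate group (spike-in depth
    anchors the between-condition scale; balancing across conditions would
    re-center a genuine global shift onto unaffected genes) before the means
    are compared.  With ``alpha`` set, TUs whose fold change is
    additionally significant under a normal approximation on log counts are
    removed even inside the tolerance band.

    ``contrasts`` maps a label (e.g. time point) to (control samples,
    treated samples).
    """
    candidates = counts.index if expressed is None else pd.Index(expressed)
    candidates = candidates[lengths.reindex(candidates) > min_length_bp]
    if len(candidates) == 0:
        raise ValueError(
            f"no candidate TU longer than {min_length_bp} bp; relax min_length_bp "
            "or the expression threshold"
        )
    sub = counts.loc[candidates].astype(float)
    if sigma is not None:
        sub = depth_normalize(sub, sigma)
    all_samples = sorted({s for ctrl, trt in contrasts.values() for s in ctrl + trt})
    missing = set(all_samples) - set(sub.columns)
    if missing:
        raise KeyError(f"count matrix lacks samples: {sorted(missing)}")
    sub = sub[all_samples].copy()
    groups = {tuple(cols) for ctrl, trt in contrasts.values() for cols in (ctrl, trt)}
    for cols in groups:
        if len(cols) < 2:
            continue
        try:
            sf = size_factors(sub[list(cols)])
        except ValueError:
            continue  # no all-nonzero row in this group; leave unbalanced
        sub[list(cols)] = sub[list(cols)].div(sf, axis=1)

    keep = pd.Series(True, index=candidates)
    pseudo = 0.5  # guards the log against zero cells
    for label, (ctrl_cols, trt_cols) in contrasts.items():
        mean_c = sub[ctrl_cols].mean(axis=1)
        mean_t = sub[trt_cols].mean(axis=1)
        log2fc = np.log2((mean_t + pseudo) / (mean_c + pseudo))
        keep &= log2fc.abs() <= log2fc_tolerance
        if alpha is not None:
            z = _log_count_z(sub[ctrl_cols], sub[trt_cols], pseudo)
            pvals = 2 * stats.norm.sf(np.abs(z))
            keep &= pd.Series(pvals, index=candidates) > alpha
    selected = candidates[keep]
    if len(selected) == 0:
        raise ValueError(
            "no non-DE reference TU found; relax log2fc_tolerance or alpha"
        )
    logger.info("selected %d non-DE reference TUs of %d candidates",
                len(selected), len(candidates))
    return selected


def _log_count_z(ctrl: pd.DataFrame, trt: pd.DataFrame, pseudo: float) -> np.ndarray:
    lc, lt = np.log(ctrl + pseudo), np.log(trt + pseudo)
    var = lc.var(axis=1, ddof=1) / lc.shape[1] + lt.var(axis=1, ddof=1) / lt.shape[1]
    return (lt.mean(axis=1) - lc.mean(axis=1)) / np.sqrt(var.clip(lower=1e-12))


# ---------------------------------------------------------------------------
# transformer-style facade
# ---------------------------------------------------------------------------


class SpikeInNormalizer:
    """Fit spike-in normalization parameters, then transform count matrices.

    ``fit`` estimates per-sample (sigma_, c_, epsilon_) from a
    :class:`SpikeInSet`; ``transform`` applies antisense-bias correction
    (columns paired as sense/antisense) and depth normalization to a TU count
    matrix.  Follows the fit/transform protocol so it slots into generic
    pipelines.
    """

    def __init__(self, rescale_sigma: bool = True, apply_epsilon: bool = False):
        self.rescale_sigma = rescale_sigma
        self.apply_epsilon = apply_epsilon

    def get_params(self, deep: bool = True) -> dict:
        return {"rescale_sigma": self.rescale_sigma, "apply_epsilon": self.apply_epsilon}

    def set_params(self, **params) -> "SpikeInNormalizer":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, spikeins: SpikeInSet, y=None) -> "SpikeInNormalizer":
        params = estimate_params(spikeins, rescale_sigma=self.rescale_sigma)
        self.sigma_ = params.sigma
        self.c_ = params.c
        self.epsilon_ = params.epsilon
        self.params_ = params
        return self

    def transform(self, sense: pd.DataFrame, antisense: pd.DataFrame | None = None) -> pd.DataFrame:
        """Antisense-correct (if antisense counts given) and depth-normalize."""
        if not hasattr(self, "sigma_"):
            raise RuntimeError("SpikeInNormalizer is not fitted")
        out = sense.astype(float).copy()
        if antisense is not None:
            for col in out.columns:
                out[col] = antisense_correct(sense[col], antisense[col], self.c_[col])
        if self.apply_epsilon:
            # experimental: subtract the expected unlabeled carry-through
            out = out.mul(1.0 / (1.0 + self.epsilon_[out.columns]), axis=1)
        return depth_normalize(out, self.sigma_)

    def fit_transform(self, spikeins: SpikeInSet, sense: pd.DataFrame,
                      antisense: pd.DataFrame | None = None) -> pd.DataFrame:
        return self.fit(spikeins).transform(sense, antisense)
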