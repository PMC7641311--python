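"""Synthetic inputs with known ground truth for every pipeline stage.

Generates annotation (genes with 1-3 nested isoforms on synthetic
chromosomes), spike-in count tables under the sense/antisense mixing model
with planted (sigma, c, epsilon), per-TU count matrices with planted non-DE
and DE subsets and size factors, and coverage tracks produced by the
elongation-velocity simulator under control and slowed-down conditions —
so estimators and profile code can be tested against the planted truth
without any external download.

Every generator is deterministic given its seed and returns a
:class:`GroundTruth` sidecar holding the planted parameters; it can be
round-tripped through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Transcript, TranscriptionUnit, build_tus
from .simulate import SimulationConfig, VelocityProfile, simulate_gene
from .spikein import SpikeInSet
from .tracks import StrandedTrack

__all__ = [
    "GroundTruth",
    "gen_annotation",
    "gen_spikeins",
    "gen_counts",
    "gen_tracks",
]


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic dataset (JSON-serializable)."""

    sigma: dict[str, float] = field(default_factory=dict)
    c: dict[str, float] = field(default_factory=dict)
    epsilon: dict[str, float] = field(default_factory=dict)
    size_factors: dict[str, float] = field(default_factory=dict)
    expression_mean: dict[str, float] = field(default_factory=dict)
    fold_change: dict[str, dict[str, float]] = field(default_factory=dict)
    reference_tus: list[str] = field(default_factory=list)
    velocity: dict[str, list] = field(default_factory=dict)
    abundance: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


_BIOTYPE_LENGTHS = {  # biotype-specific length ranges (bp); None: global range
    "histone": (400, 1_000),
    "snRNA": (100, 300),
}

DEFAULT_BIOTYPE_FRACTIONS = {
    "protein_coding": 0.75,
    "intronless": 0.15,
    "histone": 0.06,
    "snRNA": 0.04,
}


def gen_annotation(
    n_genes: int,
    length_range: tuple[int, int] = (100, 2_000_000),
    biotype_fractions: dict[str, float] | None = None,
    seed: int = 0,
    n_chroms: int = 4,
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[list[Transcript], list[TranscriptionUnit], dict[str, int], GroundTruth]:
    """Synthetic gene annotation on synthetic chromosomes.

    Gene lengths are log-uniform over ``length_range`` (histone and snRNA
    biotypes use their own short ranges); each gene gets 1-3 isoforms nested
    inside — and the first spanning — the TU; genes are placed without
    overlap on ``n_chroms`` chromosomes, alternating strands.  Returns
    (transcripts, tus, chrom_sizes, truth).  Passing explicit ``chrom_sizes``
    raises if the genes do not fit.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    fractions = biotype_fractions or DEFAULT_BIOTYPE_FRACTIONS
    rng = np.random.default_rng(seed)
    biotypes = rng.choice(
        list(fractions), size=n_genes, p=np.array(list(fractions.values())) / sum(fractions.values())
    )
    lo, hi = length_range
    if not 0 < lo < hi:
        raise ValueError("length_range must be increasing and positive")
    lengths = []
    for bt in biotypes:
        blo, bhi = _BIOTYPE_LENGTHS.get(bt, (lo, hi))
        lengths.append(int(np.exp(rng.uniform(np.log(blo), np.log(bhi)))))

    transcripts: list[Transcript] = []
    cursors = {f"chrS{k + 1}": 10_000 for k in range(n_chroms)}
    for g, (bt, length) in enumerate(zip(biotypes, lengths)):
        chrom = f"chrS{g % n_chroms + 1}"
        start = cursors[chrom]
        end = start + length
        if chrom_sizes is not None and end + 10_000 > chrom_sizes.get(chrom, 0):
            raise ValueError(
                f"gene g{g + 1:04d} ({length} bp) does not fit on {chrom} "
                f"with the configured chromosome sizes"
            )
        gap = int(2_000 + rng.exponential(0.2 * length))
        cursors[chrom] = end + gap
        strand = "+" if g % 2 == 0 else "-"
        gid = f"g{g + 1:04d}"
        n_iso = 1 if bt in ("histone", "snRNA") else int(rng.integers(1, 4))
        transcripts.append(Transcript(f"{gid}.t1", gid, chrom, start, end, strand, bt))
        for k in range(1, n_iso):
            # nested isoform inside the TU span
            s = start + int(rng.integers(0, max(1, length // 4)))
            e = end - int(rng.integers(0, max(1, length // 4)))
            if e - s < 50:
                s, e = start, end
            transcripts.append(Transcript(f"{gid}.t{k + 1}", gid, chrom, s, e, strand, bt))
    sizes = chrom_sizes or {c: cur + 10_000 for c, cur in cursors.items()}
    tus = build_tus(transcripts)
    truth = GroundTruth(seed=seed)
    return transcripts, tus, sizes, truth


def gen_spikeins(
    n_spikeins: int = 12,
    sigma: dict[str, float] | None = None,
    c: dict[str, float] | float = 0.08,
    epsilon: dict[str, float] | float = 0.02,
    depth: float = 1e4,
    n_labeled: int | None = None,
    length_range: tuple[int, int] = (300, 2_000),
    abundance_cv: float = 0.0,
    seed: int = 0,
    noise_free: bool = False,
) -> tuple[SpikeInSet, GroundTruth]:
    """Spike-in counts under the mixing model with planted (sigma, c, epsilon).

    Expected sense counts: labeled spike-ins ``depth * sigma_j * (l_i/mean_l)
    * a_i``; unlabeled spike-ins the same times ``epsilon_j`` (the unlabeled
    carry-through).  Observed antisense expectation is ``c_j`` times the
    sense expectation; counts are Poisson unless ``noise_free``.  Abundances
    ``a_i`` default to equimolar (spike-in mixes are added at controlled
    amounts); ``abundance_cv`` adds log-normal spread.
    """
    if n_spikeins < 2:
        raise ValueError("need at least two spike-ins (one labeled, one unlabeled)")
    sigma = sigma or {"sample1": 1.0, "sample2": 1.0}
    samples = list(sigma)
    c = {j: float(c) for j in samples} if np.isscalar(c) else dict(c)
    epsilon = {j: float(epsilon) for j in samples} if np.isscalar(epsilon) else dict(epsilon)
    n_labeled = n_labeled if n_labeled is not None else max(1, (2 * n_spikeins) // 3)
    if not 1 <= n_labeled <= n_spikeins - 1:
        raise ValueError("need at least one labeled and one unlabeled spike-in")
    rng = np.random.default_rng(seed)
    lengths = np.exp(rng.uniform(*np.log(length_range), n_spikeins)).astype(int)
    labeled = np.arange(n_spikeins) < n_labeled
    if abundance_cv > 0:
        s = np.sqrt(np.log1p(abundance_cv**2))
        abundance = np.exp(rng.normal(-s * s / 2, s, n_spikeins))
    else:
        abundance = np.ones(n_spikeins)
    mean_l = float(lengths.mean())

    rows = []
    for j in samples:
        base = depth * sigma[j] * (lengths / mean_l) * abundance
        mu_sense = np.where(labeled, base, epsilon[j] * base)
        mu_anti = c[j] * mu_sense
        sense = mu_sense if noise_free else rng.poisson(mu_sense).astype(float)
        anti = mu_anti if noise_free else rng.poisson(mu_anti).astype(float)
        for i in range(n_spikeins):
            rows.append((f"spike{i + 1:02d}", int(lengths[i]), bool(labeled[i]),
                         j, float(sense[i]), float(anti[i])))
    table = pd.DataFrame(rows, columns=["spikein_id", "length", "labeled",
                                        "sample", "sense", "antisense"])
    truth = GroundTruth(
        sigma={j: float(v) for j, v in sigma.items()}, c=c, epsilon=epsilon,
        abundance={f"spike{i + 1:02d}": float(a) for i, a in enumerate(abundance)},
        seed=seed,
    )
    return SpikeInSet(table), truth


def gen_counts(
    tus: list[TranscriptionUnit],
    mean_rpk: float = 50.0,
    de_fraction: float = 0.5,
    de_log2fc: float = -1.0,
    size_factors: dict[str, float] | None = None,
    time_points: tuple[str, ...] = ("t15", "t30"),
    n_replicates: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Per-TU count matrix over control/treated x time points x replicates.

    Expression means are log-normal around ``mean_rpk`` per kilobase; a
    ``de_fraction`` of TUs is planted as differentially expressed with
    ``de_log2fc`` in the treated samples at both time points, the remainder
    (the planted reference set) at fold change 1.  Counts are Poisson around
    mean_per_kb * length_kb * size_factor * fold_change.  Sample names:
    ``{ctrl|trt}_{tp}_r{k}``.
    """
    if not tus:
        raise ValueError("empty TU list")
    rng = np.random.default_rng(seed)
    n = len(tus)
    means = np.exp(rng.normal(np.log(mean_rpk), 0.5, n))
    is_de = rng.random(n) < de_fraction
    samples = [f"{cond}_{tp}_r{k + 1}" for tp in time_points
               for cond in ("ctrl", "trt") for k in range(n_replicates)]
    sf = size_factors or {s: 1.0 for s in samples}
    lengths = pd.Series({tu.gene_id: tu.length_bp for tu in tus})

    counts = {}
    for s in samples:
        treated = s.startswith("trt")
        fc = np.where(is_de & treated, 2.0**de_log2fc, 1.0)
        mu = means * (lengths.to_numpy() / 1000.0) * sf[s] * fc
        counts[s] = rng.poisson(mu).astype(float)
    mat = pd.DataFrame(counts, index=lengths.index)
    truth = GroundTruth(
        size_factors={s: float(v) for s, v in sf.items()},
        expression_mean={tu.gene_id: float(m) for tu, m in zip(tus, means)},
        fold_change={
            tp: {tu.gene_id: float(2.0**de_log2fc if d else 1.0)
                 for tu, d in zip(tus, is_de)}
            for tp in time_points
        },
        reference_tus=[tu.gene_id for tu, d in zip(tus, is_de) if not d],
        seed=seed,
    )
    return mat, lengths, truth


_COND_ID = {"control": 0, "treated": 1}


def gen_tracks(
    tus: list[TranscriptionUnit],
    cfg: SimulationConfig,
    v_control: VelocityProfile,
    v_treated: VelocityProfile,
    chrom_sizes: dict[str, int] | None = None,
    seed: int = 0,
    mnet: bool = True,
) -> dict[str, StrandedTrack]:
    """Simulated TT-seq coverage and mNET-seq-like 3'-end tracks per condition.

    TT-seq tracks come from the velocity simulator per TU (treated uses the
    slowdown profile; histone-biotype TUs keep the control velocity in the
    treated condition, planting inhibition-insensitive histone transcription).
    mNET-seq-like tracks place one count at each polymerase's active-site
    position at harvest time, giving a pol-II-occupancy analogue whose
    density scales as initiation_rate / velocity at re-equilibrated regions.

    Returns a dict with keys ``tt_control``, ``tt_treated`` and (with
    ``mnet``) ``mnet_control``, ``mnet_treated``.
    """
    rng = np.random.default_rng(seed)
    out = {name: StrandedTrack(chrom_sizes)
           for name in ("tt_control", "tt_treated", "mnet_control", "mnet_treated")}
    for tu in tus:
        sub_seed = int(rng.integers(2**31))
        for cond, v in (("control", v_control), ("treated", v_treated)):
            if cond == "treated" and tu.biotype == "histone":
                v = v_control  # histone transcription is planted as unaffected
            prof = simulate_gene(tu.length_bp, v, cfg, cond,
                                 np.random.default_rng((sub_seed, _COND_ID[cond])))
            vals = prof.values if tu.strand == "+" else prof.values[::-1]
            out[f"tt_{cond}"].add_values(tu.chrom, tu.strand, tu.start, vals)
            if mnet:
                pos = _polymerase_positions(
                    tu.length_bp, v, cfg,
                    np.random.default_rng((sub_seed, 7, _COND_ID[cond])))
                vals = np.zeros(tu.length_bp)
                np.add.at(vals, pos, 1.0)
                if tu.strand == "-":
                    vals = vals[::-1]
                out[f"mnet_{cond}"].add_values(tu.chrom, tu.strand, tu.start, vals)
    if not mnet:
        out = {k: v for k, v in out.items() if k.startswith("tt_")}
    for track in out.values():
        track.consolidate()
    return out


def _polymerase_positions(
    gene_length: int, v: VelocityProfile, cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Active-site positions of polymerases on the gene at harvest (elapsed) time."""
    harvest = cfg.elapsed
    t0_min = harvest - gene_length / v.v_min - 1e-9
    span = harvest - t0_min
    n = rng.poisson(span * cfg.initiation_rate)
    t0s = t0_min + rng.random(n) * span
    pos = np.array([v.integral(t0, harvest) for t0 in t0s])
    pos = pos[(pos >= 0) & (pos < gene_length)]
    return pos.astype(int)
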