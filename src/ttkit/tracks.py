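"""Stranded per-base signal tracks.

A :class:`StrandedTrack` holds per-base signal keyed by (chromosome, strand)
as a list of dense patches (offset + value array).  Patches exist only where
signal was written, so genome-scale tracks with signal confined to gene loci
stay small.  Queries (window sums, dense window extraction) add overlapping
patches, so repeated writes to the same region accumulate — the natural
semantics for coverage.

bedGraph is the on-disk format: one 4-column file per strand, suffixed
``.plus.bedgraph`` / ``.minus.bedgraph``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["StrandedTrack", "read_chrom_sizes", "write_chrom_sizes"]


class StrandedTrack:
    """Sparse-patch container for stranded per-base signal."""

    def __init__(self, chrom_sizes: dict[str, int] | None = None):
        # (chrom, strand) -> list of (start, np.ndarray values)
        self._patches: dict[tuple[str, str], list[tuple[int, np.ndarray]]] = {}
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else {}

    # -- writing ------------------------------------------------------------

    def add_values(self, chrom: str, strand: str, start: int, values: np.ndarray) -> None:
        """Add a dense value block starting at ``start`` (accumulating)."""
        values = np.asarray(values, dtype=float)
        if values.ndim != 1:
            raise ValueError("values must be 1-D")
        if start < 0:
            raise ValueError("start must be >= 0")
        if values.size:
            self._patches.setdefault((chrom, strand), []).append((int(start), values))

    def increment(self, chrom: str, strand: str, pos: int, amount: float = 1.0) -> None:
        """Add ``amount`` at a single base (3'-end counting)."""
        self.add_values(chrom, strand, pos, np.array([amount]))

    # -- reading ------------------------------------------------------------

    def window_values(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Dense signal over [start, end); zero where nothing was written."""
        if end <= start:
            raise ValueError("end must exceed start")
        out = np.zeros(end - start)
        for pstart, vals in self._patches.get((chrom, strand), ()):  # noqa: B905
            pend = pstart + vals.size
            lo, hi = max(start, pstart), min(end, pend)
            if lo < hi:
                out[lo - start : hi - start] += vals[lo - pstart : hi - pstart]
        return out

    def window_sum(self, chrom: str, strand: str, start: int, end: int) -> float:
        total = 0.0
        for pstart, vals in self._patches.get((chrom, strand), ()):
            pend = pstart + vals.size
            lo, hi = max(start, pstart), min(end, pend)
            if lo < hi:
                total += float(vals[lo - pstart : hi - pstart].sum())
        return total

    def total(self) -> float:
        return float(sum(v.sum() for ps in self._patches.values() for _, v in ps))

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._patches)

    def extent(self, chrom: str, strand: str) -> tuple[int, int] | None:
        ps = self._patches.get((chrom, strand))
        if not ps:
            return None
        return min(s for s, _ in ps), max(s + v.size for s, v in ps)

    # -- algebra ------------------------------------------------------------

    def scale(self, factor: float) -> "StrandedTrack":
        out = StrandedTrack(self.chrom_sizes)
        for key, ps in self._patches.items():
            out._patches[key] = [(s, v * factor) for s, v in ps]
        return out

    def __add__(self, other: "StrandedTrack") -> "StrandedTrack":
        out = StrandedTrack({**other.chrom_sizes, **self.chrom_sizes})
        for src in (self, other):
            for key, ps in src._patches.items():
                out._patches.setdefault(key, []).extend((s, v.copy()) for s, v in ps)
        return out

    def consolidate(self) -> "StrandedTrack":
        """Merge overlapping patches per key into disjoint blocks (in place)."""
        for key, ps in self._patches.items():
            if len(ps) <= 1:
                continue
            self._patches[key] = _merge_patches(ps)
        return self

    # -- IO -----------------------------------------------------------------

    def to_bedgraph(self, prefix: str) -> tuple[str, str]:
        """Write ``<prefix>.plus.bedgraph`` and ``<prefix>.minus.bedgraph``."""
        self.consolidate()
        paths = []
        for strand, suffix in (("+", ".plus.bedgraph"), ("-", ".minus.bedgraph")):
            path = prefix + suffix
            with open(path, "w") as fh:
                for (chrom, s), ps in sorted(self._patches.items()):
                    if s != strand:
                        continue
                    for start, vals in sorted(ps):
                        _write_runs(fh, chrom, start, vals)
            paths.append(path)
        return tuple(paths)

    @classmethod
    def from_bedgraph(
        cls,
        plus_path: str | None,
        minus_path: str | None = None,
        chrom_sizes: dict[str, int] | None = None,
    ) -> "StrandedTrack":
        track = cls(chrom_sizes)
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            if path is None:
                continue
            with open(path) as fh:
                for line in fh:
                    if not line.strip() or line.startswith(("track", "#")):
                        continue
                    chrom, start, end, value = line.split()[:4]
                    start, end, value = int(start), int(end), float(value)
                    if value != 0.0:
                        track.add_values(chrom, strand, start, np.full(end - start, value))
        track.consolidate()
        return track


def _merge_patches(ps: list[tuple[int, np.ndarray]]) -> list[tuple[int, np.ndarray]]:
    ps = sorted(ps, key=lambda p: p[0])
    merged: list[tuple[int, np.ndarray]] = []
    cur_start, cur = ps[0][0], ps[0][1].copy()
    for start, vals in ps[1:]:
        end = cur_start + cur.size
        if start <= end:
            new_end = max(end, start + vals.size)
            if new_end > end:
                cur = np.concatenate([cur, np.zeros(new_end - end)])
            cur[start - cur_start : start - cur_start + vals.size] += vals
        else:
            merged.append((cur_start, cur))
            cur_start, cur = start, vals.copy()
    merged.append((cur_start, cur))
    return merged


def _write_runs(fh, chrom: str, offset: int, vals: np.ndarray) -> None:
    """Emit run-length-compressed bedGraph lines, skipping zero runs."""
    if not vals.size:
        return
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [vals.size]])
    for s, e in zip(starts, ends):
        v = vals[s]
        if v != 0.0:
            fh.write(f"{chrom}\t{offset + s}\t{offset + e}\t{v:.6g}\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
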