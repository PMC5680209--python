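"""Per-position read evidence for deduplicated panel pileups.

The atom of the pipeline is a :class:`PileupSite`: one genomic position with
its deduplicated depth, the number of reads supporting a designated
alternative base, per-strand counts, and the 0-based offsets of the variant
base within its supporting reads (used by the artifact filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PileupSite"]


@dataclass(frozen=True)
class PileupSite:
    """Read evidence at a single genomic position.

    Counts refer to deduplicated reads. ``alt_read_offsets`` holds, for each
    read supporting the alternative base, the 0-based offset of that base
    within the read (read length is typically 100 bp).
    """

    chrom: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int
    alt_fwd: int
    alt_rev: int
    ref_fwd: int
    ref_rev: int
    alt_read_offsets: tuple[int, ...] = field(default=())
    true_vaf: float | None = None  # simulation truth, if known

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        counts = (self.depth, self.alt_count, self.alt_fwd, self.alt_rev,
                  self.ref_fwd, self.ref_rev)
        if any(c < 0 for c in counts):
            raise ValueError(f"negative count in pileup at {self.chrom}:{self.pos}")
        if self.alt_count > self.depth:
            raise ValueError(
                f"alt_count {self.alt_count} exceeds depth {self.depth} "
                f"at {self.chrom}:{self.pos}")
        if self.alt_fwd + self.alt_rev != self.alt_count:
            raise ValueError("stranded alt counts do not sum to alt_count")
        if self.ref_fwd + self.ref_rev != self.depth - self.alt_count:
            raise ValueError("stranded ref counts do not sum to depth - alt_count")

    @property
    def vaf(self) -> float:
        """Variant allele fraction; 0.0 at zero depth."""
        return self.alt_count / self.depth if self.depth > 0 else 0.0

    def with_counts(self, *, alt_fwd: int, alt_rev: int, depth: int | None = None,
                    alt_read_offsets: tuple[int, ...] | None = None,
                    true_vaf: float | None = None) -> "PileupSite":
        """Return a copy with updated alt counts (ref strands rebalanced).

        The forward/reverse split of the reference reads is adjusted so that
        reads removed from (or converted out of) the alt class stay on their
        original strand.
        """
        new_depth = self.depth if depth is None else depth
        alt = alt_fwd + alt_rev
        d_fwd = self.alt_fwd - alt_fwd  # alt reads leaving the alt class, fwd strand
        d_rev = self.alt_rev - alt_rev
        if depth is None:
            ref_fwd = self.ref_fwd + d_fwd
            ref_rev = self.ref_rev + d_rev
        else:
            # depth changed (downsampling): ref strands drawn by the caller are
            # unknown here; split the remaining reference reads proportionally.
            ref_total = new_depth - alt
            denom = self.ref_fwd + self.ref_rev
            ref_fwd = int(round(ref_total * (self.ref_fwd / denom))) if denom else 0
            ref_fwd = min(ref_fwd, ref_total)
            ref_rev = ref_total - ref_fwd
        return replace(
            self, depth=new_depth, alt_count=alt, alt_fwd=alt_fwd, alt_rev=alt_rev,
            ref_fwd=ref_fwd, ref_rev=ref_rev,
            alt_read_offsets=self.alt_read_offsets if alt_read_offsets is None
            else alt_read_offsets,
            true_vaf=self.true_vaf if true_vaf is None else true_vaf)


def _subsample_offsets(offsets: tuple[int, ...], k: int,
                       rng: np.random.Generator) -> tuple[int, ...]:
    """Draw k offsets without replacement, preserving order."""
    if k >= len(offsets):
        return offsets
    idx = np.sort(rng.choice(len(offsets), size=k, replace=False))
    return tuple(int(offsets[i]) for i in idx)
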