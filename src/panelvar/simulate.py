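"""Synthetic panel-sequencing data with the statistical structure of
deduplicated clinical tumor pileups.

This module generates every substrate the rest of the pipeline consumes:

* tumor pileups with binomial allele sampling on top of a purity / clone /
  copy-state expectation model (:func:`simulate_tumor_pileups`),
* germline heterozygous-SNP pileups across copy-state segments, the input
  for purity inference (:func:`simulate_snp_pileups`),
* in-silico dilution and read downsampling of existing pileups
  (:func:`dilute_in_silico`, :func:`downsample_site`), the machinery of the
  limit-of-detection assays,
* an unmatched normal cohort for panel-of-normals filtering
  (:func:`simulate_normal_cohort`),
* cell-line mixture expectations (:func:`simulate_mixture_vafs`),
* exon-level depth matrices with CNV truth (:func:`simulate_exon_depth_matrix`),
* split-read records supporting fusions (:func:`simulate_split_reads`).

Depths are drawn negative-binomially around the configured mean (panel
coverage is overdispersed across targets), then thinned binomially by the
deduplication survival fraction. Sequencing errors occur at a single global
per-base rate ``base_error_rate`` and are split uniformly across the three
non-reference bases; only the designated alternative base counts toward
``alt_count``. All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pileup import PileupSite, _subsample_offsets

__all__ = [
    "SimulationConfig", "NormalCohort", "SplitRead",
    "simulate_tumor_pileups", "simulate_snp_pileups", "dilute_in_silico",
    "downsample_site", "simulate_normal_cohort", "simulate_mixture_vafs",
    "simulate_exon_depth_matrix", "simulate_split_reads",
    "expected_somatic_vaf",
]

_BASES = ("A", "C", "G", "T")
READ_LENGTH = 100  # bp; 100-bp paired-end reads


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the tumor-pileup generator.

    ``copy_states`` gives per-site (total copies X, variant copies Y) in
    tumor cells and is cycled over sites; a site with Y = 0 is a
    non-variant site that accumulates alt reads only through sequencing
    error. ``clone_fractions`` (cancer-cell fractions) are cycled the same
    way. ``dedup_fraction`` is the fraction of nominal depth surviving
    duplicate removal (~0.8 for FFPE panels targeting ~1000x).
    """

    n_sites: int
    depth_mean: float = 1000.0
    depth_dispersion: float = 8.0  # NB size parameter; var = m + m^2/size
    base_error_rate: float = 0.001
    purity: float = 1.0
    clone_fractions: tuple[float, ...] = (1.0,)
    copy_states: tuple[tuple[int, int], ...] = ((2, 1),)
    dedup_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not (self.depth_mean > 0 and math.isfinite(self.depth_mean)):
            raise ValueError("depth_mean must be positive and finite")
        if not (self.depth_dispersion > 0 and math.isfinite(self.depth_dispersion)):
            raise ValueError("depth_dispersion must be positive and finite")
        if not (0.0 < self.base_error_rate < 0.1):
            raise ValueError("base_error_rate must be in (0, 0.1)")
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity must be in [0, 1]")
        if not self.clone_fractions or any(
                not (0.0 < c <= 1.0) for c in self.clone_fractions):
            raise ValueError("clone_fractions must be in (0, 1]")
        for X, Y in self.copy_states:
            if X < 0 or Y < 0 or Y > X:
                raise ValueError(f"invalid copy state (X={X}, Y={Y})")
        if not (0.0 < self.dedup_fraction <= 1.0):
            raise ValueError("dedup_fraction must be in (0, 1]")


def expected_somatic_vaf(purity: float, clone_fraction: float,
                         total_copies: int, variant_copies: int) -> float:
    """Expected VAF of a somatic variant before sequencing error.

    With purity P, cancer-cell fraction c, and Y variant copies of X total
    in the mutant tumor cells (non-mutant tumor cells and normal cells are
    diploid reference):

        E[VAF] = P*c*Y / (P*c*X + P*(1-c)*2 + 2*(1-P))
    """
    num = purity * clone_fraction * variant_copies
    den = (purity * clone_fraction * total_copies
           + purity * (1.0 - clone_fraction) * 2.0
           + 2.0 * (1.0 - purity))
    return num / den if den > 0 else 0.0


def _nb_depths(rng: np.random.Generator, n: int, mean: float,
               dispersion: float) -> np.ndarray:
    # numpy's negative_binomial(n, p): mean = n(1-p)/p -> p = size/(size+mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def _draw_site(rng: np.random.Generator, chrom: str, pos: int, ref: str,
               alt: str, depth: int, p_alt: float,
               true_vaf: float | None) -> PileupSite:
    alt_count = int(rng.binomial(depth, p_alt)) if depth > 0 else 0
    alt_fwd = int(rng.binomial(alt_count, 0.5))
    ref_total = depth - alt_count
    ref_fwd = int(rng.binomial(ref_total, 0.5))
    offsets = tuple(int(o) for o in np.sort(
        rng.integers(0, READ_LENGTH, size=alt_count)))
    return PileupSite(
        chrom=chrom, pos=pos, ref_base=ref, alt_base=alt, depth=depth,
        alt_count=alt_count, alt_fwd=alt_fwd, alt_rev=alt_count - alt_fwd,
        ref_fwd=ref_fwd, ref_rev=ref_total - ref_fwd,
        alt_read_offsets=offsets, true_vaf=true_vaf)


def simulate_tumor_pileups(config: SimulationConfig) -> list[PileupSite]:
    """Generate tumor pileups under the configured purity/clone/copy model.

    Sites are laid out on chromosome "chr1" at 1 kb spacing. The sampled
    alt count at a variant site is binomial at the deduplicated depth with
    success probability ``E[VAF]*(1-eps) + (1-E[VAF])*eps/3`` so that both
    true variant reads and error reads contribute; non-variant sites see
    only the error term. The error-free expectation is recorded in
    ``true_vaf``.
    """
    rng = np.random.default_rng(config.seed)
    eps = config.base_error_rate
    nominal = _nb_depths(rng, config.n_sites, config.depth_mean,
                         config.depth_dispersion)
    sites: list[PileupSite] = []
    for i in range(config.n_sites):
        X, Y = config.copy_states[i % len(config.copy_states)]
        c = config.clone_fractions[i % len(config.clone_fractions)]
        vaf = expected_somatic_vaf(config.purity, c, X, Y)
        depth = int(rng.binomial(int(nominal[i]), config.dedup_fraction))
        p_alt = vaf * (1.0 - eps) + (1.0 - vaf) * eps / 3.0
        ref, alt = "C", "T"
        sites.append(_draw_site(rng, "chr1", 1000 * (i + 1), ref, alt,
                                depth, p_alt, true_vaf=vaf))
    return sites


def simulate_snp_pileups(purity: float,
                         segments: Sequence[Mapping],
                         depth_mean: float = 1000.0,
                         depth_dispersion: float = 8.0,
                         base_error_rate: float = 0.001,
                         dedup_fraction: float = 1.0,
                         seed: int = 0) -> list[PileupSite]:
    """Germline heterozygous-SNP pileups across copy-state segments.

    Each segment dict has keys ``chrom``, ``n_snps``, ``X`` (total copies in
    tumor cells) and ``Y`` (copies carrying the alt allele). Germline het
    SNPs contribute one alt allele from each normal cell, so the expected
    alternative allele frequency follows

        AAF = (P*Y + (1-P)) / (P*X + 2*(1-P))

    and the segment's coverage scales with its total copy mass
    ``(P*X + 2(1-P))/2`` relative to a diploid segment. The alt allele is
    placed on the duplicated/retained haplotype for half the SNPs at random
    (i.e. Y vs X-Y), as in real data.
    """
    if not (0.0 <= purity <= 1.0):
        raise ValueError("purity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    eps = base_error_rate
    sites: list[PileupSite] = []
    for seg in segments:
        X, Y = int(seg["X"]), int(seg["Y"])
        if X < 1 or not (0 <= Y <= X):
            raise ValueError(f"invalid segment copy state (X={X}, Y={Y})")
        mass = (purity * X + 2.0 * (1.0 - purity)) / 2.0
        seg_mean = depth_mean * mass
        n = int(seg["n_snps"])
        nominal = _nb_depths(rng, n, seg_mean, depth_dispersion)
        for j in range(n):
            y = Y if rng.random() < 0.5 else X - Y  # haplotype orientation
            den = purity * X + 2.0 * (1.0 - purity)
            aaf = (purity * y + (1.0 - purity)) / den
            depth = int(rng.binomial(int(nominal[j]), dedup_fraction))
            p_alt = aaf * (1.0 - eps) + (1.0 - aaf) * eps / 3.0
            sites.append(_draw_site(rng, str(seg["chrom"]), 10_000 * (j + 1),
                                    "A", "G", depth, p_alt, true_vaf=aaf))
    return sites


def dilute_in_silico(sites: Iterable[PileupSite], target_vaf: float,
                     seed: int = 0) -> list[PileupSite]:
    """Dilute variant-supporting reads down to a target VAF.

    Each variant-supporting read is independently converted to the
    reference base with probability ``1 - target_vaf/observed_vaf``
    (the site's *observed* VAF, not a nominal value, is the denominator —
    manual dilutions suffer from realized-concentration error and the in
    silico assay avoids it). Depth is unchanged; converted reads keep their
    strand but move to the reference class. The realized VAF is recorded in
    ``true_vaf``.
    """
    rng = np.random.default_rng(seed)
    out: list[PileupSite] = []
    for site in sites:
        obs = site.vaf
        if target_vaf > obs:
            raise ValueError(
                f"target VAF {target_vaf} exceeds observed VAF {obs:.4f} "
                f"at {site.chrom}:{site.pos}")
        keep_p = target_vaf / obs if obs > 0 else 0.0
        kept_fwd = int(rng.binomial(site.alt_fwd, keep_p))
        kept_rev = int(rng.binomial(site.alt_rev, keep_p))
        kept = kept_fwd + kept_rev
        offsets = _subsample_offsets(site.alt_read_offsets, kept, rng)
        new = site.with_counts(alt_fwd=kept_fwd, alt_rev=kept_rev,
                               alt_read_offsets=offsets)
        out.append(new.with_counts(alt_fwd=kept_fwd, alt_rev=kept_rev,
                                   true_vaf=new.vaf))
    return out


def downsample_site(site: PileupSite, target_depth: int,
                    seed: int = 0) -> PileupSite:
    """Downsample a pileup to a target depth without replacement.

    Reads are drawn hypergeometrically (alt vs ref), so
    ``E[alt'] = alt_count * target_depth / depth`` and
    ``alt' <= min(alt_count, target_depth)``.
    """
    if target_depth > site.depth:
        raise ValueError(
            f"target_depth {target_depth} exceeds site depth {site.depth}")
    if target_depth == site.depth:
        return site
    rng = np.random.default_rng(seed)
    alt = int(rng.hypergeometric(site.alt_count, site.depth - site.alt_count,
                                 target_depth)) if target_depth > 0 else 0
    alt_fwd = int(rng.hypergeometric(site.alt_fwd, site.alt_rev, alt)) \
        if alt > 0 else 0
    offsets = _subsample_offsets(site.alt_read_offsets, alt, rng)
    return site.with_counts(alt_fwd=alt_fwd, alt_rev=alt - alt_fwd,
                            depth=target_depth, alt_read_offsets=offsets)


@dataclass(frozen=True)
class NormalCohort:
    """Genotypes of an unmatched normal cohort at candidate germline sites.

    ``genotypes`` is a (n_samples x n_sites) allele-dosage matrix in
    {0, 1, 2}; ``sites`` carries chrom/pos/ref/alt per column. The cohort
    allele frequency at each site is the carrier-allele fraction
    sum(dosages) / (2 * n_samples).
    """

    sites: pd.DataFrame
    genotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D sample x site matrix")
        if self.genotypes.shape[1] != len(self.sites):
            raise ValueError("genotype columns must match site table rows")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def allele_frequency(self) -> np.ndarray:
        """Per-site cohort allele frequency in [0, 1]."""
        if self.n_samples == 0:
            return np.zeros(len(self.sites))
        return self.genotypes.sum(axis=0) / (2.0 * self.n_samples)

    def af_lookup(self) -> dict[tuple[str, int, str, str], float]:
        """(chrom, pos, ref, alt) -> cohort allele frequency."""
        freqs = self.allele_frequency
        return {
            (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): float(freqs[i])
            for i, r in enumerate(self.sites.itertuples(index=False))
        }


def simulate_normal_cohort(n_samples: int,
                           germline_sites: Sequence[Mapping] | pd.DataFrame,
                           seed: int = 0) -> NormalCohort:
    """Draw a normal cohort with Hardy-Weinberg dosages at germline sites.

    ``germline_sites`` rows need chrom, pos, ref, alt and ``pop_af`` (the
    population allele frequency to inject); dosages are Binomial(2, pop_af)
    per sample, so the realized cohort frequency matches the injected one in
    expectation. Clinical practice uses >400 such unmatched normals to stand
    in for a matched normal.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    sites = pd.DataFrame(germline_sites)
    if sites.empty:
        raise ValueError("germline_sites must be nonempty")
    required = {"chrom", "pos", "ref", "alt", "pop_af"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"germline site spec missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    afs = sites["pop_af"].to_numpy(dtype=float)
    if ((afs < 0) | (afs > 1)).any():
        raise ValueError("pop_af must be in [0, 1]")
    genotypes = rng.binomial(2, afs, size=(n_samples, len(sites)))
    return NormalCohort(sites=sites.reset_index(drop=True), genotypes=genotypes)


def simulate_mixture_vafs(genotype_matrix: np.ndarray,
                          proportions: Sequence[float]) -> np.ndarray:
    """Expected VAF per SNP for a mixture of cell lines.

    ``genotype_matrix`` is (n_lines x n_snps) allele dosages in {0, 1, 2};
    ``proportions`` must sum to 1. A SNP heterozygous in exactly one line of
    an equal 10-line pool has expected VAF 0.05 — the design point of manual
    dilution assays built from pooled HapMap lines.
    """
    G = np.asarray(genotype_matrix)
    props = np.asarray(proportions, dtype=float)
    if not np.isin(G, (0, 1, 2)).all():
        raise ValueError("dosages must be in {0, 1, 2}")
    if G.shape[0] != props.shape[0]:
        raise ValueError("one proportion per line required")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {props.sum()!r}")
    return props @ (G / 2.0)


def simulate_exon_depth_matrix(cnv_truth: Mapping[str, int],
                               purity: float,
                               noise_cv: float,
                               seed: int = 0,
                               exons_per_gene: int = 8,
                               n_normals: int = 8,
                               base_depth: float = 1000.0) -> pd.DataFrame:
    """Exon x sample depth matrix with known copy-number truth.

    ``cnv_truth`` maps gene -> total tumor copy number C. Against a diploid
    baseline the expected depth ratio of the tumor sample is
    ``R = (P*C + 2(1-P))/2``. A per-exon capture-efficiency factor (shared
    by all samples) emulates capture/GC variability; multiplicative
    log-normal noise with the given CV is applied per cell. Normal reference
    samples are generated at C = 2. Returns a DataFrame indexed by
    (gene, exon) with columns ``tumor``, ``normal_1`` ... ``normal_k``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if not (0.0 <= purity <= 1.0):
        raise ValueError("purity must be in [0, 1]")
    if any(c < 0 for c in cnv_truth.values()):
        raise ValueError("copy numbers must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(noise_cv ** 2))

    def noise(n: int) -> np.ndarray:
        if sigma == 0:
            return np.ones(n)
        return rng.lognormal(-sigma ** 2 / 2.0, sigma, size=n)

    index = pd.MultiIndex.from_tuples(
        [(g, e) for g in cnv_truth for e in range(1, exons_per_gene + 1)],
        names=["gene", "exon"])
    n_exons = len(index)
    efficiency = rng.lognormal(0.0, 0.3, size=n_exons)
    ratio = np.repeat(
        [(purity * c + 2.0 * (1.0 - purity)) / 2.0 for c in cnv_truth.values()],
        exons_per_gene)
    data = {"tumor": base_depth * efficiency * ratio * noise(n_exons)}
    for k in range(1, n_normals + 1):
        data[f"normal_{k}"] = base_depth * efficiency * noise(n_exons)
    return pd.DataFrame(data, index=index)


@dataclass(frozen=True)
class SplitRead:
    """One alignment record supporting a candidate breakpoint.

    A split read aligns in two segments, one on each side of the junction;
    ``side`` records which side of the breakpoint the read's longer anchor
    lies on. CIGAR-style strings describe each segment (e.g. ``"60M40S"``).
    Both primary and secondary alignments are retained — counting secondary
    alignments increases fusion sensitivity.
    """

    read_id: str
    side: str  # "left" or "right"
    chrom_a: str
    pos_a: int
    strand_a: str
    cigar_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    cigar_b: str
    mapq: int
    is_secondary: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError("positions must be 1-based positive")


def _cigar(matched: int) -> str:
    clipped = max(READ_LENGTH - matched, 0)
    return f"{matched}M{clipped}S" if clipped else f"{matched}M"


def simulate_split_reads(fusion_truth: Sequence[Mapping],
                         seed: int = 0) -> list[SplitRead]:
    """Emit split-read records for configured breakpoints.

    Each truth entry is a mapping with keys ``name``, ``chrom_a``, ``pos_a``,
    ``chrom_b``, ``pos_b`` and support counts ``n_left`` / ``n_right``
    (reads anchored on each side); optional keys: ``strand_a``/``strand_b``
    (default "+"), ``n_secondary`` (how many of the reads are secondary
    alignments), ``mapq`` (default 60), ``matched_len`` (default 60) and
    ``pos_jitter`` (uniform +/- jitter on reported breakpoint positions,
    default 0).
    """
    rng = np.random.default_rng(seed)
    reads: list[SplitRead] = []
    for t in fusion_truth:
        for key in ("name", "chrom_a", "pos_a", "chrom_b", "pos_b",
                    "n_left", "n_right"):
            if key not in t:
                raise ValueError(f"fusion truth entry missing {key!r}")
        n_left, n_right = int(t["n_left"]), int(t["n_right"])
        if n_left < 0 or n_right < 0:
            raise ValueError("support counts must be >= 0")
        n_secondary = int(t.get("n_secondary", 0))
        jitter = int(t.get("pos_jitter", 0))
        mapq = int(t.get("mapq", 60))
        matched = int(t.get("matched_len", 60))
        sides = ["left"] * n_left + ["right"] * n_right
        for i, side in enumerate(sides):
            dj = (int(rng.integers(-jitter, jitter + 1)), int(rng.integers(-jitter, jitter + 1))) \
                if jitter else (0, 0)
            reads.append(SplitRead(
                read_id=f"{t['name']}/{i}",
                side=side,
                chrom_a=str(t["chrom_a"]), pos_a=int(t["pos_a"]) + dj[0],
                strand_a=str(t.get("strand_a", "+")), cigar_a=_cigar(matched),
                chrom_b=str(t["chrom_b"]), pos_b=int(t["pos_b"]) + dj[1],
                strand_b=str(t.get("strand_b", "+")), cigar_b=_cigar(matched),
                mapq=mapq, is_secondary=i >= len(sides) - n_secondary))
    return reads
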