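"""Tumor purity inference from panel SNP allele fractions.

Panel data rarely contain enough genome to run exome-style purity tools, but
germline heterozygous SNPs inside copy-altered target regions are
informative. With P the proportion of the tumor clone, and X total / Y
alternative allele copies at a group of clustered SNPs in the tumor cells
(normal cells contribute one alternative allele of two), the expected
alternative allele frequency is

    AAF = (P*Y + (1 - P)) / (P*X + 2*(1 - P)).

Copy-neutral regions are found first: SNPs with near-balanced minor allele
fractions are selected and the most prominent peak of their coverage
density is taken as the neutral depth (pure 4N-everywhere polyploidy being
vanishingly rare); gains and losses are labeled by coverage relative to
that peak. The equation is then inverted per cluster over a small (X, Y)
hypothesis grid, and purity is the *maximum* of the per-cluster solutions —
the largest clone best represents the purity. Estimates below 30% are
retained internally but flagged unreliable (and not annotated in reports).

Identifiability caveat: distinct (X, Y, P) triples can give identical AAF
*and* coverage (e.g. (4,1) at P vs (3,1) at 2P); the max rule resolves such
ties toward the lower-ploidy, larger-P interpretation. Because germline het
SNPs place the alternative allele on either haplotype, AAFs within a CNV
segment are bimodal around 1/2; clustering therefore pools *folded* AAFs
(max(a, 1-a)), which is equivalent to the full hypothesis grid since
AAF(P, X, Y) = 1 - AAF(P, X, X-Y).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .pileup import PileupSite

__all__ = [
    "SNPCluster", "PurityEstimate", "PurityModel", "PurityResults",
    "EstimationDeclined", "expected_aaf", "solve_purity",
    "find_copy_state_regions", "estimate_purity",
]

# folded (X, Y) hypotheses per copy-state label; the unfolded grid
# {(1,0),(1,1),(2,2),(3,1),(3,2),(4,1),(4,3)} maps onto these by Y <-> X-Y
_HYPOTHESES = {
    "loss": ((1, 1),),
    "neutral": ((2, 2),),
    "gain": ((3, 2), (4, 3)),
}


class EstimationDeclined(RuntimeError):
    """Purity estimation declined (too few SNPs, no coverage peak, ...)."""


def expected_aaf(P: float, X: int, Y: int) -> float:
    """Expected alternative allele frequency of a germline-het SNP cluster."""
    if not (0.0 <= P <= 1.0):
        raise ValueError("P must be in [0, 1]")
    if X < 1 or not (0 <= Y <= X):
        raise ValueError(f"invalid copy state (X={X}, Y={Y})")
    den = P * X + 2.0 * (1.0 - P)
    if den == 0.0:
        raise ZeroDivisionError("degenerate copy state: zero total alleles")
    return (P * Y + (1.0 - P)) / den


def solve_purity(observed_aaf: float, X: int, Y: int) -> float | None:
    """Invert the AAF equation for the clone proportion P.

    Closed form: P = (2A - 1) / (Y - 1 - A*(X - 2)) with A the observed
    AAF, clipped to [0, 1]. Returns None for uninformative configurations
    (zero denominator — e.g. the het-diploid state (2, 1), or (4, 2) by
    symmetry — where any P fits the data).
    """
    if not (0.0 <= observed_aaf <= 1.0):
        raise ValueError("observed_aaf must be in [0, 1]")
    A = observed_aaf
    den = (Y - 1) - A * (X - 2)
    if abs(den) < 1e-9:
        return None
    return float(np.clip((2.0 * A - 1.0) / den, 0.0, 1.0))


@dataclass(frozen=True)
class SNPCluster:
    """Pooled allele evidence for one contiguous copy-state segment.

    ``observed_aaf`` is the depth-weighted mean *folded* AAF of the
    segment's SNPs; ``depth`` the mean SNP coverage; ``copy_state_label``
    one of neutral / gain / loss from the coverage-peak step.
    """

    observed_aaf: float
    depth: float
    copy_state_label: str
    n_snps: int
    segment: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.observed_aaf <= 1.0):
            raise ValueError("observed_aaf must be in [0, 1]")
        if self.copy_state_label not in _HYPOTHESES:
            raise ValueError(f"unknown label {self.copy_state_label!r}")


@dataclass(frozen=True)
class PurityEstimate:
    """Clone-proportion estimate with the 30% reliability floor."""

    P: float
    reliable: bool
    cluster_solutions: tuple[tuple[str, int, int, float], ...] = ()
    # (segment, X, Y, P) per accepted per-cluster solution

    def __post_init__(self) -> None:
        if not (0.0 <= self.P <= 1.0):
            raise ValueError("P must be in [0, 1]")


def find_copy_state_regions(snp_sites: Sequence[PileupSite],
                            min_snps: int = 20,
                            balanced_band: tuple[float, float] = (0.40, 0.60),
                            gain_ratio: float = 1.10,
                            loss_ratio: float = 0.90,
                            peak_prominence: float = 0.10,
                            ) -> list[SNPCluster]:
    """Label contiguous SNP segments neutral / gain / loss by coverage.

    Near-balanced SNPs (AAF inside ``balanced_band``) anchor the neutral
    coverage: their depth density (Gaussian KDE) must show a prominent
    peak, whose location is the copy-neutral depth. Segments (one per
    chromosome label of the input) are then classified by mean coverage
    relative to that peak. Raises :class:`EstimationDeclined` when fewer
    than ``min_snps`` balanced SNPs exist or no prominent peak is found.
    """
    sites = [s for s in snp_sites if s.depth > 0]
    balanced = [s for s in sites
                if balanced_band[0] <= s.vaf <= balanced_band[1]]
    if len(balanced) < min_snps:
        raise EstimationDeclined(
            f"only {len(balanced)} balanced SNPs (< {min_snps}); "
            "cannot anchor the copy-neutral coverage")
    depths = np.array([s.depth for s in balanced], dtype=float)
    spread = depths.std()
    if spread == 0:
        neutral_depth = float(depths[0])
    else:
        kde = gaussian_kde(depths)
        grid = np.linspace(depths.min() - spread, depths.max() + spread, 512)
        dens = kde(grid)
        peaks, props = find_peaks(dens, prominence=peak_prominence * dens.max())
        if peaks.size == 0:
            raise EstimationDeclined("no prominent coverage peak among "
                                     "balanced SNPs")
        neutral_depth = float(grid[peaks[np.argmax(props["prominences"])]])

    clusters: list[SNPCluster] = []
    segments: dict[str, list[PileupSite]] = {}
    for s in sites:
        segments.setdefault(s.chrom, []).append(s)
    for seg, seg_sites in segments.items():
        d = np.array([s.depth for s in seg_sites], dtype=float)
        folded = np.array([max(s.vaf, 1.0 - s.vaf) for s in seg_sites])
        mean_depth = float(d.mean())
        ratio = mean_depth / neutral_depth
        label = ("gain" if ratio > gain_ratio
                 else "loss" if ratio < loss_ratio else "neutral")
        clusters.append(SNPCluster(
            observed_aaf=float(np.average(folded, weights=d)),
            depth=mean_depth, copy_state_label=label,
            n_snps=len(seg_sites), segment=seg))
    return clusters


def estimate_purity(clusters: Sequence[SNPCluster],
                    residual_tol: float = 0.05,
                    reliability_floor: float = 0.30) -> PurityEstimate:
    """Maximum-P estimate over per-cluster closed-form solutions.

    Each cluster is solved under its label's (X, Y) hypotheses; solutions
    whose implied AAF misses the observation by more than ``residual_tol``
    (possible only when the closed form was clipped to [0, 1]) are
    discarded. The maximum surviving P is the purity; ``reliable`` is False
    below the 30% floor.
    """
    if not clusters:
        raise EstimationDeclined("no clusters supplied")
    solutions: list[tuple[str, int, int, float]] = []
    for cl in clusters:
        for X, Y in _HYPOTHESES[cl.copy_state_label]:
            P = solve_purity(cl.observed_aaf, X, Y)
            if P is None or P <= 0.0:
                # P = 0 is the no-tumor-clone solution: AAF 1/2 is equally
                # consistent with a plain germline het, so it is no evidence
                continue
            if abs(expected_aaf(P, X, Y) - cl.observed_aaf) > residual_tol:
                continue
            solutions.append((cl.segment, X, Y, P))
    if not solutions:
        raise EstimationDeclined("no informative cluster solutions")
    best = max(s[3] for s in solutions)
    return PurityEstimate(P=best, reliable=best >= reliability_floor,
                          cluster_solutions=tuple(solutions))


class PurityModel:
    """End-to-end purity estimation from SNP pileups.

    ``fit`` runs copy-state segmentation then the max-P solve and returns a
    :class:`PurityResults`.
    """

    def __init__(self, snp_sites: Sequence[PileupSite], min_snps: int = 20):
        if not snp_sites:
            raise ValueError("snp_sites must be nonempty")
        self.snp_sites = list(snp_sites)
        self.min_snps = min_snps

    def fit(self, residual_tol: float = 0.05) -> "PurityResults":
        clusters = find_copy_state_regions(self.snp_sites,
                                           min_snps=self.min_snps)
        estimate = estimate_purity(clusters, residual_tol=residual_tol)
        return PurityResults(model=self, clusters=clusters, estimate=estimate)


@dataclass
class PurityResults:
    """Clusters, per-cluster solutions and the max-P purity estimate."""

    model: PurityModel
    clusters: list[SNPCluster]
    estimate: PurityEstimate

    @property
    def P(self) -> float:
        return self.estimate.P

    @property
    def reliable(self) -> bool:
        return self.estimate.reliable

    def summary(self) -> str:
        lines = ["Tumor purity estimate", "-" * 40]
        for cl in self.clusters:
            lines.append(
                f"segment {cl.segment:>8s}  {cl.copy_state_label:>7s}  "
                f"AAF {cl.observed_aaf:.3f}  depth {cl.depth:7.1f}  "
                f"n={cl.n_snps}")
        annotated = f"{self.P:.3f}" if self.reliable else "not annotated"
        lines.append(f"purity P = {annotated} "
                     f"(max over {len(self.estimate.cluster_solutions)} "
                     "cluster solutions)")
        if not self.reliable:
            lines.append(f"internal estimate {self.P:.3f} below the 30% "
                         "reliability floor")
        return "\n".join(lines)
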