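"""Candidate SNV detection and the germline / blacklist / artifact filters.

The detection rule here is a declared reference model, not a re-implementation
of any published caller: a site is called when it carries at least
``min_alt_reads`` alternative reads *and* the upper-tail binomial probability
of seeing that many error reads (per-base error rate eps, split over three
alternative bases) is below ``alpha``. Random errors recurring at one
position are vanishingly rare, so a handful of reads at ~1000x (0.3-0.4%
VAF) can already be significant; the filters downstream supply specificity.

Filtering follows routine clinical panel practice without a matched normal:

* very high VAF (>= 97%) calls are presumed germline unless at a hotspot,
* calls with population allele frequency > 3% in a panel of unmatched
  normals are removed (ethnicity-specific germline),
* a curated blacklist removes recurrent alignment artifacts,
* a logistic-regression model over artifact-signature features (indel
  proximity, neighborhood mutation count, strand bias, clustered read
  positions) removes residual false positives; its operating point is
  chosen on the ROC curve by maximal Youden index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .pileup import PileupSite

__all__ = [
    "DetectionModel", "FilterThresholds", "FeatureVector", "VariantCall",
    "ArtifactFilterModel", "ArtifactFilterResults",
    "detect_site", "detect_counts", "compute_fp_features", "train_fp_filter",
    "apply_filters", "classify_tier",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("indel_proximity", "neighborhood_mutation_count",
                 "strand_bias_score", "read_position_clustering")


@dataclass(frozen=True)
class DetectionModel:
    """Reference detection rule for a single pileup site."""

    min_alt_reads: int = 4
    error_rate: float = 0.001  # per-base sequencing error (all three alts)
    alpha: float = 1e-6        # binomial error-test significance
    min_vaf: float | None = None

    def __post_init__(self) -> None:
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.error_rate < 1.0):
            raise ValueError("error_rate must be in (0, 1)")

    def required_alt_reads(self, depth: int) -> int:
        """Smallest alt count at this depth that passes both thresholds."""
        if depth <= 0:
            return depth + 1  # unreachable: no call at zero depth
        p = self.error_rate / 3.0
        # smallest a with P(Binom(depth, p) >= a) < alpha
        a = int(stats.binom.isf(self.alpha, depth, p)) + 1
        while a > 1 and stats.binom.sf(a - 2, depth, p) < self.alpha:
            a -= 1
        while stats.binom.sf(a - 1, depth, p) >= self.alpha:
            a += 1
        return max(a, self.min_alt_reads)


def detect_counts(depths: np.ndarray, alt_counts: np.ndarray,
                  model: DetectionModel) -> np.ndarray:
    """Vectorized detection decision on (depth, alt_count) arrays."""
    depths = np.asarray(depths, dtype=int)
    alts = np.asarray(alt_counts, dtype=int)
    required = {int(d): model.required_alt_reads(int(d))
                for d in np.unique(depths)}
    req = np.array([required[int(d)] for d in depths.ravel()]
                   ).reshape(depths.shape)
    called = (depths > 0) & (alts >= req)
    if model.min_vaf is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.where(depths > 0, alts / np.maximum(depths, 1), 0.0)
        called &= vaf >= model.min_vaf
    return called


@dataclass
class VariantCall:
    """A candidate SNV with its filter flags and tier."""

    site: PileupSite
    vaf: float
    filter_flags: frozenset[str] = frozenset()
    tier: int | None = None
    is_hotspot: bool = False

    @property
    def passes(self) -> bool:
        return not self.filter_flags

    @property
    def key(self) -> tuple[str, int, str, str]:
        s = self.site
        return (s.chrom, s.pos, s.ref_base, s.alt_base)


def detect_site(site: PileupSite, model: DetectionModel) -> VariantCall | None:
    """Apply the reference detection rule; None when no call."""
    if site.depth <= 0:
        return None
    if bool(detect_counts(np.array([site.depth]), np.array([site.alt_count]),
                          model)[0]):
        return VariantCall(site=site, vaf=site.vaf)
    return None


# ---------------------------------------------------------------------------
# artifact-signature features


@dataclass(frozen=True)
class FeatureVector:
    """Artifact-signature features of one candidate site."""

    indel_proximity: float           # 1 if an indel lies within the window
    neighborhood_mutation_count: float
    strand_bias_score: float         # -log10 Fisher exact p, >= 0
    read_position_clustering: float  # 1/(1 + sd of alt read offsets)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def strand_bias_score(ref_fwd: int, ref_rev: int,
                      alt_fwd: int, alt_rev: int) -> float:
    """-log10 of the two-sided Fisher exact p on the 2x2 strand table."""
    _, p = stats.fisher_exact([[ref_fwd, ref_rev], [alt_fwd, alt_rev]],
                              alternative="two-sided")
    return 0.0 if p >= 1.0 else -math.log10(max(p, 1e-300))


def compute_fp_features(site: PileupSite,
                        indel_positions: Sequence[int] = (),
                        candidate_positions: Sequence[int] = (),
                        indel_window: int = 25,
                        neighbor_window: int = 50) -> FeatureVector:
    """Deterministic feature vector for the false-positive filter.

    ``indel_positions`` and ``candidate_positions`` are positions of nearby
    indels and of *other* candidate SNVs on the same chromosome. Window
    sizes (25 bp for indel proximity, 50 bp for the mutation neighborhood)
    are configurable.
    """
    indel = float(any(abs(p - site.pos) <= indel_window
                      for p in indel_positions))
    neighbors = float(sum(1 for p in candidate_positions
                          if p != site.pos and abs(p - site.pos) <= neighbor_window))
    sb = strand_bias_score(site.ref_fwd, site.ref_rev,
                           site.alt_fwd, site.alt_rev)
    offs = np.asarray(site.alt_read_offsets, dtype=float)
    clustering = 1.0 / (1.0 + float(np.std(offs))) if offs.size else 0.0
    return FeatureVector(indel, neighbors, sb, clustering)


# ---------------------------------------------------------------------------
# logistic-regression false-positive filter


class ArtifactFilterModel:
    """Logistic-regression artifact filter over FP-signature features.

    Built from a labeled feature matrix (label 1 = artifact) such as low-VAF
    calls in normal samples at positions with abnormally high transition or
    transversion rates. ``fit`` returns an :class:`ArtifactFilterResults`.
    """

    def __init__(self, features: pd.DataFrame | np.ndarray,
                 labels: Sequence[int]):
        X = np.asarray(features, dtype=float)
        if isinstance(features, pd.DataFrame):
            self.feature_names = tuple(features.columns)
        else:
            self.feature_names = FEATURE_NAMES[:X.shape[1]]
        y = np.asarray(labels, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("features and labels are misaligned")
        if not np.isfinite(X).all():
            raise ValueError("features must be finite")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present to train the filter")
        self.X, self.y = X, y

    def fit(self, seed: int = 0, cv_folds: int = 5) -> "ArtifactFilterResults":
        clf = LogisticRegression(C=np.inf, max_iter=2000)
        regularized = False
        clf.fit(self.X, self.y)
        prob = clf.predict_proba(self.X)[:, 1]
        separated = (roc_auc_score(self.y, prob) == 1.0
                     or np.abs(clf.coef_).max() > 30)
        if separated:  # (quasi-)separation: ridge-stabilize the weights
            clf = LogisticRegression(C=1.0, max_iter=2000)
            clf.fit(self.X, self.y)
            regularized = True
            prob = clf.predict_proba(self.X)[:, 1]
        fpr, tpr, thr = roc_curve(self.y, prob)
        youden = tpr - fpr
        threshold = float(np.clip(thr[int(np.argmax(youden))], 1e-9, 1 - 1e-9))
        folds = min(cv_folds, int(np.bincount(self.y).min()))
        if folds >= 2:
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            cv_auc = float(np.mean(cross_val_score(
                clf, self.X, self.y, cv=cv, scoring="roc_auc")))
        else:
            cv_auc = float("nan")
        return ArtifactFilterResults(
            model=self, clf=clf, threshold=threshold,
            roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
            auc=float(roc_auc_score(self.y, prob)), cv_auc=cv_auc,
            regularized=regularized)


@dataclass
class ArtifactFilterResults:
    """Fitted artifact filter: weights, ROC curve and operating point."""

    model: ArtifactFilterModel
    clf: LogisticRegression
    threshold: float
    roc: pd.DataFrame
    auc: float
    cv_auc: float
    regularized: bool

    @property
    def weights(self) -> pd.Series:
        w = pd.Series(self.clf.coef_[0], index=self.model.feature_names)
        w["intercept"] = float(self.clf.intercept_[0])
        return w

    def predict_proba(self, features: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        return self.clf.predict_proba(X)[:, 1]

    def is_artifact(self, features: np.ndarray | pd.DataFrame) -> np.ndarray:
        return self.predict_proba(features) >= self.threshold

    def summary(self) -> str:
        lines = ["Artifact filter (logistic regression)",
                 "-" * 38]
        for name, w in self.weights.items():
            lines.append(f"{name:>28s}  {w:+.4f}")
        lines.append(f"{'decision threshold':>28s}  {self.threshold:.4f}")
        lines.append(f"{'training AUC':>28s}  {self.auc:.4f}")
        lines.append(f"{'cross-validated AUC':>28s}  {self.cv_auc:.4f}")
        if self.regularized:
            lines.append("note: quasi-separation detected; L2-regularized fit")
        return "\n".join(lines)


def train_fp_filter(features: pd.DataFrame | np.ndarray,
                    labels: Sequence[int],
                    seed: int = 0) -> ArtifactFilterResults:
    """Convenience wrapper: build and fit the artifact filter."""
    return ArtifactFilterModel(features, labels).fit(seed=seed)


# ---------------------------------------------------------------------------
# germline / PoN / blacklist / artifact filtering and tiers


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs of the deterministic filter stack."""

    germline_vaf_cutoff: float = 0.97  # >= removes (non-hotspot)
    pon_af_cutoff: float = 0.03        # >  removes
    lr_score_cutoff: float | None = None  # None: use the fitted ROC threshold

    def __post_init__(self) -> None:
        for name in ("germline_vaf_cutoff", "pon_af_cutoff"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.lr_score_cutoff is not None and not (0.0 < self.lr_score_cutoff < 1.0):
            raise ValueError("lr_score_cutoff must be in (0, 1)")


Key = tuple[str, int, str, str]


def _keyset(positions: Iterable[Sequence]) -> set[Key]:
    out: set[Key] = set()
    for row in positions:
        if isinstance(row, Mapping):
            out.add((str(row["chrom"]), int(row["pos"]),
                     str(row["ref"]), str(row["alt"])))
        else:
            chrom, pos, ref, alt = row[:4]
            out.add((str(chrom), int(pos), str(ref), str(alt)))
    return out


@dataclass
class FilterReport:
    """Flagged calls plus per-filter removal counts."""

    calls: list[VariantCall]
    removed: dict[str, int]

    @property
    def surviving(self) -> list[VariantCall]:
        return [c for c in self.calls if c.passes]


def apply_filters(calls: Sequence[VariantCall],
                  cohort_af: Mapping[Key, float] | None = None,
                  hotspots: Iterable[Sequence] = (),
                  blacklist: Iterable[Sequence] = (),
                  lr_results: ArtifactFilterResults | None = None,
                  features: pd.DataFrame | np.ndarray | None = None,
                  thresholds: FilterThresholds = FilterThresholds(),
                  ) -> FilterReport:
    """Set germline/PoN/blacklist/artifact flags on candidate calls.

    Flags are set independently (so they commute); a call survives iff no
    flag is set. ``cohort_af`` maps (chrom, pos, ref, alt) to the panel-of-
    normals allele frequency; positions absent from the cohort are treated
    as frequency 0. The >= convention applies to the 97% germline-VAF rule
    and the strict > convention to the 3% PoN rule.
    """
    hot = _keyset(hotspots)
    black = _keyset(blacklist)
    cohort_af = cohort_af or {}
    artifact = np.zeros(len(calls), dtype=bool)
    if lr_results is not None:
        if features is None:
            raise ValueError("features are required when an LR filter is given")
        prob = lr_results.predict_proba(features)
        cutoff = (thresholds.lr_score_cutoff
                  if thresholds.lr_score_cutoff is not None
                  else lr_results.threshold)
        artifact = prob >= cutoff
    flagged: list[VariantCall] = []
    removed = {"germline_vaf": 0, "pon": 0, "blacklist": 0, "lr_artifact": 0}
    for i, call in enumerate(calls):
        flags: set[str] = set()
        is_hot = call.key in hot
        if call.vaf >= thresholds.germline_vaf_cutoff and not is_hot:
            flags.add("germline_vaf")
        if cohort_af.get(call.key, 0.0) > thresholds.pon_af_cutoff:
            flags.add("pon")
        if call.key in black:
            flags.add("blacklist")
        if artifact[i]:
            flags.add("lr_artifact")
        for f in flags:
            removed[f] += 1
        flagged.append(replace(call, filter_flags=frozenset(flags),
                               is_hotspot=is_hot))
    return FilterReport(calls=flagged, removed=removed)


def classify_tier(call: VariantCall,
                  tier1_positions: Iterable[Sequence],
                  cosmic_positions: Iterable[Sequence]) -> int:
    """Assign a clinical tier: 1 actionable, 2 known (COSMIC), 3 other."""
    key = call.key
    if key in _keyset(tier1_positions):
        return 1
    if key in _keyset(cosmic_positions):
        return 2
    return 3


def classify_fusion_tier(partner_known: bool) -> int:
    """Fusions: known partner gene -> tier 1, novel partner -> tier 2."""
    return 1 if partner_known else 2
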