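"""Limit-of-detection calibration by in-silico dilution and probit regression.

The limit of detection (LOD) of a sequencing assay is the lowest variant
allele fraction consistently detected with >= 95% sensitivity at a given
depth — the CLSI framing used for conventional molecular tests. It is
estimated here the way a laboratory runs a dilution assay:

1. heterozygous-SNP pileups are diluted in silico to a grid of target VAFs
   and thinned to a grid of depths (:func:`run_dilution_grid`), tallying
   detection outcomes of the reference detection model per (VAF, depth)
   cell;
2. a probit regression of detection on log10(depth) is fitted per VAF
   (:class:`ProbitSensitivityModel`) — probit rather than logit because the
   link is the cumulative normal distribution;
3. the 95%-sensitivity depth is solved in closed form
   (:meth:`ProbitSensitivityResults.depth_for_sensitivity`), and the LOD at
   any depth follows by scanning the calibrated VAFs
   (:func:`lod_at_depth`).

Trials are binned by *realized* post-dilution VAF (+-20% relative width
around each nominal target) because the realized concentration of a diluted
site differs from the intended one — the same concern that motivates in
silico over manual dilution. The covariate is log10(depth) since calibrated
depths span two orders of magnitude.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtri

from .detect import DetectionModel, detect_counts
from .pileup import PileupSite

__all__ = [
    "SensitivityRecord", "ProbitSensitivityModel", "ProbitSensitivityResults",
    "LODResult", "run_dilution_grid", "fit_probit", "depth_for_sensitivity",
    "lod_at_depth", "detection_rate_by_downsampling", "lod_report",
    "records_to_frame", "calibrate_lod_curve",
]


@dataclass(frozen=True)
class SensitivityRecord:
    """Detection tally for one (VAF bin, depth) cell of a dilution grid."""

    vaf_bin: float
    depth_bin: int
    n_trials: int
    n_detected: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_detected <= self.n_trials):
            raise ValueError("n_detected must be in [0, n_trials]")

    @property
    def sensitivity(self) -> float:
        return self.n_detected / self.n_trials if self.n_trials else float("nan")


def records_to_frame(records: Sequence[SensitivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.vaf_bin, r.depth_bin, r.n_trials, r.n_detected, r.sensitivity)
         for r in records],
        columns=["vaf_bin", "depth_bin", "n_trials", "n_detected",
                 "sensitivity"])


def run_dilution_grid(het_sites: Sequence[PileupSite],
                      vafs: Sequence[float],
                      depths: Sequence[int],
                      model: DetectionModel,
                      reps: int = 10,
                      seed: int = 0,
                      bin_rel_width: float = 0.2) -> list[SensitivityRecord]:
    """Dilute, thin and detect over a (VAF, depth) grid.

    For each target VAF, every substrate site is re-diluted ``reps`` times
    (fresh conversion randomness per repetition, mirroring repeated assay
    runs); each diluted site is then thinned without replacement to every
    grid depth not exceeding the site's depth and the detection model is
    applied to the thinned counts. A trial contributes to a cell only when
    its realized post-dilution VAF falls within +-``bin_rel_width``
    (relative) of the nominal target.
    """
    if not het_sites:
        raise ValueError("het_sites must be nonempty")
    if not len(vafs) or not len(depths):
        raise ValueError("VAF and depth grids must be nonempty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    depth0 = np.array([s.depth for s in het_sites], dtype=int)
    alt0 = np.array([s.alt_count for s in het_sites], dtype=int)
    obs0 = alt0 / np.maximum(depth0, 1)
    records: list[SensitivityRecord] = []
    for v in vafs:
        if (v > obs0).any():
            bad = int(np.argmax(v > obs0))
            raise ValueError(
                f"target VAF {v} exceeds substrate VAF {obs0[bad]:.4f} at "
                f"{het_sites[bad].chrom}:{het_sites[bad].pos}")
        lo, hi = v * (1 - bin_rel_width), v * (1 + bin_rel_width)
        trials = np.zeros(len(depths), dtype=int)
        detected = np.zeros(len(depths), dtype=int)
        for _ in range(reps):
            keep_p = np.where(obs0 > 0, v / np.maximum(obs0, 1e-12), 0.0)
            alt_d = rng.binomial(alt0, keep_p)
            realized = alt_d / np.maximum(depth0, 1)
            in_bin = (realized >= lo) & (realized <= hi)
            for j, d in enumerate(depths):
                use = in_bin & (depth0 >= d)
                if not use.any():
                    continue
                thinned = rng.hypergeometric(
                    alt_d[use], depth0[use] - alt_d[use], d)
                hits = detect_counts(np.full(thinned.shape, d), thinned, model)
                trials[j] += int(use.sum())
                detected[j] += int(hits.sum())
        for j, d in enumerate(depths):
            if trials[j] > 0:
                records.append(SensitivityRecord(
                    vaf_bin=float(v), depth_bin=int(d),
                    n_trials=int(trials[j]), n_detected=int(detected[j])))
    return records


# ---------------------------------------------------------------------------
# probit sensitivity model


class ProbitSensitivityModel:
    """Probit regression of detection sensitivity on log10(depth).

    Built from the :class:`SensitivityRecord` cells of a single VAF bin:

        P(detected | depth) = Phi(a + b * log10(depth))

    ``fit`` is by maximum likelihood (binomial GLM, probit link). A fit with
    b <= 0 is rejected downstream: sensitivity must rise with depth. With
    completely separated outcomes (every cell 0% or 100%, split by a depth
    threshold) the likelihood has no finite maximizer; the fit falls back to
    a bias-reduced form (Jeffreys-style augmentation: half a success and
    half a failure added to each cell) and is flagged.
    """

    def __init__(self, records: Sequence[SensitivityRecord]):
        if len({r.vaf_bin for r in records}) > 1:
            raise ValueError("fit one model per VAF bin")
        usable = [r for r in records if r.n_trials > 0]
        depths = sorted({r.depth_bin for r in usable})
        if len(depths) < 2:
            raise ValueError("need >= 2 distinct depth bins")
        self.records = list(usable)
        self.vaf = usable[0].vaf_bin

    @property
    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        d = np.array([r.depth_bin for r in self.records], dtype=float)
        k = np.array([r.n_detected for r in self.records], dtype=float)
        n = np.array([r.n_trials for r in self.records], dtype=float)
        return d, k, n

    def _is_separated(self) -> bool:
        d, k, n = self._arrays
        degenerate = (k == 0) | (k == n)
        if not degenerate.all():
            return False
        order = np.argsort(d)
        steps = (k[order] == n[order]).astype(int)
        return bool(np.all(np.diff(steps) >= 0))  # monotone 0->1 step

    def fit(self) -> "ProbitSensitivityResults":
        d, k, n = self._arrays
        separated = self._is_separated()
        if separated:
            k = k + 0.5
            n = n + 1.0
        exog = sm.add_constant(np.log10(d))
        endog = np.column_stack([k, n - k])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(endog, exog,
                         family=sm.families.Binomial(
                             link=sm.families.links.Probit()))
            res = glm.fit(maxiter=200)
        return ProbitSensitivityResults(model=self, _glm=res,
                                        separation=separated)


@dataclass
class ProbitSensitivityResults:
    """Fitted probit sensitivity curve for one VAF."""

    model: ProbitSensitivityModel
    _glm: "sm.GLMResults"
    separation: bool

    @property
    def intercept(self) -> float:
        return float(self._glm.params[0])

    @property
    def slope(self) -> float:
        """Sensitivity gain per log10-read; > 0 for an accepted fit."""
        return float(self._glm.params[1])

    @property
    def bse(self) -> tuple[float, float]:
        return tuple(float(x) for x in self._glm.bse)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        return np.asarray(self._glm.conf_int(alpha))

    @property
    def deviance(self) -> float:
        return float(self._glm.deviance)

    def sensitivity_at(self, depth: np.ndarray | float) -> np.ndarray | float:
        from scipy.special import ndtr
        eta = self.intercept + self.slope * np.log10(depth)
        return ndtr(eta)

    def depth_for_sensitivity(self, s: float = 0.95) -> float:
        """Depth at which the fitted sensitivity reaches ``s``.

        Inverts the probit line: depth = 10 ** ((Phi^-1(s) - a) / b).
        """
        if not (0.0 < s < 1.0):
            raise ValueError("target sensitivity must be in (0, 1)")
        if self.slope <= 0:
            raise ValueError(
                "probit slope must be positive to solve for a depth "
                f"(got b={self.slope:.4g})")
        return float(10.0 ** ((ndtri(s) - self.intercept) / self.slope))

    def summary(self) -> str:
        a, b = self.intercept, self.slope
        se_a, se_b = self.bse
        lines = [
            f"Probit sensitivity model  (VAF bin {self.model.vaf:.4g})",
            "-" * 48,
            f"intercept a       {a:+.4f}  (se {se_a:.4f})",
            f"slope b / log10 d {b:+.4f}  (se {se_b:.4f})",
            f"deviance          {self.deviance:.3f}",
            f"depth @ 95% sens  {self.depth_for_sensitivity(0.95):.1f}x"
            if b > 0 else "depth @ 95% sens  undefined (b <= 0)",
        ]
        if self.separation:
            lines.append("note: complete separation; bias-reduced fit")
        return "\n".join(lines)


def fit_probit(records: Sequence[SensitivityRecord]) -> ProbitSensitivityResults:
    """Fit the probit sensitivity curve for one VAF bin's records."""
    return ProbitSensitivityModel(records).fit()


def depth_for_sensitivity(results: ProbitSensitivityResults,
                          s: float = 0.95) -> float:
    return results.depth_for_sensitivity(s)


# ---------------------------------------------------------------------------
# LOD queries


@dataclass(frozen=True)
class LODResult:
    """LOD at a queried depth, with extrapolation flagging."""

    depth: float
    lod_vaf: float | None
    extrapolated: bool
    note: str = ""


def lod_at_depth(results_by_vaf: Mapping[float, ProbitSensitivityResults],
                 depth: float,
                 s: float = 0.95) -> LODResult:
    """Smallest calibrated VAF whose ``s``-sensitivity depth is <= depth.

    Queries deeper than every calibrated requirement return the smallest
    calibrated VAF, flagged as a boundary; queries shallower than the
    requirement of the largest calibrated VAF are flagged extrapolations
    with no LOD value.
    """
    if len(results_by_vaf) < 2:
        raise ValueError("need >= 2 calibrated VAF models")
    vafs = sorted(results_by_vaf)
    d95 = {v: results_by_vaf[v].depth_for_sensitivity(s) for v in vafs}
    achievable = [v for v in vafs if d95[v] <= depth]
    if not achievable:
        return LODResult(depth=depth, lod_vaf=None, extrapolated=True,
                         note="depth below the calibrated range")
    lod = min(achievable)
    boundary = depth > max(d95.values()) and lod == vafs[0]
    return LODResult(depth=depth, lod_vaf=lod,
                     extrapolated=boundary,
                     note="depth above all calibrated 95%-depths"
                     if boundary else "")


def detection_rate_by_downsampling(sites: Sequence[PileupSite],
                                   depths: Sequence[int],
                                   model: DetectionModel,
                                   n_iter: int = 10,
                                   seed: int = 0) -> pd.DataFrame:
    """Mean detection rate after downsampling patient sites to each depth.

    Emulates the re-sampling check run on real positive samples: each site
    (assumed detected at full depth) is hypergeometrically thinned
    ``n_iter`` times per target depth and the reference model re-applied.
    Sites shallower than a target depth are skipped (with a warning) at
    that depth. Returns depth, rate, standard error of the mean, and the
    number of contributing sites.
    """
    rng = np.random.default_rng(seed)
    depth0 = np.array([s.depth for s in sites], dtype=int)
    alt0 = np.array([s.alt_count for s in sites], dtype=int)
    rows = []
    for d in depths:
        use = depth0 >= d
        if not use.all():
            warnings.warn(
                f"{int((~use).sum())} site(s) shallower than {d}x skipped",
                stacklevel=2)
        if not use.any():
            continue
        per_site = np.zeros(int(use.sum()))
        for _ in range(n_iter):
            thinned = rng.hypergeometric(alt0[use], depth0[use] - alt0[use], d)
            per_site += detect_counts(np.full(thinned.shape, d), thinned,
                                      model).astype(float)
        per_site /= n_iter
        sem = float(per_site.std(ddof=1) / math.sqrt(per_site.size)) \
            if per_site.size > 1 else 0.0
        rows.append({"depth": int(d), "rate": float(per_site.mean()),
                     "sem": sem, "n_sites": int(use.sum())})
    return pd.DataFrame(rows)


def calibrate_lod_curve(vafs: Sequence[float],
                        depths: Sequence[int] | None = None,
                        model: DetectionModel | None = None,
                        n_sites: int = 222,
                        substrate_depth: float = 1500.0,
                        dedup_fraction: float = 0.8,
                        base_error_rate: float = 0.001,
                        reps: int = 10,
                        seed: int = 0,
                        ) -> tuple[dict[float, ProbitSensitivityResults],
                                   list[SensitivityRecord]]:
    """Full in-silico dilution calibration on a synthetic het-SNP substrate.

    Simulates ``n_sites`` heterozygous SNPs whose deduplicated coverage
    averages ``substrate_depth`` (nominal coverage
    ``substrate_depth / dedup_fraction`` thinned by duplicate removal),
    dilutes them to each target VAF, thins across the depth grid with
    ``reps`` repetitions per cell, and fits one probit sensitivity model
    per VAF. Returns the fitted models keyed by VAF plus the raw records.
    """
    from .simulate import simulate_snp_pileups

    if model is None:
        model = DetectionModel()
    if depths is None:
        depths = np.unique(np.round(np.geomspace(12, substrate_depth,
                                                 13)).astype(int))
    ss = np.random.SeedSequence(seed)
    sim_seed, grid_seed = (int(s) for s in ss.generate_state(2) >> 1)
    sites = simulate_snp_pileups(
        purity=1.0,
        segments=[{"chrom": "chr1", "n_snps": n_sites, "X": 2, "Y": 1}],
        depth_mean=substrate_depth / dedup_fraction,
        base_error_rate=base_error_rate,
        dedup_fraction=dedup_fraction, seed=sim_seed)
    records = run_dilution_grid(sites, vafs, list(depths), model,
                                reps=reps, seed=grid_seed)
    results = {}
    for v in vafs:
        results[float(v)] = fit_probit([r for r in records
                                        if r.vaf_bin == float(v)])
    return results, records


def lod_report(positions: pd.DataFrame,
               results_by_vaf: Mapping[float, ProbitSensitivityResults],
               lod_ceiling: float = 0.5,
               s: float = 0.95) -> pd.DataFrame:
    """Per-position LOD annotation for a panel.

    ``positions`` needs columns chrom, pos, depth. Positions whose LOD
    exceeds ``lod_ceiling`` (or that cannot reach the target sensitivity at
    their depth) are marked ``insufficient power``; zero-depth positions
    are marked ``no power``. Reporting LOD per position — rather than mean
    coverage — makes an uncalled position interpretable: true absence vs
    lack of statistical power.
    """
    required = {"chrom", "pos", "depth"}
    missing = required - set(positions.columns)
    if missing:
        raise ValueError(f"positions table missing columns: {sorted(missing)}")
    rows = []
    for r in positions.itertuples(index=False):
        depth = int(r.depth)
        if depth <= 0:
            rows.append({"chrom": r.chrom, "pos": int(r.pos), "depth": depth,
                         "lod_vaf": np.nan, "status": "no power"})
            continue
        res = lod_at_depth(results_by_vaf, depth, s=s)
        if res.lod_vaf is None or res.lod_vaf > lod_ceiling:
            status = "insufficient power"
        else:
            status = "ok"
        rows.append({"chrom": r.chrom, "pos": int(r.pos), "depth": depth,
                     "lod_vaf": np.nan if res.lod_vaf is None else res.lod_vaf,
                     "status": status})
    return pd.DataFrame(rows)
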