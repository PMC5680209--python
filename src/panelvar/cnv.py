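"""Copy-number calling from exon-level panel depth with purity adjustment.

Per-exon mean depth is first normalized by the sample's overall target
coverage, then standardized by the median normalized depth of a panel of
normal individuals at the same exon (>= 3 normals required); this cancels
exon-to-exon capture-efficiency and GC effects, so a diploid exon has
standardized ratio R ~= 1. Observed ratios are attenuated by normal-cell
admixture: with purity P, R = (P*C + 2(1-P))/2 for tumor copy number C, so
the purity-adjusted amplitude is

    amplitude = log2(C / 2),  C = max(0, (2R - 2(1-P)) / P).

A gene whose median exon amplitude exceeds +1 (log2) is called an
amplification; below -1, a deletion; boundaries are strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CNVCall", "normalize_and_standardize", "purity_adjusted_amplitude",
           "call_cnv"]


@dataclass(frozen=True)
class CNVCall:
    gene: str
    call: str  # amplification / deletion / neutral
    adjusted_amplitude: float
    n_exons: int


def normalize_and_standardize(sample_depths: pd.Series,
                              normal_depths: pd.DataFrame) -> pd.DataFrame:
    """Standardized exon depth ratios R against a normal reference.

    ``sample_depths`` is indexed by (gene, exon); ``normal_depths`` has the
    same index and one column per normal sample. Exons whose reference
    median is zero are masked. Returns a frame with columns raw,
    normalized, ratio, masked.
    """
    if normal_depths.shape[1] < 3:
        raise ValueError("the normal reference needs >= 3 samples")
    if not sample_depths.index.equals(normal_depths.index):
        normal_depths = normal_depths.reindex(sample_depths.index)
        if normal_depths.isna().any().any():
            raise ValueError("normal reference does not cover all exons")
    sample_norm = sample_depths / sample_depths.mean()
    ref_norm = normal_depths.div(normal_depths.mean(axis=0), axis=1)
    ref_median = ref_norm.median(axis=1)
    masked = ref_median <= 0
    ratio = sample_norm / ref_median.where(~masked)
    out = pd.DataFrame({
        "raw": sample_depths,
        "normalized": sample_norm,
        "ratio": ratio,
        "masked": masked,
    })
    return out


def purity_adjusted_amplitude(R: float | np.ndarray,
                              P: float) -> float | np.ndarray:
    """log2 copy-number amplitude implied by ratio R at purity P.

    The implied tumor copy number (2R - 2(1-P))/P is floored at 0; a fully
    deleted region returns -inf. At P = 1 this is the identity log2(R).
    """
    if not (0.0 < P <= 1.0):
        raise ValueError("purity must be in (0, 1]")
    R_arr = np.asarray(R, dtype=float)
    if (R_arr < 0).any():
        raise ValueError("depth ratios must be >= 0")
    C = np.maximum((2.0 * R_arr - 2.0 * (1.0 - P)) / P, 0.0)
    with np.errstate(divide="ignore"):
        amp = np.log2(C / 2.0)
    return amp if isinstance(R, np.ndarray) else float(amp)


def call_cnv(records: pd.DataFrame, purity: float = 1.0,
             amplitude_threshold: float = 1.0) -> list[CNVCall]:
    """Gene-level CNV calls from standardized exon ratios.

    ``records`` is the output of :func:`normalize_and_standardize` (index
    (gene, exon), columns ratio and masked). The gene amplitude is the
    median purity-adjusted exon amplitude over unmasked exons; strict
    inequalities at +-``amplitude_threshold`` decide the call, so an
    amplitude of exactly 1.0 stays neutral.
    """
    usable = records[~records["masked"]]
    if usable.empty:
        raise ValueError("no unmasked exons to call")
    calls: list[CNVCall] = []
    for gene, grp in usable.groupby(level="gene", sort=True):
        amp = purity_adjusted_amplitude(grp["ratio"].to_numpy(), purity)
        gene_amp = float(np.median(amp))
        if gene_amp > amplitude_threshold:
            verdict = "amplification"
        elif gene_amp < -amplitude_threshold:
            verdict = "deletion"
        else:
            verdict = "neutral"
        calls.append(CNVCall(gene=str(gene), call=verdict,
                             adjusted_amplitude=gene_amp,
                             n_exons=len(grp)))
    return calls
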