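"""Readers and writers tying pipeline stages together over plain-text formats.

TSV is the lingua franca between stages so that any stage can be run and
tested in isolation; BED inputs (0-based half-open) are converted to the
1-based inclusive coordinates used internally; calls are exported as VCF
4.2 with FILTER entries GERMLINE_VAF / PON / BLACKLIST / LR_ARTIFACT and
INFO keys VAF and TIER. Every run can echo its configuration and seed to a
JSON manifest for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from importlib import metadata
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import VariantCall
from .pileup import PileupSite

__all__ = [
    "PILEUP_COLUMNS", "write_pileup_tsv", "read_pileup_tsv",
    "read_bed", "bed_interval_to_positions", "read_positions_tsv",
    "write_vcf", "read_vcf_records", "write_manifest", "require_columns",
]

PILEUP_COLUMNS = ["chrom", "pos", "ref_base", "alt_base", "depth",
                  "alt_count", "alt_fwd", "alt_rev", "ref_fwd", "ref_rev",
                  "alt_read_offsets", "true_vaf"]


class TableFormatError(ValueError):
    """A tabular input is missing required structure."""


def require_columns(df: pd.DataFrame, required: Sequence[str],
                    what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{what} is missing required column(s): {', '.join(missing)}")


def write_pileup_tsv(sites: Iterable[PileupSite], path: str | Path) -> None:
    """Write pileup sites as TSV; offsets are comma-joined integers."""
    rows = []
    for s in sites:
        rows.append({
            "chrom": s.chrom, "pos": s.pos, "ref_base": s.ref_base,
            "alt_base": s.alt_base, "depth": s.depth,
            "alt_count": s.alt_count, "alt_fwd": s.alt_fwd,
            "alt_rev": s.alt_rev, "ref_fwd": s.ref_fwd, "ref_rev": s.ref_rev,
            "alt_read_offsets": ",".join(map(str, s.alt_read_offsets)),
            "true_vaf": "" if s.true_vaf is None else f"{s.true_vaf:.6g}",
        })
    pd.DataFrame(rows, columns=PILEUP_COLUMNS).to_csv(path, sep="\t",
                                                      index=False)


def read_pileup_tsv(path: str | Path) -> list[PileupSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     keep_default_na=False)
    require_columns(df, PILEUP_COLUMNS[:-2], f"pileup table {path}")
    sites = []
    for i, r in enumerate(df.itertuples(index=False)):
        try:
            offsets = tuple(
                int(x) for x in str(getattr(r, "alt_read_offsets", "")).split(",")
                if x != "" and x != "nan")
            tv = getattr(r, "true_vaf", "")
            sites.append(PileupSite(
                chrom=str(r.chrom), pos=int(r.pos), ref_base=str(r.ref_base),
                alt_base=str(r.alt_base), depth=int(r.depth),
                alt_count=int(r.alt_count), alt_fwd=int(r.alt_fwd),
                alt_rev=int(r.alt_rev), ref_fwd=int(r.ref_fwd),
                ref_rev=int(r.ref_rev), alt_read_offsets=offsets,
                true_vaf=None if tv in ("", "nan") else float(tv)))
        except (ValueError, TypeError) as exc:
            raise TableFormatError(
                f"{path} line {i + 2}: malformed pileup row ({exc})") from exc
    return sites


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into 1-based inclusive columns.

    Returns a frame with chrom, start (1-based), end (inclusive) and, when
    present, name.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TableFormatError(f"{path} line {ln}: fewer than 3 BED fields")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise TableFormatError(
                    f"{path} line {ln}: non-integer BED coordinates") from exc
            if end0 < start0:
                raise TableFormatError(f"{path} line {ln}: end < start")
            rows.append({"chrom": parts[0], "start": start0 + 1, "end": end0,
                         "name": parts[3] if len(parts) > 3 else ""})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def bed_interval_to_positions(chrom: str, start0: int, end0: int
                              ) -> list[tuple[str, int]]:
    """Expand one BED half-open interval into 1-based positions."""
    return [(chrom, p) for p in range(start0 + 1, end0 + 1)]


def read_positions_tsv(path: str | Path) -> pd.DataFrame:
    """Read a hotspot/blacklist/tier list: chrom, pos, ref, alt (+extras)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    require_columns(df, ["chrom", "pos", "ref", "alt"],
                    f"position list {path}")
    return df


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=panelvar
##FILTER=<ID=GERMLINE_VAF,Description="VAF >= 97% at a non-hotspot position (presumed germline)">
##FILTER=<ID=PON,Description="Population allele frequency > 3% in the panel of normals">
##FILTER=<ID=BLACKLIST,Description="Recurrent artifact position (curated blacklist)">
##FILTER=<ID=LR_ARTIFACT,Description="Logistic-regression artifact score above the ROC-selected threshold">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">
##INFO=<ID=TIER,Number=1,Type=Integer,Description="Clinical tier (1 actionable, 2 known, 3 other)">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Deduplicated depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""

_FLAG_TO_VCF = {"germline_vaf": "GERMLINE_VAF", "pon": "PON",
                "blacklist": "BLACKLIST", "lr_artifact": "LR_ARTIFACT"}


def write_vcf(calls: Iterable[VariantCall], path: str | Path,
              contigs: Sequence[str] = ()) -> None:
    """Write calls as a minimal VCF 4.2 text file."""
    lines = [_VCF_HEADER]
    header, columns = _VCF_HEADER.rsplit("#CHROM", 1)
    lines = [header]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>\n")
    lines.append("#CHROM" + columns)
    for call in sorted(calls, key=lambda c: (c.site.chrom, c.site.pos)):
        s = call.site
        filt = ";".join(sorted(_FLAG_TO_VCF[f] for f in call.filter_flags)) \
            or "PASS"
        info = f"VAF={call.vaf:.6g};DP={s.depth}"
        if call.tier is not None:
            info += f";TIER={call.tier}"
        lines.append(f"{s.chrom}\t{s.pos}\t.\t{s.ref_base}\t{s.alt_base}\t."
                     f"\t{filt}\t{info}\n")
    Path(path).write_text("".join(lines))


def read_vcf_records(path: str | Path) -> pd.DataFrame:
    """Read a VCF back into a frame (chrom, pos, ref, alt, filters, vaf, tier).

    Uses cyvcf2, i.e. an independent parser from the writer above.
    """
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        rows.append({
            "chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF,
            "alt": rec.ALT[0] if rec.ALT else "",
            "filters": rec.FILTER or "PASS",
            "vaf": rec.INFO.get("VAF"),
            "tier": rec.INFO.get("TIER"),
            "dp": rec.INFO.get("DP"),
        })
    return pd.DataFrame(rows)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_manifest(path: str | Path, *, command: str, seed: int | None,
                   config: Mapping | None = None) -> None:
    """Echo command, seed, configuration and package version to JSON."""
    try:
        version = metadata.version("panelvar")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    payload = {"command": command, "seed": seed, "version": version,
               "config": _jsonable(config or {})}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
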