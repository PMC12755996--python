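"""Read, validate and convert polygenic risk model (PGM) weight files.

A PGM is a list of variants, each with an effect allele and a per-allele
weight (beta).  The on-disk dialect is the PGS Catalog scoring-file format:
``#``-prefixed metadata lines (``#pgs_id=...``, ``#genome_build=...``,
``#HmPOS_build=...``) followed by a tab-separated table whose columns include
``effect_allele`` and ``effect_weight`` plus either native coordinates
(``chr_name``/``chr_position``) or harmonized ones (``hm_chr``/``hm_pos``).

Coordinates are 1-based throughout the model; BED output is standard 0-based
half-open.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from ._util import chrom_sort_key, style_chrom
from .exceptions import FormatError

_ALLELE_RE = re.compile(r"^[ACGT]+$")

#: values treated as "absent" in allele / coordinate cells
_NA_TOKENS = {"", ".", "NA", "nan", "None"}


@dataclass(frozen=True)
class WeightEntry:
    """One PGM component variant: coordinate, effect allele and weight."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: Optional[str]
    beta: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.effect_allele:
            raise ValueError("effect_allele must be non-empty")
        if not math.isfinite(self.beta):
            raise ValueError(f"beta must be finite, got {self.beta}")
        if self.other_allele is not None and self.other_allele == self.effect_allele:
            raise ValueError("effect_allele and other_allele must differ")


@dataclass(frozen=True)
class RejectedRow:
    """A data row that could not be turned into a :class:`WeightEntry`."""

    row_number: int  # 1-based index among data rows (header excluded)
    reason: str
    raw: dict


@dataclass
class PGSModel:
    """An ordered collection of weight entries plus file-level metadata."""

    entries: list[WeightEntry]
    pgs_id: str = ""
    genome_build: str = ""
    rejected: list[RejectedRow] = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return len(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass(frozen=True)
class BedInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")


def _clean(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in _NA_TOKENS else s


def _valid_allele(allele: str) -> bool:
    return bool(_ALLELE_RE.match(allele))


def import_pgs_weight_file(path, use_harmonized: bool = True) -> PGSModel:
    """Parse a PGS Catalog–format scoring file into a :class:`PGSModel`.

    Parameters
    ----------
    path
        Scoring file, plain text or gzip-compressed (``.gz``).
    use_harmonized
        Prefer harmonized coordinates (``hm_chr``/``hm_pos``) when those
        columns are present; otherwise fall back to native
        ``chr_name``/``chr_position``.

    Rows lacking a usable coordinate or effect allele, with a non-numeric
    weight, with non-ACGT allele codes (e.g. structured HLA alleles) or
    duplicating an earlier (chrom, pos, effect, other) entry are rejected and
    reported in ``model.rejected``; parsing continues.

    Raises
    ------
    FormatError
        If the file is empty, lacks the required columns, or has no usable
        coordinate column pair.
    """
    path = Path(path)
    metadata: dict[str, str] = {}
    # pandas skips comment lines, so scan the header block separately
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                metadata[key.strip()] = value.strip()

    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty scoring file (no header found)") from None
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty scoring file")

    cols = set(df.columns)
    for required in ("effect_allele", "effect_weight"):
        if required not in cols:
            raise FormatError(f"{path}: missing required column {required!r}")

    have_native = {"chr_name", "chr_position"} <= cols
    have_harmonized = {"hm_chr", "hm_pos"} <= cols
    if not have_native and not have_harmonized:
        raise FormatError(
            f"{path}: no coordinate columns found "
            "(need chr_name/chr_position or hm_chr/hm_pos)"
        )
    prefer_harmonized = use_harmonized and have_harmonized

    id_col = next((c for c in ("rsID", "rsid", "variant_id", "ID") if c in cols), None)

    entries: list[WeightEntry] = []
    rejected: list[RejectedRow] = []
    seen: set[tuple] = set()

    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = dict(zip(df.columns, row))

        def reject(reason: str) -> None:
            rejected.append(RejectedRow(row_number=i, reason=reason, raw=raw))

        if prefer_harmonized:
            chrom = _clean(raw.get("hm_chr"))
            pos_s = _clean(raw.get("hm_pos"))
            if (chrom is None or pos_s is None) and have_native:
                chrom = _clean(raw.get("chr_name"))
                pos_s = _clean(raw.get("chr_position"))
        else:
            chrom = _clean(raw.get("chr_name")) if have_native else None
            pos_s = _clean(raw.get("chr_position")) if have_native else None
            if (chrom is None or pos_s is None) and have_harmonized:
                chrom = _clean(raw.get("hm_chr"))
                pos_s = _clean(raw.get("hm_pos"))

        if chrom is None or pos_s is None:
            reject("missing coordinate")
            continue
        try:
            pos = int(float(pos_s))
        except ValueError:
            reject(f"non-integer position {pos_s!r}")
            continue
        if pos < 1:
            reject(f"position {pos} < 1")
            continue

        effect = _clean(raw.get("effect_allele"))
        if effect is None:
            reject("missing effect allele")
            continue
        effect = effect.upper()
        if not _valid_allele(effect):
            reject(f"effect allele {effect!r} is not an A/C/G/T sequence")
            continue

        other = _clean(raw.get("other_allele"))
        if other is not None:
            other = other.upper()
            if not _valid_allele(other):
                reject(f"other allele {other!r} is not an A/C/G/T sequence")
                continue
            if other == effect:
                reject("other_allele equals effect_allele")
                continue

        weight_s = _clean(raw.get("effect_weight"))
        if weight_s is None:
            reject("missing effect weight")
            continue
        try:
            beta = float(weight_s)
        except ValueError:
            reject(f"non-numeric effect_weight {weight_s!r}")
            continue
        if not math.isfinite(beta):
            reject(f"non-finite effect_weight {weight_s!r}")
            continue

        key = (chrom, pos, effect, other)
        if key in seen:
            reject("duplicate (chrom, pos, effect_allele, other_allele) entry")
            continue
        seen.add(key)

        variant_id = _clean(raw.get(id_col)) if id_col else None
        if variant_id is None:
            variant_id = f"{chrom}:{pos}"
        entries.append(
            WeightEntry(
                variant_id=variant_id,
                chrom=chrom,
                pos=pos,
                effect_allele=effect,
                other_allele=other,
                beta=beta,
            )
        )

    build = metadata.get("HmPOS_build") or metadata.get("genome_build") or ""
    return PGSModel(
        entries=entries,
        pgs_id=metadata.get("pgs_id", ""),
        genome_build=build,
        rejected=rejected,
    )


def convert_pgs_to_bed(
    model: PGSModel, slop: int = 0, chr_style: str = "as-is"
) -> list[BedInterval]:
    """Convert model coordinates to sorted, deduplicated BED intervals.

    A variant at 1-based position ``p`` maps to the half-open interval
    ``(p - 1 - slop, p + slop)``; a negative start is clamped to 0.  Multiple
    model entries at the same coordinate (different alleles) collapse to a
    single interval.  Indels emit the single base at ``pos`` — region filters
    match VCF records by POS, so positional filtering needs nothing wider.
    """
    if slop < 0:
        raise ValueError(f"slop must be non-negative, got {slop}")
    if not model.entries:
        raise ValueError("cannot convert an empty model to BED")

    by_coord: dict[tuple, BedInterval] = {}
    for entry in model.entries:
        chrom = style_chrom(entry.chrom, chr_style)
        start = max(0, entry.pos - 1 - slop)
        end = entry.pos + slop
        key = (chrom, start, end)
        if key not in by_coord:
            by_coord[key] = BedInterval(chrom=chrom, start=start, end=end, name=entry.variant_id)
    return sorted(by_coord.values(), key=lambda b: (chrom_sort_key(b.chrom), b.start, b.end))


def write_bed(intervals: Iterable[BedInterval], path) -> None:
    """Write 4-column BED (chrom, start, end, name), tab-separated, no header."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_bed(path) -> list[BedInterval]:
    """Read a 3+ column BED file (used for VCF region restriction)."""
    intervals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_no}: BED line has fewer than 3 columns")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}-{parts[2]}"
            intervals.append(
                BedInterval(chrom=parts[0], start=int(parts[1]), end=int(parts[2]), name=name)
            )
    return intervals
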