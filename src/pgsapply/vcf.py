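"""Import VCF genotypes into a ploidy-aware per-sample allele-call table.

Only the GT FORMAT field is consumed; dosage-style fields (DS/GP) are out of
scope because scoring is allele-count based.  Ploidy is taken verbatim from
GT — haploid calls stay haploid (hemizygous dosage 0/1), with no
pseudoautosomal-region logic.  The FILTER column is ignored; users pre-filter
with external tools.

Multiallelic sites must arrive as single merged records: two VCF records at
the same (chrom, pos) raise a :class:`~pgsapply.exceptions.FormatError`,
since split representation silently corrupts dosage computation.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pysam

from ._util import normalize_chrom
from .exceptions import FormatError
from .weights import BedInterval, read_bed

_GT_RE = re.compile(r"^(\.|\d+)([/|](\.|\d+))?$")


@dataclass(frozen=True)
class VcfSite:
    """One merged VCF record: coordinate, REF and the ordered ALT alleles."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    site_id: str = "."

    def __post_init__(self) -> None:
        if not self.alts:
            raise ValueError(f"{self.chrom}:{self.pos}: a site needs at least one ALT")
        if self.ref in self.alts:
            raise ValueError(f"{self.chrom}:{self.pos}: REF allele repeated in ALT")

    @property
    def alleles(self) -> tuple[str, ...]:
        """REF followed by ALTs; allele index i of a GT call addresses alleles[i]."""
        return (self.ref,) + self.alts


@dataclass(frozen=True)
class GenotypeCall:
    """Allele indices for one sample at one site; ``None`` marks a missing allele."""

    allele_indices: tuple[Optional[int], ...]
    phased: bool = False

    @property
    def ploidy(self) -> int:
        return len(self.allele_indices)

    @property
    def fully_missing(self) -> bool:
        return all(i is None for i in self.allele_indices)

    def gt_string(self, phased: Optional[bool] = None) -> str:
        sep = "|" if (self.phased if phased is None else phased) else "/"
        return sep.join("." if i is None else str(i) for i in self.allele_indices)


class GenotypeTable:
    """Ordered sites × ordered samples with exactly one call per pair."""

    def __init__(
        self,
        sites: list[VcfSite],
        samples: list[str],
        calls: list[list[GenotypeCall]],
    ) -> None:
        if len(calls) != len(sites):
            raise ValueError("calls must have one row per site")
        for row in calls:
            if len(row) != len(samples):
                raise ValueError("each call row must have one entry per sample")
        self.sites = sites
        self.samples = samples
        self.calls = calls
        self._site_index = {
            (normalize_chrom(s.chrom), s.pos): i for i, s in enumerate(sites)
        }

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def find_site(self, chrom: str, pos: int) -> Optional[int]:
        """Index of the site at (chrom, pos), chr-prefix-insensitive; None if absent."""
        return self._site_index.get((normalize_chrom(chrom), pos))

    def call(self, site_idx: int, sample_idx: int) -> GenotypeCall:
        return self.calls[site_idx][sample_idx]


def parse_gt(gt_string: str, n_alts: int) -> tuple[list[Optional[int]], bool]:
    """Parse a VCF GT string into allele indices plus a phased flag.

    ``"0/1" -> [0, 1]``; ``"1" -> [1]`` (haploid); ``"./." -> [None, None]``;
    ``"0/." -> [0, None]``.  Phasing comes from the ``|`` separator.

    Raises
    ------
    FormatError
        On an empty string, malformed grammar, or an allele index exceeding
        the site's ALT count.
    """
    if not gt_string:
        raise FormatError("empty GT string")
    if not _GT_RE.match(gt_string):
        raise FormatError(f"malformed GT string {gt_string!r}")
    phased = "|" in gt_string
    indices: list[Optional[int]] = []
    for token in re.split(r"[/|]", gt_string):
        if token == ".":
            indices.append(None)
        else:
            idx = int(token)
            if idx > n_alts:
                raise FormatError(
                    f"GT allele index {idx} out of range for a site with {n_alts} ALT allele(s)"
                )
            indices.append(idx)
    return indices, phased


class _RegionFilter:
    """Membership test for BED intervals with half-open 0-based semantics."""

    def __init__(self, intervals: Sequence[BedInterval]) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(normalize_chrom(iv.chrom), []).append((iv.start, iv.end))
        self._starts: dict[str, list[int]] = {}
        self._merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[tuple[int, int]] = []
            for start, end in ivs:
                if merged and start <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], end))
                else:
                    merged.append((start, end))
            self._merged[chrom] = merged
            self._starts[chrom] = [m[0] for m in merged]

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff 1-based pos falls inside some interval (start < pos <= end)."""
        chrom = normalize_chrom(chrom)
        if chrom not in self._merged:
            return False
        i = bisect_right(self._starts[chrom], pos - 1) - 1
        if i < 0:
            return False
        start, end = self._merged[chrom][i]
        return start <= pos - 1 < end


def import_vcf(path, region_bed=None) -> GenotypeTable:
    """Load a VCF (plain or bgzipped) into a :class:`GenotypeTable`.

    Parameters
    ----------
    path
        VCF 4.x file with a GT FORMAT field.
    region_bed
        Optional BED path; only records whose POS falls inside an interval
        (half-open, 0-based) are retained.

    Raises
    ------
    FormatError
        On duplicate (chrom, pos) records (split multiallelics must be merged
        first, e.g. with ``bcftools norm -m+``), or when GT is absent.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"VCF not found: {path}")
    region = _RegionFilter(read_bed(region_bed)) if region_bed is not None else None

    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read VCF {path}: {exc}") from exc

    if "GT" not in vf.header.formats:
        raise FormatError(f"{path}: no GT FORMAT field defined in the header")

    samples = list(vf.header.samples)
    sites: list[VcfSite] = []
    calls: list[list[GenotypeCall]] = []
    seen: set[tuple[str, int]] = set()

    for rec in vf:
        if region is not None and not region.contains(rec.chrom, rec.pos):
            continue
        key = (normalize_chrom(rec.chrom), rec.pos)
        if key in seen:
            raise FormatError(
                f"{path}: duplicate records at {rec.chrom}:{rec.pos}; multiallelic sites "
                "must be merged into single records (e.g. `bcftools norm -m+`)"
            )
        seen.add(key)
        alts = tuple(a for a in (rec.alts or ()) if a is not None)
        if not alts:
            continue  # monomorphic record carries no dosage information
        site = VcfSite(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alts=alts,
            site_id=rec.id or ".",
        )
        row: list[GenotypeCall] = []
        for sample in samples:
            sample_rec = rec.samples[sample]
            gt = sample_rec.get("GT")
            if gt is None or len(gt) == 0:
                gt = (None,)
            for idx in gt:
                if idx is not None and idx > len(alts):
                    raise FormatError(
                        f"{path}: {rec.chrom}:{rec.pos} sample {sample}: GT allele index "
                        f"{idx} out of range for {len(alts)} ALT allele(s)"
                    )
            row.append(GenotypeCall(allele_indices=tuple(gt), phased=bool(sample_rec.phased)))
        sites.append(site)
        calls.append(row)

    vf.close()
    return GenotypeTable(sites=sites, samples=samples, calls=calls)
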