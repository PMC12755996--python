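"""Small shared helpers: chromosome-name normalization and ordering."""

from __future__ import annotations


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr``/``CHR`` prefix.

    Model/VCF chromosome matching is prefix-insensitive: mixed ``chr1`` vs
    ``1`` conventions are the dominant real-world join failure and the
    normalization is lossless for matching purposes.
    """
    if chrom[:3].lower() == "chr":
        return chrom[3:]
    return chrom


def style_chrom(chrom: str, chr_style: str) -> str:
    """Apply a chromosome naming style: ``with-prefix``, ``without-prefix`` or ``as-is``."""
    if chr_style == "as-is":
        return chrom
    bare = normalize_chrom(chrom)
    if chr_style == "with-prefix":
        return "chr" + bare
    if chr_style == "without-prefix":
        return bare
    raise ValueError(f"unknown chr_style: {chr_style!r}")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome order: 1..22 numerically, then X, Y, MT, then others."""
    bare = normalize_chrom(chrom)
    if bare.isdigit():
        return (0, int(bare), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if bare.upper() in special:
        return (1, special[bare.upper()], "")
    return (2, 0, bare)
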