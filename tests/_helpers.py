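"""Shared test utilities: tiny hand-built VCF/weight fixtures and oracles."""

from __future__ import annotations

import textwrap
from pathlib import Path

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=1>
    ##contig=<ID=2>
    ##contig=<ID=X>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    """
)


def write_vcf(path: Path, records: list[str], samples: list[str]) -> Path:
    """Write a minimal VCF; each record is a pre-formatted tab-joined line."""
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_HEADER + cols + "\n" + "".join(r + "\n" for r in records))
    return path


def vcf_record(chrom, pos, ref, alt, gts, vid=".") -> str:
    return f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)


def write_weights(
    path: Path,
    rows: list[dict],
    metadata: dict | None = None,
    columns: tuple = (
        "rsID",
        "chr_name",
        "chr_position",
        "effect_allele",
        "other_allele",
        "effect_weight",
    ),
) -> Path:
    """Write a PGS Catalog–dialect scoring file from row dicts."""
    lines = []
    for key, value in (metadata or {"pgs_id": "PGSTEST", "genome_build": "GRCh38"}).items():
        lines.append(f"#{key}={value}")
    lines.append("\t".join(columns))
    for row in rows:
        lines.append("\t".join(str(row.get(c, "")) for c in columns))
    path.write_text("\n".join(lines) + "\n")
    return path


def naive_pgs(merged, genotypes) -> list[float]:
    """Independent nested-loop sum(beta * dosage), missing contributing 0."""
    scoreable = [m for m in merged if m.effect_allele_index is not None and not m.removed]
    out = []
    for i in range(genotypes.n_samples):
        total = 0.0
        for mv in scoreable:
            call = genotypes.calls[mv.site_idx][i]
            observed = [a for a in call.allele_indices if a is not None]
            if not observed:
                continue
            dosage = sum(1 for a in observed if a == mv.effect_allele_index)
            total += mv.weight.beta * dosage
        out.append(total)
    return out


def rank_auc_oracle(scores, labels) -> float:
    """AUC as the Mann–Whitney U statistic over all case/control pairs."""
    cases = [s for s, l in zip(scores, labels) if l == 1]
    controls = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                wins += 1.0
            elif c == d:
                wins += 0.5
    return wins / (len(cases) * len(controls))


def swap_ref_alt_vcf(src: Path, dst: Path) -> Path:
    """Rewrite a biallelic-or-multiallelic VCF swapping REF with the first ALT
    and remapping GT indices 0<->1 consistently (label invariance fixture)."""
    out_lines = []
    for line in src.read_text().splitlines():
        if line.startswith("#"):
            out_lines.append(line)
            continue
        fields = line.split("\t")
        ref, alts = fields[3], fields[4].split(",")
        fields[3], alts[0] = alts[0], ref
        fields[4] = ",".join(alts)
        new_gts = []
        for gt in fields[9:]:
            sep = "|" if "|" in gt else "/"
            toks = gt.split(sep)
            mapped = []
            for t in toks:
                if t == "0":
                    mapped.append("1")
                elif t == "1":
                    mapped.append("0")
                else:
                    mapped.append(t)
            new_gts.append(sep.join(mapped))
        out_lines.append("\t".join(fields[:9] + new_gts))
    dst.write_text("\n".join(out_lines) + "\n")
    return dst
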