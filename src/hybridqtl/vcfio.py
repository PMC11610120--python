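"""Plain-text VCF 4.2 emission for synthetic founder and pool call sets.

Reading always goes through pysam; these writers exist so the synthetic
generator can emit Freebayes-style records (GT:DP:RO:AO) with exact control
over monomorphic reference lines, which real callers rarely emit but which
the marker derivation needs to see founder depth at non-variant sites.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .markers import ContigMap

_HEADER_LINES = [
    '##fileformat=VCFv4.2',
    '##INFO=<ID=TYPE,Number=A,Type=String,Description="Allele type">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference allele observation count">',
    '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">',
]


def _header(contig_map: ContigMap, sample: str) -> list[str]:
    lines = list(_HEADER_LINES)
    for row in contig_map.df.itertuples():
        lines.append(f"##contig=<ID={row.contig},length={int(row.length)}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    return lines


def write_founder_vcf(
    path: str | Path,
    founder: str,
    records: Iterable[tuple[str, int, str, str | None, int]],
    contig_map: ContigMap,
) -> None:
    """Write one founder's haploid calls.

    ``records`` are (contig, pos, ref, alt_or_None, depth); ``alt=None``
    emits a monomorphic reference line (ALT=".", GT=0).
    """
    lines = _header(contig_map, founder)
    for contig, pos, ref, alt, depth in records:
        if alt is None:
            lines.append(
                f"{contig}\t{pos}\t.\t{ref}\t.\t.\t.\t.\t"
                f"GT:DP:RO:AO\t0:{depth}:{depth}:."
            )
        else:
            lines.append(
                f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t.\tTYPE=snp\t"
                f"GT:DP:RO:AO\t1:{depth}:0:{depth}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_pool_vcf(
    path: str | Path,
    pool_name: str,
    counts: pd.DataFrame,
    contig_map: ContigMap,
) -> None:
    """Write pooled read counts (columns contig, pos, ref, alt, ro, ao)."""
    lines = _header(contig_map, pool_name)
    for row in counts.itertuples():
        dp = int(row.ro) + int(row.ao)
        lines.append(
            f"{row.contig}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
            f"TYPE=snp\tGT:DP:RO:AO\t.:{dp}:{int(row.ro)}:{int(row.ao)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
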