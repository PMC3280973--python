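"""File-format helpers: FASTA, BED, VCF and TSV emission.

FASTA goes through Biopython; BED and the cohort/Ct TSVs are plain
tab-separated tables written with pandas.  Deletions are emitted as VCF
4.2 symbolic ``<DEL>`` records (1-based POS, INFO END/SVLEN plus the
junction insertion and microhomology) by a minimal text emitter.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_bed",
    "write_tsv",
    "write_deletions_vcf",
]


def write_fasta(records: Iterable[Tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_bed(bed: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in bed.columns]
    bed[cols].to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##ALT=<ID=DEL,Description="Deletion">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Difference in length between REF and ALT alleles">
##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Non-templated nucleotides at the junction">
##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Length of microhomology at the junction">
##contig=<ID={contig},length={length}>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_deletions_vcf(
    deletions: Sequence[dict],
    contig: str,
    contig_length: int,
    reference_sequence: str,
    path: str | Path,
) -> None:
    """Write symbolic DEL records.

    Each deletion dict needs 0-based half-open ``start``/``end`` plus
    optional ``id``, ``inserted_nt`` and ``microhomology_len``.  POS is
    emitted 1-based on the base before the deleted segment, as the VCF
    convention for symbolic alleles requires.
    """
    lines = [_VCF_HEADER.format(contig=contig, length=contig_length)]
    for i, d in enumerate(sorted(deletions, key=lambda x: (x["start"], x["end"]))):
        start, end = int(d["start"]), int(d["end"])
        if not 0 < start < end <= contig_length:
            raise ValueError(f"deletion interval ({start}, {end}) outside contig")
        ref_base = reference_sequence[start - 1]
        info = [
            "SVTYPE=DEL",
            f"END={end}",
            f"SVLEN={-(end - start)}",
        ]
        if d.get("inserted_nt"):
            info.append(f"INSSEQ={d['inserted_nt']}")
        if d.get("microhomology_len"):
            info.append(f"HOMLEN={int(d['microhomology_len'])}")
        lines.append(
            "\t".join(
                [
                    contig,
                    str(start),  # 1-based position of the base before the event
                    str(d.get("id", f"del{i + 1}")),
                    ref_base,
                    "<DEL>",
                    ".",
                    "PASS",
                    ";".join(info),
                ]
            )
            + "\n"
        )
    Path(path).write_text("".join(lines))
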