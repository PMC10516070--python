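"""Readers and writers for the standard formats the pipeline speaks.

FASTA via Biopython, GFF3 reading via gffutils, VCF via pysam, BED and
cohort tables via pandas. All on-disk interval formats follow their native
conventions (BED 0-based half-open, GFF3/VCF 1-based); the in-memory
representation is 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .regions import CisElement, NearCodingRegion, TranscriptModel
from .tracks import FunctionalTrackElement

logger = logging.getLogger(__name__)

SCORE_COLUMNS = {
    "CADD_PHRED": "cadd_phred",
    "PHYLOP": "phylop",
    "SPLICEAI_MAX": "spliceai_max",
    "CLNSIG": "clinvar_status",
    "AF_INT": "af_internal",
    "AC_INT": "ac_internal",
    "AF_GNOMAD_POPMAX": "af_gnomad_popmax",
}


def write_fasta(genome: dict[str, str | bytearray], path: str | Path) -> None:
    records = []
    for chrom, seq in genome.items():
        if isinstance(seq, (bytes, bytearray)):
            seq = bytes(seq).decode()
        records.append(SeqRecord(Seq(seq), id=chrom, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in transcripts:
            s, e = tx.span
            gene_id = f"gene:{tx.gene_symbol}"
            tx_id = f"transcript:{tx.transcript_id}"
            attrs = f"ID={gene_id};gene_name={tx.gene_symbol}"
            fh.write(
                f"{tx.chrom}\tnearcoding\tgene\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{tx.chrom}\tnearcoding\tmRNA\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                f"ID={tx_id};Parent={gene_id};transcript_id={tx.transcript_id};"
                f"gene_name={tx.gene_symbol}\n"
            )
            for i, (xs, xe) in enumerate(tx.exons, 1):
                fh.write(
                    f"{tx.chrom}\tnearcoding\texon\t{xs + 1}\t{xe}\t.\t{tx.strand}\t.\t"
                    f"ID={tx_id}.exon{i};Parent={tx_id}\n"
                )
            for cs, ce in tx.cds_intervals():
                fh.write(
                    f"{tx.chrom}\tnearcoding\tCDS\t{cs + 1}\t{ce}\t.\t{tx.strand}\t0\t"
                    f"ID={tx_id}.cds;Parent={tx_id}\n"
                )


def read_gff3(path: str | Path) -> list[TranscriptModel]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
        tx_id = mrna.attributes.get("transcript_id", [mrna.id])[0]
        gene = mrna.attributes.get("gene_name", [""])[0]
        out.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_symbol=gene,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_start=min(s for s, _ in cds) if cds else None,
                cds_end=max(e for _, e in cds) if cds else None,
            )
        )
    out.sort(key=lambda t: (t.chrom, t.span[0], t.transcript_id))
    return out


def write_regions_bed(regions: list[NearCodingRegion], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "name": [f"{r.transcript_id}|{r.region_class}" for r in regions],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path: str | Path) -> list[NearCodingRegion]:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
    )
    out = []
    for rec in df.itertuples():
        tx_id, rclass = rec.name.split("|")
        out.append(NearCodingRegion(rec.chrom, rec.start, rec.end, rclass, tx_id))
    return out


def write_ccre_bed(ccres: list[CisElement], path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": [c.chrom for c in ccres],
            "start": [c.start for c in ccres],
            "end": [c.end for c in ccres],
            "name": [c.label for c in ccres],
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def read_ccre_bed(path: str | Path) -> list[CisElement]:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
    )
    return [
        CisElement(rec.chrom, rec.start, rec.end, rec.name) for rec in df.itertuples()
    ]


def write_track_bed(
    elements: list[FunctionalTrackElement], path: str | Path
) -> None:
    """BED with the track in column 4 and attributes as key=value in col 5."""
    rows = []
    for el in elements:
        attrs = ";".join(f"{k}={_fmt_attr(v)}" for k, v in sorted(el.attributes.items()))
        rows.append((el.chrom, el.start, el.end, el.track, attrs or "."))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_track_bed(path: str | Path) -> list[FunctionalTrackElement]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "track", "attrs"],
    )
    out = []
    for rec in df.itertuples():
        attrs = {}
        if isinstance(rec.attrs, str) and rec.attrs != ".":
            for item in rec.attrs.split(";"):
                k, v = item.split("=", 1)
                attrs[k] = _parse_attr(v)
        out.append(
            FunctionalTrackElement(rec.chrom, rec.start, rec.end, rec.track, attrs)
        )
    return out


def _fmt_attr(v) -> str:
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, (tuple, list)):
        return ",".join(str(x) for x in v)
    return str(v)


def _parse_attr(v: str):
    if "," in v:
        return tuple(int(x) if x.isdigit() else float(x) for x in v.split(","))
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            continue
    return v


def write_vcf(
    variants: pd.DataFrame, contig_lengths: dict[str, int], path: str | Path
) -> None:
    """Write a variant table (0-based ``pos``) as an uncompressed VCF.

    Score columns are emitted as the INFO keys in :data:`SCORE_COLUMNS`.
    """
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.info.add("CADD_PHRED", 1, "Float", "CADD PHRED score")
    header.info.add("PHYLOP", 1, "Float", "PhyloP conservation score")
    header.info.add("SPLICEAI_MAX", 1, "Float", "Max splice-disruption delta")
    header.info.add("CLNSIG", 1, "String", "ClinVar clinical significance")
    header.info.add("AF_INT", 1, "Float", "Internal cohort allele frequency")
    header.info.add("AC_INT", 1, "Integer", "Internal cohort allele count")
    header.info.add("AF_GNOMAD_POPMAX", 1, "Float", "gnomAD popmax allele frequency")
    inv = {v: k for k, v in SCORE_COLUMNS.items()}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for rec in variants.to_dict("records"):
            r = vf.new_record(
                contig=rec["chrom"],
                start=int(rec["pos"]),
                alleles=(rec["ref"], rec["alt"]),
                id=str(rec.get("variant_id")) or None,
            )
            for col, key in inv.items():
                val = rec.get(col)
                if val is None or (isinstance(val, float) and pd.isna(val)):
                    continue
                if col == "clinvar_status":
                    if val:
                        r.info[key] = str(val).replace(" ", "_")
                elif col == "ac_internal":
                    r.info[key] = int(val)
                else:
                    r.info[key] = float(val)
            vf.write(r)


def read_vcf(path: str | Path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            row = {
                "variant_id": rec.id or f"{rec.contig}:{rec.start}",
                "chrom": rec.contig,
                "pos": rec.start,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else "",
            }
            for key, col in SCORE_COLUMNS.items():
                if key in rec.info:
                    val = rec.info[key]
                    row[col] = val if not isinstance(val, tuple) else val[0]
            rows.append(row)
    return pd.DataFrame(rows)
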