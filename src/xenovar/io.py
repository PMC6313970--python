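"""File interchange: FASTA/FASTQ/SAM/BED/VCF/TSV writers and readers.

Simulated samples can be fully materialized as the standard files a real
dual-alignment workflow would start from (references as FASTA, reads as
FASTQ, one SAM per genome), and every downstream product (partition lists,
candidate/final VCFs, truth tables, run metadata) has a plain-text form, so
any stage can be re-run and audited from disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .clonal import ClonalModel
from .filters import VariantCall
from .genome import BASES, GenomePair, codes_to_seq
from .pileup import CandidateVariant
from .reads import CIG_D, CIG_I, CIG_M, MAPQ_UNMAPPED, ReadSet

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genome_pair(genomes: GenomePair, human_path, mouse_path) -> None:
    write_fasta(human_path, {genomes.contig_name_human: genomes.human_seq})
    write_fasta(mouse_path, {genomes.contig_name_mouse: genomes.mouse_seq})


def write_fastq(readset: ReadSet, path) -> None:
    """Reads in sequencing orientation (reverse-strand reads complemented)."""
    qual = chr(readset.base_quality + 33)
    with open(path, "w") as fh:
        for i in range(readset.n_reads):
            seq = codes_to_seq(readset.read_sequence(i))
            if readset.strand[i]:
                seq = seq.translate(_COMPLEMENT)[::-1]
            fh.write(f"@{readset.read_id(i)}\n{seq}\n+\n{qual * len(seq)}\n")


def _cigar_string(cigar) -> str:
    ops = "MID"
    return "".join(f"{length}{ops[op]}" for op, length in cigar)


def write_sam(readset: ReadSet, path, genomes: GenomePair, genome: str = "human") -> None:
    """One sample's alignments against one of the two references.

    Reads unmapped against that genome are emitted with the unmapped flag;
    mapped records are coordinate-sorted. All reads are primary records.
    """
    if genome == "human":
        contig, mapqs = genomes.contig_name_human, readset.mapq_human
    elif genome == "mouse":
        contig, mapqs = genomes.contig_name_mouse, readset.mapq_mouse
    else:
        raise ValueError("genome must be 'human' or 'mouse'")
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": contig, "LN": len(genomes)}]}
    )
    order = np.argsort(readset.starts, kind="stable")
    qual_str = chr(readset.base_quality + 33)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        unmapped = []
        for i in map(int, order):
            rec = pysam.AlignedSegment(header)
            rec.query_name = readset.read_id(i)
            seq = codes_to_seq(readset.read_sequence(i))
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array(qual_str * len(seq))
            if mapqs[i] == MAPQ_UNMAPPED:
                rec.is_unmapped = True
                unmapped.append(rec)
                continue
            rec.reference_id = 0
            rec.reference_start = int(readset.starts[i])
            rec.mapping_quality = int(mapqs[i])
            rec.is_reverse = bool(readset.strand[i])
            if readset.is_complex[i]:
                rec.cigartuples = list(readset.complex_reads[i].cigar)
            else:
                rec.cigartuples = [(CIG_M, readset.read_length)]
            out.write(rec)
        for rec in unmapped:
            out.write(rec)


def read_mapq_table(path) -> dict[str, int | None]:
    """{read_id: MAPQ or None} from primary records of a SAM/BAM file."""
    out: dict[str, int | None] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mapq = None if rec.is_unmapped else int(rec.mapping_quality)
            if rec.query_name in out and out[rec.query_name] != mapq:
                raise ValueError(f"conflicting records for read {rec.query_name!r}")
            out[rec.query_name] = mapq
    return out


def write_bed(regions, path) -> None:
    """0-based half-open intervals, optionally named."""
    with open(path, "w") as fh:
        for region in regions:
            fh.write("\t".join(str(x) for x in region[:4]) + "\n")


def read_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            row = (parts[0], int(parts[1]), int(parts[2]))
            out.append(row + ((parts[3],) if len(parts) > 3 else ()))
    return out


def write_partition_tsv(partition, path) -> None:
    rows = [
        {"read_id": rid, "dataset": "strict" if rid in partition.strict_ids else "relaxed_only"}
        for rid in sorted(partition.relaxed_ids)
    ]
    pd.DataFrame(rows, columns=["read_id", "dataset"]).to_csv(path, sep="\t", index=False)


_VCF_INFO = [
    ("DP", 1, "Integer", "Total read depth"),
    ("FDP", 1, "Integer", "Filtered (flow-equivalent) depth"),
    ("FAO", 1, "Integer", "Alternate allele observations"),
    ("RO", 1, "Integer", "Reference allele observations"),
    ("SAF", 1, "Integer", "Alternate observations on the forward strand"),
    ("SAR", 1, "Integer", "Alternate observations on the reverse strand"),
    ("STB", 1, "Float", "Strand bias (majority-strand share of alt reads)"),
    ("HRUN", 1, "Integer", "Reference homopolymer run length"),
    ("GQ", 1, "Float", "Genotype quality (Phred gap of genotype likelihoods)"),
    ("MQR", 1, "Float", "Mean mapping quality of reference reads"),
    ("MQA", 1, "Float", "Mean mapping quality of alternate reads"),
    ("RLR", 1, "Float", "Mean read length of reference reads"),
    ("RLA", 1, "Float", "Mean read length of alternate reads"),
    ("MMQSR", 1, "Float", "Mean mismatch quality sum of reference reads"),
    ("MMQSA", 1, "Float", "Mean mismatch quality sum of alternate reads"),
    ("VTYPE", 1, "String", "SNP or indel"),
    ("PROV", 1, "String", "Dataset provenance: strict, relaxed or both"),
    ("GENE", ".", "String", "Overlapping gene(s)"),
    ("DRIVER", 0, "Flag", "Variant in a driver gene"),
]


def _vcf_header(contig: str, length: int) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add(contig, length=length)
    for name, number, vtype, desc in _VCF_INFO:
        header.info.add(name, number, vtype, desc)
    return header


def write_vcf(calls, path, contig: str, contig_length: int) -> None:
    """Candidate or final calls as a 1-based VCF with the full metric set."""
    header = _vcf_header(contig, contig_length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: _cand(c).pos):
            cand = _cand(call)
            rec = out.new_record(
                contig=contig, start=cand.pos - 1, alleles=(cand.ref, cand.alt),
                qual=round(cand.QUAL, 2),
            )
            info = rec.info
            info["DP"], info["FDP"], info["FAO"], info["RO"] = cand.DP, cand.FDP, cand.FAO, cand.RO
            info["SAF"], info["SAR"] = cand.alt_fwd, cand.alt_rev
            info["STB"], info["HRUN"], info["GQ"] = round(cand.STB, 4), cand.HRUN, round(cand.GQ, 2)
            for tag, value in (
                ("MQR", cand.mapq_ref_mean), ("MQA", cand.mapq_alt_mean),
                ("RLR", cand.readlen_ref_mean), ("RLA", cand.readlen_alt_mean),
                ("MMQSR", cand.mmqs_ref_mean), ("MMQSA", cand.mmqs_alt_mean),
            ):
                if value is not None:
                    info[tag] = round(float(value), 2)
            info["VTYPE"] = cand.vtype
            if isinstance(call, VariantCall):
                if call.provenance:
                    info["PROV"] = call.provenance
                if call.genes:
                    info["GENE"] = list(call.genes)
                if call.is_driver:
                    info["DRIVER"] = True
            out.write(rec)


def _cand(call) -> CandidateVariant:
    return call.candidate if isinstance(call, VariantCall) else call


def read_vcf_candidates(path) -> list:
    """Round-trip a VCF written by :func:`write_vcf` back into candidates."""
    out = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            info = rec.info
            out.append(
                CandidateVariant(
                    contig=rec.contig, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                    vtype=info["VTYPE"], DP=info["DP"], FDP=info["FDP"], FAO=info["FAO"],
                    RO=info["RO"], alt_fwd=info["SAF"], alt_rev=info["SAR"],
                    STB=float(info["STB"]), HRUN=info["HRUN"],
                    QUAL=float(rec.qual), GQ=float(info["GQ"]),
                    mapq_ref_mean=float(info["MQR"]) if "MQR" in info else None,
                    mapq_alt_mean=float(info["MQA"]) if "MQA" in info else None,
                    readlen_ref_mean=float(info["RLR"]) if "RLR" in info else None,
                    readlen_alt_mean=float(info["RLA"]) if "RLA" in info else None,
                    mmqs_ref_mean=float(info["MMQSR"]) if "MMQSR" in info else None,
                    mmqs_alt_mean=float(info["MMQSA"]) if "MMQSA" in info else None,
                )
            )
    return out


def write_truth_vcf(model: ClonalModel, path, contig: str, contig_length: int) -> None:
    header = pysam.VariantHeader()
    header.contigs.add(contig, length=contig_length)
    header.info.add("STAGEAF", ".", "String", "Expected allele fraction per stage")
    header.info.add("GERMLINE", 0, "Flag", "Planted germline variant")
    header.info.add("CLONES", ".", "String", "Carrying clones")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(model.variants, key=lambda v: v.pos0):
            rec = out.new_record(contig=contig, start=v.pos0, alleles=(v.ref, v.alt))
            rec.info["STAGEAF"] = [
                f"{stage}:{model.expected_af(v.variant_id, stage):.4f}" for stage in model.stages()
            ]
            if v.germline:
                rec.info["GERMLINE"] = True
            else:
                rec.info["CLONES"] = [model.clones[i].clone_id for i in model.carriers(v.variant_id)]
            out.write(rec)


def write_read_origins(truth, readset: ReadSet, path) -> None:
    from .clonal import ORIGIN_NAMES

    with open(path, "w") as fh:
        fh.write("read_id\torigin\n")
        for i in range(readset.n_reads):
            fh.write(f"{readset.read_id(i)}\t{ORIGIN_NAMES[truth.read_origins[i]]}\n")


def read_pop_af_tsv(path) -> dict:
    """{(contig, pos, ref, alt): max population AF} from a 5-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
    return {
        (row.contig, int(row.pos), row.ref, row.alt): float(row.af)
        for row in df.itertuples()
    }


def write_pop_af_tsv(table: dict, path) -> None:
    rows = [
        {"contig": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "af": v}
        for k, v in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "af"]).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def write_pairs_tsv(pairing, path) -> None:
    pd.DataFrame(pairing, columns=["primary", "xenograft"]).to_csv(path, sep="\t", index=False)


def write_run_metadata(path, **fields) -> None:
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
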