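"""Readers and writers for the toolkit's file formats.

Two variant-table dialects are supported:

``vcf_min``
    A minimal VCF v4.2 subset handled through :mod:`pysam`, with INFO keys
    ``DP`` (total depth), ``AO`` or ``AD`` (alt-supporting reads), ``LOC``
    (location class), ``EFF`` (effect class) and ``GENE``.

``tsv``
    A tab-separated table with header ``chr start end ref alt location gene
    fraction depth validated appearance`` mirroring a printed variant table
    that reports allelic fraction and depth but not raw alt-read counts;
    alt reads are derived as ``round(fraction * depth)``.

The genotype/phenotype panel is a TSV with a first header row of mouse ids,
a second header row of phenotypes (``Aff``/``Unaff``), then one row per
variant. Peptides are plain FASTA via Biopython.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Sequence, Tuple

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    EffectClass,
    GenotypeCall,
    Laterality,
    LocationClass,
    PanelMouse,
    Phenotype,
    SegregationPanel,
    VariantCall,
)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_TSV_HEADER = [
    "chr", "start", "end", "ref", "alt", "location", "gene",
    "fraction", "depth", "validated", "appearance",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _parse_location(text: str, line_no: int) -> LocationClass:
    try:
        return LocationClass(text)
    except ValueError:
        raise ParseError(
            f"line {line_no}: unknown location class {text!r}"
        ) from None


def _parse_effect(text: str, line_no: int) -> EffectClass:
    try:
        return EffectClass(text)
    except ValueError:
        raise ParseError(f"line {line_no}: unknown effect class {text!r}") from None


def _parse_bool(text: str, line_no: int) -> bool:
    t = text.strip().lower()
    if t in {"yes", "true", "1"}:
        return True
    if t in {"no", "false", "0"}:
        return False
    raise ParseError(f"line {line_no}: expected Yes/No, got {text!r}")


# ---------------------------------------------------------------------------
# variant tables


def read_variant_table(path: os.PathLike | str, dialect: str = "tsv") -> List[VariantCall]:
    """Read a variant table under the named dialect.

    Positions are preserved 1-based. The allelic fraction is recomputed from
    alt_reads/depth when both are present, otherwise taken from the printed
    fraction column.
    """
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf_min":
        return _read_vcf_min(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path) -> List[VariantCall]:
    calls: List[VariantCall] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip() for h in header] != _TSV_HEADER:
            raise ParseError(f"line 1: bad header {header!r}")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_TSV_HEADER):
                raise ParseError(
                    f"line {line_no}: expected {len(_TSV_HEADER)} fields, got {len(fields)}"
                )
            try:
                chrom, start, end, ref, alt, loc, gene, frac, depth, val, app = fields
                fraction = float(frac)
                depth_i = int(depth)
                location = _parse_location(loc, line_no)
                call = VariantCall(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    ref=ref,
                    alt=alt,
                    depth=depth_i,
                    alt_reads=int(round(fraction * depth_i)),
                    fraction=fraction,
                    location_class=location,
                    effect_class=(
                        EffectClass.NONSYNONYMOUS
                        if location is LocationClass.EXONIC
                        else EffectClass.UNKNOWN
                    ),
                    gene=gene,
                    validated_by_sanger=_parse_bool(val, line_no),
                    present_in_backcross_affected=_parse_bool(app, line_no),
                )
            except ParseError:
                raise
            except (ValueError, TypeError) as exc:
                raise ParseError(f"line {line_no}: {exc}") from None
            calls.append(call)
    return calls


def write_variant_table(calls: Iterable[VariantCall], path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        _write_tsv(calls, path)
    elif dialect == "vcf_min":
        _write_vcf_min(calls, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_tsv(calls, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for v in calls:
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.start),
                        str(v.end),
                        v.ref,
                        v.alt,
                        v.location_class.value,
                        v.gene,
                        repr(v.fraction),
                        str(v.depth),
                        "Yes" if v.validated_by_sanger else "No",
                        "Yes" if v.present_in_backcross_affected else "No",
                    ]
                )
                + "\n"
            )


def _vcf_header(calls: Sequence[VariantCall]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">')
    header.add_line('##INFO=<ID=AO,Number=1,Type=Integer,Description="Alt-supporting reads">')
    header.add_line('##INFO=<ID=LOC,Number=1,Type=String,Description="Location class">')
    header.add_line('##INFO=<ID=EFF,Number=1,Type=String,Description="Effect class">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    seen = []
    for v in calls:
        if v.chrom not in seen:
            seen.append(v.chrom)
    for chrom in seen:
        header.contigs.add(chrom)
    return header


def _write_vcf_min(calls, path) -> None:
    calls = list(calls)
    header = _vcf_header(calls)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in calls:
            rec = out.new_record(
                contig=v.chrom,
                start=v.start - 1,
                stop=v.end,
                alleles=(v.ref, v.alt),
            )
            rec.info["DP"] = v.depth
            rec.info["AO"] = v.alt_reads
            rec.info["LOC"] = v.location_class.value
            rec.info["EFF"] = v.effect_class.value
            if v.gene:
                rec.info["GENE"] = v.gene
            out.write(rec)


def _read_vcf_min(path) -> List[VariantCall]:
    calls: List[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            depth = int(info["DP"])
            if "AO" in info:
                ao = info["AO"]
                alt_reads = int(ao[0] if isinstance(ao, tuple) else ao)
            elif "AD" in info:
                ad = info["AD"]
                alt_reads = int(ad[-1] if isinstance(ad, tuple) else ad)
            else:
                raise ParseError(
                    f"record {rec.chrom}:{rec.pos}: neither AO nor AD present"
                )
            loc = _parse_location(str(info.get("LOC", "intergenic")), rec.pos)
            eff = _parse_effect(str(info.get("EFF", "unknown")), rec.pos)
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    start=rec.pos,
                    end=rec.stop,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else "",
                    depth=depth,
                    alt_reads=alt_reads,
                    fraction=alt_reads / depth if depth else 0.0,
                    location_class=loc,
                    effect_class=eff,
                    gene=str(info.get("GENE", "") or ""),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# genotype/phenotype panel


def _parse_phenotype(text: str, line_no: int) -> Phenotype:
    t = text.strip().lower().rstrip(".")
    if t in {"aff", "affected"}:
        return Phenotype.AFFECTED
    if t in {"unaff", "unaffected"}:
        return Phenotype.UNAFFECTED
    raise ParseError(f"line {line_no}: unknown phenotype label {text!r}")


def read_panel(path) -> SegregationPanel:
    """Read a genotype/phenotype panel TSV.

    Both the Unicode minus (U+2212) and the ASCII hyphen-minus denote a
    non-carrier; ``?`` is an untyped (missing) cell.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise ParseError("panel needs two header rows and at least one variant row")
    mouse_ids = lines[0].split("\t")[1:]
    phen_fields = lines[1].split("\t")
    phenos = phen_fields[1:]
    if len(phenos) != len(mouse_ids):
        raise ParseError(
            f"line 2: {len(phenos)} phenotypes for {len(mouse_ids)} mice"
        )
    mice = [
        PanelMouse(mouse_id=mid, phenotype=_parse_phenotype(ph, 2))
        for mid, ph in zip(mouse_ids, phenos)
    ]
    variants: List[str] = []
    calls = {}
    for line_no, line in enumerate(lines[2:], start=3):
        fields = line.split("\t")
        if len(fields) != len(mouse_ids) + 1:
            raise ParseError(
                f"line {line_no}: expected {len(mouse_ids) + 1} fields, got {len(fields)}"
            )
        vid = fields[0]
        try:
            row = [GenotypeCall.parse(c) for c in fields[1:]]
        except ValueError as exc:
            raise ParseError(f"line {line_no}: {exc}") from None
        variants.append(vid)
        calls[vid] = row
    return SegregationPanel(mice=mice, variants=variants, calls=calls)


def write_panel(panel: SegregationPanel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variant\t" + "\t".join(m.mouse_id for m in panel.mice) + "\n")
        fh.write(
            "phenotype\t"
            + "\t".join(
                "Aff" if m.phenotype is Phenotype.AFFECTED else "Unaff"
                for m in panel.mice
            )
            + "\n"
        )
        for vid in panel.variants:
            fh.write(vid + "\t" + "\t".join(c.value for c in panel.calls[vid]) + "\n")


def read_traits(path) -> dict:
    """Read a two-column TSV ``mouse_id <tab> 0|1`` of binary trait scores."""
    scores = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(f"line {line_no}: expected 2 fields")
            scores[fields[0]] = _parse_bool(fields[1], line_no)
    return scores


# ---------------------------------------------------------------------------
# peptides


def read_peptides(path) -> List[Tuple[str, str]]:
    """Read FASTA peptides as ordered ``(id, sequence)`` pairs.

    Sequences must be non-empty and drawn from the 20-letter amino-acid
    alphabet (uppercased on read).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"record {rec.id!r}: empty sequence")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ParseError(
                f"record {rec.id!r}: non-amino-acid characters {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_peptides(records: Iterable[Tuple[str, str]], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records],
        str(path),
        "fasta",
    )
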