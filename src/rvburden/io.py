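"""Readers and writers for the external formats the pipeline touches.

Conventions
-----------
* VCF, the annotation sidecar, GWAS tables and genotype tables are 1-based
  at the file boundary; BED is 0-based half-open. Everything is converted
  to the internal 0-based half-open convention on read.
* The annotation sidecar is an ANNOVAR-multianno-shaped TSV keyed by
  (chrom, pos, ref, alt); any column beyond the fixed annotation columns
  is interpreted as an allele-frequency reference dataset.
* Missing values are written as "." and preserved as *absent* on read —
  never silently imputed to 0.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

from .types import (
    EffectRaw,
    GeneSet,
    GenomicInterval,
    Group,
    GwasSnp,
    PREDICTOR_KEYS,
    RankedGeneList,
    Subject,
    VariantAnnotation,
    VariantCall,
    Zygosity,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

MISSING = "."

# sidecar column -> internal predictor key
SIDECAR_SCORE_COLUMNS = {
    "phylop_pm": "phylop_placental",
    "phylop_100v": "phylop_100vert",
    "sift": "sift",
    "polyphen2": "polyphen2",
    "mutation_assessor": "mutation_assessor",
    "cadd_phred": "cadd_phred",
    "mutation_taster": "mutation_taster",
}

SIDECAR_FIXED_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "effect"] + list(
    SIDECAR_SCORE_COLUMNS
)

EFFECT_SYNONYMS = {
    "stop_gain": EffectRaw.STOP_GAIN,
    "stopgain": EffectRaw.STOP_GAIN,
    "nonsense": EffectRaw.STOP_GAIN,
    "frameshift": EffectRaw.FRAMESHIFT,
    "core_splice": EffectRaw.CORE_SPLICE,
    "splice": EffectRaw.CORE_SPLICE,
    "missense": EffectRaw.MISSENSE,
    "other": EffectRaw.OTHER,
    "synonymous": EffectRaw.OTHER,
}


class RecordError(ValueError):
    """A malformed record, reported with its source location."""


def _parse_float(token: str) -> Optional[float]:
    token = token.strip()
    if token in ("", MISSING, "NA", "nan"):
        return None
    return float(token)


# ---------------------------------------------------------------------------
# Variant calls: multi-sample VCF + annotation sidecar TSV
# ---------------------------------------------------------------------------

def read_annotation_sidecar(
    path: PathLike,
) -> dict[tuple[str, int, str, str], VariantAnnotation]:
    """Read the per-site annotation TSV keyed by (chrom, 0-based pos, ref, alt)."""
    annotations: dict[tuple[str, int, str, str], VariantAnnotation] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fields = reader.fieldnames or []
        missing_cols = [c for c in SIDECAR_FIXED_COLUMNS if c not in fields]
        if missing_cols:
            raise RecordError(f"{path}: sidecar missing columns {missing_cols}")
        freq_columns = [c for c in fields if c not in SIDECAR_FIXED_COLUMNS]
        for lineno, row in enumerate(reader, start=2):
            try:
                pos0 = int(row["pos"]) - 1
                effect_token = row["effect"].strip().lower()
                if effect_token not in EFFECT_SYNONYMS:
                    raise ValueError(f"unknown effect class {row['effect']!r}")
                scores = {}
                for col, key in SIDECAR_SCORE_COLUMNS.items():
                    value = _parse_float(row[col])
                    if value is not None:
                        scores[key] = value
                freqs = {}
                for col in freq_columns:
                    value = _parse_float(row[col])
                    if value is not None:
                        freqs[col] = value
                annotation = VariantAnnotation(
                    gene=row["gene"].strip(),
                    effect_raw=EFFECT_SYNONYMS[effect_token],
                    scores=scores,
                    allele_freqs=freqs,
                )
            except (ValueError, KeyError) as exc:
                raise RecordError(f"{path}:{lineno}: {exc}") from exc
            key = (normalize_chrom(row["chrom"]), pos0, row["ref"].strip(), row["alt"].strip())
            annotations[key] = annotation
    return annotations


def _zygosity_from_gt(gt: tuple) -> Optional[Zygosity]:
    """Map a pysam GT tuple to a zygosity, or None if the site is reference/missing."""
    alleles = [a for a in gt if a is not None]
    if not alleles or all(a == 0 for a in alleles):
        return None
    if any(a > 1 for a in alleles):
        raise ValueError(f"multi-allelic genotype {gt}; split records upstream")
    if len(alleles) == 1:
        return Zygosity.HEMIZYGOUS
    if all(a == 1 for a in alleles):
        return Zygosity.HOMOZYGOUS
    return Zygosity.HETEROZYGOUS


def read_variant_calls(
    vcf_path: PathLike,
    annotation_path: PathLike,
) -> list[tuple[VariantCall, VariantAnnotation]]:
    """Read subject-level variant calls with their site annotations.

    Returns one (call, annotation) pair per subject carrying a non-reference
    genotype, sorted by (chrom, pos, ref, alt, subject). A variant present in
    the VCF but absent from the sidecar is an error naming the variant.
    """
    annotations = read_annotation_sidecar(annotation_path)
    records: list[tuple[VariantCall, VariantAnnotation]] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for i, rec in enumerate(vcf.fetch(), start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise RecordError(
                    f"{vcf_path}: record {i} ({rec.chrom}:{rec.pos}) must have exactly one ALT"
                )
            alt = rec.alts[0]
            quality_pass = (len(rec.filter) == 0) or ("PASS" in rec.filter)
            interval = GenomicInterval(rec.chrom, rec.pos - 1, rec.pos - 1 + len(rec.ref))
            key = (normalize_chrom(rec.chrom), rec.pos - 1, rec.ref, alt)
            if key not in annotations:
                raise RecordError(
                    f"{vcf_path}: record {i}: no sidecar annotation for "
                    f"{rec.chrom}:{rec.pos} {rec.ref}>{alt}"
                )
            annotation = annotations[key]
            for sample_name, sample in rec.samples.items():
                try:
                    zyg = _zygosity_from_gt(sample.get("GT", ()))
                except ValueError as exc:
                    raise RecordError(f"{vcf_path}: record {i}, sample {sample_name}: {exc}")
                if zyg is None:
                    continue
                call = VariantCall(
                    interval=interval,
                    ref=rec.ref,
                    alt=alt,
                    subject_id=sample_name,
                    zygosity=zyg,
                    quality_pass=quality_pass,
                )
                records.append((call, annotation))
    records.sort(key=lambda ca: (*ca[0].site_key, ca[0].subject_id))
    return records


def write_variant_calls(
    vcf_path: PathLike,
    annotation_path: PathLike,
    records: Sequence[tuple[VariantCall, VariantAnnotation]],
    subject_ids: Optional[Sequence[str]] = None,
    freq_datasets: Optional[Sequence[str]] = None,
) -> None:
    """Write records as a multi-sample VCFv4.2 plus the annotation sidecar.

    ``subject_ids`` fixes the sample column order (default: sorted subjects
    seen in the records). Round-trips through :func:`read_variant_calls`.
    """
    if subject_ids is None:
        subject_ids = sorted({c.subject_id for c, _ in records})
    # site -> (annotation, quality, per-subject zygosity)
    sites: dict[tuple, dict] = {}
    for call, annotation in records:
        chrom = call.interval.chrom
        key = (normalize_chrom(chrom), call.interval.start, call.ref, call.alt)
        entry = sites.setdefault(
            key,
            {"chrom": chrom, "annotation": annotation, "quality": call.quality_pass, "gts": {}},
        )
        entry["gts"][call.subject_id] = call.zygosity
    if freq_datasets is None:
        freq_datasets = sorted({d for _, a in records for d in a.allele_freqs})

    ordered = sorted(sites.items())
    contigs = []
    for (chrom_norm, *_), entry in ordered:
        if entry["chrom"] not in contigs:
            contigs.append(entry["chrom"])

    gt_string = {
        Zygosity.HETEROZYGOUS: "0/1",
        Zygosity.HOMOZYGOUS: "1/1",
        Zygosity.HEMIZYGOUS: "1",
    }
    with open(vcf_path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for chrom in contigs:
            out.write(f"##contig=<ID={chrom}>\n")
        out.write('##FILTER=<ID=FAIL,Description="Failed upstream quality criteria">\n')
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(subject_ids)
            + "\n"
        )
        for (chrom_norm, pos0, ref, alt), entry in ordered:
            filt = "PASS" if entry["quality"] else "FAIL"
            gts = [
                gt_string[entry["gts"][s]] if s in entry["gts"] else "0/0"
                for s in subject_ids
            ]
            fields = [entry["chrom"], str(pos0 + 1), ".", ref, alt, ".", filt, ".", "GT", *gts]
            out.write("\t".join(fields) + "\n")

    def fmt(value: Optional[float]) -> str:
        return MISSING if value is None else repr(float(value))

    with open(annotation_path, "w") as out:
        header = SIDECAR_FIXED_COLUMNS + list(freq_datasets)
        out.write("\t".join(header) + "\n")
        for (chrom_norm, pos0, ref, alt), entry in ordered:
            a: VariantAnnotation = entry["annotation"]
            row = [entry["chrom"], str(pos0 + 1), ref, alt, a.gene, a.effect_raw.value]
            for col, key in SIDECAR_SCORE_COLUMNS.items():
                row.append(fmt(a.scores.get(key)))
            for ds in freq_datasets:
                row.append(fmt(a.allele_freqs.get(ds)))
            out.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT) and ranked lists
# ---------------------------------------------------------------------------

def read_gene_sets(path: PathLike) -> list[GeneSet]:
    """Read GMT: name <tab> description <tab> symbol...; duplicates collapse with a warning."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RecordError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = fields[0].strip()
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if not genes:
                raise RecordError(f"{path}:{lineno}: gene-set {name!r} is empty")
            if len(set(genes)) != len(genes):
                logger.warning(
                    "gene-set %s: collapsed %d duplicate symbols",
                    name,
                    len(genes) - len(set(genes)),
                )
            sets.append(GeneSet(name=name, genes=frozenset(genes)))
    return sets


def write_gene_sets(path: PathLike, sets: Iterable[GeneSet], description: str = "") -> None:
    with open(path, "w") as out:
        for gs in sets:
            out.write("\t".join([gs.name, description, *sorted(gs.genes)]) + "\n")


def read_ranked_list(path: PathLike) -> RankedGeneList:
    """Read a ranked gene list TSV: columns (gene, rank), or an ordered single column."""
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise RecordError(f"{path}: empty ranked list")
    start = 0
    first = lines[0].split("\t")
    if first[0].strip().lower() == "gene":  # header row
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = line.split("\t")
        gene = fields[0].strip()
        if len(fields) >= 2:
            try:
                rank = int(fields[1])
            except ValueError as exc:
                raise RecordError(f"{path}:{lineno}: bad rank {fields[1]!r}") from exc
        else:
            rank = len(entries) + 1
        entries.append((gene, rank))
    try:
        return RankedGeneList(entries=tuple(entries))
    except ValueError as exc:
        raise RecordError(f"{path}: {exc}") from exc


def write_ranked_list(path: PathLike, ranked: RankedGeneList) -> None:
    with open(path, "w") as out:
        out.write("gene\trank\n")
        for gene, rank in ranked.entries:
            out.write(f"{gene}\t{rank}\n")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

_BOOL_TOKENS = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}

SAMPLE_SHEET_FIXED = ["subject_id", "group", "deletion_chrom", "deletion_start", "deletion_end"]


def read_sample_sheet(path: PathLike) -> list[Subject]:
    """Sample sheet TSV: subject_id, group, deletion interval (0-based BED-style
    start/end), plus one boolean column per phenotype flag."""
    subjects = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fields = reader.fieldnames or []
        missing = [c for c in SAMPLE_SHEET_FIXED if c not in fields]
        if missing:
            raise RecordError(f"{path}: sample sheet missing columns {missing}")
        flag_columns = [c for c in fields if c not in SAMPLE_SHEET_FIXED]
        seen = set()
        for lineno, row in enumerate(reader, start=2):
            sid = row["subject_id"].strip()
            if sid in seen:
                raise RecordError(f"{path}:{lineno}: duplicate subject_id {sid!r}")
            seen.add(sid)
            try:
                group = Group(row["group"].strip().lower())
                deletion = GenomicInterval(
                    row["deletion_chrom"].strip(),
                    int(row["deletion_start"]),
                    int(row["deletion_end"]),
                )
                flags = {}
                for col in flag_columns:
                    token = row[col].strip().lower()
                    if token not in _BOOL_TOKENS:
                        raise ValueError(f"flag {col}={row[col]!r} is not boolean")
                    flags[col] = _BOOL_TOKENS[token]
            except ValueError as exc:
                raise RecordError(f"{path}:{lineno}: {exc}") from exc
            subjects.append(
                Subject(subject_id=sid, group=group, phenotype_flags=flags, deletion=deletion)
            )
    return subjects


def write_sample_sheet(path: PathLike, subjects: Sequence[Subject]) -> None:
    flag_columns = sorted({f for s in subjects for f in s.phenotype_flags})
    with open(path, "w") as out:
        out.write("\t".join(SAMPLE_SHEET_FIXED + flag_columns) + "\n")
        for s in subjects:
            d = s.deletion
            row = [
                s.subject_id,
                s.group.value,
                d.chrom if d else MISSING,
                str(d.start) if d else MISSING,
                str(d.end) if d else MISSING,
            ]
            row += [str(s.phenotype_flags.get(f, False)).lower() for f in flag_columns]
            out.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# GWAS summary statistics, genotype table, GO table, BED
# ---------------------------------------------------------------------------

def read_gwas_table(path: PathLike) -> list[GwasSnp]:
    """GWAS TSV: snp_id, chrom, pos (1-based), effect_allele, [other_allele,]
    odds_ratio, p_value."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"snp_id", "chrom", "pos", "effect_allele", "odds_ratio", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise RecordError(f"{path}: GWAS table missing columns {sorted(missing)}")
    snps = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        other = getattr(row, "other_allele", None)
        if other is not None and (not isinstance(other, str) or other == MISSING):
            other = None
        try:
            snps.append(
                GwasSnp(
                    snp_id=str(row.snp_id),
                    interval=GenomicInterval(str(row.chrom), int(row.pos) - 1, int(row.pos)),
                    effect_allele=str(row.effect_allele),
                    odds_ratio=float(row.odds_ratio),
                    p_value=float(row.p_value),
                    other_allele=other,
                )
            )
        except ValueError as exc:
            raise RecordError(f"{path}:{i}: {exc}") from exc
    return snps


def write_gwas_table(path: PathLike, snps: Sequence[GwasSnp]) -> None:
    with open(path, "w") as out:
        out.write("snp_id\tchrom\tpos\teffect_allele\tother_allele\todds_ratio\tp_value\n")
        for s in snps:
            out.write(
                "\t".join(
                    [
                        s.snp_id,
                        s.interval.chrom,
                        str(s.interval.start + 1),
                        s.effect_allele,
                        s.other_allele or MISSING,
                        repr(s.odds_ratio),
                        repr(s.p_value),
                    ]
                )
                + "\n"
            )


GenotypeTable = dict[str, dict[tuple[str, int], tuple[str, str]]]


def read_genotype_table(path: PathLike) -> GenotypeTable:
    """Genotype TSV: subject_id, chrom, pos (1-based), allele1, allele2.

    Returns subject -> {(chrom, 0-based pos): (allele1, allele2)}; haploid
    (hemizygous) sites repeat the single allele in both slots is NOT assumed —
    allele2 may be "." and is then stored equal to allele1.
    """
    table: GenotypeTable = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                key = (normalize_chrom(row["chrom"]), int(row["pos"]) - 1)
                a1 = row["allele1"].strip()
                a2 = row["allele2"].strip()
                if a2 == MISSING:
                    a2 = a1
            except (KeyError, ValueError) as exc:
                raise RecordError(f"{path}:{lineno}: {exc}") from exc
            table.setdefault(row["subject_id"].strip(), {})[key] = (a1, a2)
    return table


def write_genotype_table(path: PathLike, table: GenotypeTable) -> None:
    with open(path, "w") as out:
        out.write("subject_id\tchrom\tpos\tallele1\tallele2\n")
        for sid in sorted(table):
            for (chrom, pos0), (a1, a2) in sorted(table[sid].items()):
                out.write(f"{sid}\t{chrom}\t{pos0 + 1}\t{a1}\t{a2}\n")


def read_gene_go_table(path: PathLike) -> dict[str, set[tuple[str, int]]]:
    """Gene->GO TSV: gene, term_id, term_size. Term sizes are taken as given."""
    mapping: dict[str, set[tuple[str, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                size = int(row["term_size"])
                if size <= 0:
                    raise ValueError(f"term size must be positive, got {size}")
            except (KeyError, ValueError) as exc:
                raise RecordError(f"{path}:{lineno}: {exc}") from exc
            mapping.setdefault(row["gene"].strip(), set()).add((row["term_id"].strip(), size))
    return mapping


def write_gene_go_table(path: PathLike, mapping: Mapping[str, set[tuple[str, int]]]) -> None:
    with open(path, "w") as out:
        out.write("gene\tterm_id\tterm_size\n")
        for gene in sorted(mapping):
            for term, size in sorted(mapping[gene]):
                out.write(f"{gene}\t{term}\t{size}\n")


def read_bed(path: PathLike) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            try:
                intervals.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except (IndexError, ValueError) as exc:
                raise RecordError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(path: PathLike, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as out:
        for iv in intervals:
            out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
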