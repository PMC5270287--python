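"""Readers and writers for the standard formats the pipeline touches.

Annotated variants travel as VCF 4.x with per-record INFO annotations
(gene, effect, impact, scores, allele frequencies); pedigrees as 6-column
PED; linkage loci as BED-like tab-separated text (coordinates in bp or Mb,
declared explicitly); case-control genotype counts as CSV.

VCF access goes through pysam/htslib.  htslib stores INFO floats in single
precision, so on read every numeric annotation is normalized to the shortest
decimal that round-trips through float32 — "0.272" comes back as 0.272, not
0.27200001478195190.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .exceptions import ConfigError, ParseError, VocabularyError
from .variants import (
    CHROMOSOMES,
    AnnotatedVariant,
    Effect,
    Genotype,
    GenotypeMatrix,
    Impact,
    LinkageLocus,
    PedMember,
    Pedigree,
    normalize_chrom,
)

__all__ = [
    "DEFAULT_ANNOTATION_KEYS",
    "read_annotated_vcf",
    "write_annotated_vcf",
    "read_pedigree",
    "write_pedigree",
    "read_loci",
    "read_counts_csv",
    "write_counts_csv",
]

#: Default mapping from AnnotatedVariant field -> VCF INFO key.
DEFAULT_ANNOTATION_KEYS: dict[str, str] = {
    "gene": "GENE",
    "effect": "EFFECT",
    "impact": "IMPACT",
    "aa_change": "AA_CHANGE",
    "sift": "SIFT",
    "polyphen2_hdiv": "PP2_HDIV",
    "phylop": "PHYLOP",
    "phastcons": "PHASTCONS",
    "af_global": "AF_GLOBAL",
    "af_east_asian": "AF_EAS",
    "af_korean": "AF_KOR",
}

_STRING_FIELDS = ("gene", "effect", "impact", "aa_change")
_FLOAT_FIELDS = (
    "sift",
    "polyphen2_hdiv",
    "phylop",
    "phastcons",
    "af_global",
    "af_east_asian",
    "af_korean",
)


def _shortest_float32(value: float) -> float:
    """Shortest decimal representation that round-trips through float32."""
    return float(np.format_float_positional(np.float32(value), unique=True))


def _info_scalar(value):
    # htslib returns Number=1 INFO values as scalars, but be tolerant of
    # 1-tuples from Number=A annotations on already-split records.
    if isinstance(value, tuple):
        value = value[0]
    return value


def read_annotated_vcf(
    path: str | Path,
    annotation_keys: Mapping[str, str] | None = None,
) -> tuple[list[AnnotatedVariant], GenotypeMatrix]:
    """Read an annotated VCF into variants plus a genotype matrix.

    Multi-allelic records are split into one :class:`AnnotatedVariant` per
    ALT allele; the per-ALT genotype is HOM_ALT / HET / HOM_REF by the count
    of that ALT allele in the sample's diploid call, MISSING if either allele
    is uncalled.  Absent annotations stay missing (``None``), never 0.

    Parameters
    ----------
    path:
        VCF file (plain text or bgzipped).
    annotation_keys:
        Field-name -> INFO-key mapping; defaults to
        :data:`DEFAULT_ANNOTATION_KEYS`.  Keys for gene/effect/impact must be
        declared in the header or a :class:`ConfigError` is raised.
    """
    keys = dict(DEFAULT_ANNOTATION_KEYS)
    if annotation_keys:
        keys.update(annotation_keys)
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: malformed VCF: {exc}") from exc

    header_infos = set(vf.header.info.keys())
    required = {keys[f] for f in ("gene", "effect", "impact")}
    missing_keys = sorted(required - header_infos)
    if missing_keys:
        raise ConfigError(
            f"{path}: annotation key(s) {missing_keys} absent from VCF header"
        )

    samples = list(vf.header.samples)
    variants: list[AnnotatedVariant] = []
    rows: list[list[int]] = []
    try:
        records = list(vf)
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: malformed VCF record: {exc}") from exc
    finally:
        vf.close()

    for rec in records:
        info = rec.info
        fields: dict[str, object] = {}
        for fname in _STRING_FIELDS:
            # pysam raises for INFO keys absent from the header; undeclared
            # annotation keys simply mean the annotation is missing
            val = (
                _info_scalar(info.get(keys[fname]))
                if keys[fname] in header_infos
                else None
            )
            fields[fname] = None if val is None else str(val)
        for fname in _FLOAT_FIELDS:
            val = (
                _info_scalar(info.get(keys[fname]))
                if keys[fname] in header_infos
                else None
            )
            fields[fname] = None if val is None else _shortest_float32(float(val))
        if fields["gene"] is None or fields["effect"] is None or fields["impact"] is None:
            raise ParseError(
                f"{path}: record {rec.chrom}:{rec.pos} lacks gene/effect/impact "
                f"annotation"
            )
        effect = Effect.parse(str(fields.pop("effect")))
        impact = Impact.parse(str(fields.pop("impact")))
        alts = rec.alts or ()
        for alt_index, alt in enumerate(alts, start=1):
            try:
                var = AnnotatedVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    rsid=None if rec.id in (None, ".") else rec.id,
                    effect=effect,
                    impact=impact,
                    **fields,  # type: ignore[arg-type]
                )
            except (ValueError, VocabularyError) as exc:
                if isinstance(exc, VocabularyError):
                    raise
                raise ParseError(f"{path}: record {rec.chrom}:{rec.pos}: {exc}") from exc
            variants.append(var)
            row = []
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                row.append(int(_map_genotype(gt, alt_index)))
            rows.append(row)

    calls = (
        np.asarray(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    matrix = GenotypeMatrix([v.key for v in variants], samples, calls)
    return variants, matrix


def _map_genotype(gt, alt_index: int) -> Genotype:
    """Map a diploid GT tuple to the call state for one ALT allele.

    Total mapping: any tuple that is not two called alleles is MISSING.
    """
    if gt is None or len(gt) != 2 or any(a is None for a in gt):
        return Genotype.MISSING
    n_alt = sum(1 for a in gt if a == alt_index)
    return Genotype(n_alt)


def write_annotated_vcf(
    path: str | Path,
    variants: Sequence[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    annotation_keys: Mapping[str, str] | None = None,
) -> Path:
    """Write variants and genotypes to a (plain-text) VCF 4.2 file.

    One record per variant (records are bi-allelic by construction); missing
    annotations are omitted from INFO rather than written as 0.
    """
    keys = dict(DEFAULT_ANNOTATION_KEYS)
    if annotation_keys:
        keys.update(annotation_keys)
    path = Path(path)

    header = pysam.VariantHeader()
    for chrom in CHROMOSOMES:
        header.contigs.add(chrom, length=250_000_000)
    descriptions = {
        "gene": "Gene symbol",
        "effect": "Variant effect category (snpEff classic vocabulary)",
        "impact": "Variant impact class (HIGH/MODERATE/LOW/MODIFIER)",
        "aa_change": "Amino acid change",
        "sift": "SIFT deleteriousness score (0-1, <0.05 damaging)",
        "polyphen2_hdiv": "PolyPhen2 HDIV damage probability (0-1)",
        "phylop": "PhyloP conservation score",
        "phastcons": "PhastCons conserved-element score (0-1)",
        "af_global": "Global (1000 Genomes) alternate allele frequency",
        "af_east_asian": "East-Asian alternate allele frequency",
        "af_korean": "Korean reference-panel alternate allele frequency",
    }
    for fname in _STRING_FIELDS:
        header.info.add(keys[fname], 1, "String", descriptions[fname])
    for fname in _FLOAT_FIELDS:
        header.info.add(keys[fname], 1, "Float", descriptions[fname])
    header.formats.add("GT", 1, "String", "Genotype")
    for sample in genotypes.samples:
        header.add_sample(sample)

    _GT_TUPLES = {
        Genotype.HOM_REF: (0, 0),
        Genotype.HET: (0, 1),
        Genotype.HOM_ALT: (1, 1),
        Genotype.MISSING: (None, None),
    }

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for var in variants:
            rec = out.new_record(
                contig=var.chrom,
                start=var.pos - 1,
                alleles=(var.ref, var.alt),
            )
            rec.id = var.rsid
            for fname in _STRING_FIELDS:
                val = getattr(var, fname)
                if val is not None:
                    sval = val.value if isinstance(val, (Effect, Impact)) else str(val)
                    rec.info[keys[fname]] = sval
            for fname in _FLOAT_FIELDS:
                val = getattr(var, fname)
                if val is not None:
                    rec.info[keys[fname]] = float(val)
            for sample in genotypes.samples:
                call = genotypes.call(var.key, sample)
                rec.samples[sample]["GT"] = _GT_TUPLES[call]
            out.write(rec)
    return path


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (family, individual, father, mother, sex,
    phenotype).

    Phenotype 2 means affected, 1 unaffected; any other code is rejected —
    the segregation model needs a definite affection status for every sample.
    A free-text role label (father/mother/child/member) is inferred from the
    parent columns and sex for reporting.
    """
    path = Path(path)
    members: list[PedMember] = []
    raw_rows: list[tuple[str, ...]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = tuple(line.split())
            if len(parts) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 whitespace-separated columns, "
                    f"got {len(parts)}"
                )
            raw_rows.append(parts[:6] + (str(lineno),))
    if not raw_rows:
        raise ParseError(f"{path}: pedigree file contains no samples")

    parent_ids = {r[2] for r in raw_rows} | {r[3] for r in raw_rows}
    for fam, ind, father, mother, sex_s, pheno, lineno in raw_rows:
        try:
            sex = int(sex_s)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: unparsable sex code {sex_s!r}") from None
        if pheno == "2":
            affected = True
        elif pheno == "1":
            affected = False
        else:
            raise VocabularyError(
                f"{path}:{lineno}: phenotype code {pheno!r} not in declared "
                f"vocabulary {{1: unaffected, 2: affected}}"
            )
        if ind in parent_ids:
            role = {1: "father", 2: "mother"}.get(sex, "parent")
        elif father != "0" or mother != "0":
            role = "child"
        else:
            role = "member"
        members.append(
            PedMember(
                family=fam,
                individual=ind,
                father=father,
                mother=mother,
                sex=sex,
                affected=affected,
                role=role,
            )
        )
    try:
        ped = Pedigree(members)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for warning in ped.validate():
        import warnings as _warnings

        _warnings.warn(f"{path}: {warning}", stacklevel=2)
    return ped


def write_pedigree(path: str | Path, ped: Pedigree) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for m in ped.members:
            pheno = 2 if m.affected else 1
            fh.write(
                f"{m.family}\t{m.individual}\t{m.father}\t{m.mother}\t{m.sex}\t{pheno}\n"
            )
    return path


def read_loci(path: str | Path, units: str = "bp") -> list[LinkageLocus]:
    """Read a BED-like locus file: chrom, start, end, name (tab/space split).

    Coordinates are interpreted as 1-based inclusive.  With ``units='Mb'``
    (the dialect linkage studies print, e.g. "chr3 122.2 129.5 3q21") each
    coordinate is multiplied by exactly 1,000,000.
    """
    if units not in ("bp", "Mb"):
        raise ConfigError(f"loci units must be 'bp' or 'Mb', got {units!r}")
    scale = 1_000_000 if units == "Mb" else 1
    path = Path(path)
    loci: list[LinkageLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 columns (chrom start end name)"
                )
            chrom_s, start_s, end_s, name = parts[:4]
            try:
                start = round(float(start_s) * scale)
                end = round(float(end_s) * scale)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: unparsable coordinate in {parts[1:3]}"
                ) from None
            if start > end:
                raise ParseError(f"{path}:{lineno}: start {start} > end {end}")
            try:
                loci.append(
                    LinkageLocus(name=name, chrom=chrom_s, start_bp=start, end_bp=end)
                )
            except VocabularyError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return loci


# -- case-control genotype count tables --------------------------------------

COUNTS_CSV_COLUMNS = ["snp", "group", "hom_ref", "het", "hom_alt", "ref_allele", "alt_allele"]


def read_counts_csv(path: str | Path):
    """Read a case-control genotype counts CSV into CaseControlCounts objects.

    Schema: snp, group (case|control), hom_ref, het, hom_alt and optional
    ref_allele / alt_allele columns.
    """
    from .assoc import CaseControlCounts  # local import avoids a cycle

    path = Path(path)
    rows: dict[str, dict[str, tuple[int, int, int]]] = {}
    alleles: dict[str, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "snp",
            "group",
            "hom_ref",
            "het",
            "hom_alt",
        } <= set(reader.fieldnames):
            raise ParseError(
                f"{path}: counts CSV must have columns snp, group, hom_ref, het, hom_alt"
            )
        for lineno, row in enumerate(reader, start=2):
            group = row["group"].strip().lower()
            if group not in ("case", "control"):
                raise VocabularyError(
                    f"{path}:{lineno}: group must be 'case' or 'control', got {row['group']!r}"
                )
            try:
                counts = (int(row["hom_ref"]), int(row["het"]), int(row["hom_alt"]))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: unparsable genotype count") from None
            snp = row["snp"].strip()
            rows.setdefault(snp, {})[group] = counts
            alleles.setdefault(
                snp,
                (row.get("ref_allele") or "REF", row.get("alt_allele") or "ALT"),
            )
    out = []
    for snp, groups in rows.items():
        if set(groups) != {"case", "control"}:
            raise ParseError(f"{path}: SNP {snp!r} lacks a case or control row")
        ref, alt = alleles[snp]
        out.append(
            CaseControlCounts(
                snp=snp,
                ref_allele=ref,
                alt_allele=alt,
                case=groups["case"],
                control=groups["control"],
            )
        )
    return out


def write_counts_csv(path: str | Path, counts) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COUNTS_CSV_COLUMNS)
        for cc in counts:
            for group, trio in (("case", cc.case), ("control", cc.control)):
                writer.writerow(
                    [cc.snp, group, *trio, cc.ref_allele, cc.alt_allele]
                )
    return path
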