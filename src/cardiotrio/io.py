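"""Readers and writers for the standard formats the pipeline touches.

SAM/BAM and VCF parsing is delegated to :mod:`pysam`; this module reduces
records to the package's domain types and loads the packaged cohort fixture.
All coordinates exposed here are 1-based inclusive; BED conversion happens
only in :func:`write_cnv_bed` / :func:`read_cnv_bed`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pysam

from .model import (
    CnvCall,
    CohortCase,
    GenomicInterval,
    IntegrityError,
    PanelGene,
    ReadPairRecord,
    TrioVariant,
)

# GRCh37 chrX pseudoautosomal regions (1-based inclusive).
PAR1_X = (60001, 2699520)
PAR2_X = (154931044, 155260560)

_X_NAMES = {"chrX", "X"}
_Y_NAMES = {"chrY", "Y"}


class SamParseError(Exception):
    """A SAM line could not be parsed."""


class PedigreeConfigError(Exception):
    """Pedigree samples are inconsistent with the VCF header."""


def in_par(chrom: str, pos: int) -> bool:
    """True if (chrom, pos) lies in a chrX pseudoautosomal region."""
    if chrom not in _X_NAMES:
        return False
    return PAR1_X[0] <= pos <= PAR1_X[1] or PAR2_X[0] <= pos <= PAR2_X[1]


def is_hemizygous_region(chrom: str, pos: int, sex: str) -> bool:
    """True where a male sample carries a single allele (non-PAR X, or Y)."""
    if sex != "M":
        return False
    if chrom in _Y_NAMES:
        return True
    return chrom in _X_NAMES and not in_par(chrom, pos)


@dataclass(frozen=True)
class Pedigree:
    """A trio: sample names of proband, mother and father, plus proband sex."""

    proband: str
    mother: str
    father: str
    proband_sex: str  # "M" | "F"

    def __post_init__(self) -> None:
        if self.proband_sex not in ("M", "F"):
            raise ValueError(f"bad proband sex {self.proband_sex!r}")


def read_pedigree(path) -> Pedigree:
    """Parse a 6-column PED file describing a single trio.

    The proband is the individual whose father and mother columns are both
    non-zero; its sex comes from the PED sex code (1=M, 2=F).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise PedigreeConfigError(f"PED line has {len(parts)} columns: {line!r}")
            rows.append(parts)
    probands = [r for r in rows if r[2] != "0" and r[3] != "0"]
    if len(probands) != 1:
        raise PedigreeConfigError(
            f"expected exactly one individual with both parents, found {len(probands)}"
        )
    p = probands[0]
    sex = {"1": "M", "2": "F"}.get(p[4])
    if sex is None:
        raise PedigreeConfigError(f"proband sex code must be 1 or 2, got {p[4]!r}")
    return Pedigree(proband=p[1], father=p[2], mother=p[3], proband_sex=sex)


def read_sam_pairs(
    path, region: Optional[GenomicInterval] = None
) -> Iterator[ReadPairRecord]:
    """Stream primary alignments from a SAM/BAM file as ReadPairRecord.

    Secondary, supplementary and unmapped alignments are excluded; input
    order is preserved. When ``region`` is given only reads whose alignment
    start falls inside it are yielded; a region on a chromosome absent from
    the file yields an empty stream.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        n_header_lines = str(af.header).count("\n")
        record_no = 0
        it = af.fetch(until_eof=True)
        while True:
            try:
                read = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise SamParseError(
                    f"malformed SAM record near line {n_header_lines + record_no + 1}: {exc}"
                ) from exc
            record_no += 1
            if read.is_secondary or read.is_supplementary or read.is_unmapped:
                continue
            pos = read.reference_start + 1
            if region is not None:
                if read.reference_name != region.chrom:
                    continue
                if not region.start <= pos <= region.end:
                    continue
            yield ReadPairRecord(
                read_id=read.query_name,
                chrom=read.reference_name,
                pos=pos,
                mapq=read.mapping_quality,
                tlen=read.template_length,
                is_reverse=read.is_reverse,
                mate_is_reverse=read.mate_is_reverse,
                is_first_in_pair=read.is_read1,
            )


@dataclass(frozen=True)
class AnnotationConfig:
    """INFO keys carrying the variant annotations (gnomAD/ClinVar-style defaults)."""

    gene_key: str = "GENE"
    consequence_key: str = "CONSEQ"
    af_key: str = "gnomAD_AF"
    class_key: str = "CLNSIG"


_CLNSIG_MAP = {
    "pathogenic": "pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "uncertain_significance": "vus",
    "vus": "vus",
    "likely_benign": "likely_benign",
    "benign": "benign",
}


def _info_per_alt(value, alt_index: int, n_alts: int):
    """Pick the per-ALT element of an INFO value (Number=A) or pass scalars through."""
    if isinstance(value, (tuple, list)):
        if len(value) == n_alts:
            return value[alt_index]
        return value[0] if value else None
    return value


def _info_get(info, key: str, default):
    """INFO lookup tolerant of keys absent from the header."""
    try:
        return info.get(key, default)
    except (KeyError, ValueError):
        return default


def _classify_gt(alleles, alt_allele_index: int) -> str:
    if alleles is None or len(alleles) == 0 or any(a is None for a in alleles):
        return "missing"
    hits = sum(1 for a in alleles if a == alt_allele_index)
    if len(alleles) == 1:
        return "hemi" if hits == 1 else "hom_ref"
    if hits == 2:
        return "hom_alt"
    if hits == 1:
        return "het"
    return "hom_ref"


def read_trio_vcf(
    path,
    pedigree: Pedigree,
    annotation: AnnotationConfig = AnnotationConfig(),
) -> Iterator[TrioVariant]:
    """Stream a trio VCF as one TrioVariant per ALT allele per site.

    Missing genotypes map to ``missing``. A heterozygous call for a male
    proband on non-PAR chrX is kept as ``het`` and flagged ``male_x_het``
    rather than silently converted to hemizygous.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for name in (pedigree.proband, pedigree.mother, pedigree.father):
            if name not in samples:
                raise PedigreeConfigError(
                    f"pedigree sample {name!r} absent from VCF header {samples}"
                )
        for rec in vf:
            alts = rec.alts or ()
            for k, alt in enumerate(alts):
                allele_idx = k + 1
                gts = {}
                for role, name in (
                    ("proband", pedigree.proband),
                    ("mother", pedigree.mother),
                    ("father", pedigree.father),
                ):
                    gts[role] = _classify_gt(rec.samples[name].get("GT"), allele_idx)
                flags = set()
                if (
                    gts["proband"] == "het"
                    and is_hemizygous_region(rec.chrom, rec.pos, pedigree.proband_sex)
                ):
                    flags.add("male_x_het")
                info = rec.info
                gene = _info_per_alt(_info_get(info, annotation.gene_key, "."), k, len(alts))
                conseq = _info_per_alt(
                    _info_get(info, annotation.consequence_key, "other"), k, len(alts)
                )
                af = _info_per_alt(_info_get(info, annotation.af_key, None), k, len(alts))
                raw_cls = _info_per_alt(
                    _info_get(info, annotation.class_key, "unknown"), k, len(alts)
                )
                cls = _CLNSIG_MAP.get(str(raw_cls).lower(), "unknown")
                yield TrioVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    gene=str(gene),
                    consequence=str(conseq),
                    gt_proband=gts["proband"],
                    gt_mother=gts["mother"],
                    gt_father=gts["father"],
                    af_pop=float(af) if af is not None else None,
                    clinical_class=cls,
                    flags=frozenset(flags),
                )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("cardiotrio").joinpath("data", name)))


def _read_tsv(path) -> list[dict]:
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    return list(csv.DictReader(lines, delimiter="\t"))


def _opt(value: str):
    return None if value in (".", "", "NA") else value


def load_cohort_fixture(path=None) -> list[CohortCase]:
    """Load the packaged 42-case cohort table, verifying every published margin.

    Raises IntegrityError (never repairs) if any count disagrees with the
    published cohort composition.
    """
    path = path or _data_path("cohort_cases.tsv")
    cases = []
    for row in _read_tsv(path):
        t1 = _opt(row["t1_days"])
        t2 = _opt(row["t2_days"])
        cases.append(
            CohortCase(
                case_id=row["case_id"],
                urgent=row["urgent"] == "yes",
                age_months=float(row["age_months"]),
                sex=row["sex"],
                cm_type=row["cm_type"],
                cm_class=row["cm_class"],
                diagnosed=row["diagnosed"] == "yes",
                gene=_opt(row["gene"]),
                zygosity=_opt(row["zygosity"]),
                parental_origin=_opt(row["parental_origin"]),
                family_history=row["family_history"] == "yes",
                prenatal=row["prenatal"] == "yes",
                t1_days=float(t1) if t1 else None,
                t2_days=float(t2) if t2 else None,
            )
        )
    _check_fixture_margins(cases)
    return cases


def _check_fixture_margins(cases: Sequence[CohortCase]) -> None:
    checks = {
        "total cases": (len(cases), 42),
        "diagnosed": (sum(c.diagnosed for c in cases), 29),
        "urgent": (sum(c.urgent for c in cases), 24),
        "non-urgent": (sum(not c.urgent for c in cases), 18),
        "male": (sum(c.sex == "M" for c in cases), 26),
        "female": (sum(c.sex == "F" for c in cases), 16),
        "HCM": (sum(c.cm_type == "HCM" for c in cases), 30),
        "DCM": (sum(c.cm_type == "DCM" for c in cases), 12),
        "isolated": (sum(c.cm_class == "isolated" for c in cases), 12),
        "complex": (sum(c.cm_class in ("syndromic", "metabolic") for c in cases), 30),
        "family history": (sum(c.family_history for c in cases), 5),
        "prenatal": (sum(c.prenatal for c in cases), 9),
    }
    for label, (got, want) in checks.items():
        if got != want:
            raise IntegrityError(f"cohort fixture: {label} = {got}, expected {want}")


@dataclass(frozen=True)
class DiagnosticVariantRow:
    """One reported allele of a diagnosed case (per-variant cohort fixture row)."""

    case_id: str
    gene: str
    chrom: str
    pos: int
    end: Optional[int]
    ref: Optional[str]
    alt: Optional[str]
    consequence: str
    zygosity: str  # hetero | homo | hemi
    origin: str  # de_novo | mother | father | both
    clinical_class: str
    cdna: str


def load_diagnostic_variants(path=None) -> list[DiagnosticVariantRow]:
    """Load the per-variant transcription for the 29 diagnosed cases (33 alleles)."""
    path = path or _data_path("diagnostic_variants.tsv")
    rows = []
    for row in _read_tsv(path):
        rows.append(
            DiagnosticVariantRow(
                case_id=row["case_id"],
                gene=row["gene"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                end=int(row["end"]) if _opt(row["end"]) else None,
                ref=_opt(row["ref"]),
                alt=_opt(row["alt"]),
                consequence=row["consequence"],
                zygosity=row["zygosity"],
                origin=row["origin"],
                clinical_class=row["clinical_class"],
                cdna=row["cdna"],
            )
        )
    if len({r.case_id for r in rows}) != 29:
        raise IntegrityError("diagnostic variant fixture must cover exactly 29 cases")
    return rows


def load_panel(path=None) -> list[PanelGene]:
    """Load the cardiomyopathy gene panel (packaged by default)."""
    path = path or _data_path("panel_cardiomyopathy.tsv")
    return [
        PanelGene(
            symbol=row["symbol"],
            inheritance_modes=frozenset(row["modes"].split(",")),
            mechanism=row["mechanism"],
            phenotype_tags=frozenset(row["tags"].split(",")) if row["tags"] else frozenset(),
        )
        for row in _read_tsv(path)
    ]


def load_gene_etiology(path=None) -> dict:
    """Load the gene -> etiological class map (packaged by default)."""
    path = path or _data_path("gene_etiology.tsv")
    return {row["gene"]: row["etiology"] for row in _read_tsv(path)}


def read_gene_intervals(path=None) -> list[tuple]:
    """Read gene intervals from a BED file as (GenomicInterval, symbol), sorted.

    Defaults to the packaged toy ATAD3-cluster intervals.
    """
    path = path or _data_path("genes_atad3_cluster.bed")
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            out.append((GenomicInterval(chrom, start0 + 1, end0), name))
    return sorted(out, key=lambda t: (t[0].chrom, t[0].start, t[0].end))


# ---------------------------------------------------------------------------
# BED output for CNV calls
# ---------------------------------------------------------------------------

def write_cnv_bed(calls: Sequence[CnvCall], path) -> None:
    """Write CNV calls as BED6 (0-based half-open); name = type:support:source."""
    with open(path, "w") as fh:
        fh.write("# CNV calls: chrom start end type:support:source score strand\n")
        for call in calls:
            iv = call.interval
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t"
                f"{call.sv_type}:{call.support}:{call.source}\t{call.support}\t.\n"
            )


def read_cnv_bed(path) -> list[CnvCall]:
    """Read CNV calls written by :func:`write_cnv_bed` (round-trip inverse)."""
    calls = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start0, end0, name = line.split("\t")[:4]
            sv_type, support, source = name.split(":")
            calls.append(
                CnvCall(
                    interval=GenomicInterval(chrom, int(start0) + 1, int(end0)),
                    sv_type=sv_type,
                    support=int(support),
                    source=source,
                    rank=len(calls) + 1,
                )
            )
    return calls
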