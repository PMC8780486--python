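"""Synthetic inputs for the pipeline, each with a machine-readable truth manifest.

Three generators cover the pipeline's inputs:

* paired-end exome-like alignments (SAM) over one toy chromosome with
  implanted tandem duplications and deletions whose read pairs carry the
  anomalous TLEN/orientation signatures the discordant-pair caller detects;
* trio VCFs with planted causal variants under each inheritance model plus
  Mendelian-consistent noise variants with a gnomAD-like frequency spectrum;
* per-target read-depth count matrices (case + reference samples) for the
  depth-ratio CNV stage.

Reads are emitted as already-aligned SAM because the discordant-pair caller
consumes alignment fields (MAPQ, TLEN, orientation) only; SEQ/QUAL are
placeholders. All generators are deterministic: the same seed and parameters
yield byte-identical output.

Signature conventions (recorded in every manifest): a deletion produces
FR pairs anchored in the flanks, so |TLEN| = span + flanking gap; a tandem
duplication produces everted RF pairs with |TLEN| ~ span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import GenomicInterval

DEFAULT_CHROM = "chrS"
DEFAULT_REFERENCE_LENGTH = 2_000_000
DEFAULT_READ_LENGTH = 150


@dataclass(frozen=True)
class CnvTruth:
    """A planted copy-number event and the read support it should emit."""

    interval: GenomicInterval
    sv_type: str  # "tandem_dup" | "deletion"
    n_supporting_pairs: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sv_type not in ("tandem_dup", "deletion"):
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.n_supporting_pairs < 0:
            raise ValueError("n_supporting_pairs must be >= 0")


@dataclass(frozen=True)
class TrioTruth:
    """A planted causal configuration for one synthetic trio."""

    model: str  # de_novo | ar_homozygous | compound_het | xl_hemizygous | inherited_dominant
    gene: str
    variant_keys: tuple = ()  # filled by the generator when empty
    noise_variants: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in (
            "de_novo",
            "ar_homozygous",
            "compound_het",
            "xl_hemizygous",
            "inherited_dominant",
        ):
            raise ValueError(f"unknown trio model {self.model!r}")


def _sam_line(
    read_id: str,
    flag: int,
    chrom: str,
    pos: int,
    mapq: int,
    cigar: str,
    pnext: int,
    tlen: int,
) -> str:
    return f"{read_id}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t=\t{pnext}\t{tlen}\t*\t*"


# SAM flag bit combinations for a mapped pair (leftmost mate listed first).
_FLAGS_FR = (0x1 | 0x20 | 0x40, 0x1 | 0x10 | 0x80)  # forward + reverse mate
_FLAGS_RF = (0x1 | 0x10 | 0x40, 0x1 | 0x20 | 0x80)  # everted: reverse + forward mate
_FLAGS_PROPER = (0x1 | 0x2 | 0x20 | 0x40, 0x1 | 0x2 | 0x10 | 0x80)


def _emit_pair(
    lines: list,
    read_id: str,
    chrom: str,
    left_pos: int,
    right_pos: int,
    tlen: int,
    mapq: int,
    read_length: int,
    flags: tuple,
) -> None:
    cigar = f"{read_length}M"
    lines.append(
        (left_pos, read_id, _sam_line(read_id, flags[0], chrom, left_pos, mapq, cigar, right_pos, tlen))
    )
    lines.append(
        (right_pos, read_id, _sam_line(read_id, flags[1], chrom, right_pos, mapq, cigar, left_pos, -tlen))
    )


def simulate_read_pairs(
    truth: Sequence[CnvTruth] = (),
    reference_length: int = DEFAULT_REFERENCE_LENGTH,
    normal_insert_mean: int = 350,
    normal_insert_sd: int = 50,
    n_background_pairs: int = 2000,
    read_length: int = DEFAULT_READ_LENGTH,
    decoy_fraction: float = 0.01,
    chrom: str = DEFAULT_CHROM,
    seed: int = 0,
) -> tuple:
    """Generate a coordinate-sorted SAM text plus a truth manifest.

    Background pairs are proper FR pairs with template length drawn from
    Normal(normal_insert_mean, normal_insert_sd) truncated positive, MAPQ 60.
    Each truth event emits ``n_supporting_pairs`` discordant pairs whose
    implied template interval matches the truth interval within one read
    length. A ``decoy_fraction`` of additional pairs carries CNV-like TLEN
    but MAPQ < 60 (multi-mapping decoys the MAPQ filter must remove).
    """
    for t in truth:
        if t.interval.chrom != chrom:
            raise ValueError(f"truth chromosome {t.interval.chrom!r} != {chrom!r}")
        if t.interval.end > reference_length:
            raise ValueError(
                f"truth interval {t.interval} exceeds reference length {reference_length}"
            )
    rng = np.random.default_rng(seed)
    lines: list = []

    min_template = 2 * read_length + 10
    for i in range(n_background_pairs):
        t = int(rng.normal(normal_insert_mean, normal_insert_sd))
        t = max(t, min_template)
        pos = int(rng.integers(1, max(2, reference_length - t)))
        _emit_pair(
            lines,
            f"bg{i}",
            chrom,
            pos,
            pos + t - read_length,
            t,
            60,
            read_length,
            _FLAGS_PROPER,
        )

    n_decoys = int(round(decoy_fraction * n_background_pairs))
    for i in range(n_decoys):
        t = int(rng.integers(2500, 350_001))
        t = min(t, reference_length - 1)
        pos = int(rng.integers(1, max(2, reference_length - t)))
        mapq = int(rng.integers(0, 60))
        _emit_pair(
            lines,
            f"decoy{i}",
            chrom,
            pos,
            pos + t - read_length,
            t,
            mapq,
            read_length,
            _FLAGS_FR,
        )

    events = []
    for j, t in enumerate(truth):
        flags = _FLAGS_RF if t.sv_type == "tandem_dup" else _FLAGS_FR
        pair_ids = []
        for i in range(t.n_supporting_pairs):
            a = int(rng.integers(0, read_length + 1))
            b = int(rng.integers(0, read_length + 1))
            left = max(1, t.interval.start - a)
            right_end = min(reference_length, t.interval.end + b)
            tlen = right_end - left + 1
            read_id = f"ev{j}_{i}"
            pair_ids.append(read_id)
            _emit_pair(
                lines,
                read_id,
                chrom,
                left,
                right_end - read_length + 1,
                tlen,
                60,
                read_length,
                flags,
            )
        events.append(
            {
                "chrom": t.interval.chrom,
                "start": t.interval.start,
                "end": t.interval.end,
                "span": t.interval.span,
                "sv_type": t.sv_type,
                "n_supporting_pairs": t.n_supporting_pairs,
                "pair_ids": pair_ids,
            }
        )

    lines.sort(key=lambda x: (x[0], x[1]))
    header = f"@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:{chrom}\tLN:{reference_length}\n"
    sam_text = header + "".join(line + "\n" for _, _, line in lines)
    manifest = {
        "chrom": chrom,
        "reference_length": reference_length,
        "read_length": read_length,
        "normal_insert_mean": normal_insert_mean,
        "normal_insert_sd": normal_insert_sd,
        "n_background_pairs": n_background_pairs,
        "n_decoy_pairs": n_decoys,
        "seed": seed,
        "events": events,
    }
    return sam_text, manifest


# ---------------------------------------------------------------------------
# Trio VCF generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AfModel:
    """Frequency spectrum parameters for planted and noise variants.

    Causal alleles are either novel (absent from the population reference,
    probability ``causal_novel_prob``) or drawn log-uniformly below
    ``causal_af_max``. Noise variants mix a common component (uniform on
    [0.01, 0.5]) with a rare tail (log-uniform on [1e-6, 1e-2])."""

    causal_af_max: float = 1e-5
    causal_novel_prob: float = 0.5
    noise_common_fraction: float = 0.6


_TRIO_CONTIGS = ("chr1", "chr2", "chr3", "chr4", "chr5", "chrX")
_AUTOSOMES = ("chr1", "chr2", "chr3", "chr4", "chr5")
_CONTIG_LEN = 50_000_000
_NOISE_CLASSES = ("benign", "likely_benign", "vus")
_BASES = ("A", "C", "G", "T")


def gene_loci(panel) -> dict:
    """Deterministic toy locus for each panel gene: X-linked genes go to
    non-PAR chrX, the rest round-robin over five autosomes."""
    loci = {}
    auto_i = 0
    x_i = 0
    for g in sorted(panel, key=lambda g: g.symbol):
        if g.inheritance_modes == frozenset({"XL"}):
            start = 5_000_000 + x_i * 200_000
            loci[g.symbol] = GenomicInterval("chrX", start, start + 50_000)
            x_i += 1
        else:
            chrom = _AUTOSOMES[auto_i % len(_AUTOSOMES)]
            start = 1_000_000 + (auto_i // len(_AUTOSOMES)) * 200_000
            loci[g.symbol] = GenomicInterval(chrom, start, start + 50_000)
            auto_i += 1
    return loci


def _draw_snv(rng, interval: GenomicInterval, used: set) -> tuple:
    while True:
        pos = int(rng.integers(interval.start, interval.end + 1))
        if (interval.chrom, pos) not in used:
            used.add((interval.chrom, pos))
            break
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    return interval.chrom, pos, str(ref), str(alt)


def _causal_consequence(rng, mechanism: str) -> str:
    if mechanism == "lof":
        return "lof"
    if mechanism == "non_lof":
        return "missense"
    return str(rng.choice(["lof", "missense", "splice"]))


def _noise_site(rng, used: set, af_model: AfModel) -> dict:
    chrom = str(rng.choice(_AUTOSOMES))
    while True:
        pos = int(rng.integers(1_000_000, _CONTIG_LEN))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            break
    ref, alt = (str(b) for b in rng.choice(_BASES, size=2, replace=False))
    if rng.random() < af_model.noise_common_fraction:
        af = float(rng.uniform(0.01, 0.5))
    else:
        af = float(10 ** rng.uniform(-6, -2))
    # Mendelian-consistent transmission: parents drawn from HWE at af,
    # child inherits one allele from each parent.
    gm = _hwe_genotype(rng, af)
    gf = _hwe_genotype(rng, af)
    gp = (_transmit(rng, gm), _transmit(rng, gf))
    return {
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "gene": "NOISE",
        "conseq": str(rng.choice(["missense", "other", "splice", "inframe"])),
        "af": af,
        "cls": str(rng.choice(_NOISE_CLASSES)),
        "gt": {"proband": _gt_str(sorted(gp)), "mother": _gt_str(gm), "father": _gt_str(gf)},
    }


def _hwe_genotype(rng, af: float) -> tuple:
    return tuple(sorted(int(rng.random() < af) for _ in range(2)))


def _transmit(rng, parent_gt: tuple) -> int:
    return parent_gt[int(rng.integers(0, 2))]


def _gt_str(gt) -> str:
    return "/".join(str(a) for a in gt)


def simulate_trio_vcf(
    truth: Sequence[TrioTruth],
    panel,
    af_model: AfModel = AfModel(),
    n_noise_variants: int = 200,
    proband_sex: str = "M",
    seed: int = 0,
    samples: tuple = ("PROBAND", "MOTHER", "FATHER"),
) -> tuple:
    """Generate a trio VCF text plus a manifest of the planted causal keys.

    Genotypes follow the declared model exactly (de novo: proband het with
    hom-ref parents; AR homozygous: proband hom-alt with carrier parents;
    compound het: two hets in the proband, one per parent; X-linked: haploid
    alt proband with carrier mother). Noise variants are autosomal,
    Mendelian-consistent transmissions, never labelled pathogenic.
    """
    if proband_sex not in ("M", "F"):
        raise ValueError(f"bad proband_sex {proband_sex!r}")
    panel_by_symbol = {g.symbol: g for g in panel}
    loci = gene_loci(panel)
    rng = np.random.default_rng(seed)
    used: set = set()
    records = []
    causal_manifest = []

    for t in truth:
        if t.gene not in panel_by_symbol:
            raise ValueError(f"truth gene {t.gene!r} not in panel")
        gene = panel_by_symbol[t.gene]
        locus = loci[t.gene]
        if t.model == "xl_hemizygous":
            if proband_sex != "M":
                raise ValueError("xl_hemizygous requested for a female proband")
            if locus.chrom != "chrX":
                raise ValueError(f"xl_hemizygous truth gene {t.gene} must be X-linked")
        n_vars = 2 if t.model == "compound_het" else 1
        keys = list(t.variant_keys)
        while len(keys) < n_vars:
            keys.append(_draw_snv(rng, locus, used))
        if rng.random() < af_model.causal_novel_prob:
            af = None
        else:
            af = float(10 ** rng.uniform(-8, np.log10(af_model.causal_af_max)))
        cls = str(rng.choice(["pathogenic", "likely_pathogenic"]))
        gt_sets = _causal_genotypes(t.model, n_vars, rng)
        for (chrom, pos, ref, alt), gt in zip(keys, gt_sets):
            records.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": t.gene,
                    "conseq": _causal_consequence(rng, gene.mechanism),
                    "af": af,
                    "cls": cls,
                    "gt": gt,
                }
            )
        causal_manifest.append(
            {"model": t.model, "gene": t.gene, "keys": [list(k) for k in keys]}
        )

    for _ in range(n_noise_variants):
        records.append(_noise_site(rng, used, af_model))

    order = {c: i for i, c in enumerate(_TRIO_CONTIGS)}
    records.sort(key=lambda r: (order.get(r["chrom"], 99), r["pos"]))

    header = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c},length={_CONTIG_LEN}>" for c in _TRIO_CONTIGS],
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Predicted consequence">',
        '##INFO=<ID=gnomAD_AF,Number=1,Type=Float,Description="Population allele frequency">',
        '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="Clinical classification">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    body = []
    for r in records:
        info = f"GENE={r['gene']};CONSEQ={r['conseq']};CLNSIG={r['cls']}"
        if r["af"] is not None:
            info += f";gnomAD_AF={r['af']:.3e}"
        body.append(
            f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t100\tPASS\t{info}\tGT\t"
            f"{r['gt']['proband']}\t{r['gt']['mother']}\t{r['gt']['father']}"
        )
    vcf_text = "\n".join(header + body) + "\n"
    manifest = {
        "samples": {"proband": samples[0], "mother": samples[1], "father": samples[2]},
        "proband_sex": proband_sex,
        "causal": causal_manifest,
        "n_noise_variants": n_noise_variants,
        "seed": seed,
    }
    return vcf_text, manifest


def _causal_genotypes(model: str, n_vars: int, rng) -> list:
    if model == "de_novo":
        return [{"proband": "0/1", "mother": "0/0", "father": "0/0"}]
    if model == "ar_homozygous":
        return [{"proband": "1/1", "mother": "0/1", "father": "0/1"}]
    if model == "compound_het":
        return [
            {"proband": "0/1", "mother": "0/1", "father": "0/0"},
            {"proband": "0/1", "mother": "0/0", "father": "0/1"},
        ]
    if model == "xl_hemizygous":
        return [{"proband": "1", "mother": "0/1", "father": "0"}]
    if model == "inherited_dominant":
        if rng.random() < 0.5:
            return [{"proband": "0/1", "mother": "0/1", "father": "0/0"}]
        return [{"proband": "0/1", "mother": "0/0", "father": "0/1"}]
    raise ValueError(model)


# ---------------------------------------------------------------------------
# Read-depth counts
# ---------------------------------------------------------------------------

def simulate_depth_counts(
    targets: Sequence[GenomicInterval],
    truth: Sequence[CnvTruth] = (),
    mean_depth: float = 500.0,
    n_reference_samples: int = 5,
    dispersion: float = 2500.0,
    seed: int = 0,
) -> tuple:
    """Per-target read counts for a case sample and a reference panel.

    Counts are negative-binomial around ``mean_depth`` (variance
    mu + mu^2/dispersion). Case expectations are scaled x1.5 on targets
    inside a duplicated truth interval and x0.5 inside a deleted one;
    reference samples carry no events.
    """
    targets = list(targets)
    for a, b in zip(targets, targets[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            if a.start > b.start:
                raise ValueError("targets must be sorted")
            raise ValueError(f"overlapping targets: {a} / {b}")
    rng = np.random.default_rng(seed)
    n = len(targets)
    scale = np.ones(n)
    affected = {"tandem_dup": [], "deletion": []}
    for t in truth:
        for i, tgt in enumerate(targets):
            if tgt.overlap(t.interval) > 0:
                scale[i] = 1.5 if t.sv_type == "tandem_dup" else 0.5
                affected[t.sv_type].append(i)

    def nb(mu: np.ndarray) -> np.ndarray:
        p = dispersion / (dispersion + mu)
        return rng.negative_binomial(dispersion, p)

    case_counts = nb(mean_depth * scale)
    reference = np.column_stack(
        [nb(np.full(n, mean_depth)) for _ in range(n_reference_samples)]
    )
    manifest = {
        "mean_depth": mean_depth,
        "n_reference_samples": n_reference_samples,
        "dispersion": dispersion,
        "seed": seed,
        "affected_targets": affected,
        "events": [
            {
                "chrom": t.interval.chrom,
                "start": t.interval.start,
                "end": t.interval.end,
                "sv_type": t.sv_type,
            }
            for t in truth
        ],
    }
    return case_counts, reference, manifest
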