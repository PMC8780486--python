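"""Sequential trio variant prioritization.

The cascade resolves the transmission model of every variant from the trio
genotypes, gates on population allele frequency with model-specific
thresholds (dominant-acting models demand rarer alleles than recessive
ones), requires the gene to sit on the phenotype panel with a matching
inheritance mode and pathogenic mechanism, suppresses everything below the
reportable clinical classes (VUS and below are never reported, per
laboratory policy), and returns the survivors ranked.

Variant classification itself (pathogenic / likely pathogenic / VUS ...) is
consumed as an annotation, never computed here; the mechanism check is the
only classification-adjacent logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .io import (
    AnnotationConfig,
    Pedigree,
    is_hemizygous_region,
    load_cohort_fixture,
    load_diagnostic_variants,
    read_trio_vcf,
)
from .model import CandidateDiagnosis, InheritanceCall, PanelGene, TrioVariant


@dataclass(frozen=True)
class PrioritizeConfig:
    """Frequency gates and panel/mechanism policy of the cascade."""

    af_max_dominant: float = 1e-4
    af_max_recessive_allele: float = 5e-3
    require_panel_match: bool = True
    require_mechanism_match: bool = True
    reportable_classes: frozenset = frozenset({"pathogenic", "likely_pathogenic"})

    def __post_init__(self) -> None:
        if self.af_max_dominant > self.af_max_recessive_allele:
            raise ValueError("af_max_dominant must be <= af_max_recessive_allele")


_CARRIER = ("het", "hom_alt", "hemi")


def _resolve_single(v: TrioVariant, proband_sex: str) -> InheritanceCall:
    gts = (v.gt_proband, v.gt_mother, v.gt_father)
    if "missing" in gts:
        return InheritanceCall("unresolved", (v.key,), v.gene)

    if is_hemizygous_region(v.chrom, v.pos, proband_sex):
        # Male proband, non-PAR X (or Y): the hemizygous rule applies.
        if v.gt_proband == "hemi" and v.gt_mother == "het" and v.gt_father == "hom_ref":
            return InheritanceCall("xl_hemizygous", (v.key,), v.gene)
        return InheritanceCall("unresolved", (v.key,), v.gene)

    # Autosomes, female-proband chrX and PAR follow the diploid rules.
    p, m, f = gts
    if p == "het":
        if m == "hom_ref" and f == "hom_ref":
            return InheritanceCall("de_novo", (v.key,), v.gene)
        if m in _CARRIER and f == "hom_ref":
            return InheritanceCall("inherited_maternal", (v.key,), v.gene)
        if f in _CARRIER and m == "hom_ref":
            return InheritanceCall("inherited_paternal", (v.key,), v.gene)
        return InheritanceCall("unresolved", (v.key,), v.gene)
    if p == "hom_alt":
        if m == "het" and f == "het":
            return InheritanceCall("ar_homozygous", (v.key,), v.gene)
        if m == "hom_ref" or f == "hom_ref":
            # Impossible transmission on an autosome: flag, never raise.
            return InheritanceCall(
                "unresolved", (v.key,), v.gene, mendelian_error=True
            )
        return InheritanceCall("unresolved", (v.key,), v.gene)
    return InheritanceCall("unresolved", (v.key,), v.gene)


def determine_inheritance(
    variants: Sequence[TrioVariant], proband_sex: str
) -> list:
    """Resolve the transmission model of every variant in a trio.

    Per-variant rules run first; then, per gene, one maternally and one
    paternally inherited heterozygous variant combine into a single
    compound-het call replacing the two singletons (first of each by
    position when several are available). Inconsistent transmissions come
    back ``unresolved`` with a Mendelian-error flag, never as an exception.
    """
    singles = [(v, _resolve_single(v, proband_sex)) for v in variants]
    by_gene: dict = {}
    for v, call in singles:
        if call.model in ("inherited_maternal", "inherited_paternal"):
            by_gene.setdefault(v.gene, []).append((v, call))

    replaced = set()
    compounds = []
    for gene, items in by_gene.items():
        items.sort(key=lambda vc: (vc[0].chrom, vc[0].pos, vc[0].alt))
        maternal = [vc for vc in items if vc[1].model == "inherited_maternal"]
        paternal = [vc for vc in items if vc[1].model == "inherited_paternal"]
        for (vm, cm), (vf, cf) in zip(maternal, paternal):
            keys = tuple(sorted((vm.key, vf.key)))
            compounds.append(InheritanceCall("compound_het", keys, gene))
            replaced.add(id(cm))
            replaced.add(id(cf))

    out = [call for _, call in singles if id(call) not in replaced]
    out.extend(compounds)
    return out


def _variants_for(call: InheritanceCall, variants: Sequence[TrioVariant]) -> list:
    by_key = {}
    for v in variants:
        by_key.setdefault(v.key, v)
    return [by_key[k] for k in call.variant_keys if k in by_key]


def frequency_filter(
    call: InheritanceCall,
    variants: Sequence[TrioVariant],
    config: PrioritizeConfig = PrioritizeConfig(),
) -> bool:
    """Population-frequency gate; absent frequency counts as novel (0)."""
    if call.model == "unresolved":
        return False
    if call.model in ("ar_homozygous", "compound_het"):
        threshold = config.af_max_recessive_allele
    else:
        threshold = config.af_max_dominant
    for v in _variants_for(call, variants):
        af = v.af_pop if v.af_pop is not None else 0.0
        if af > threshold:
            return False
    return True


_MODEL_TO_MODE = {
    "de_novo": "AD",
    "inherited_maternal": "AD",
    "inherited_paternal": "AD",
    "ar_homozygous": "AR",
    "compound_het": "AR",
    "xl_hemizygous": "XL",
}


def panel_mechanism_filter(
    call: InheritanceCall,
    variants: Sequence[TrioVariant],
    panel: Sequence[PanelGene],
    config: PrioritizeConfig = PrioritizeConfig(),
) -> bool:
    """Phenotype-panel and pathogenic-mechanism gate.

    The gene must be on the panel (unless waived), the resolved model must
    match one of the gene's inheritance modes, and each variant's
    consequence must fit the gene's expected mechanism: loss-of-function
    genes demand lof consequences, non-lof genes reject them, and
    ``either`` accepts both.
    """
    if call.model == "unresolved":
        return False
    gene = next((g for g in panel if g.symbol == call.gene), None)
    if gene is None:
        return not config.require_panel_match
    mode = _MODEL_TO_MODE[call.model]
    if mode not in gene.inheritance_modes:
        return False
    if config.require_mechanism_match and gene.mechanism != "either":
        for v in _variants_for(call, variants):
            if gene.mechanism == "lof" and v.consequence != "lof":
                return False
            if gene.mechanism == "non_lof" and v.consequence == "lof":
                return False
    return True


_CLASS_WEIGHT = {"pathogenic": 3.0, "likely_pathogenic": 2.0}
_MODEL_WEIGHT = {
    "de_novo": 2.0,
    "ar_homozygous": 2.0,
    "compound_het": 2.0,
    "xl_hemizygous": 2.0,
    "inherited_maternal": 1.0,
    "inherited_paternal": 1.0,
}


def _score(call: InheritanceCall, vs: Sequence[TrioVariant]) -> float:
    cls = min(_CLASS_WEIGHT.get(v.clinical_class, 0.0) for v in vs)
    af = max(v.af_pop if v.af_pop is not None else 0.0 for v in vs)
    rarity = min(-math.log10(af + 1e-12), 12.0)
    return cls * 1e4 + _MODEL_WEIGHT.get(call.model, 0.0) * 1e3 + rarity


def prioritize_candidates(
    variants: Sequence[TrioVariant],
    proband_sex: str,
    panel: Sequence[PanelGene],
    config: PrioritizeConfig = PrioritizeConfig(),
) -> list:
    """Run the sequential cascade on in-memory variants; survivors ranked."""
    calls = determine_inheritance(variants, proband_sex)
    candidates = []
    for call in calls:
        if call.model == "unresolved":
            continue
        passed = ["inheritance"]
        if not frequency_filter(call, variants, config):
            continue
        passed.append("frequency")
        if not panel_mechanism_filter(call, variants, panel, config):
            continue
        passed.append("panel_mechanism")
        vs = _variants_for(call, variants)
        if not vs or any(
            v.clinical_class not in config.reportable_classes for v in vs
        ):
            continue
        passed.append("reportable_class")
        panel_gene = next((g for g in panel if g.symbol == call.gene), None)
        candidates.append(
            CandidateDiagnosis(
                inheritance=call,
                variants=tuple(vs),
                panel_gene=panel_gene,
                passed_filters=tuple(passed),
                score=_score(call, vs),
            )
        )
    candidates.sort(
        key=lambda c: (-c.score, c.inheritance.gene, c.inheritance.variant_keys)
    )
    return candidates


def prioritize_trio(
    vcf_path,
    pedigree: Pedigree,
    panel: Sequence[PanelGene],
    config: PrioritizeConfig = PrioritizeConfig(),
    annotation: AnnotationConfig = AnnotationConfig(),
) -> list:
    """Read a trio VCF and run the full prioritization cascade."""
    variants = list(read_trio_vcf(vcf_path, pedigree, annotation))
    return prioritize_candidates(variants, pedigree.proband_sex, panel, config)


# ---------------------------------------------------------------------------
# Replay of the packaged diagnostic cohort through the inheritance resolver
# ---------------------------------------------------------------------------

_ZYG_GT = {
    # (zygosity, origin) -> (proband, mother, father)
    ("hetero", "de_novo"): ("het", "hom_ref", "hom_ref"),
    ("hetero", "mother"): ("het", "het", "hom_ref"),
    ("hetero", "father"): ("het", "hom_ref", "het"),
    ("homo", "both"): ("hom_alt", "het", "het"),
    ("hemi", "mother"): ("hemi", "het", "hom_ref"),
}


def diagnostic_trio_configurations() -> dict:
    """Trio genotype configurations of the 29 diagnosed cohort cases.

    Reconstructed from the packaged per-variant fixture: each printed
    zygosity/origin cell maps to the trio genotypes it denotes. Returns
    {case_id: (variants, proband_sex)}.
    """
    sexes = {c.case_id: c.sex for c in load_cohort_fixture()}
    configs: dict = {}
    for row in load_diagnostic_variants():
        gts = _ZYG_GT[(row.zygosity, row.origin)]
        v = TrioVariant(
            chrom=row.chrom,
            pos=row.pos,
            ref=row.ref or "N",
            alt=row.alt or "<ALT>",
            gene=row.gene,
            consequence=row.consequence,
            gt_proband=gts[0],
            gt_mother=gts[1],
            gt_father=gts[2],
            af_pop=None,
            clinical_class=row.clinical_class,
        )
        configs.setdefault(row.case_id, ([], sexes[row.case_id]))[0].append(v)
    return configs


def replay_diagnostic_inheritance() -> dict:
    """Resolve each diagnosed case's transmission model from its genotypes.

    Returns {case_id: model}, where a case with two inherited-dominant calls
    in different genes (the double heterozygote) is classed
    ``inherited_dominant`` — two dominant variants, one per parent, not a
    compound heterozygote.
    """
    out = {}
    for case_id, (variants, sex) in diagnostic_trio_configurations().items():
        calls = [
            c
            for c in determine_inheritance(variants, sex)
            if c.model != "unresolved"
        ]
        if not calls:
            raise ValueError(f"case {case_id}: no model resolved")
        if any(c.model == "compound_het" for c in calls):
            out[case_id] = "compound_het"
        elif len(calls) == 1:
            model = calls[0].model
            if model in ("inherited_maternal", "inherited_paternal"):
                model = "inherited_dominant"
            out[case_id] = model
        elif all(
            c.model in ("inherited_maternal", "inherited_paternal") for c in calls
        ):
            out[case_id] = "inherited_dominant"
        else:
            raise ValueError(f"case {case_id}: ambiguous models {calls}")
    return out
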