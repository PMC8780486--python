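"""Cohort-level statistics: diagnostic yield, inheritance and etiology
breakdowns, and turnaround-time summaries.

Fractions are exact rationals internally; rounding to the one-decimal
percentage convention happens only at rendering.
"""

from __future__ import annotations

import statistics
from typing import Optional, Sequence

from .io import load_gene_etiology
from .model import BreakdownReport, CohortCase, IntegrityError, YieldReport

_STRATA = {
    "all": lambda c: True,
    "urgent": lambda c: c.urgent,
    "non_urgent": lambda c: not c.urgent,
}


def _stratify(cases: Sequence[CohortCase], stratum: str) -> list:
    try:
        pred = _STRATA[stratum]
    except KeyError:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {sorted(_STRATA)}")
    return [c for c in cases if pred(c)]


def diagnostic_yield(cases: Sequence[CohortCase], stratum: str = "all") -> YieldReport:
    """Fraction of cases in the stratum with a definitive molecular diagnosis."""
    selected = _stratify(cases, stratum)
    if not selected:
        raise ValueError(f"stratum {stratum!r} selects no cases")
    return YieldReport(
        n_total=len(selected),
        n_diagnosed=sum(c.diagnosed for c in selected),
        stratum=stratum,
    )


def _inheritance_category(case: CohortCase) -> str:
    if case.zygosity in ("homo", "compound_het"):
        return "autosomal_recessive"
    if case.zygosity == "hemi":
        return "x_linked"
    if case.zygosity == "hetero":
        if case.parental_origin == "de_novo":
            return "de_novo"
        if case.parental_origin in ("mother", "father", "both"):
            return "inherited_dominant"
    raise IntegrityError(
        f"case {case.case_id}: cannot map zygosity={case.zygosity!r} / "
        f"parental_origin={case.parental_origin!r} to an inheritance category"
    )


def inheritance_breakdown(cases: Sequence[CohortCase]) -> BreakdownReport:
    """Transmission-mode breakdown over the diagnosed cases."""
    diagnosed = [c for c in cases if c.diagnosed]
    counts = {
        "de_novo": 0,
        "autosomal_recessive": 0,
        "x_linked": 0,
        "inherited_dominant": 0,
    }
    for c in diagnosed:
        counts[_inheritance_category(c)] += 1
    return BreakdownReport(category_counts=counts, denominator=len(diagnosed))


def etiology_breakdown(
    cases: Sequence[CohortCase], gene_class_map: Optional[dict] = None
) -> BreakdownReport:
    """Etiological-class breakdown over the diagnosed cases.

    A case explained by two genes (semicolon-joined) must map to a single
    class and is counted once; an unmapped gene is an integrity error.
    """
    gene_class_map = gene_class_map or load_gene_etiology()
    diagnosed = [c for c in cases if c.diagnosed]
    counts = {"metabolic_mito": 0, "sarcomeric": 0, "rasopathy": 0, "ultra_rare": 0}
    for c in diagnosed:
        classes = set()
        for gene in c.gene.split(";"):
            if gene not in gene_class_map:
                raise IntegrityError(f"case {c.case_id}: gene {gene!r} not in etiology map")
            classes.add(gene_class_map[gene])
        if len(classes) != 1:
            raise IntegrityError(
                f"case {c.case_id}: genes map to multiple classes {sorted(classes)}"
            )
        counts[classes.pop()] += 1
    return BreakdownReport(category_counts=counts, denominator=len(diagnosed))


def _summary(values: list) -> Optional[dict]:
    if not values:
        return None
    return {
        "n": len(values),
        "mean": statistics.fmean(values),
        "median": statistics.median(values),
        "min": min(values),
        "max": max(values),
    }


def turnaround_summary(cases: Sequence[CohortCase]) -> dict:
    """Mean / median / range of T1 (preliminary) and T2 (definitive) times.

    Per stratum and field: a dict of summary statistics plus the count of
    cases without the field, or None when no case carries it (an explicit
    absent-result marker, never zero).
    """
    out: dict = {}
    for stratum in _STRATA:
        selected = _stratify(cases, stratum)
        entry = {}
        for fieldname in ("t1_days", "t2_days"):
            values = [getattr(c, fieldname) for c in selected]
            present = [v for v in values if v is not None]
            entry[fieldname] = {
                "summary": _summary(present),
                "n_missing": len(values) - len(present),
            }
        out[stratum] = entry
    return out
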