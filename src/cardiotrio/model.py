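"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive everywhere inside the package; conversion
to BED's 0-based half-open convention happens only at the output boundary
(:func:`cardiotrio.io.write_cnv_bed`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional


class IntegrityError(Exception):
    """Packaged or user-supplied data violates its own invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully closed genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases (0 if disjoint or on another chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(overlap/span(a), overlap/span(b)) — 1.0 for identical intervals."""
        ov = self.overlap(other)
        if ov == 0:
            return 0.0
        return min(ov / self.span, ov / other.span)


@dataclass(frozen=True)
class ReadPairRecord:
    """One aligned read of a pair, reduced to the fields the CNV caller uses.

    ``tlen`` follows SAM TLEN semantics: signed observed template length,
    positive on the leftmost mate, negative on the rightmost.
    """

    read_id: str
    chrom: str
    pos: int  # 1-based leftmost mapped base
    mapq: int
    tlen: int
    is_reverse: bool
    mate_is_reverse: bool
    is_first_in_pair: bool

    def __post_init__(self) -> None:
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"mapq must be in [0, 60], got {self.mapq}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


GENOTYPES = ("hom_ref", "het", "hom_alt", "hemi", "missing")
CONSEQUENCES = ("lof", "missense", "splice", "inframe", "other")
CLINICAL_CLASSES = (
    "pathogenic",
    "likely_pathogenic",
    "vus",
    "likely_benign",
    "benign",
    "unknown",
)


@dataclass(frozen=True)
class TrioVariant:
    """One ALT allele at one site with proband/mother/father genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str  # one of CONSEQUENCES
    gt_proband: str
    gt_mother: str
    gt_father: str
    af_pop: Optional[float] = None  # population allele frequency; None = absent/novel
    clinical_class: str = "unknown"
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        for gt in (self.gt_proband, self.gt_mother, self.gt_father):
            if gt not in GENOTYPES:
                raise ValueError(f"unknown genotype {gt!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.clinical_class not in CLINICAL_CLASSES:
            raise ValueError(f"unknown clinical class {self.clinical_class!r}")
        if self.af_pop is not None and not 0.0 <= self.af_pop <= 1.0:
            raise ValueError(f"af_pop must be in [0, 1], got {self.af_pop}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PanelGene:
    """A phenotype-panel gene with its accepted inheritance modes and mechanism."""

    symbol: str
    inheritance_modes: frozenset  # subset of {"AD", "AR", "XL"}
    mechanism: str  # "lof" | "non_lof" | "either"
    phenotype_tags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.inheritance_modes:
            raise ValueError(f"{self.symbol}: inheritance_modes must be non-empty")
        bad = set(self.inheritance_modes) - {"AD", "AR", "XL"}
        if bad:
            raise ValueError(f"{self.symbol}: unknown inheritance modes {bad}")
        if self.mechanism not in ("lof", "non_lof", "either"):
            raise ValueError(f"{self.symbol}: unknown mechanism {self.mechanism!r}")


@dataclass(frozen=True)
class CohortCase:
    """One study patient — the unit of cohort statistics."""

    case_id: str
    urgent: bool
    age_months: float
    sex: str  # "M" | "F"
    cm_type: str  # "HCM" | "DCM"
    cm_class: str  # "isolated" | "syndromic" | "metabolic"
    diagnosed: bool
    gene: Optional[str] = None  # ";"-joined when two genes explain one case
    zygosity: Optional[str] = None  # hetero | homo | hemi | compound_het
    parental_origin: Optional[str] = None  # de_novo | mother | father | both
    family_history: bool = False
    prenatal: bool = False
    t1_days: Optional[float] = None
    t2_days: Optional[float] = None

    def __post_init__(self) -> None:
        if self.diagnosed != (self.gene is not None):
            raise IntegrityError(
                f"case {self.case_id}: diagnosed must be true iff gene is present"
            )
        if self.sex not in ("M", "F"):
            raise IntegrityError(f"case {self.case_id}: bad sex {self.sex!r}")
        if self.cm_type not in ("HCM", "DCM"):
            raise IntegrityError(f"case {self.case_id}: bad cm_type {self.cm_type!r}")
        if self.cm_class not in ("isolated", "syndromic", "metabolic"):
            raise IntegrityError(f"case {self.case_id}: bad cm_class {self.cm_class!r}")
        if self.diagnosed and self.zygosity not in (
            "hetero",
            "homo",
            "hemi",
            "compound_het",
        ):
            raise IntegrityError(
                f"case {self.case_id}: diagnosed case needs a valid zygosity"
            )
        if self.t1_days is not None and self.t2_days is not None:
            if self.t1_days > self.t2_days:
                raise IntegrityError(
                    f"case {self.case_id}: t1_days > t2_days"
                )


@dataclass(frozen=True)
class CnvCall:
    """A candidate copy-number interval emitted by one of the CNV stages."""

    interval: GenomicInterval
    sv_type: str  # "dup" | "del" | "unknown"
    support: int
    source: str  # "discordant" | "depth" | "consensus"
    genes: tuple = ()
    rank: int = 1

    def __post_init__(self) -> None:
        if self.sv_type not in ("dup", "del", "unknown"):
            raise ValueError(f"bad sv_type {self.sv_type!r}")
        if self.source not in ("discordant", "depth", "consensus"):
            raise ValueError(f"bad source {self.source!r}")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


@dataclass(frozen=True)
class DiscordantCluster:
    """A group of discordant templates with very similar implied coordinates."""

    interval: GenomicInterval
    member_ids: tuple
    orientation_profile: dict = field(default_factory=dict)  # {"FR": n, "RF": n, "other": n}

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("cluster must have at least one member")

    @property
    def support(self) -> int:
        return len(self.member_ids)


INHERITANCE_MODELS = (
    "de_novo",
    "inherited_maternal",
    "inherited_paternal",
    "ar_homozygous",
    "compound_het",
    "xl_hemizygous",
    "unresolved",
)


@dataclass(frozen=True)
class InheritanceCall:
    """The resolved transmission model for a variant (or variant pair) in a trio."""

    model: str
    variant_keys: tuple  # of (chrom, pos, ref, alt); two keys iff compound_het
    gene: str
    mendelian_error: bool = False

    def __post_init__(self) -> None:
        if self.model not in INHERITANCE_MODELS:
            raise ValueError(f"unknown inheritance model {self.model!r}")
        if self.model == "compound_het" and len(self.variant_keys) != 2:
            raise ValueError("compound_het must carry exactly two variant keys")


@dataclass(frozen=True)
class CandidateDiagnosis:
    """A prioritized candidate: an inheritance call plus its surviving variants."""

    inheritance: InheritanceCall
    variants: tuple  # of TrioVariant
    panel_gene: Optional[PanelGene]
    passed_filters: tuple  # ordered filter names, for audit
    score: float


@dataclass(frozen=True)
class YieldReport:
    """Diagnostic yield over one stratum; the fraction is exact internally."""

    n_total: int
    n_diagnosed: int
    stratum: str

    @property
    def yield_fraction(self) -> Fraction:
        return Fraction(self.n_diagnosed, self.n_total)

    @property
    def yield_pct(self) -> float:
        """Percentage rounded to one decimal, the cohort tables' convention."""
        return round(float(self.yield_fraction) * 100, 1)


@dataclass(frozen=True)
class BreakdownReport:
    """Category counts over a stratum with exact fractions."""

    category_counts: dict
    denominator: int
    stratum: str = "diagnosed"

    @property
    def fractions(self) -> dict:
        return {
            k: Fraction(v, self.denominator) for k, v in self.category_counts.items()
        }

    def pct(self, category: str) -> float:
        return round(self.category_counts[category] / self.denominator * 100, 1)
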