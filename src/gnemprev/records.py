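"""Domain types for variant catalogs.

A catalog is a list of :class:`VariantRecord` objects keyed by a canonical
HGVS c. identifier on a fixed reference transcript.  Records carry the
functional consequence, provenance, clinical classification, an optional
in-silico annotation profile, and per-population allele counts as reported
by a gnomAD-style database.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Consequence(str, enum.Enum):
    """Functional consequence class of a coding variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_CANONICAL = "splice_canonical"
    SPLICE_REGION = "splice_region"
    SYNONYMOUS = "synonymous"
    START_LOSS = "start_loss"
    OTHER = "other"


class Provenance(str, enum.Enum):
    """Where a variant record came from."""

    LITERATURE = "literature"
    CLINVAR = "clinvar"
    LOVD = "lovd"
    HGMD = "hgmd"
    INHOUSE = "inhouse"
    GNOMAD_ONLY = "gnomad_only"


class ClinicalClass(str, enum.Enum):
    KNOWN_PATHOGENIC = "known_pathogenic"
    VUS = "vus"
    BENIGN = "benign"
    OTHER_DISEASE = "other_disease"


class SiftCall(str, enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    ABSENT = "absent"


class PolyPhenCall(str, enum.Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    DAMAGING = "damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    ABSENT = "absent"


class HsfCall(str, enum.Enum):
    """Human Splicing Finder verdict."""

    BIG_IMPACT = "big_impact"
    IMPORTANT_IMPACT = "important_impact"
    NONE = "none"
    ABSENT = "absent"


class ValidationError(ValueError):
    """An input value violates a structural invariant."""


@dataclass
class PopulationCounts:
    """Allele counts at one site in one population.

    ac / an / nhomalt follow the gnomAD convention: alternate allele count,
    total called alleles, and number of homozygous-alternate individuals.
    """

    ac: int
    an: int
    nhomalt: int = 0

    def __post_init__(self) -> None:
        if self.ac < 0 or self.an < 0 or self.nhomalt < 0:
            raise ValidationError(f"negative count in {self}")
        if self.ac > self.an:
            raise ValidationError(f"ac ({self.ac}) exceeds an ({self.an})")
        if 2 * self.nhomalt > self.ac:
            raise ValidationError(
                f"2*nhomalt ({2 * self.nhomalt}) exceeds ac ({self.ac})"
            )


@dataclass
class InSilicoProfile:
    """Precomputed in-silico annotations used by the triage vote.

    All fields are optional; absent tools never count as positive evidence.
    """

    cadd: float | None = None
    sift: SiftCall = SiftCall.ABSENT
    polyphen: PolyPhenCall = PolyPhenCall.ABSENT
    primateai: float | None = None
    spliceai: float | None = None
    hsf: HsfCall = HsfCall.ABSENT

    def __post_init__(self) -> None:
        for name in ("primateai", "spliceai"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} score {v} outside [0, 1]")


GLOBAL_POPULATION = "all"


@dataclass
class VariantRecord:
    """One variant: identity, classification, annotations, population counts."""

    key: str
    hgvs_c: str
    transcript: str
    hgvs_p: str | None = None
    consequence: Consequence = Consequence.OTHER
    provenance: set[Provenance] = field(default_factory=set)
    clinical_class: ClinicalClass = ClinicalClass.VUS
    profile: InSilicoProfile | None = None
    counts: dict[str, PopulationCounts] = field(default_factory=dict)

    def counts_for(self, population: str) -> PopulationCounts | None:
        """Counts for a population label; ``"all"`` falls back to the sum
        over per-population entries when no explicit global entry exists."""
        if population in self.counts:
            return self.counts[population]
        if population == GLOBAL_POPULATION and self.counts:
            return PopulationCounts(
                ac=sum(c.ac for c in self.counts.values()),
                an=sum(c.an for c in self.counts.values()),
                nhomalt=sum(c.nhomalt for c in self.counts.values()),
            )
        return None

    @property
    def global_af(self) -> float | None:
        """Global allele frequency AC/AN, or None when AN is unavailable/zero."""
        c = self.counts_for(GLOBAL_POPULATION)
        if c is None or c.an == 0:
            return None
        return c.ac / c.an

    def populations(self) -> list[str]:
        return [p for p in self.counts if p != GLOBAL_POPULATION]
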