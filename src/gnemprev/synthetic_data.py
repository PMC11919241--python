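"""Synthetic gnomAD-like catalogs with known ground truth.

The generator emulates the structure of a population allele-count export:
rare variants with true frequencies drawn from a log-uniform law, allele
counts sampled per ancestry group by drawing diploid genotypes (so the
``ac ≤ an`` and ``2·nhomalt ≤ ac`` invariants hold by construction), CADD
scores drawn from separated pathogenic-like and benign-like normal
distributions, and binary in-silico tool outputs flipped at configurable
error rates.  Every draw goes through one seeded generator, so identical
seeds give identical catalogs.

Default population sizes mirror the exome sample sizes of a gnomAD
v2.1.1-scale release (~125k individuals across eight ancestry groups).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .prevalence import CompatibilityPolicy, PolicyConfig, build_policy
from .records import (
    ClinicalClass,
    Consequence,
    HsfCall,
    InSilicoProfile,
    PolyPhenCall,
    PopulationCounts,
    Provenance,
    SiftCall,
    VariantRecord,
)
from .variant_io import DEFAULT_TRANSCRIPT

#: diploid individuals per ancestry group (gnomAD v2.1.1 exome-like)
DEFAULT_POPULATIONS: tuple[tuple[str, int], ...] = (
    ("afr", 2 * 8128),
    ("amr", 2 * 17296),
    ("asj", 2 * 5040),
    ("eas", 2 * 9197),
    ("fin", 2 * 10824),
    ("nfe", 2 * 56885),
    ("sas", 2 * 15308),
    ("oth", 2 * 3070),
)

DEFAULT_CLASS_MIX: dict[str, float] = {
    "missense": 0.70,
    "nonsense": 0.08,
    "frameshift": 0.07,
    "splice_canonical": 0.05,
    "synonymous": 0.10,
}

_BASES = "ACGT"


class SimulationConfig(BaseModel):
    """Generator settings; defaults describe the emulated study conditions."""

    n_variants: int = 60
    populations: tuple[tuple[str, int], ...] = DEFAULT_POPULATIONS
    class_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    freq_law: tuple[float, float] = (1e-6, 1e-3)  # log-uniform bounds on true q
    pathogenic_fraction: float = 0.5
    cadd_pathogenic: tuple[float, float] = (28.0, 5.0)  # (mean, sd)
    cadd_benign: tuple[float, float] = (8.0, 5.0)
    tool_fp: float = 0.05  # benign variant looks positive
    tool_fn: float = 0.05  # pathogenic variant looks negative
    seed: int = 0
    transcript: str = DEFAULT_TRANSCRIPT

    @field_validator("class_mix")
    @classmethod
    def _mix_sums_to_one(cls, v: dict[str, float]) -> dict[str, float]:
        if any(p < 0 for p in v.values()) or abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must be a probability distribution")
        for name in v:
            Consequence(name)  # unknown class -> config error
        return v

    @field_validator("populations")
    @classmethod
    def _an_positive(cls, v):
        if any(an <= 0 for _, an in v):
            raise ValueError("allele numbers must be positive")
        return v

    @field_validator("pathogenic_fraction", "tool_fp", "tool_fn")
    @classmethod
    def _probability(cls, v: float) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        return v


@dataclass
class GroundTruth:
    """What the generator knows: per-variant true frequency and labels."""

    true_q: dict[str, float]
    pathogenic: dict[str, bool]
    consequence: dict[str, Consequence]

    def policy(self, config: PolicyConfig | None = None) -> CompatibilityPolicy:
        records = [
            VariantRecord(key=k, hgvs_c=k, transcript="", consequence=c)
            for k, c in self.consequence.items()
        ]
        cfg = config or PolicyConfig(mild_list=())
        return build_policy(records, cfg)


def true_prevalence(
    truth: GroundTruth,
    policy: CompatibilityPolicy | None = None,
    pathogenic_only: bool = True,
) -> float:
    """Genotype frequency implied by the true allele frequencies.

    Quadratic form ``Σ_ij A_ij q_i q_j`` over ordered pairs of (by default)
    the truly pathogenic variants; ``policy=None`` allows every pair.
    """
    keys = [
        k for k in truth.true_q if (not pathogenic_only) or truth.pathogenic[k]
    ]
    q = np.array([truth.true_q[k] for k in keys])
    if not keys:
        return 0.0
    if policy is None:
        return float(np.sum(q)) ** 2
    A = policy.matrix(keys)
    return float(q @ A @ q)


def _draw_counts(rng: np.random.Generator, n_ind: int, q: float) -> PopulationCounts:
    # sample genotypes of n_ind diploids under HWE at frequency q
    nhom, nhet, _ = rng.multinomial(n_ind, [q * q, 2 * q * (1 - q), (1 - q) ** 2])
    return PopulationCounts(ac=2 * int(nhom) + int(nhet), an=2 * n_ind,
                            nhomalt=int(nhom))


def _flip(rng: np.random.Generator, positive: bool, fp: float, fn: float) -> bool:
    if positive:
        return rng.random() >= fn
    return rng.random() < fp


def _profile(
    rng: np.random.Generator, pathogenic: bool, consequence: Consequence,
    config: SimulationConfig,
) -> InSilicoProfile:
    mean, sd = config.cadd_pathogenic if pathogenic else config.cadd_benign
    cadd = float(rng.normal(mean, sd))
    fp, fn = config.tool_fp, config.tool_fn
    splice_variant = consequence in (
        Consequence.SPLICE_CANONICAL, Consequence.SPLICE_REGION
    )
    protein_pos = _flip(rng, pathogenic and not splice_variant, fp, fn)
    primate_pos = _flip(rng, pathogenic and consequence is Consequence.MISSENSE, fp, fn)
    splice_pos = _flip(rng, pathogenic and splice_variant, fp, fn)
    return InSilicoProfile(
        cadd=cadd,
        sift=SiftCall.DELETERIOUS if protein_pos else SiftCall.TOLERATED,
        polyphen=PolyPhenCall.PROBABLY_DAMAGING if protein_pos else PolyPhenCall.BENIGN,
        primateai=float(rng.uniform(0.81, 1.0)) if primate_pos
        else float(rng.uniform(0.0, 0.79)),
        spliceai=float(rng.uniform(0.55, 1.0)) if splice_pos
        else float(rng.uniform(0.0, 0.45)),
        hsf=HsfCall.IMPORTANT_IMPACT if splice_pos else HsfCall.NONE,
    )


def _synthetic_hgvs(rng: np.random.Generator, pos: int) -> str:
    ref, alt = rng.choice(list(_BASES), size=2, replace=False)
    return f"c.{pos}{ref}>{alt}"


def simulate_catalog(
    config: SimulationConfig | None = None,
) -> tuple[list[VariantRecord], GroundTruth]:
    """Generate a catalog of rare variants with known ground truth.

    Per variant: a true frequency from the log-uniform law, a consequence
    class from the mix, a pathogenicity flag, per-population counts from
    diploid genotype sampling, and an annotation profile whose CADD score
    comes from the pathogenic-like or benign-like normal model.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.freq_law
    classes = list(config.class_mix)
    probs = [config.class_mix[c] for c in classes]

    records: list[VariantRecord] = []
    true_q: dict[str, float] = {}
    pathogenic: dict[str, bool] = {}
    consequence_of: dict[str, Consequence] = {}
    positions = rng.choice(
        np.arange(1, 2300), size=config.n_variants, replace=False
    )
    for i in range(config.n_variants):
        q = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        consequence = Consequence(classes[rng.choice(len(classes), p=probs)])
        is_path = bool(rng.random() < config.pathogenic_fraction)
        hgvs_c = _synthetic_hgvs(rng, int(positions[i]))
        key = f"{config.transcript}:{hgvs_c}"
        counts = {
            pop: _draw_counts(rng, an // 2, q) for pop, an in config.populations
        }
        records.append(
            VariantRecord(
                key=key,
                hgvs_c=hgvs_c,
                transcript=config.transcript,
                consequence=consequence,
                provenance={Provenance.GNOMAD_ONLY},
                clinical_class=ClinicalClass.VUS,
                profile=_profile(rng, is_path, consequence, config),
                counts=counts,
            )
        )
        true_q[key] = q
        pathogenic[key] = is_path
        consequence_of[key] = consequence
    truth = GroundTruth(
        true_q=true_q, pathogenic=pathogenic, consequence=consequence_of
    )
    return records, truth
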