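"""Triage of variants of uncertain significance.

The pipeline mirrors standard practice for recessive-disease variant
screening: a minor-allele-frequency prefilter, CADD-score cutoffs derived
from normal fits to known-pathogenic and known-benign score distributions,
and a two-of-three in-silico vote (splicing, protein-impact, primate
constraint) for the residual gray zone.  The result is four nested variant
sets of decreasing confidence in pathogenicity:

* S1 — known pathogenic variants only;
* S2 — S1 plus uncertain variants above the upper CADD cutoff;
* S3 — S2 plus gray-zone variants passing the in-silico vote;
* S4 — S2 plus all gray-zone variants.
"""

from __future__ import annotations

import enum
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .records import (
    HsfCall,
    InSilicoProfile,
    PolyPhenCall,
    SiftCall,
    ValidationError,
    VariantRecord,
)

LIKELY_PATHOGENIC = "likely_pathogenic"
GRAY_ZONE = "gray_zone"
LIKELY_BENIGN = "likely_benign"

#: PrimateAI score above which the primate-constraint category votes positive
PRIMATEAI_THRESHOLD = 0.805
#: SpliceAI max delta score above which the splicing category votes positive
SPLICEAI_THRESHOLD = 0.5


class VariantSetLabel(str, enum.Enum):
    S1_KNOWN = "S1_known"
    S2_PLUS_CADD23 = "S2_plus_cadd23"
    S3_PLUS_GRAYZONE_VOTE = "S3_plus_grayzone_vote"
    S4_PLUS_ALL_CADD13 = "S4_plus_all_cadd13"


@dataclass
class VariantSet:
    label: VariantSetLabel
    members: list[str]


@dataclass
class CaddCutoffs:
    """CADD thresholds derived from normal fits to labelled score sets.

    ``lower`` is three (by default) standard deviations below the mean of
    the pathogenic fit; ``upper`` is the same distance above the mean of
    the benign fit.  Scores above ``upper`` are treated as likely
    pathogenic, scores below ``lower`` as likely benign.
    """

    lower: float
    upper: float
    pathogenic_fit: tuple[float, float]
    benign_fit: tuple[float, float]


# --------------------------------------------------------------------------
# MAF prefilter
# --------------------------------------------------------------------------

def maf_filter(
    vus: Iterable[VariantRecord],
    cutoff: float = 0.001,
    inclusive: bool = False,
) -> list[VariantRecord]:
    """Remove records whose global allele frequency exceeds ``cutoff``.

    The default convention removes on strict ``AF > cutoff`` (a frequency
    exactly at the cutoff is kept); ``inclusive=True`` removes ``AF >=
    cutoff`` instead.  Records without a usable global AN are skipped with
    a warning.  Input order is preserved.
    """
    kept: list[VariantRecord] = []
    for rec in vus:
        af = rec.global_af
        if af is None:
            warnings.warn(f"{rec.key}: no global AN>0; skipped by MAF filter")
            continue
        removed = af >= cutoff if inclusive else af > cutoff
        if not removed:
            kept.append(rec)
    return kept


# --------------------------------------------------------------------------
# CADD cutoff fitting and triage
# --------------------------------------------------------------------------

class CaddTriageClassifier(BaseEstimator, ClassifierMixin):
    """Three-way CADD triage fitted from labelled score distributions.

    Fit normal distributions to the CADD scores of known-pathogenic and
    known-benign variants; the decision thresholds sit ``k`` standard
    deviations inside each fit.  Prediction assigns ``likely_pathogenic``
    above the benign-derived upper cutoff, ``likely_benign`` below the
    pathogenic-derived lower cutoff, and ``gray_zone`` in between (missing
    scores, passed as NaN, always land in the gray zone).

    Parameters
    ----------
    k : float, default 3.0
        Number of standard deviations defining each cutoff.
    round_cutoffs : bool, default False
        Round both cutoffs to the nearest integer (reporting convention).
    ddof : int, default 1
        Delta degrees of freedom of the standard-deviation estimator
        (1 = sample sd).
    """

    def __init__(self, k: float = 3.0, round_cutoffs: bool = False, ddof: int = 1):
        self.k = k
        self.round_cutoffs = round_cutoffs
        self.ddof = ddof

    def fit(self, X, y):
        """Fit from scores ``X`` (1-d, or a single-column 2-d array) and
        labels ``y`` in {"pathogenic", "benign"}."""
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=object).reshape(-1)
        if X.shape != y.shape:
            raise ValueError("X and y must have the same length")
        path = X[y == "pathogenic"]
        ben = X[y == "benign"]
        for name, scores in (("pathogenic", path), ("benign", ben)):
            scores = scores[np.isfinite(scores)]
            if scores.size < 2:
                raise ValueError(
                    f"need at least 2 finite {name} scores to estimate a sd"
                )
        path = path[np.isfinite(path)]
        ben = ben[np.isfinite(ben)]
        self.pathogenic_fit_ = (float(np.mean(path)), float(np.std(path, ddof=self.ddof)))
        self.benign_fit_ = (float(np.mean(ben)), float(np.std(ben, ddof=self.ddof)))
        if self.pathogenic_fit_[1] == 0 or self.benign_fit_[1] == 0:
            warnings.warn("zero spread in a score set; cutoff collapses to the mean")
        lower = self.pathogenic_fit_[0] - self.k * self.pathogenic_fit_[1]
        upper = self.benign_fit_[0] + self.k * self.benign_fit_[1]
        if self.round_cutoffs:
            lower, upper = float(round(lower)), float(round(upper))
        if lower >= upper:
            warnings.warn(
                f"lower cutoff ({lower:g}) >= upper cutoff ({upper:g}); the "
                "score distributions are well separated and the gray zone "
                "is the interval between the cutoffs"
            )
        self.lower_ = lower
        self.upper_ = upper
        self.classes_ = np.array([GRAY_ZONE, LIKELY_BENIGN, LIKELY_PATHOGENIC])
        return self

    def predict(self, X):
        check_is_fitted(self, "lower_")
        X = np.asarray(X, dtype=float).reshape(-1)
        out = np.full(X.shape, GRAY_ZONE, dtype=object)
        finite = np.isfinite(X)
        # unified rule: reduces to (> upper -> path, < lower -> benign,
        # else gray) when lower < upper, and stays consistent when the
        # fitted distributions are separated enough that lower >= upper
        is_path = finite & (X > self.upper_) & (X >= self.lower_)
        is_benign = finite & (X < self.lower_) & (X <= self.upper_)
        out[is_path] = LIKELY_PATHOGENIC
        out[is_benign] = LIKELY_BENIGN
        return out

    def cutoffs_(self) -> CaddCutoffs:
        check_is_fitted(self, "lower_")
        return CaddCutoffs(
            lower=self.lower_,
            upper=self.upper_,
            pathogenic_fit=self.pathogenic_fit_,
            benign_fit=self.benign_fit_,
        )


def fit_cadd_cutoffs(
    pathogenic_scores: Sequence[float],
    benign_scores: Sequence[float],
    k: float = 3.0,
    round_cutoffs: bool = False,
    ddof: int = 1,
) -> CaddCutoffs:
    """Convenience wrapper over :class:`CaddTriageClassifier.fit`."""
    X = list(pathogenic_scores) + list(benign_scores)
    y = ["pathogenic"] * len(list(pathogenic_scores)) + ["benign"] * len(
        list(benign_scores)
    )
    clf = CaddTriageClassifier(k=k, round_cutoffs=round_cutoffs, ddof=ddof)
    return clf.fit(X, y).cutoffs_()


def cadd_triage(
    vus: Iterable[VariantRecord], cutoffs: CaddCutoffs
) -> dict[str, list[VariantRecord]]:
    """Partition records into likely_pathogenic / gray_zone / likely_benign.

    Records without a CADD score fall in the gray zone.  The three parts
    are pairwise disjoint and their union is the input.
    """
    clf = CaddTriageClassifier()
    clf.lower_, clf.upper_ = cutoffs.lower, cutoffs.upper
    clf.pathogenic_fit_ = cutoffs.pathogenic_fit
    clf.benign_fit_ = cutoffs.benign_fit
    clf.classes_ = np.array([GRAY_ZONE, LIKELY_BENIGN, LIKELY_PATHOGENIC])
    records = list(vus)
    scores = [
        (r.profile.cadd if r.profile and r.profile.cadd is not None else math.nan)
        for r in records
    ]
    parts: dict[str, list[VariantRecord]] = {
        LIKELY_PATHOGENIC: [],
        GRAY_ZONE: [],
        LIKELY_BENIGN: [],
    }
    if records:
        for rec, label in zip(records, clf.predict(scores)):
            parts[label].append(rec)
    return parts


# --------------------------------------------------------------------------
# gray-zone in-silico vote
# --------------------------------------------------------------------------

def gray_zone_vote(profile: InSilicoProfile | None) -> str:
    """Two-of-three in-silico vote for a gray-zone variant.

    ``pathogenic`` when HSF predicts a big impact on splicing, or when at
    least two of three categories are positive: (1) splicing — HSF
    important impact or SpliceAI > 0.5; (2) protein impact — SIFT
    deleterious or PolyPhen (probably) damaging; (3) PrimateAI > 0.805.
    Absent tools never vote positive.
    """
    if profile is None:
        return "not_pathogenic"
    if profile.hsf is HsfCall.BIG_IMPACT:
        return "pathogenic"
    splicing = profile.hsf is HsfCall.IMPORTANT_IMPACT or (
        profile.spliceai is not None and profile.spliceai > SPLICEAI_THRESHOLD
    )
    protein = profile.sift is SiftCall.DELETERIOUS or profile.polyphen in (
        PolyPhenCall.PROBABLY_DAMAGING,
        PolyPhenCall.DAMAGING,
    )
    primate = profile.primateai is not None and profile.primateai > PRIMATEAI_THRESHOLD
    votes = sum((splicing, protein, primate))
    return "pathogenic" if votes >= 2 else "not_pathogenic"


# --------------------------------------------------------------------------
# variant-set assembly
# --------------------------------------------------------------------------

def assemble_variant_sets(
    known: Iterable[str],
    triaged: Mapping[str, Iterable[str]],
    gray_votes: Mapping[str, str],
) -> list[VariantSet]:
    """Build the four nested sets S1 ⊆ S2 ⊆ S3 ⊆ S4.

    ``triaged`` maps the partition labels to VUS keys; ``gray_votes`` maps
    gray-zone keys to their vote verdict.  Known keys must not overlap the
    VUS keys.
    """
    known = list(dict.fromkeys(known))
    likely_path = list(triaged.get(LIKELY_PATHOGENIC, []))
    gray = list(triaged.get(GRAY_ZONE, []))
    vus_keys = set(likely_path) | set(gray) | set(triaged.get(LIKELY_BENIGN, []))
    overlap = set(known) & vus_keys
    if overlap:
        raise ValidationError(
            f"known and VUS keys overlap: {sorted(overlap)[:5]}"
        )
    s1 = list(known)
    s2 = s1 + likely_path
    s3 = s2 + [k for k in gray if gray_votes.get(k) == "pathogenic"]
    s4 = s2 + gray
    return [
        VariantSet(VariantSetLabel.S1_KNOWN, s1),
        VariantSet(VariantSetLabel.S2_PLUS_CADD23, s2),
        VariantSet(VariantSetLabel.S3_PLUS_GRAYZONE_VOTE, s3),
        VariantSet(VariantSetLabel.S4_PLUS_ALL_CADD13, s4),
    ]


# --------------------------------------------------------------------------
# precomputed pathogenicity-score classification (MAVERICK / AlphaMissense)
# --------------------------------------------------------------------------

class ScoreThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Three-way thresholding of precomputed [0, 1] pathogenicity scores.

    Scores strictly above ``pathogenic_min`` are pathogenic, strictly below
    ``benign_max`` benign, and the closed interval in between ambiguous
    (both boundaries fall in the ambiguous class).
    """

    def __init__(self, benign_max: float = 0.4, pathogenic_min: float = 0.8):
        self.benign_max = benign_max
        self.pathogenic_min = pathogenic_min

    def fit(self, X=None, y=None):
        self.classes_ = np.array(["ambiguous", "benign", "pathogenic"])
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float).reshape(-1)
        if np.any((X < 0) | (X > 1) | ~np.isfinite(X)):
            raise ValidationError("scores must lie in [0, 1]")
        out = np.full(X.shape, "ambiguous", dtype=object)
        out[X > self.pathogenic_min] = "pathogenic"
        out[X < self.benign_max] = "benign"
        return out


def classify_precomputed_scores(
    scores: Mapping[str, float],
    thresholds: tuple[float, float] = (0.4, 0.8),
) -> tuple[Counter, dict[str, str]]:
    """Classify per-variant scores; returns (class counts, per-key classes)."""
    benign_max, pathogenic_min = thresholds
    clf = ScoreThresholdClassifier(benign_max, pathogenic_min).fit()
    keys = list(scores)
    labels = clf.predict([scores[k] for k in keys]) if keys else []
    classes = dict(zip(keys, labels))
    return Counter(classes.values()), classes
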