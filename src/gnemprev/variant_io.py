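"""Reading, normalizing, merging, and cross-referencing variant tables.

Input tables are UTF-8 delimited text (tab or comma, auto-detected) with a
header row.  Column names can be remapped through a :class:`TableSchema`;
per-population allele counts are discovered from ``ac_<pop>`` / ``an_<pop>``
/ ``nhomalt_<pop>`` column triples, with bare ``ac`` / ``an`` / ``nhomalt``
taken as the global population.

HGVS handling is deliberately string-level: keys are canonicalized tokens
(case-folded nucleotides, lowercase edit keywords, transcript prefix), with
no sequence-aware validation or inter-transcript lifting.  Protein-only
records are rejected into a quarantine report rather than matched fuzzily.
"""

from __future__ import annotations

import io
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .records import (
    GLOBAL_POPULATION,
    ClinicalClass,
    Consequence,
    HsfCall,
    InSilicoProfile,
    PolyPhenCall,
    PopulationCounts,
    Provenance,
    SiftCall,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger(__name__)

DEFAULT_TRANSCRIPT = "NM_001128227"


class SchemaError(ValueError):
    """A mandatory column is missing or the schema config is malformed."""


class NormalizationError(ValueError):
    """An HGVS string could not be canonicalized."""


# --------------------------------------------------------------------------
# key normalization
# --------------------------------------------------------------------------

# edit keywords stay lowercase; longest first so "delins" wins over "del"/"ins"
_EDIT_KEYWORDS = ("delins", "del", "dup", "ins", "inv")
_NUCLEOTIDES = set("ACGTUN")
_LETTER_RUN = re.compile(r"[A-Za-z]+")


def _fold_letter_run(run: str) -> str:
    """Lowercase edit keywords, uppercase nucleotide runs; reject the rest."""
    out: list[str] = []
    rest = run.lower()
    while rest:
        for kw in _EDIT_KEYWORDS:
            if rest.startswith(kw):
                out.append(kw)
                rest = rest[len(kw):]
                break
        else:
            if all(ch.upper() in _NUCLEOTIDES for ch in rest):
                out.append(rest.upper())
                rest = ""
            else:
                raise NormalizationError(f"unrecognized token {run!r}")
    return "".join(out)


def normalize_variant_key(hgvs_c: str, transcript: str = DEFAULT_TRANSCRIPT) -> str:
    """Canonicalize a coding-DNA HGVS string into ``<transcript>:c.<body>``.

    Whitespace is stripped, the ``c.`` prefix is case-folded, nucleotides
    are uppercased and edit keywords (del/dup/ins/inv/delins) lowercased,
    so that differently written but identical variants map to one key.
    The function is idempotent on its own output (with the transcript
    prefix already attached).

    Raises :class:`NormalizationError` for protein-level or otherwise
    unparseable notation.
    """
    s = re.sub(r"\s+", "", hgvs_c)
    if not s:
        raise NormalizationError("empty HGVS string")
    # accept an already-canonical key for the same transcript
    if ":" in s:
        prefix, _, body = s.partition(":")
        if prefix != transcript:
            raise NormalizationError(
                f"key {hgvs_c!r} carries transcript {prefix!r}, expected {transcript!r}"
            )
        s = body
    if s[:2].lower() != "c.":
        raise NormalizationError(
            f"{hgvs_c!r} is not coding-DNA (c.) notation"
        )
    body = s[2:]
    if not body or not re.match(r"[-*]?\d", body):
        raise NormalizationError(f"{hgvs_c!r} lacks a parseable position")
    folded = _LETTER_RUN.sub(lambda m: _fold_letter_run(m.group(0)), body)
    return f"{transcript}:c.{folded}"


def normalize_catalog(
    records: Iterable[VariantRecord], transcript: str = DEFAULT_TRANSCRIPT
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Re-key every record onto ``transcript``; unparseable records are
    routed to a quarantine list together with the rejection reason."""
    kept: list[VariantRecord] = []
    quarantined: list[tuple[VariantRecord, str]] = []
    for rec in records:
        try:
            rec.key = normalize_variant_key(rec.hgvs_c, transcript)
            rec.transcript = transcript
            kept.append(rec)
        except NormalizationError as exc:
            quarantined.append((rec, str(exc)))
    return kept, quarantined


# --------------------------------------------------------------------------
# table reading
# --------------------------------------------------------------------------

#: canonical column names understood after schema renaming
_ANNOTATION_COLS = ("cadd", "sift", "polyphen", "primateai", "spliceai", "hsf")


@dataclass
class TableSchema:
    """Column mapping from source headers to canonical names.

    ``rename`` maps source column → canonical column.  Canonical columns:
    ``key`` or ``hgvs_c`` (one mandatory), ``hgvs_p``, ``transcript``,
    ``consequence``, ``clinical_class``, ``provenance``, the annotation
    columns, and ``ac[_<pop>]`` / ``an[_<pop>]`` / ``nhomalt[_<pop>]``.
    """

    rename: dict[str, str] = field(default_factory=dict)
    transcript: str = DEFAULT_TRANSCRIPT
    normalize_keys: bool = True

    @classmethod
    def from_mapping(cls, cfg: dict) -> "TableSchema":
        return cls(
            rename=dict(cfg.get("rename", {})),
            transcript=cfg.get("transcript", DEFAULT_TRANSCRIPT),
            normalize_keys=bool(cfg.get("normalize_keys", True)),
        )


def _is_missing(value) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return True
    s = str(value).strip()
    return s == "" or s.lower() in {"na", "nan", "none", "absent", ".", "-"}


def _parse_float(value, column: str, row: int) -> float | None:
    if _is_missing(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        warnings.warn(
            f"row {row}: malformed numeric value {value!r} in column "
            f"{column!r} treated as absent"
        )
        return None


def _parse_count(value, column: str, row: int) -> int | None:
    if _is_missing(value):
        return None
    try:
        return int(float(value))
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: malformed count {value!r} in column {column!r}"
        ) from None


def _parse_enum(enum_cls, value, absent):
    if _is_missing(value):
        return absent
    s = str(value).strip().lower().replace(" ", "_")
    try:
        return enum_cls(s)
    except ValueError:
        return absent


def _discover_populations(columns: Sequence[str]) -> list[str]:
    pops = []
    for col in columns:
        m = re.match(r"^ac_(\w+)$", col)
        if m and f"an_{m.group(1)}" in columns:
            pops.append(m.group(1))
    return pops


def read_variant_table(
    source: str | Path | TextIO,
    schema: TableSchema | dict | None = None,
) -> list[VariantRecord]:
    """Read a delimited variant table into records.

    Missing annotation cells become "absent"; malformed annotation numerics
    are reported as warnings and treated as absent; malformed or invariant-
    violating counts raise :class:`ValidationError` naming the row.
    """
    if schema is None:
        schema = TableSchema()
    elif isinstance(schema, dict):
        schema = TableSchema.from_mapping(schema)

    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    else:
        text = source.read()
        df = pd.read_csv(io.StringIO(text), sep=None, engine="python", dtype=str)
    df = df.rename(columns=schema.rename)
    df.columns = [c.strip().lower() for c in df.columns]

    if "key" not in df.columns and "hgvs_c" not in df.columns:
        raise SchemaError("table must contain a 'key' or 'hgvs_c' column")

    pops = _discover_populations(list(df.columns))
    has_global = "ac" in df.columns and "an" in df.columns

    records: list[VariantRecord] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is line 1
        hgvs_c = row.get("hgvs_c") if "hgvs_c" in df.columns else None
        raw_key = row.get("key") if "key" in df.columns else None
        ident = raw_key if not _is_missing(raw_key) else hgvs_c
        if _is_missing(ident):
            raise ValidationError(f"row {rownum}: no variant identifier")
        ident = str(ident)
        if schema.normalize_keys:
            key = normalize_variant_key(ident, schema.transcript)
        else:
            key = ident

        counts: dict[str, PopulationCounts] = {}
        labels = ([GLOBAL_POPULATION] if has_global else []) + pops
        for pop in labels:
            suffix = "" if pop == GLOBAL_POPULATION else f"_{pop}"
            ac = _parse_count(row.get(f"ac{suffix}"), f"ac{suffix}", rownum)
            an = _parse_count(row.get(f"an{suffix}"), f"an{suffix}", rownum)
            if ac is None or an is None:
                continue
            nh = _parse_count(row.get(f"nhomalt{suffix}"), f"nhomalt{suffix}", rownum)
            try:
                counts[pop] = PopulationCounts(ac=ac, an=an, nhomalt=nh or 0)
            except ValidationError as exc:
                raise ValidationError(f"row {rownum}: {exc}") from None

        profile = None
        if any(c in df.columns for c in _ANNOTATION_COLS):
            profile = InSilicoProfile(
                cadd=_parse_float(row.get("cadd"), "cadd", rownum),
                sift=_parse_enum(SiftCall, row.get("sift"), SiftCall.ABSENT),
                polyphen=_parse_enum(
                    PolyPhenCall, row.get("polyphen"), PolyPhenCall.ABSENT
                ),
                primateai=_parse_float(row.get("primateai"), "primateai", rownum),
                spliceai=_parse_float(row.get("spliceai"), "spliceai", rownum),
                hsf=_parse_enum(HsfCall, row.get("hsf"), HsfCall.ABSENT),
            )

        prov: set[Provenance] = set()
        if "provenance" in df.columns and not _is_missing(row.get("provenance")):
            for token in re.split(r"[;,|]", str(row["provenance"])):
                token = token.strip().lower()
                if token:
                    prov.add(Provenance(token))

        records.append(
            VariantRecord(
                key=key,
                hgvs_c=str(hgvs_c) if not _is_missing(hgvs_c) else key.split(":", 1)[-1],
                hgvs_p=None if _is_missing(row.get("hgvs_p")) else str(row["hgvs_p"]),
                transcript=schema.transcript,
                consequence=_parse_enum(
                    Consequence, row.get("consequence"), Consequence.OTHER
                ),
                provenance=prov,
                clinical_class=_parse_enum(
                    ClinicalClass, row.get("clinical_class"), ClinicalClass.VUS
                ),
                profile=profile,
                counts=counts,
            )
        )
    return records


def write_catalog(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write a normalized catalog as a TSV (one row per record)."""
    rows = []
    for r in records:
        row: dict = {
            "key": r.key,
            "hgvs_c": r.hgvs_c,
            "hgvs_p": r.hgvs_p or "",
            "transcript": r.transcript,
            "consequence": r.consequence.value,
            "clinical_class": r.clinical_class.value,
            "provenance": ";".join(sorted(p.value for p in r.provenance)),
        }
        if r.profile is not None:
            p = r.profile
            row.update(
                cadd="" if p.cadd is None else p.cadd,
                sift=p.sift.value,
                polyphen=p.polyphen.value,
                primateai="" if p.primateai is None else p.primateai,
                spliceai="" if p.spliceai is None else p.spliceai,
                hsf=p.hsf.value,
            )
        for pop, c in r.counts.items():
            suffix = "" if pop == GLOBAL_POPULATION else f"_{pop}"
            row[f"ac{suffix}"] = c.ac
            row[f"an{suffix}"] = c.an
            row[f"nhomalt{suffix}"] = c.nhomalt
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# merge / exclude / cross-reference
# --------------------------------------------------------------------------

# precedence on clinical-class conflicts during merge (highest wins)
_CLASS_PRECEDENCE = {
    ClinicalClass.KNOWN_PATHOGENIC: 3,
    ClinicalClass.OTHER_DISEASE: 2,
    ClinicalClass.VUS: 1,
    ClinicalClass.BENIGN: 0,
}


def _merge_pair(a: VariantRecord, b: VariantRecord) -> VariantRecord:
    if _CLASS_PRECEDENCE[b.clinical_class] > _CLASS_PRECEDENCE[a.clinical_class]:
        a, b = b, a
    if a.clinical_class is not b.clinical_class:
        logger.info(
            "merge conflict on %s: clinical_class %s vs %s -> %s",
            a.key, a.clinical_class.value, b.clinical_class.value,
            a.clinical_class.value,
        )
    merged = VariantRecord(
        key=a.key,
        hgvs_c=a.hgvs_c,
        hgvs_p=a.hgvs_p or b.hgvs_p,
        transcript=a.transcript,
        consequence=a.consequence if a.consequence is not Consequence.OTHER else b.consequence,
        provenance=a.provenance | b.provenance,
        clinical_class=a.clinical_class,
        profile=a.profile or b.profile,
        counts=dict(a.counts),
    )
    for pop, c in b.counts.items():
        if pop not in merged.counts:
            merged.counts[pop] = c
        elif (c.ac, c.an, c.nhomalt) != (
            merged.counts[pop].ac, merged.counts[pop].an, merged.counts[pop].nhomalt
        ):
            logger.info("merge conflict on %s: counts for %s differ; keeping first",
                        a.key, pop)
    return merged


def merge_and_dedupe(lists: Iterable[Iterable[VariantRecord]]) -> list[VariantRecord]:
    """Union several catalogs into one record per canonical key.

    Provenance sets are unioned; clinical-class conflicts resolve by
    precedence known_pathogenic > other_disease > vus > benign with every
    conflict logged.  First-seen order of keys is preserved, so the
    operation is idempotent.
    """
    by_key: dict[str, VariantRecord] = {}
    for records in lists:
        for rec in records:
            if rec.key in by_key:
                by_key[rec.key] = _merge_pair(by_key[rec.key], rec)
            else:
                by_key[rec.key] = rec
    return list(by_key.values())


def exclude_other_disease(
    catalog: Iterable[VariantRecord], exclusion: Iterable[str]
) -> list[VariantRecord]:
    """Drop records attributed to other GNE-related diseases.

    Exclusion keys absent from the catalog produce a warning, not an error.
    """
    catalog = list(catalog)
    exclusion = set(exclusion)
    present = {r.key for r in catalog}
    for missing in sorted(exclusion - present):
        warnings.warn(f"exclusion key {missing} not found in catalog")
    return [r for r in catalog if r.key not in exclusion]


def cross_reference_population_db(
    curated: Iterable[VariantRecord], popdb: Iterable[VariantRecord]
) -> tuple[list[VariantRecord], list[str]]:
    """Attach population counts from a database export to a curated list.

    Returns ``(matched, unmatched_keys)``; the two partition the curated
    input.  A duplicated key within the database table is an error because
    its counts would be ambiguous.
    """
    db: dict[str, VariantRecord] = {}
    for rec in popdb:
        if rec.key in db:
            raise ValidationError(f"duplicate key in population table: {rec.key}")
        db[rec.key] = rec
    matched: list[VariantRecord] = []
    unmatched: list[str] = []
    for rec in curated:
        hit = db.get(rec.key)
        if hit is None:
            unmatched.append(rec.key)
            continue
        out = VariantRecord(
            key=rec.key,
            hgvs_c=rec.hgvs_c,
            hgvs_p=rec.hgvs_p or hit.hgvs_p,
            transcript=rec.transcript,
            consequence=rec.consequence
            if rec.consequence is not Consequence.OTHER
            else hit.consequence,
            provenance=rec.provenance | hit.provenance,
            clinical_class=rec.clinical_class,
            profile=rec.profile or hit.profile,
            counts=dict(hit.counts),
        )
        matched.append(out)
    return matched, unmatched
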