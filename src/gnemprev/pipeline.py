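"""End-to-end pipeline: normalize → triage → estimate → report.

The pipeline is a pure function of its inputs, configuration, and seed:
run metadata records the parameters and SHA-256 checksums of every input
table so a run can be audited and reproduced.  Stage-level record counts
are logged so filter attrition is visible (known/VUS counts, MAF-filter
survivors, CADD partition sizes, gray-zone vote passes).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import prevalence as prev
from . import triage as tri
from . import variant_io as vio
from .records import ClinicalClass, GLOBAL_POPULATION

logger = logging.getLogger(__name__)

METHODS = ("ml", "bayes_mean", "bayes_var")


class RunConfig(BaseModel):
    """Configuration for one pipeline run (paths resolve relative to cwd)."""

    known_tables: list[str]
    vus_table: str
    popdb_table: str | None = None  # counts for the known list, if separate
    exclusion_keys: str | None = None  # text file, one canonical key per line
    transcript: str = vio.DEFAULT_TRANSCRIPT
    maf_cutoff: float = 0.001
    maf_inclusive: bool = False
    k: float = 3.0
    round_cutoffs: bool = False
    cadd_cutoffs: tuple[float, float] | None = None  # (lower, upper) override
    methods: list[str] = Field(default_factory=lambda: ["ml"])
    severity: bool = True
    mild_list: list[str] | None = None
    bootstrap: int | None = None
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _policy_config(cfg: RunConfig) -> prev.PolicyConfig:
    if cfg.mild_list is None:
        return prev.PolicyConfig()
    return prev.PolicyConfig(
        mild_list=tuple(
            vio.normalize_variant_key(k, cfg.transcript) for k in cfg.mild_list
        )
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle as a dict and
    writes estimates TSV, variant-set JSON, decision-trace TSV, and run
    metadata JSON into ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = vio.TableSchema(transcript=config.transcript)

    # -- stage 1: curated known-pathogenic catalog ------------------------
    stage = "normalize"
    try:
        known_lists = [vio.read_variant_table(p, schema) for p in config.known_tables]
        known = vio.merge_and_dedupe(known_lists)
        logger.info("%s: %d unique known variants after merge", stage, len(known))
        if config.exclusion_keys:
            keys = [
                vio.normalize_variant_key(line, config.transcript)
                for line in Path(config.exclusion_keys).read_text().split()
                if line.strip()
            ]
            known = vio.exclude_other_disease(known, keys)
            logger.info("%s: %d known variants after exclusions", stage, len(known))
        known = [
            r for r in known if r.clinical_class is not ClinicalClass.OTHER_DISEASE
        ]

        popdb = vio.read_variant_table(config.vus_table, schema)
        if config.popdb_table:
            popdb = vio.merge_and_dedupe(
                [popdb, vio.read_variant_table(config.popdb_table, schema)]
            )
        known, unmatched = vio.cross_reference_population_db(known, popdb)
        logger.info(
            "%s: %d known variants matched in population table, %d unmatched",
            stage, len(known), len(unmatched),
        )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # -- stage 2: triage ---------------------------------------------------
    stage = "triage"
    try:
        known_keys = {r.key for r in known}
        vus = [
            r
            for r in popdb
            if r.key not in known_keys
            and r.clinical_class is ClinicalClass.VUS
        ]
        benign = [
            r for r in popdb if r.clinical_class is ClinicalClass.BENIGN
        ]
        logger.info("%s: %d VUS, %d benign-labelled records", stage, len(vus), len(benign))

        filtered = tri.maf_filter(vus, config.maf_cutoff, config.maf_inclusive)
        logger.info("%s: %d VUS pass the MAF filter", stage, len(filtered))

        if config.cadd_cutoffs is not None:
            lower, upper = config.cadd_cutoffs
            cutoffs = tri.CaddCutoffs(lower, upper, (math.nan, math.nan),
                                      (math.nan, math.nan))
        else:
            path_scores = [
                r.profile.cadd for r in known
                if r.profile and r.profile.cadd is not None
            ]
            benign_scores = [
                r.profile.cadd for r in benign
                if r.profile and r.profile.cadd is not None
            ]
            cutoffs = tri.fit_cadd_cutoffs(
                path_scores, benign_scores, k=config.k,
                round_cutoffs=config.round_cutoffs,
            )
        logger.info("%s: CADD cutoffs lower=%.3f upper=%.3f", stage,
                    cutoffs.lower, cutoffs.upper)

        parts = tri.cadd_triage(filtered, cutoffs)
        logger.info(
            "%s: %d likely pathogenic / %d gray zone / %d likely benign", stage,
            len(parts[tri.LIKELY_PATHOGENIC]), len(parts[tri.GRAY_ZONE]),
            len(parts[tri.LIKELY_BENIGN]),
        )
        votes = {
            r.key: tri.gray_zone_vote(r.profile) for r in parts[tri.GRAY_ZONE]
        }
        logger.info("%s: %d gray-zone variants pass the in-silico vote", stage,
                    sum(v == "pathogenic" for v in votes.values()))
        sets = tri.assemble_variant_sets(
            sorted(known_keys),
            {label: [r.key for r in recs] for label, recs in parts.items()},
            votes,
        )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    sets_json = {s.label.value: s.members for s in sets}
    (out / "variant_sets.json").write_text(json.dumps(sets_json, indent=2))

    trace_rows = []
    for part, recs in parts.items():
        for r in recs:
            trace_rows.append(
                {
                    "key": r.key,
                    "global_af": r.global_af,
                    "cadd": r.profile.cadd if r.profile else None,
                    "cadd_class": part,
                    "gray_vote": votes.get(r.key, ""),
                }
            )
    pd.DataFrame(trace_rows).to_csv(out / "decision_trace.tsv", sep="\t", index=False)

    # -- stage 3: estimates ------------------------------------------------
    stage = "estimate"
    try:
        by_key = {r.key: r for r in popdb}
        by_key.update({r.key: r for r in known})
        frames = []
        for vset in sets:
            catalog = [by_key[k] for k in vset.members if k in by_key]
            policy = prev.build_policy(catalog, _policy_config(config))
            for method in config.methods:
                for pol in ([None, policy] if config.severity else [None]):
                    df = prev.per_population_estimates(
                        catalog, method=method, policy=pol,
                        set_label=vset.label.value,
                    )
                    if config.bootstrap and catalog:
                        lo, hi = prev.bootstrap_ci(
                            catalog, method=method, policy=pol,
                            replicates=config.bootstrap, seed=config.seed,
                        )
                        df.loc[df["population"] == GLOBAL_POPULATION, "ci_lo"] = lo
                        df.loc[df["population"] == GLOBAL_POPULATION, "ci_hi"] = hi
                    frames.append(df)
        estimates = pd.concat(frames, ignore_index=True)
        estimates["value_per_million"] = estimates["value_per_million"].round(2)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)

    inputs = [*config.known_tables, config.vus_table]
    if config.popdb_table:
        inputs.append(config.popdb_table)
    if config.exclusion_keys:
        inputs.append(config.exclusion_keys)
    try:
        pkg_version = _pkg_version("gnemprev")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    metadata = {
        "package_version": pkg_version,
        "seed": config.seed,
        "parameters": json.loads(config.model_dump_json()),
        "input_checksums": {p: _sha256(p) for p in inputs},
        "cadd_cutoffs": {"lower": cutoffs.lower, "upper": cutoffs.upper},
        "stage_counts": {
            "known_matched": len(known),
            "known_unmatched": len(unmatched),
            "vus": len(vus),
            "vus_after_maf": len(filtered),
            "cadd_likely_pathogenic": len(parts[tri.LIKELY_PATHOGENIC]),
            "cadd_gray_zone": len(parts[tri.GRAY_ZONE]),
            "cadd_likely_benign": len(parts[tri.LIKELY_BENIGN]),
            "gray_zone_vote_pass": sum(
                v == "pathogenic" for v in votes.values()
            ),
        },
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2))

    return {
        "estimates": estimates,
        "variant_sets": sets_json,
        "metadata": metadata,
    }
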