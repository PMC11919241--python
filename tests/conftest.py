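import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from gnemprev.records import (
    Consequence,
    InSilicoProfile,
    PopulationCounts,
    VariantRecord,
)
from gnemprev.variant_io import DEFAULT_TRANSCRIPT


def make_record(
    hgvs_c: str,
    consequence: Consequence = Consequence.MISSENSE,
    ac: int | None = None,
    an: int | None = None,
    cadd: float | None = None,
    pops: dict | None = None,
    **kwargs,
) -> VariantRecord:
    """Minimal record builder used across test modules."""
    counts = {}
    if ac is not None and an is not None:
        counts["all"] = PopulationCounts(ac=ac, an=an)
    for pop, (pac, pan) in (pops or {}).items():
        counts[pop] = PopulationCounts(ac=pac, an=pan)
    profile = InSilicoProfile(cadd=cadd) if cadd is not None else kwargs.pop("profile", None)
    return VariantRecord(
        key=f"{DEFAULT_TRANSCRIPT}:{hgvs_c}",
        hgvs_c=hgvs_c,
        transcript=DEFAULT_TRANSCRIPT,
        consequence=consequence,
        counts=counts,
        profile=profile,
        **kwargs,
    )


@pytest.fixture
def record_factory():
    return make_record
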