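import pytest
from hypothesis import settings

from phosphoflow.evidence_io import EvidenceRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_record(
    protein="P1",
    start=1,
    sequence="AAASAAK",
    phospho=(),
    probs=None,
    ratio=1.0,
    replicate="r1",
    setup="SR",
    mods=(),
):
    """Terse EvidenceRecord factory for unit tests; ``phospho`` and the keys
    of ``probs`` are 1-based protein positions."""
    phospho = tuple(sorted(phospho))
    if probs is None:
        probs = {p: 1.0 for p in phospho}
    return EvidenceRecord(
        protein_id=protein,
        peptide_start=start,
        bare_sequence=sequence,
        modified_sequence=f"_{sequence}_",
        phospho_positions=phospho,
        per_position_probability=dict(probs),
        other_mods=frozenset(mods),
        ratio_hl=ratio,
        replicate_id=replicate,
        setup_id=setup,
    )


@pytest.fixture
def record_factory():
    return make_record
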