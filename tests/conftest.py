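import numpy as np
import pytest

from terminopep import (
    ConditionModel,
    DigestParams,
    PeptideQuantRecord,
    ProteaseModel,
    ProteinRecord,
)

# one protein where every residue occurs exactly once, so subsite windows
# can be read off by eye
TOY_SEQ = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def toy_protein() -> ProteinRecord:
    return ProteinRecord(id="P1", sequence=TOY_SEQ)


@pytest.fixture
def write_fasta_text(tmp_path):
    def _write(text: str, name: str = "ref.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def make_record(seq: str, conf: float = 0.99, **intensities) -> PeptideQuantRecord:
    """Quant record with keyword conditions, e.g. make_record('AC', A=[1, 2])."""
    return PeptideQuantRecord(
        sequence=seq, confidence=conf,
        intensities={k: list(v) for k, v in intensities.items()},
    )


def trp_p2prime_model(efficiency: float = 0.9, fold: float = 10.0) -> ProteaseModel:
    """A protease preferring Trp at P2' (fold-change vs every other residue)."""
    return ProteaseModel.from_preferences(
        "trp_p2prime", {"P2'": {"W": fold}}, efficiency=efficiency
    )


def trp_condition(label: str = "SV", **kw) -> ConditionModel:
    return ConditionModel(label, [trp_p2prime_model(**kw)])


def uniform_condition(label: str = "raw", efficiency: float = 0.12) -> ConditionModel:
    return ConditionModel(label, [ProteaseModel.uniform(efficiency=efficiency)])
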