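import csv
import json
from pathlib import Path

import pytest

from retellchain import synthetic_data as sd
from retellchain.concepts import SenseInventory
from retellchain.lexical_norms import fixture_norms

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def inventory() -> SenseInventory:
    return SenseInventory.fixture()


@pytest.fixture(scope="session")
def norms():
    return fixture_norms()


@pytest.fixture(scope="session")
def sim_lexicon() -> sd.SimLexicon:
    return sd.build_toy_lexicon(120, seed=1)


@pytest.fixture(scope="session")
def human_params() -> sd.SimParams:
    return sd.load_preset("human")


@pytest.fixture(scope="session")
def llm_params() -> sd.SimParams:
    return sd.load_preset("llm")


@pytest.fixture(scope="session")
def example_retellings() -> list[dict]:
    with open(DATA / "example_retellings.csv", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


@pytest.fixture(scope="session")
def golden_annotations() -> list[dict]:
    return json.loads((DATA / "example_annotations.json").read_text(encoding="utf-8"))


def make_chain_rows(chain_id="c1", producer="human", condition="happy", texts=None):
    """Four canonical corpus rows for one chain."""
    if texts is None:
        texts = [
            "They saw the dog by the river and the dog ran to the water. "
            "The man watched the bird and the cat sat by the tree.",
            "They saw the dog near the river and it ran into the water. "
            "A man watched the bird while the cat sat under the tree.",
            "The dog ran to the river and the man watched a bird. "
            "The cat stayed close to the old tree near the house.",
            "A dog ran toward the river while the man watched the birds. "
            "The old cat rested quietly by the tree near their house.",
        ]
    return [
        {
            "chain_id": chain_id,
            "retelling_index": i,
            "producer": producer,
            "condition": condition,
            "text": text,
        }
        for i, text in enumerate(texts)
    ]


def write_corpus_csv(path: Path, rows: list[dict]) -> Path:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["chain_id", "retelling_index", "producer", "condition", "text"]
        )
        writer.writeheader()
        writer.writerows(rows)
    return path
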