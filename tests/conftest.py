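import pandas as pd
import pytest

from distractorlab import AnswerKey, ResponseMatrix, generate_exam
from distractorlab.synthdata import ExamGeneratorConfig


def make_exam(columns: dict[str, list[str]], correct: dict[str, str]):
    """Build a (ResponseMatrix, AnswerKey) pair from per-item choice lists."""
    n = len(next(iter(columns.values())))
    table = pd.DataFrame(columns, index=[f"c{i + 1}" for i in range(n)])
    return ResponseMatrix(table), AnswerKey(correct=dict(correct))


@pytest.fixture(scope="session")
def default_exam():
    """One synthetic exam at the default study-sized configuration."""
    return generate_exam(seed=11)


@pytest.fixture(scope="session")
def small_exam():
    """A quick 100-candidate, 20-item synthetic exam."""
    cfg = ExamGeneratorConfig(n_candidates=100, n_items=20)
    return generate_exam(cfg, seed=7)


@pytest.fixture
def tiny_exam():
    """4 candidates x 3 items with hand-checkable statistics."""
    return make_exam(
        {
            "i1": ["A", "A", "B", "C"],
            "i2": ["B", "B", "B", "A"],
            "i3": ["E", "D", "E", "E"],
        },
        {"i1": "A", "i2": "B", "i3": "E"},
    )
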