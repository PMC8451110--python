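import itertools

import numpy as np
import pytest

from nsltpkit.records import EightCMMatch, ProteinRecord
from nsltpkit.screen import ScreenConfig


@pytest.fixture
def config():
    return ScreenConfig()


def random_protein(rng: np.random.Generator, length: int, cys_prob: float = 0.06) -> str:
    """Random sequence with elevated cysteine frequency (for motif search tests)."""
    others = "ADEFGHIKLMNPQRSTVWY"
    letters = []
    for _ in range(length):
        if rng.random() < cys_prob:
            letters.append("C")
        else:
            letters.append(others[int(rng.integers(0, len(others)))])
    return "".join(letters)


def brute_force_8cm(sequence: str, config: ScreenConfig) -> list[EightCMMatch]:
    """Independent oracle: exhaustive enumeration of all cysteine 8-subsets."""
    cys = [i + 1 for i, res in enumerate(sequence) if res == "C"]  # 1-based
    bounds = config.gap_bounds
    out = []
    for combo in itertools.combinations(cys, 8):
        p = combo
        if p[3] != p[2] + 1 or p[5] != p[4] + 2:
            continue
        gaps = (p[1] - p[0] - 1, p[2] - p[1] - 1, p[4] - p[3] - 1,
                p[6] - p[5] - 1, p[7] - p[6] - 1)
        if any(not (lo <= g <= hi) for g, (lo, hi) in zip(gaps, bounds)):
            continue
        if p[7] - p[0] + 1 > config.max_span:
            continue
        out.append(
            EightCMMatch(cys_positions=p, gaps=gaps, cxc_x=sequence[p[4]],
                         span=(p[0], p[7]))
        )
    out.sort(key=lambda m: (m.span[0], m.span[1] - m.span[0]))
    return out


@pytest.fixture
def make_protein():
    def _make(sequence: str, name: str = "P1") -> ProteinRecord:
        return ProteinRecord(id=name, sequence=sequence)

    return _make
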