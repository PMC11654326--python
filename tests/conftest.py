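import numpy as np
import pytest

import minlinmo as mm


@pytest.fixture
def write_csv(tmp_path):
    """Write raw CSV text to a temp file and return its path."""
    def _write(text: str, name: str = "data.csv") -> str:
        path = tmp_path / name
        path.write_text(text)
        return str(path)
    return _write


@pytest.fixture
def planted_small():
    """Two strong planted signals among 2,000 noise columns (n=500)."""
    truth = mm.SyntheticTruth(support=[3, 17], effects=[1.5, -1.0], noise_sd=0.5)
    m, y, truth = mm.generate_planted(500, 2000, truth, seed=42)
    return m, y, truth


def brute_force_screen(m: mm.PredictorMatrix, y: mm.OutcomeVector,
                       threshold: float) -> list[tuple[int, float]]:
    """Independent O(np) re-screen: per-column textbook correlation, then sort."""
    entries = []
    yv = y.values
    for j in range(m.n_predictors):
        x = m.values[:, j]
        n = len(yv)
        sx, sy = x.sum(), yv.sum()
        sxx, syy, sxy = (x * x).sum(), (yv * yv).sum(), (x * yv).sum()
        den = np.sqrt(n * sxx - sx * sx) * np.sqrt(n * syy - sy * sy)
        if den == 0:
            continue
        r = abs((n * sxy - sx * sy) / den)
        if r > threshold:
            entries.append((j, r))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries
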