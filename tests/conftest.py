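import numpy as np
import pytest

import tatasel as ts


@pytest.fixture(scope="session")
def model():
    """The packaged PWM, dinucleotide scales and default parameters."""
    return ts.load_model()


@pytest.fixture(scope="session")
def catalog():
    return ts.default_annotations()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_promoter(rng, length=70, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[b] for b in rng.choice(4, size=length, p=p))


def brute_force_affinity(sequence, pwm, scales, params):
    """Independent enumeration of every window on both strands.

    Recomputes each window score from the raw weight matrix and scale
    tables with plain Python loops and returns (max score, offset, strand)
    under sense-first / 5'-most tie-breaking.
    """
    L = params.L
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def score(window):
        s = params.w0
        for j, b in enumerate(window):
            s += params.w_pwm * pwm.weights[j][base_idx[b]]
        for name, w in (("ta_richness", params.w_ta),
                        ("minor_groove_width", params.w_mg),
                        ("melting", params.w_melt)):
            vals = [scales[name].values[window[j:j + 2]]
                    for j in range(L - 1)]
            s += w * sum(vals) / len(vals)
        return s

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(sequence))
    n = len(sequence)
    candidates = []
    for i in range(n - L + 1):
        candidates.append((score(sequence[i:i + L]), i, "+"))
    if params.scan_both_strands:
        for i in range(n - L + 1):
            candidates.append((score(rc[i:i + L]), n - L - i, "-"))
    best = candidates[0]
    for c in candidates[1:]:
        if c[0] > best[0] or (c[0] == best[0] and (
                (c[2] == "+" and best[2] == "-")
                or (c[2] == best[2] and c[1] < best[1]))):
            best = c
    return best
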