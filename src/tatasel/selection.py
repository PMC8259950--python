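"""Exact binomial tests for selection-mode inference on marker counts.

Under neutral drift, variants damaging a protein-binding site are expected
to outnumber those improving it; an excess of site-improving candidate
markers therefore signals natural selection against underexpression. The
one-sided exact binomial upper tail P(X >= n_improve | n, 1/2) tests that
directional null. A doubled-tail two-sided binomial tests whether
disease-aggravating and disease-relieving markers are equivalent in number.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import binom

from .markers import MarkerTally


@dataclass(frozen=True)
class BinomialResult:
    k: int
    n: int
    p_one_sided: float
    p_two_sided: float
    verdict_drift_consistent: bool


def binom_upper_tail(k: int, n: int) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, 1/2)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(binom.sf(k - 1, n, 0.5))


def binom_two_sided(k: int, n: int) -> float:
    """Doubled-tail two-sided exact binomial p at p0 = 1/2, capped at 1."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    lower = float(binom.cdf(k, n, 0.5))
    upper = float(binom.sf(k - 1, n, 0.5))
    return min(1.0, 2.0 * min(lower, upper))


def neutral_drift_test(n_improve: int, n_damage: int,
                       alpha: float = 0.05) -> BinomialResult:
    """Test the neutral-drift expectation that damaging variants are not
    outnumbered by improving ones.

    The one-sided p is P(X >= n_improve); drift-consistent means this tail
    is not small (p > alpha), i.e. improving markers do NOT significantly
    outnumber damaging ones.
    """
    n = n_improve + n_damage
    if n < 1:
        raise ValueError("no markers to test")
    p_one = binom_upper_tail(n_improve, n)
    p_two = binom_two_sided(n_improve, n)
    return BinomialResult(k=n_improve, n=n, p_one_sided=p_one,
                          p_two_sided=p_two,
                          verdict_drift_consistent=p_one > alpha)


def equivalence_test(n_up: int, n_down: int) -> float:
    """Two-sided exact binomial test of up/down marker equivalence."""
    n = n_up + n_down
    if n < 1:
        raise ValueError("no markers to test")
    return binom_two_sided(n_up, n)


def summarize_selection(tallies: list[MarkerTally],
                        alpha: float = 0.05) -> pd.DataFrame:
    """One row per category: both tests' p-values and the selection verdict.

    Categories without significant markers are flagged 'no markers'.
    """
    rows = []
    for t in tallies:
        row = {
            "category": t.category,
            "N_G": t.n_genes, "N_S": t.n_snps, "N_R": t.n_significant,
            "N_improve": t.n_improved, "N_damage": t.n_damaged,
            "N_up": t.n_up, "N_down": t.n_down,
        }
        if t.n_significant == 0:
            row.update({"p_drift": None, "drift_verdict": "no markers",
                        "p_updown": None, "updown_verdict": "no markers"})
        else:
            drift = neutral_drift_test(t.n_improved, t.n_damaged, alpha)
            p_ud = equivalence_test(t.n_up, t.n_down)
            row.update({
                "p_drift": drift.p_one_sided,
                "drift_verdict": ("neutral drift"
                                  if drift.verdict_drift_consistent
                                  else "selection against damage"),
                "p_updown": p_ud,
                "updown_verdict": ("equivalent" if p_ud >= alpha else
                                   ("toward aggravation" if t.n_up > t.n_down
                                    else "toward relief")),
            })
        rows.append(row)
    return pd.DataFrame(rows)
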