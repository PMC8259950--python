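"""Cross-validation of disease-direction predictions against
domestic-vs-wild differential expression.

The chain: filter published DEG tables at adjusted significance, pair animal
DEGs with annotated human orthologs by symbol, interpret each expression
difference as divergence from the nearest common ancestor (the domestic
lineage in excess iff log2FC > 0, the wild lineage in the complementary
state), map each lineage state through the gene's disease-effect annotation,
and test the resulting lineage x effect 2x2 table with Pearson's chi-square,
Fisher's exact test and per-lineage exact binomials.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom

from .markers import AnnotationCatalog, GeneAnnotation
from .selection import binom_upper_tail

#: Species-specific symbol aliases applied (upper-cased) before ortholog
#: matching; e.g. the dog hemoglobin locus Hbbl pairs with human HBB.
ORTHOLOG_ALIASES = {"HBBL": "HBB"}

LINEAGES = ("domestic", "wild")
STATES = ("deficit", "excess")


class DegError(ValueError):
    pass


@dataclass(frozen=True)
class DegRecord:
    """One differentially expressed gene from a domestic-vs-wild contrast
    (log2fc is domestic over wild)."""

    dataset_id: str
    domestic_label: str
    wild_label: str
    tissue: str
    gene_symbol: str
    log2fc: float
    p_adj: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise DegError(f"{self.gene_symbol}: non-finite log2fc")
        if not 0 <= self.p_adj <= 1:
            raise DegError(f"{self.gene_symbol}: p_adj {self.p_adj} outside [0,1]")


@dataclass(frozen=True)
class DivergenceCall:
    """Per-lineage expression state relative to the nearest common
    ancestor."""

    gene_symbol: str
    domestic_state: str
    wild_state: str


@dataclass(frozen=True)
class OrthologPair:
    deg: DegRecord
    human_gene: str
    annotation: GeneAnnotation


@dataclass
class CrossvalResult:
    """The 2x2 lineage x disease-effect table with its statistics."""

    table: np.ndarray  # rows: domestic, wild; cols: aggravate, relieve
    chi2_stat: float
    chi2_p: float
    chi2_yates_stat: float
    chi2_yates_p: float
    fisher_p_two_sided: float
    binom_p_domestic: float
    binom_p_wild: float
    pairs: list[OrthologPair] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)
    degenerate: bool = False


def filter_degs(records: list[DegRecord],
                threshold: float = 0.05) -> list[DegRecord]:
    """Keep DEGs at adjusted significance p_adj <= threshold (inclusive),
    preserving order."""
    return [r for r in records if r.p_adj <= threshold]


def map_orthologs(degs: list[DegRecord], catalog: AnnotationCatalog
                  ) -> tuple[list[OrthologPair], list[str]]:
    """Pair animal DEGs with annotated human genes by case-insensitive
    symbol, via the alias table for species-specific locus names.

    Returns (pairs, unmatched_symbols); missing annotations are reported,
    not fatal.
    """
    pairs, unmatched = [], []
    for deg in degs:
        symbol = deg.gene_symbol.upper()
        symbol = ORTHOLOG_ALIASES.get(symbol, symbol)
        if symbol in catalog:
            pairs.append(OrthologPair(deg=deg, human_gene=symbol,
                                      annotation=catalog[symbol]))
        else:
            unmatched.append(deg.gene_symbol)
    return pairs, unmatched


def call_divergence(deg: DegRecord) -> DivergenceCall:
    """Interpret a DEG as complementary lineage states relative to the
    nearest common ancestor."""
    if deg.log2fc == 0:
        raise DegError(f"{deg.gene_symbol}: log2fc = 0 has no divergence "
                       "direction")
    if deg.log2fc > 0:
        return DivergenceCall(deg.gene_symbol, "excess", "deficit")
    return DivergenceCall(deg.gene_symbol, "deficit", "excess")


def map_ra_effect(call: DivergenceCall,
                  ann: GeneAnnotation) -> tuple[str, str]:
    """Map each lineage's expression state to its disease effect
    (aggravate/relieve)."""
    by_state = {"deficit": ann.deficit_effect, "excess": ann.excess_effect}
    return by_state[call.domestic_state], by_state[call.wild_state]


def build_contingency(effects: list[tuple[str, str]]) -> np.ndarray:
    """Count (domestic_effect, wild_effect) pairs into a 2x2 table
    [lineage x {aggravate, relieve}]; each pair contributes one count per
    row, so both row margins equal the pair count."""
    if not effects:
        raise DegError("no ortholog pairs to tabulate")
    table = np.zeros((2, 2), dtype=int)
    col = {"aggravate": 0, "relieve": 1}
    for dom_eff, wild_eff in effects:
        table[0, col[dom_eff]] += 1
        table[1, col[wild_eff]] += 1
    return table


def pearson_chi2(table: np.ndarray, yates: bool = False
                 ) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table (1 df), optionally with the Yates
    continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("need a non-negative 2x2 table")
    row = obs.sum(axis=1, keepdims=True)
    colsum = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(colsum == 0):
        raise DegError("degenerate margin in contingency table")
    expected = row @ colsum / total
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev ** 2 / expected).sum())
    return stat, float(chi2_dist.sf(stat, df=1))


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Enumerates all tables with the observed margins and sums the
    hypergeometric point probabilities not exceeding the observed one
    (within a 1e-12 relative tolerance).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative integer 2x2 table")
    r1, r2 = t.sum(axis=1)
    c1, _c2 = t.sum(axis=0)
    n = t.sum()
    if r1 == 0 or r2 == 0 or c1 == 0 or _c2 == 0:
        raise DegError("degenerate margin in contingency table")
    rv = hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(t[0, 0])
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(1.0, p)


def crossval_report(degs: list[DegRecord], catalog: AnnotationCatalog,
                    alpha: float = 0.05,
                    p_adj_threshold: float = 0.05) -> CrossvalResult:
    """Run the full cross-validation chain and return the 2x2 table with
    all statistics.

    Per-lineage binomials are one-sided upper tails on the larger cell of
    each row. With a zero column margin the chi-square and Fisher statistics
    are reported as NaN/1 rather than raising; that case and single-pair
    tables are flagged degenerate.
    """
    kept = filter_degs(degs, p_adj_threshold)
    pairs, unmatched = map_orthologs(kept, catalog)
    effects = []
    retained = []
    for pair in pairs:
        try:
            call = call_divergence(pair.deg)
        except DegError as exc:
            warnings.warn(str(exc), RuntimeWarning, stacklevel=2)
            continue
        effects.append(map_ra_effect(call, pair.annotation))
        retained.append(pair)
    table = build_contingency(effects)
    binom_dom = binom_upper_tail(int(table[0].max()), int(table[0].sum()))
    binom_wild = binom_upper_tail(int(table[1].max()), int(table[1].sum()))
    zero_margin = bool((table.sum(axis=0) == 0).any())
    degenerate = zero_margin or len(retained) < 2
    if zero_margin:
        chi2_stat = chi2_yates = float("nan")
        chi2_p = chi2_yates_p = fisher_p = 1.0
    else:
        chi2_stat, chi2_p = pearson_chi2(table, yates=False)
        chi2_yates, chi2_yates_p = pearson_chi2(table, yates=True)
        fisher_p = fisher_exact(table)
    return CrossvalResult(
        table=table,
        chi2_stat=chi2_stat, chi2_p=chi2_p,
        chi2_yates_stat=chi2_yates, chi2_yates_p=chi2_yates_p,
        fisher_p_two_sided=fisher_p,
        binom_p_domestic=binom_dom, binom_p_wild=binom_wild,
        pairs=retained, unmatched=unmatched,
        degenerate=degenerate,
    )


def crossval_frame(result: CrossvalResult) -> pd.DataFrame:
    """Render the cross-validation result as a report-shaped DataFrame."""
    t = result.table
    return pd.DataFrame({
        "lineage": ["domestic", "wild"],
        "aggravate": t[:, 0],
        "relieve": t[:, 1],
        "binomial_p": [result.binom_p_domestic, result.binom_p_wild],
        "chi2": [result.chi2_stat, None],
        "chi2_p": [result.chi2_p, None],
        "fisher_p": [result.fisher_p_two_sided, None],
    })
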