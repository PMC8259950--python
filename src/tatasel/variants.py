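"""Allele-level comparison of TBP-promoter affinity.

Given a promoter carrying the ancestral (wt) allele and a variant
specification, the minor-allele sequence is produced by editing, both
alleles are scored with :func:`tatasel.affinity.estimate_affinity`, and the
difference is tested with Fisher's Z:

    Z = |value_wt - value_min| / sqrt(se_wt^2 + se_min^2)
    p = 2 * (1 - Phi(Z))

A significant drop in the minor allele's -ln(K_D) is reported as
``deficiency`` (predicted underexpression), a significant rise as
``excess`` (overexpression), otherwise ``insignificant``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy.stats import norm

from .affinity import (
    AffinityEstimate,
    AffinityInputError,
    AffinityModelParams,
    DinucScale,
    PromoterSequence,
    TbpPwm,
    _check_alphabet,
    estimate_affinity,
)

DECISIONS = ("deficiency", "excess", "insignificant")
SITE_DIRECTIONS = ("damaged", "improved", "unchanged")


class AlleleError(ValueError):
    """Raised when a variant's reference allele does not match the promoter."""


@dataclass(frozen=True)
class SnpSpec:
    """A promoter variant: substitution, insertion or deletion.

    ``offset`` is the TSS-relative offset of the 5'-most affected base
    (for a pure insertion, the base immediately 3' of the inserted string).
    Empty ``ref_allele`` means insertion; empty ``alt_allele`` deletion.
    """

    snp_id: str
    offset: int
    ref_allele: str
    alt_allele: str
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        ref = self.ref_allele.upper() if self.ref_allele else ""
        alt = self.alt_allele.upper() if self.alt_allele else ""
        if not ref and not alt:
            raise ValueError(f"{self.snp_id}: both alleles empty")
        for allele, label in ((ref, "ref"), (alt, "alt")):
            if allele:
                _check_alphabet(allele, f"{self.snp_id} {label} allele")
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)


@dataclass(frozen=True)
class AlleleComparison:
    """Paired wt/min affinity estimates with the Z-test verdict."""

    wt: AffinityEstimate
    min: AffinityEstimate
    z: float
    p_value: float
    decision: str
    site_direction: str
    degenerate: bool = False


def apply_variant(seq: PromoterSequence, snp: SnpSpec) -> PromoterSequence:
    """Edit the variant into the promoter, returning the minor-allele
    sequence.

    Indels change the sequence length; no re-padding to 70 bp is performed
    (an 18-bp deletion leaves a 52-bp editable sequence).
    """
    i = seq.offset_to_index(snp.offset)
    if snp.ref_allele:
        observed = seq.sequence[i:i + len(snp.ref_allele)]
        if observed != snp.ref_allele:
            raise AlleleError(
                f"{snp.snp_id}: at offset {snp.offset} expected "
                f"{snp.ref_allele!r}, promoter has {observed!r}")
        edited = (seq.sequence[:i] + snp.alt_allele
                  + seq.sequence[i + len(snp.ref_allele):])
    else:  # pure insertion 5' of the offset base
        edited = seq.sequence[:i] + snp.alt_allele + seq.sequence[i:]
    return PromoterSequence(
        gene_symbol=seq.gene_symbol,
        sequence=edited,
        tss_offset=seq.tss_offset,
        strand_label=seq.strand_label,
    )


def fisher_z_compare(wt: AffinityEstimate,
                     min_: AffinityEstimate) -> tuple[float, float, bool]:
    """Fisher's Z for the wt/min affinity difference and its two-sided
    normal p-value.

    Returns ``(z, p, degenerate)``; a degenerate comparison (both standard
    errors zero while the values differ) is reported as ``(inf, 0.0, True)``
    with a warning.
    """
    diff = abs(wt.value - min_.value)
    denom = math.hypot(wt.stderr, min_.stderr)
    if denom == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, False
        warnings.warn("both standard errors are zero with differing values; "
                      "Z is infinite", RuntimeWarning, stacklevel=2)
        return math.inf, 0.0, True
    z = diff / denom
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return z, max(p, 5e-324), False


def compare_alleles(seq: PromoterSequence, snp: SnpSpec, pwm: TbpPwm,
                    scales: Mapping[str, DinucScale],
                    params: AffinityModelParams) -> AlleleComparison:
    """Score both alleles of a promoter SNP and emit the verdict."""
    edited = apply_variant(seq, snp)
    if len(edited) < params.L:
        raise AffinityInputError(
            f"{snp.snp_id}: edited sequence shorter than window L={params.L}")
    wt = estimate_affinity(seq, pwm, scales, params)
    mn = estimate_affinity(edited, pwm, scales, params)
    z, p, degenerate = fisher_z_compare(wt, mn)
    if mn.value < wt.value:
        direction = "damaged"
    elif mn.value > wt.value:
        direction = "improved"
    else:
        direction = "unchanged"
    if p >= params.alpha:
        decision = "insignificant"
    elif mn.value < wt.value:
        decision = "deficiency"
    else:
        decision = "excess"
    return AlleleComparison(wt=wt, min=mn, z=z, p_value=p,
                            decision=decision, site_direction=direction,
                            degenerate=degenerate)


def compare_batch(promoters: Mapping[str, PromoterSequence],
                  snps: list[SnpSpec], pwm, scales, params) -> pd.DataFrame:
    """Compare a batch of SNPs against their promoters.

    Returns a DataFrame with one row per SNP (columns: snp_id, gene,
    wt_value, wt_se, min_value, min_se, z, p, decision, site_direction).
    """
    rows = []
    for snp in snps:
        key = snp.gene_symbol.upper()
        if key not in promoters:
            raise KeyError(f"{snp.snp_id}: no promoter loaded for gene "
                           f"{snp.gene_symbol!r}")
        cmp = compare_alleles(promoters[key], snp, pwm, scales, params)
        rows.append({
            "snp_id": snp.snp_id,
            "gene": snp.gene_symbol,
            "wt_value": cmp.wt.value,
            "wt_se": cmp.wt.stderr,
            "min_value": cmp.min.value,
            "min_se": cmp.min.stderr,
            "z": cmp.z,
            "p": cmp.p_value,
            "decision": cmp.decision,
            "site_direction": cmp.site_direction,
        })
    return pd.DataFrame(rows)
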