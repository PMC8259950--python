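"""Seeded synthetic corpora and transcribed in-text fixtures.

Every generator is a pure function of its spec (identical spec -> identical
corpus), producing 70-bp promoters with planted TATA boxes of tunable
strength, variant sets with known effect direction (damage / improve /
neutral), and domestic-vs-wild DEG tables with configurable skew. The
fixtures transcribe the published ortholog-comparison records and the
dataset sizes of the seven domestic-vs-wild RNA-Seq contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .affinity import (
    BASES,
    AffinityModelParams,
    PromoterSequence,
    TATA_CONSENSUS,
    TbpPwm,
    _scan_scores,
)
from .crossval import DegRecord
from .markers import AnnotationCatalog, GeneAnnotation
from .variants import SnpSpec


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class DegSpec:
    """Shape of a synthetic DEG corpus.

    ``dataset_sizes`` defaults to the seven published domestic-vs-wild
    contrasts (1740 DEGs in total). ``frac_domestic_aggravate`` is the
    probability that the expression state reached by the domestic lineage
    maps to disease aggravation (the planted correlation the recovery tests
    re-detect).
    """

    dataset_sizes: tuple[tuple[str, int], ...] | None = None
    frac_domestic_excess: float = 0.5
    frac_domestic_aggravate: float = 0.9
    frac_insignificant: float = 0.2


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_promoters: int = 50
    background_gc: float = 0.5
    box_strength: float = 1.0
    box_offset: int = -30
    n_damage: int = 1
    n_improve: int = 1
    n_neutral: int = 1
    promoter_length: int = 70
    deg_spec: DegSpec = field(default_factory=DegSpec)

    def __post_init__(self) -> None:
        for name in ("background_gc", "box_strength"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0,1], got {v}")


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one generated promoter."""

    gene_symbol: str
    box_start: int            # 0-based index of the planted box
    planted_positions: tuple[int, ...]  # indices actually set to consensus


def _random_base(rng: np.random.Generator, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, p=p)]


def gen_promoters(spec: SyntheticSpec
                  ) -> tuple[list[PromoterSequence], list[PlantedSite]]:
    """Generate promoters of i.i.d. background at the given GC content with
    a TATA consensus planted at ``box_offset``.

    ``box_strength`` is the fraction of the 8 consensus positions planted;
    the planted subset is drawn per promoter. Returns the sequences together
    with their ground-truth site maps.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.promoter_length
    box = TATA_CONSENSUS
    box_start = spec.box_offset + n  # tss_offset = -1 convention
    if box_start < 0 or box_start + len(box) > n:
        raise GenerationError(
            f"box at offset {spec.box_offset} falls outside the "
            f"{n}-bp window")
    gc = spec.background_gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    promoters, truth = [], []
    n_plant = round(spec.box_strength * len(box))
    for j in range(spec.n_promoters):
        seq = [BASES[b] for b in rng.choice(4, size=n, p=p)]
        planted = tuple(sorted(rng.choice(len(box), size=n_plant,
                                          replace=False)))
        for k in planted:
            seq[box_start + k] = box[k]
        gene = f"SYN{j:04d}"
        promoters.append(PromoterSequence(gene_symbol=gene,
                                          sequence="".join(seq)))
        truth.append(PlantedSite(gene_symbol=gene, box_start=box_start,
                                 planted_positions=tuple(box_start + k
                                                         for k in planted)))
    return promoters, truth


def gen_snps(spec: SyntheticSpec, promoters: list[PromoterSequence],
             truth: list[PlantedSite], pwm: TbpPwm,
             scales, params: AffinityModelParams
             ) -> list[tuple[SnpSpec, str]]:
    """Generate variants of known effect direction against each promoter.

    damage: a planted consensus position mutated to the PWM-worst base;
    improve: a non-consensus position inside the box window set to the
    PWM-best base; neutral: a substitution at least 10 bp away from the
    best-scoring window and outside as many of the other top-K window
    spans as the 70-bp geometry allows. Returns (snp, true_label) pairs.
    """
    rng = np.random.default_rng(spec.seed + 1)
    out: list[tuple[SnpSpec, str]] = []
    worst = pwm.weights.argmin(axis=1)
    best = pwm.weights.argmax(axis=1)
    K = params.top_k_for_se
    for seq, site in zip(promoters, truth):
        n = len(seq)
        b = site.box_start

        core = [i for i in site.planted_positions
                if seq.sequence[i] == TATA_CONSENSUS[i - b]]
        for _ in range(spec.n_damage):
            if not core:
                raise GenerationError(
                    f"{seq.gene_symbol}: no planted consensus position to "
                    "damage")
            i = int(rng.choice(core))
            ref = seq.sequence[i]
            alt = BASES[worst[i - b]]
            if alt == ref:  # consensus row whose worst base equals ref
                raise GenerationError(f"{seq.gene_symbol}: degenerate row")
            out.append((SnpSpec(snp_id=f"{seq.gene_symbol}_dmg{i}",
                                offset=i - n, ref_allele=ref, alt_allele=alt,
                                gene_symbol=seq.gene_symbol), "damage"))

        window_rows = range(b, min(b + pwm.length, n))
        improvable = [i for i in window_rows
                      if seq.sequence[i] != BASES[best[i - b]]]
        for _ in range(spec.n_improve):
            if not improvable:
                raise GenerationError(
                    f"{seq.gene_symbol}: no improvable position in the box "
                    "window")
            i = int(rng.choice(improvable))
            out.append((SnpSpec(snp_id=f"{seq.gene_symbol}_imp{i}",
                                offset=i - n, ref_allele=seq.sequence[i],
                                alt_allele=BASES[best[i - b]],
                                gene_symbol=seq.gene_symbol), "improve"))

        scored = _scan_scores(seq.sequence, pwm, scales, params)
        scored.sort(key=lambda t: t[0], reverse=True)
        # 10-bp clearance around the best-scoring (planted) site is a hard
        # constraint; the spans of the lower-ranked top-K windows are peeled
        # off rank by rank if they block every position of the short window.
        best_start = scored[0][1]
        best_zone = set(range(best_start - 10, best_start + params.L + 10))
        eligible: list[int] = []
        for allowed in range(K, 0, -1):
            hot = set(best_zone)
            for _score, start, _strand in scored[1:allowed]:
                hot.update(range(start, start + params.L))
            eligible = [i for i in range(n) if i not in hot]
            if eligible:
                break
        for _ in range(spec.n_neutral):
            if not eligible:
                raise GenerationError(
                    f"{seq.gene_symbol}: no position clear of the planted "
                    "site")
            i = int(rng.choice(eligible))
            ref = seq.sequence[i]
            alt = BASES[int(rng.choice([j for j in range(4)
                                        if BASES[j] != ref]))]
            out.append((SnpSpec(snp_id=f"{seq.gene_symbol}_neu{i}",
                                offset=i - n, ref_allele=ref, alt_allele=alt,
                                gene_symbol=seq.gene_symbol), "neutral"))
    return out


#: The seven published domestic-vs-wild RNA-Seq contrasts and DEG counts.
DATASETS = (
    ("guinea_pig_vs_cavy", "guinea pig", "cavy", "frontal cortex", 883),
    ("pig_vs_boar", "pig", "boar", "frontal cortex", 30),
    ("rabbit_dom_vs_wild", "domesticated rabbit", "wild rabbit",
     "frontal cortex", 17),
    ("rat_tame_vs_aggressive", "tame rat", "aggressive rat",
     "frontal cortex", 20),
    ("dog_vs_wolf_cortex", "dog", "wolf", "frontal cortex", 13),
    ("dog_vs_wolf_blood", "dog", "wolf", "blood", 450),
    ("fox_tame_vs_aggressive", "tame fox", "aggressive fox", "pituitary", 327),
)


def fixture_table1() -> list[tuple[str, int]]:
    """Dataset sizes of the seven published contrasts (1740 DEGs total)."""
    return [(d[0], d[4]) for d in DATASETS]


def gen_deg_table(spec: SyntheticSpec
                  ) -> tuple[list[DegRecord], AnnotationCatalog, dict]:
    """Generate a synthetic DEG corpus with a planted lineage-effect
    correlation.

    Each gene's log2FC sign follows ``frac_domestic_excess``; its annotation
    is built so that the domestic-lineage state aggravates disease with
    probability ``frac_domestic_aggravate`` (the wild state gets the
    complementary effect). A ``frac_insignificant`` share of records draws
    p_adj above 0.05 to exercise filtering. Returns (records, ground-truth
    catalog, truth metadata).
    """
    d = spec.deg_spec
    rng = np.random.default_rng(spec.seed + 2)
    sizes = (d.dataset_sizes if d.dataset_sizes is not None
             else tuple((ds[0], ds[4]) for ds in DATASETS))
    meta = {ds[0]: ds for ds in DATASETS}
    records: list[DegRecord] = []
    catalog = AnnotationCatalog()
    truth = {"domestic_aggravate": 0, "domestic_relieve": 0}
    g = 0
    for dataset_id, count in sizes:
        dom, wild, tissue = (meta[dataset_id][1:4]
                             if dataset_id in meta
                             else ("domestic", "wild", "tissue"))
        for _ in range(count):
            gene = f"DEG{g:05d}"
            g += 1
            excess = rng.random() < d.frac_domestic_excess
            magnitude = float(rng.lognormal(mean=0.0, sigma=0.8))
            log2fc = magnitude if excess else -magnitude
            if rng.random() < d.frac_insignificant:
                p_adj = float(rng.uniform(0.051, 1.0))
            else:
                p_adj = float(rng.uniform(0.0, 0.05))
            records.append(DegRecord(
                dataset_id=dataset_id, domestic_label=dom, wild_label=wild,
                tissue=tissue, gene_symbol=gene, log2fc=log2fc, p_adj=p_adj))
            dom_aggravates = rng.random() < d.frac_domestic_aggravate
            dom_state_effect = "aggravate" if dom_aggravates else "relieve"
            wild_state_effect = "relieve" if dom_aggravates else "aggravate"
            if excess:
                deficit_effect, excess_effect = (wild_state_effect,
                                                 dom_state_effect)
            else:
                deficit_effect, excess_effect = (dom_state_effect,
                                                 wild_state_effect)
            catalog.add(GeneAnnotation(
                gene_symbol=gene, category="comorbid_clinical",
                deficit_effect=deficit_effect, excess_effect=excess_effect,
                note="synthetic"))
            truth["domestic_aggravate" if dom_aggravates
                  else "domestic_relieve"] += 1
    return records, catalog, truth


#: Ortholog-comparison records transcribed from the published table:
#: (dataset_id, animal gene, log2fc, p_adj).
_TABLE3_ROWS = (
    ("fox_tame_vs_aggressive", "Esr2", -0.3, 0.05),
    ("fox_tame_vs_aggressive", "Il1r2", -0.4, 0.05),
    ("fox_tame_vs_aggressive", "Il9r", 0.4, 0.05),
    ("fox_tame_vs_aggressive", "Npy", 0.4, 1e-2),
    ("fox_tame_vs_aggressive", "Tgfb2", 0.5, 1e-2),
    ("rabbit_dom_vs_wild", "F7", -2.7, 0.05),
    ("guinea_pig_vs_cavy", "Ccr6", 2.2, 0.05),
    ("guinea_pig_vs_cavy", "Cetp", 2.1, 1e-3),
    ("guinea_pig_vs_cavy", "Il1b", 2.3, 1e-2),
    ("guinea_pig_vs_cavy", "Pdyn", 0.9, 1e-2),
    ("dog_vs_wolf_blood", "Hbbl", -5.9, 1e-8),
)


def fixture_table3() -> tuple[list[DegRecord], list[GeneAnnotation]]:
    """The 11 published ortholog DEG records and the matching human-gene
    annotations."""
    from .markers import default_annotations

    meta = {ds[0]: ds for ds in DATASETS}
    records = []
    for dataset_id, gene, log2fc, p_adj in _TABLE3_ROWS:
        _, dom, wild, tissue, _n = meta[dataset_id]
        records.append(DegRecord(
            dataset_id=dataset_id, domestic_label=dom, wild_label=wild,
            tissue=tissue, gene_symbol=gene, log2fc=log2fc, p_adj=p_adj))
    catalog = default_annotations()
    genes = {"ESR2", "IL1R2", "IL9R", "NPY", "TGFB2", "F7", "CCR6", "CETP",
             "IL1B", "PDYN", "HBB"}
    annotations = [catalog[g] for g in sorted(genes)]
    return records, annotations
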