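"""Mapping allele verdicts to disease-direction markers and tallying them.

A curated catalog records, per gene, whether an expression deficit or excess
aggravates or relieves rheumatoid arthritis. A significant allele comparison
becomes a candidate SNP marker whose disease direction follows the catalog;
per-category tallies count genes (N_G), SNPs examined (N_S), significant
markers (N_R), site-improving/damaging markers (N_> / N_<) and
disease-aggravating/relieving markers (N_up / N_down).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .variants import AlleleComparison

CATEGORIES = ("comorbid_clinical", "ra_associated", "immunostimulatory",
              "immunosuppressive")
EFFECTS = ("aggravate", "relieve")


class AnnotationError(ValueError):
    """Raised for malformed or duplicate catalog entries."""


class AnnotationLookupError(KeyError):
    """Raised when a gene has no catalog entry."""


@dataclass(frozen=True)
class GeneAnnotation:
    gene_symbol: str
    category: str
    deficit_effect: str
    excess_effect: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise AnnotationError(
                f"{self.gene_symbol}: unknown category {self.category!r}")
        for eff in (self.deficit_effect, self.excess_effect):
            if eff not in EFFECTS:
                raise AnnotationError(
                    f"{self.gene_symbol}: unknown effect token {eff!r}")

    def inverted(self) -> "GeneAnnotation":
        """Catalog entry with both effect directions flipped (for symmetry
        checks)."""
        flip = {"aggravate": "relieve", "relieve": "aggravate"}
        return GeneAnnotation(self.gene_symbol, self.category,
                              flip[self.deficit_effect],
                              flip[self.excess_effect], self.note)


@dataclass(frozen=True)
class MarkerRecord:
    snp_id: str
    gene_symbol: str
    decision: str
    site_direction: str
    ra_direction: str  # "up" (aggravate), "down" (relieve), "none"


@dataclass
class MarkerTally:
    """Per-category marker counts (one summary-table row)."""

    category: str
    n_genes: int = 0
    n_snps: int = 0
    n_significant: int = 0
    n_improved: int = 0
    n_damaged: int = 0
    n_up: int = 0
    n_down: int = 0


class AnnotationCatalog(dict):
    """Case-insensitive gene-symbol -> GeneAnnotation map."""

    def add(self, ann: GeneAnnotation) -> None:
        key = ann.gene_symbol.upper()
        if key in self:
            raise AnnotationError(f"duplicate annotation for {ann.gene_symbol}")
        self[key] = ann

    def lookup(self, gene_symbol: str) -> GeneAnnotation:
        try:
            return self[gene_symbol.upper()]
        except KeyError:
            raise AnnotationLookupError(
                f"gene {gene_symbol!r} has no catalog annotation") from None

    def inverted(self) -> "AnnotationCatalog":
        out = AnnotationCatalog()
        for ann in self.values():
            out.add(ann.inverted())
        return out


def load_annotations(path: str | Path) -> AnnotationCatalog:
    """Load the gene catalog from TSV (gene, category, deficit_effect,
    excess_effect, note) or an equivalent JSON list."""
    path = Path(path)
    catalog = AnnotationCatalog()
    if path.suffix.lower() == ".json":
        for row in json.loads(path.read_text()):
            catalog.add(GeneAnnotation(
                gene_symbol=row["gene"], category=row["category"],
                deficit_effect=row["deficit_effect"],
                excess_effect=row["excess_effect"],
                note=row.get("note", "")))
        return catalog
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "category", "deficit_effect", "excess_effect"}
    if missing := required - set(df.columns):
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    for row in df.itertuples(index=False):
        catalog.add(GeneAnnotation(
            gene_symbol=row.gene, category=row.category,
            deficit_effect=row.deficit_effect,
            excess_effect=row.excess_effect,
            note=getattr(row, "note", "") or ""))
    return catalog


def default_annotations() -> AnnotationCatalog:
    from importlib import resources
    with resources.as_file(
            resources.files("tatasel.data").joinpath("ra_annotations.tsv")) as p:
        return load_annotations(p)


def classify_marker(snp_id: str, gene_symbol: str, cmp: AlleleComparison,
                    ann: GeneAnnotation) -> MarkerRecord:
    """Turn an allele comparison into a disease-direction marker record.

    Deficiency maps through the gene's deficit effect, excess through its
    excess effect; insignificant comparisons carry no disease direction.
    """
    if cmp.decision == "deficiency":
        effect = ann.deficit_effect
    elif cmp.decision == "excess":
        effect = ann.excess_effect
    else:
        effect = None
    ra_direction = {None: "none", "aggravate": "up", "relieve": "down"}[effect]
    return MarkerRecord(snp_id=snp_id, gene_symbol=gene_symbol,
                        decision=cmp.decision,
                        site_direction=cmp.site_direction,
                        ra_direction=ra_direction)


def tally(records: list[MarkerRecord],
          catalog: AnnotationCatalog) -> dict[str, MarkerTally]:
    """Aggregate marker records into per-category tallies.

    Insignificant records contribute to N_S only. The conservation laws
    N_> + N_< = N_R and N_up + N_down = N_R hold by construction.
    """
    tallies = {c: MarkerTally(category=c) for c in CATEGORIES}
    genes_seen: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    for rec in records:
        ann = catalog.lookup(rec.gene_symbol)
        t = tallies[ann.category]
        t.n_snps += 1
        if rec.decision == "insignificant":
            continue
        t.n_significant += 1
        genes_seen[ann.category].add(rec.gene_symbol.upper())
        if rec.site_direction == "improved":
            t.n_improved += 1
        else:
            t.n_damaged += 1
        if rec.ra_direction == "up":
            t.n_up += 1
        else:
            t.n_down += 1
    for cat, t in tallies.items():
        t.n_genes = len(genes_seen[cat])
    return tallies


def tally_frame(tallies: dict[str, MarkerTally]) -> pd.DataFrame:
    """Render tallies as a summary-table-shaped DataFrame."""
    rows = [{
        "category": t.category,
        "N_G": t.n_genes,
        "N_S": t.n_snps,
        "N_R": t.n_significant,
        "N_improve": t.n_improved,
        "N_damage": t.n_damaged,
        "N_up": t.n_up,
        "N_down": t.n_down,
    } for t in tallies.values()]
    return pd.DataFrame(rows)
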