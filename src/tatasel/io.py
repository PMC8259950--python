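"""File I/O for the pipeline's plain-text formats.

Promoters travel as FASTA with ``>GENE|TSS_OFFSET`` headers, variants and
DEG tables as TSV, the run configuration as YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .affinity import PromoterSequence
from .crossval import DegRecord
from .variants import SnpSpec


class FormatError(ValueError):
    pass


class ConfigError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[PromoterSequence]:
    """Read promoters from FASTA; headers are ``GENE|TSS_OFFSET`` (e.g.
    ``MMP12|-1``). Sequences are upper-cased; duplicate gene+offset pairs
    are rejected."""
    out: list[PromoterSequence] = []
    seen: set[tuple[str, int]] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 2:
            raise FormatError(
                f"{path}: header {rec.id!r} is not GENE|TSS_OFFSET")
        gene, raw_offset = parts
        try:
            tss_offset = int(raw_offset)
        except ValueError:
            raise FormatError(
                f"{path}: header {rec.id!r} has non-integer offset") from None
        key = (gene.upper(), tss_offset)
        if key in seen:
            raise FormatError(f"{path}: duplicate record {rec.id!r}")
        seen.add(key)
        out.append(PromoterSequence(gene_symbol=gene,
                                    sequence=str(rec.seq),
                                    tss_offset=tss_offset))
    return out


def write_fasta(promoters: list[PromoterSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(p.sequence), id=f"{p.gene_symbol}|{p.tss_offset}",
                         description="") for p in promoters]
    SeqIO.write(records, str(path), "fasta")


def read_snp_tsv(path: str | Path) -> list[SnpSpec]:
    """Read variants from TSV (snp_id, gene, offset, ref, alt); '-' or empty
    marks a missing allele side."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    required = {"snp_id", "gene", "offset", "ref", "alt"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(SnpSpec(
            snp_id=row.snp_id, gene_symbol=row.gene,
            offset=int(row.offset),
            ref_allele="" if row.ref in ("-", "") else row.ref,
            alt_allele="" if row.alt in ("-", "") else row.alt))
    return out


def write_snp_tsv(snps: list[SnpSpec], path: str | Path) -> None:
    pd.DataFrame([{
        "snp_id": s.snp_id, "gene": s.gene_symbol, "offset": s.offset,
        "ref": s.ref_allele or "-", "alt": s.alt_allele or "-",
    } for s in snps]).to_csv(path, sep="\t", index=False)


def read_deg_tsv(path: str | Path) -> list[DegRecord]:
    """Read a DEG table from TSV (dataset_id, domestic_label, wild_label,
    tissue, gene, log2fc, p_adj)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"dataset_id", "domestic_label", "wild_label", "tissue",
                "gene", "log2fc", "p_adj"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [DegRecord(
        dataset_id=str(r.dataset_id), domestic_label=str(r.domestic_label),
        wild_label=str(r.wild_label), tissue=str(r.tissue),
        gene_symbol=str(r.gene), log2fc=float(r.log2fc),
        p_adj=float(r.p_adj)) for r in df.itertuples(index=False)]


def write_deg_tsv(records: list[DegRecord], path: str | Path) -> None:
    pd.DataFrame([{
        "dataset_id": r.dataset_id, "domestic_label": r.domestic_label,
        "wild_label": r.wild_label, "tissue": r.tissue,
        "gene": r.gene_symbol, "log2fc": r.log2fc, "p_adj": r.p_adj,
    } for r in records]).to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Paths and settings of a full pipeline run."""

    promoters: Path | None = None
    snps: Path | None = None
    degs: Path | None = None
    annotations: Path | None = None
    pwm: Path | None = None
    scales: Path | None = None
    params: Path | None = None
    out_dir: Path = Path("tatasel_out")
    alpha: float = 0.05
    p_adj_threshold: float = 0.05
    yates: bool = False
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0,1), got {self.alpha}")
        for name in ("promoters", "snps", "degs", "annotations", "pwm",
                     "scales", "params"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} file not found: {p}")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    base = Path(path).parent
    kwargs = {}
    for name in ("promoters", "snps", "degs", "annotations", "pwm",
                 "scales", "params", "out_dir"):
        if name in raw:
            kwargs[name] = base / raw.pop(name)
    for name in ("alpha", "p_adj_threshold", "yates", "seed", "overrides"):
        if name in raw:
            kwargs[name] = raw.pop(name)
    if raw:
        raise ConfigError(f"{path}: unknown config keys {sorted(raw)}")
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg
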