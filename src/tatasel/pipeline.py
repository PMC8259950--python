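"""End-to-end run: compare alleles, classify markers, tally, test selection
mode, and cross-validate against DEG tables."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .affinity import load_model
from .crossval import crossval_frame, crossval_report
from .io import RunConfig, read_deg_tsv, read_fasta, read_snp_tsv
from .markers import classify_marker, default_annotations, load_annotations, \
    tally, tally_frame
from .selection import summarize_selection
from .variants import compare_alleles

log = logging.getLogger("tatasel")


def _params_hash(params) -> str:
    from dataclasses import asdict
    blob = json.dumps(asdict(params), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; write TSV/JSON reports to
    ``config.out_dir`` and return the report bundle.

    Stages without configured inputs are skipped; any stage error aborts
    with a stage-named message.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pwm, scales, params = load_model(
        pwm_path=config.pwm, scales_path=config.scales,
        params_path=config.params, alpha=config.alpha, **config.overrides)
    catalog = (load_annotations(config.annotations) if config.annotations
               else default_annotations())
    log.info("tatasel %s | seed=%d | params=%s", __version__, config.seed,
             _params_hash(params))
    bundle: dict = {"version": __version__, "seed": config.seed,
                    "params_hash": _params_hash(params)}

    if config.promoters and config.snps:
        try:
            promoters = {p.gene_symbol.upper(): p
                         for p in read_fasta(config.promoters)}
            snps = read_snp_tsv(config.snps)
            records = []
            comparisons = []
            for snp in snps:
                seq = promoters[snp.gene_symbol.upper()]
                cmp = compare_alleles(seq, snp, pwm, scales, params)
                comparisons.append((snp, cmp))
                records.append(classify_marker(
                    snp.snp_id, snp.gene_symbol, cmp,
                    catalog.lookup(snp.gene_symbol)))
        except Exception as exc:
            raise RuntimeError(f"allele-comparison stage failed: {exc}") from exc
        import pandas as pd
        cmp_df = pd.DataFrame([{
            "snp_id": s.snp_id, "gene": s.gene_symbol,
            "wt_value": c.wt.value, "wt_se": c.wt.stderr,
            "min_value": c.min.value, "min_se": c.min.stderr,
            "z": c.z, "p": c.p_value, "decision": c.decision,
            "site_direction": c.site_direction,
        } for s, c in comparisons])
        cmp_df.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
        try:
            tallies = tally(records, catalog)
        except Exception as exc:
            raise RuntimeError(f"tally stage failed: {exc}") from exc
        tdf = tally_frame(tallies)
        tdf.to_csv(out_dir / "tallies.tsv", sep="\t", index=False)
        sel = summarize_selection(list(tallies.values()), alpha=config.alpha)
        sel.to_csv(out_dir / "selection.tsv", sep="\t", index=False)
        bundle["comparisons"] = cmp_df
        bundle["tallies"] = tdf
        bundle["selection"] = sel

    if config.degs:
        try:
            degs = read_deg_tsv(config.degs)
            result = crossval_report(degs, catalog, alpha=config.alpha,
                                     p_adj_threshold=config.p_adj_threshold)
        except Exception as exc:
            raise RuntimeError(f"cross-validation stage failed: {exc}") from exc
        cv = crossval_frame(result)
        cv.to_csv(out_dir / "crossval.tsv", sep="\t", index=False)
        (out_dir / "crossval.json").write_text(json.dumps({
            "table": result.table.tolist(),
            "chi2": result.chi2_stat, "chi2_p": result.chi2_p,
            "chi2_yates": result.chi2_yates_stat,
            "fisher_p": result.fisher_p_two_sided,
            "binom_p_domestic": result.binom_p_domestic,
            "binom_p_wild": result.binom_p_wild,
            "n_pairs": len(result.pairs),
            "unmatched": result.unmatched,
        }, indent=2))
        bundle["crossval"] = result
    return bundle
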