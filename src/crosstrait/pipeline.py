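"""End-to-end orchestration: impute -> meta -> overlap-correct -> shared loci -> gene sets.

A :class:`RunConfig` (usually parsed from YAML) names the input files
and carries every stage parameter; :func:`run_pipeline` executes the
stages in order, writes each stage's table under the output directory,
and returns a machine-readable summary.  A frozen copy of the resolved
config is written alongside the outputs so a run can be reproduced
exactly; identical config and seeds give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import genesets as gs
from . import impute as imp
from . import ld as ldmod
from . import meta as metamod
from . import overlap as ov
from .sumstats import SnpAssoc, harmonize, read_sumstats, to_dataframe

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs: paths first, then stage knobs."""

    out_dir: str
    target_studies: list[str] = field(default_factory=list)  # sumstats to impute+meta
    conditioning_study: str | None = None  # study 1 (source of z1)
    index_snps: str | None = None  # index SNP table (sumstats format)
    panel_dir: str | None = None  # LD reference; enables imputation + intervals
    genes_bed: str | None = None
    sets_gmt: str | None = None

    ridge: float = imp.DEFAULT_RIDGE
    min_r2pred: float = 0.0
    weight: str = "total"
    require_all: bool = False
    drop_ambiguous: bool = False

    # overlap model: covariance either given or derived from shared counts
    n1: tuple[int, int] | None = None  # (cases, controls) of study 1
    n2: tuple[int, int] | None = None
    ns: tuple[int, int] | None = None  # shared (cases, controls)
    cov: float | None = None
    var1: float | None = None  # estimated from data when None
    var2: float | None = None
    variance_mode: str = "marginal"

    alpha: float = 0.05
    m: int | None = None  # Bonferroni multiplicity; defaults to n_tested
    proxy_r2: float = 0.8

    r2_threshold: float = 0.5
    pad_bp: int = 0
    flank_bp: int = 50_000
    set_min_size: int = 10
    set_max_size: int = 200
    n_perm: int = 10_000
    n_boot: int = 1_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("n1", "n2", "ns"):
            if raw.get(key) is not None:
                raw[key] = tuple(int(x) for x in raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("n1", "n2", "ns"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are kept under failed/."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; return the run summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    summary: dict = {"stages": {}, "manifest": ["config.yaml"]}
    stage = "init"
    try:
        # ---- load + (optionally) impute target studies -------------------
        stage = "impute"
        t0 = time.perf_counter()
        panel = ldmod.load_panel(config.panel_dir) if config.panel_dir else None
        studies: list[list[SnpAssoc]] = []
        n_dropped_acc = 0
        for path in config.target_studies:
            recs = read_sumstats(path, drop_ambiguous=config.drop_ambiguous)
            if panel is not None:
                recs, dropped = _impute_study(recs, panel, config.ridge, config.min_r2pred)
                n_dropped_acc += dropped
            studies.append(recs)
        summary["stages"]["impute"] = {
            "n_studies": len(studies),
            "n_snps": [len(s) for s in studies],
            "n_dropped_low_accuracy": n_dropped_acc,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        # ---- meta-analysis ----------------------------------------------
        stage = "meta"
        t0 = time.perf_counter()
        meta_results = metamod.combine_studies(
            studies, weight=config.weight, require_all=config.require_all
        )
        meta_by_id = {r.snp_id: r for r in meta_results}
        _write_meta(meta_results, out / "meta.tsv")
        summary["manifest"].append("meta.tsv")
        summary["stages"]["meta"] = {
            "n_snps": len(meta_results),
            "seconds": round(time.perf_counter() - t0, 3),
        }

        # ---- overlap model ----------------------------------------------
        stage = "overlap-correct"
        t0 = time.perf_counter()
        conditioning = (
            read_sumstats(config.conditioning_study, drop_ambiguous=config.drop_ambiguous)
            if config.conditioning_study
            else []
        )
        cond_by_id = {r.snp_id: r for r in conditioning}
        var1 = config.var1
        if var1 is None:
            var1 = ov.estimate_inflation([r.z for r in conditioning])
        var2 = config.var2
        if var2 is None:
            var2 = ov.estimate_inflation([r.z_meta for r in meta_results])
        if config.cov is not None:
            cov = config.cov
        elif config.ns is not None:
            spec = ov.OverlapSpec(*config.n1, *config.n2, *config.ns)
            cov = ov.theoretical_overlap_cov(spec)
        else:
            cov = 0.0
        model = ov.build_null(var1, var2, cov)
        summary["model"] = {
            "var1": model.var1, "var2": model.var2,
            "cov": model.cov, "corr": model.corr,
        }
        summary["stages"]["overlap-correct"] = {"seconds": round(time.perf_counter() - t0, 3)}

        # ---- shared-locus report ----------------------------------------
        stage = "shared-loci"
        t0 = time.perf_counter()
        if config.index_snps:
            index = read_sumstats(config.index_snps)
            tested, tally = enr.map_snps(index, set(meta_by_id))
            z1, z2, src_p, kept = [], [], [], []
            for rec in tested:
                m = meta_by_id[rec.snp_id]
                target = SnpAssoc(
                    snp_id=m.snp_id, chrom=rec.chrom, pos=rec.pos,
                    allele1=m.allele1, allele2=m.allele2, z=m.z_meta,
                )
                _, aligned, _ = harmonize(rec, target)
                cond = cond_by_id.get(rec.snp_id, rec)
                z1.append(cond.z)
                z2.append(aligned.z)
                src_p.append(cond.p)
                kept.append(rec)
            z_corr, p_corr = ov.conditional_transform(
                np.array(z1), np.array(z2), model, variance_mode=config.variance_mode
            )
            m_bonf = config.m if config.m is not None else tally.n_tested
            genes_df = _genes_frame(config.genes_bed) if config.genes_bed else None
            report = enr.build_report(
                kept, p_corr, z_corr, tally, m=m_bonf, alpha=config.alpha,
                source_p=src_p, gene_annotations=genes_df,
            )
            report.table.to_csv(out / "shared_loci_full.tsv", sep="\t", index=False)
            report.nominal_table.to_csv(out / "shared_loci_nominal.tsv", sep="\t", index=False)
            summary["manifest"] += ["shared_loci_full.tsv", "shared_loci_nominal.tsv"]
            summary["shared_loci"] = report.summary()
            concordance, _ = enr.direction_concordance(
                np.column_stack([z1, z2])
            ) if z1 else (float("nan"), None)
            summary["shared_loci"]["direction_concordance"] = concordance
        else:
            report = None
        summary["stages"]["shared-loci"] = {"seconds": round(time.perf_counter() - t0, 3)}

        # ---- gene-set enrichment ----------------------------------------
        stage = "geneset"
        t0 = time.perf_counter()
        if report is not None and config.genes_bed and config.sets_gmt and panel is not None:
            nominal_ids = set(report.nominal_table["snp_id"])
            hits = [r for r in (read_sumstats(config.index_snps)) if r.snp_id in nominal_ids]
            intervals = ldmod.build_intervals(
                hits, panel, r2_threshold=config.r2_threshold, pad_bp=config.pad_bp
            )
            genes = gs.read_gene_bed(config.genes_bed)
            sets = gs.filter_sets_by_size(
                gs.read_gmt(config.sets_gmt),
                {g.gene_id for g in genes},
                config.set_min_size,
                config.set_max_size,
            )
            results = gs.test_gene_sets(
                intervals, genes, sets,
                n_perm=config.n_perm, n_boot=config.n_boot,
                seed=config.seed, flank_bp=config.flank_bp,
            )
            frame = gs.results_to_frame(results)
            frame.to_csv(out / "gene_sets.tsv", sep="\t", index=False)
            summary["manifest"].append("gene_sets.tsv")
            summary["gene_sets"] = {
                "n_intervals": len(intervals),
                "n_sets_tested": len(sets),
                "n_nominal": int((frame["empirical_p"] < config.alpha).sum()),
            }
        summary["stages"]["geneset"] = {"seconds": round(time.perf_counter() - t0, 3)}

    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for name in summary.get("manifest", []):
            src = out / name
            if src.exists():
                shutil.move(str(src), failed / name)
        raise StageError(stage, exc) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    summary["manifest"].append("summary.json")
    return summary


def _impute_study(records, panel, ridge, min_r2pred):
    """Fill the panel's untyped SNPs for one study; keep only accurate calls."""
    typed_by_id = {r.snp_id: r for r in records}
    out: list[SnpAssoc] = list(records)
    dropped_total = 0
    for block in panel:
        typed = {sid: typed_by_id[sid].z for sid in block.snp_ids if sid in typed_by_id}
        results = imp.impute_block(block, typed, ridge=ridge)
        results, dropped = imp.filter_by_accuracy(results, min_r2pred)
        dropped_total += dropped
        for res in results:
            if res.typed:
                continue
            info = block.snps[block.index_of(res.snp_id)]
            anchor = next(iter(typed_by_id.values()), None)
            out.append(
                SnpAssoc(
                    snp_id=res.snp_id, chrom=info.chrom, pos=info.pos,
                    allele1=info.allele1, allele2=info.allele2,
                    z=res.z_imputed, accuracy=res.r2pred,
                    n_case=anchor.n_case if anchor else 0,
                    n_control=anchor.n_control if anchor else 0,
                )
            )
    return out, dropped_total


def _write_meta(results, path) -> None:
    pd.DataFrame(
        [
            (r.snp_id, r.allele1, r.allele2, r.z_meta, r.p_meta, r.n_studies)
            for r in results
        ],
        columns=["SNP", "A1", "A2", "Z_META", "P_META", "NSTUDIES"],
    ).to_csv(path, sep="\t", index=False)


def _genes_frame(path) -> pd.DataFrame:
    genes = gs.read_gene_bed(path)
    return pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end) for g in genes],
        columns=["gene_id", "chrom", "start", "end"],
    )
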