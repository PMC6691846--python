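"""End-to-end pipeline driver: QC -> kinship -> GWAS -> FS -> annotation.

The pipeline consumes a genotype VCF, a phenotype TSV and a pedigree TSV
(plus optional GFF3 gene annotation and a conserved-interval BED), runs
every stage in the fixed order, and writes one file per result into the
output directory. All numeric outputs are deterministic given the
inputs and the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import io as fio
from .fs import expand_signatures, gomp, ses
from .gwas import manhattan_table, qq_inflation, scan, significance_threshold
from .modelsel import ModelConfig, compare_models, default_grid
from .qc import filter_variants, ld_prune
from .relatedness import kinship_matrix, verify_families

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("famgwas")


@dataclass
class PipelineConfig:
    """Paths, thresholds and the model grid for one pipeline run."""

    genotypes_vcf: str = ""
    phenotypes_tsv: str = ""
    pedigree_tsv: str = ""
    annotation_gff3: str | None = None
    conserved_bed: str | None = None
    out_dir: str = "famgwas_out"
    traits: list[str] = field(
        default_factory=lambda: [
            "fat_pct", "weight_g", "tag_weight_g", "length_width"
        ]
    )
    maf_min: float = 0.05
    callrate_min: float = 0.90
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.05
    alpha: float = 0.05
    reassign_margin: float = 0.05
    annotation_window: int = 10_000
    fs_grid: list[ModelConfig] | None = None
    fixed_signature: bool = False
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        grid = raw.pop("fs_grid", None)
        config = cls(**raw)
        if grid is not None:
            config.fs_grid = [ModelConfig(**g) for g in grid]
        return config

    def to_json(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2, default=str)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of result objects.

    Stage order: variant QC, kinship-based family verification (flagged
    samples are excluded downstream), per-trait association scan with an
    LD-derived threshold, per-trait feature-selection grid scored by
    clustered LOOCV, and annotation of every significant or selected
    variant. Each stage's output is also written to ``config.out_dir``;
    a stage failure aborts with a stage-named error, keeping the partial
    outputs already written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    gm = _stage("load")(fio.read_vcf)(config.genotypes_vcf)
    ped = fio.read_pedigree_tsv(config.pedigree_tsv)
    phenos = fio.read_phenotypes_tsv(config.phenotypes_tsv)
    missing_traits = [t for t in config.traits if t not in phenos.columns]
    if missing_traits:
        raise RuntimeError(
            f"pipeline stage 'load' failed: traits {missing_traits} "
            "absent from the phenotype table"
        )

    # ---- QC ----------------------------------------------------------
    @_stage("qc")
    def _qc():
        gm_qc, report = filter_variants(
            gm, config.maf_min, config.callrate_min, require_complete=True
        )
        with open(out / "qc_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        return gm_qc, report

    gm_qc, qc_report = _qc()
    bundle["qc_report"] = qc_report

    # ---- relatedness -------------------------------------------------
    @_stage("relatedness")
    def _rel():
        kin = kinship_matrix(gm_qc)
        kin.to_csv(out / "kinship.tsv", sep="\t")
        check = verify_families(kin, ped, config.reassign_margin)
        check.to_csv(out / "family_check.tsv", sep="\t", index=False)
        return kin, check

    kin, family_check = _rel()
    bundle["kinship"] = kin
    bundle["family_check"] = family_check
    flagged = set(
        family_check.loc[
            family_check["status"] != "confirmed", "sample_id"
        ]
    )
    if flagged:
        log.info("excluding %d flagged samples: %s", len(flagged),
                 sorted(flagged))
    bundle["excluded_samples"] = sorted(flagged)

    # ---- per-trait analysis ------------------------------------------
    pheno_idx = phenos.set_index("sample_id")
    keep_samples = [
        s
        for s in gm_qc.sample_ids
        if s not in flagged and s in pheno_idx.index
    ]
    gm_s = gm_qc.subset_samples(keep_samples)
    fam_of = ped.family_of()
    fam = np.array([fam_of[s] for s in keep_samples])

    retained = _stage("ld_prune")(ld_prune)(
        gm_s, config.prune_window, config.prune_step, config.prune_r2
    )
    (out / "independent_variants.txt").write_text(
        "\n".join(retained) + "\n"
    )
    raw_thr, threshold = significance_threshold(len(retained), config.alpha)
    bundle["n_independent"] = len(retained)
    bundle["threshold"] = threshold
    bundle["threshold_raw"] = raw_thr

    associations, signatures, cv_reports = {}, {}, {}
    grid = config.fs_grid if config.fs_grid is not None else default_grid()
    hit_ids: set[str] = set()
    for trait in config.traits:
        y = pheno_idx.loc[keep_samples, trait].to_numpy(dtype=float)

        @_stage(f"gwas[{trait}]")
        def _scan(y=y, trait=trait):
            res = scan(gm_s, y, family_ids=fam, threshold=threshold)
            res.to_csv(out / f"association_{trait}.tsv", sep="\t", index=False)
            lam, qq = qq_inflation(res["p_value"].to_numpy())
            qq.to_csv(out / f"qq_{trait}.tsv", sep="\t", index=False)
            main, scaff = manhattan_table(res)
            main.to_csv(out / f"manhattan_{trait}.tsv", sep="\t", index=False)
            scaff.to_csv(
                out / f"manhattan_scaffolds_{trait}.tsv", sep="\t", index=False
            )
            return res, lam

        res, lam = _scan()
        associations[trait] = res
        hit_ids |= set(res.loc[res["significant"], "id"])

        @_stage(f"modelsel[{trait}]")
        def _cv(y=y, trait=trait):
            report = compare_models(
                gm_s, y, fam, grid=grid, fixed_signature=config.fixed_signature
            )
            payload = {
                "best_model": report.best_model,
                "per_model": report.per_model.to_dict(orient="records"),
            }
            with open(out / f"cv_report_{trait}.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            return report

        report = _cv()
        cv_reports[trait] = report

        @_stage(f"fs[{trait}]")
        def _fs(y=y, trait=trait, report=report):
            best = next(
                g for g in grid if g.tag == report.best_model
            )
            if best.algorithm == "ses":
                sig = ses(y, gm_s, alpha=best.alpha, max_k=best.max_k,
                          family_ids=fam)
                payload = {
                    "model": best.tag,
                    "selected": list(sig.selected),
                    "equivalence_classes": {
                        k: sorted(v)
                        for k, v in sig.equivalence_classes.items()
                    },
                    "signatures": [
                        sorted(s) for s in expand_signatures(sig, limit=32)
                    ],
                }
                chosen = set(sig.selected)
            else:
                trace = gomp(y, gm_s, stop_delta=best.stop_delta)
                payload = {
                    "model": best.tag,
                    "selected": list(trace.selected),
                    "bic_path": trace.bic_path,
                }
                chosen = set(trace.selected)
            with open(out / f"signature_{trait}.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            return payload, chosen

        payload, chosen = _fs()
        signatures[trait] = payload
        hit_ids |= chosen

    bundle["associations"] = associations
    bundle["signatures"] = signatures
    bundle["cv_reports"] = cv_reports
    bundle["lambda_gc"] = lam

    # ---- annotation --------------------------------------------------
    @_stage("annotate")
    def _annot():
        genes = (
            ann.read_gff3(config.annotation_gff3)
            if config.annotation_gff3
            else []
        )
        conserved = (
            ann.read_bed(config.conserved_bed) if config.conserved_bed else {}
        )
        hits = gm_s.variants[gm_s.variants["id"].isin(hit_ids)]
        records = ann.annotate_variants(
            hits, genes, conserved, window=config.annotation_window
        )
        table = pd.DataFrame(
            [
                {
                    "id": r.variant_id,
                    "genes": ";".join(r.genes),
                    "position_class": r.position_class,
                    "distance": r.distance,
                    "conserved": r.conserved,
                }
                for r in records
            ]
        )
        table.to_csv(out / "annotation.tsv", sep="\t", index=False)
        return table

    bundle["annotation"] = _annot()
    log.info("pipeline complete; outputs in %s", out)
    return bundle
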