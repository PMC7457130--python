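"""End-to-end orchestration: simulate -> segment -> call -> burden -> mcr ->
associate -> survival, plus the built-in published-table fixture runner.

A single seed in the configuration drives every stage (permutations reuse
it; the generator splits it per sample by counter), so a rerun with the
same configuration produces byte-identical artifacts — the manifest records
a SHA-256 content hash per output file to make that checkable.  On stage
failure the stage's partial outputs are renamed with a '.partial' suffix
and a nonzero status propagates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import tables
from .array_io import (
    ValidationError,
    clinical_frame,
    load_cytobands,
    write_clinical,
    write_intensities,
    write_mcr_table,
    write_probe_map,
    write_segments,
)
from .burden import burden_table
from .mcr import McrParams, call_mcrs, carrier_matrix
from .segmentation import SegmentationParams, segment_sample
from .state_calling import LohParams, call_sample
from .survival import combined_risk, prognostic_subcohort, recurrence_scan
from .synthetic import (
    ClinicalModel,
    PlantedRegion,
    SimulationConfig,
    default_config,
    simulate_cohort,
)

__all__ = ["PipelineConfig", "config_from_yaml", "run_all", "fixtures_tables"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "call", "burden", "mcr", "associate", "survival")


@dataclass
class PipelineConfig:
    """Everything run_all needs; all stage parameters plus one seed."""

    out_dir: Path
    seed: int
    simulation: SimulationConfig | None = None  # default_config(seed) when None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    loh: LohParams = field(default_factory=LohParams)
    mcr: McrParams | None = None  # seed injected from the pipeline seed when None
    association_alpha: float = 0.01
    survival_alpha: float = 0.05
    cytoband_path: Path | None = None

    def resolved(self) -> "PipelineConfig":
        sim = self.simulation or default_config(self.seed)
        mcr = self.mcr or McrParams(seed=self.seed)
        return PipelineConfig(
            out_dir=Path(self.out_dir),
            seed=self.seed,
            simulation=sim,
            segmentation=self.segmentation,
            loh=self.loh,
            mcr=mcr,
            association_alpha=self.association_alpha,
            survival_alpha=self.survival_alpha,
            cytoband_path=self.cytoband_path,
        )


def config_from_yaml(path, out_dir=None, seed=None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file mirroring the dataclass keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = seed if seed is not None else raw.get("seed")
    if seed is None:
        raise ValidationError("config must provide a seed")
    out_dir = Path(out_dir if out_dir is not None else raw.get("out_dir", "cnvland_out"))

    sim = None
    if "simulation" in raw:
        s = dict(raw["simulation"])
        regions = tuple(PlantedRegion(**r) for r in s.pop("planted_regions", []))
        clin = ClinicalModel(**s.pop("clinical_model", {}))
        sim = SimulationConfig(
            seed=int(s.pop("seed", seed)), planted_regions=regions,
            clinical_model=clin, **s,
        )
    seg = SegmentationParams(**raw.get("segmentation", {}))
    loh = LohParams(**raw.get("loh", {}))
    mcr = McrParams(seed=int(seed), **raw.get("mcr", {})) if "mcr" in raw else None
    return PipelineConfig(
        out_dir=out_dir,
        seed=int(seed),
        simulation=sim,
        segmentation=seg,
        loh=loh,
        mcr=mcr,
        association_alpha=float(raw.get("association_alpha", 0.01)),
        survival_alpha=float(raw.get("survival_alpha", 0.05)),
        cytoband_path=raw.get("cytobands"),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _header(cfg: PipelineConfig, stage: str, params: str) -> str:
    return f"cnvland pipeline stage={stage} seed={cfg.seed} {params}"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str,
               params: str = "", index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header(cfg, stage, params)}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.8g")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the artifact manifest.

    The manifest maps stage -> {filename: sha256}.  A failed stage renames
    its outputs to '<name>.partial' and re-raises.
    """
    cfg = config.resolved()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cytobands = load_cytobands(cfg.cytoband_path) if cfg.cytoband_path else None
    manifest: dict[str, dict[str, str]] = {}

    def record(stage: str, *paths: Path):
        manifest[stage] = {p.name: _sha256(p) for p in sorted(paths)}

    stage_files: list[Path] = []

    def stage_guard(stage):
        class _Guard:
            def __enter__(self):
                stage_files.clear()
                logger.info("stage %s: start (seed=%d)", stage, cfg.seed)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    for p in stage_files:
                        if p.exists():
                            p.rename(p.with_suffix(p.suffix + ".partial"))
                    logger.error("stage %s failed: %s", stage, exc)
                    return False
                record(stage, *stage_files)
                logger.info("stage %s: done (%d files)", stage, len(stage_files))
                return False

        return _Guard()

    def out_path(name: str) -> Path:
        p = out / name
        stage_files.append(p)
        return p

    # --- simulate -----------------------------------------------------------
    with stage_guard("simulate"):
        probe_map, samples, clinical, truth = simulate_cohort(cfg.simulation)
        write_intensities(out_path("intensities.tsv"), probe_map, samples)
        write_probe_map(out_path("probe_map.tsv"), probe_map)
        write_clinical(out_path("clinical.tsv"), clinical)
        truth_df = pd.DataFrame(
            [
                {
                    "name": r.name, "chromosome": r.chromosome,
                    "start_bp": r.start_bp, "end_bp": r.end_bp, "state": r.state,
                    "hazard_multiplier": r.hazard_multiplier,
                }
                for r in truth.regions
            ]
        )
        _write_tsv(truth_df, out_path("truth_regions.tsv"), cfg, "simulate",
                   "planted-region truth", index=False)
        _write_tsv(truth.carrier_flags.astype(int), out_path("truth_carriers.tsv"),
                   cfg, "simulate", "carrier truth")

    # --- segment ------------------------------------------------------------
    with stage_guard("segment"):
        segments = {
            s.sample_id: segment_sample(s, probe_map, cfg.segmentation) for s in samples
        }
        flat = [seg for sid in sorted(segments) for seg in segments[sid]]
        write_segments(
            flat, out_path("segments.tsv"),
            header_comment=_header(cfg, "segment",
                                   f"T={cfg.segmentation.T} "
                                   f"min_probes={cfg.segmentation.min_probes}"),
        )

    # --- call ---------------------------------------------------------------
    with stage_guard("call"):
        sample_by_id = {s.sample_id: s for s in samples}
        calls = {
            sid: call_sample(segs, sample_by_id[sid], cfg.loh, probe_map)
            for sid, segs in segments.items()
        }
        flat = [c for sid in sorted(calls) for c in calls[sid]]
        write_segments(
            flat, out_path("calls.tsv"),
            header_comment=_header(cfg, "call",
                                   f"window={cfg.loh.window_snps} "
                                   f"gain>={cfg.loh.gain_lrr} loss<={cfg.loh.loss_lrr}"),
        )

    # --- burden -------------------------------------------------------------
    with stage_guard("burden"):
        bt = burden_table(calls, probe_map)
        _write_tsv(bt, out_path("burden.tsv"), cfg, "burden")

    # --- mcr ----------------------------------------------------------------
    with stage_guard("mcr"):
        regions = call_mcrs(calls, probe_map, cfg.mcr, cytobands)
        write_mcr_table(
            regions, out_path("mcr.tsv"),
            header_comment=_header(cfg, "mcr",
                                   f"q<{cfg.mcr.q_cutoff} "
                                   f"permutations={cfg.mcr.n_permutations}"),
        )
        cm = carrier_matrix(regions, calls, cfg.mcr)
        _write_tsv(cm, out_path("carrier_matrix.tsv"), cfg, "mcr")

    # --- associate ----------------------------------------------------------
    with stage_guard("associate"):
        clin = clinical_frame(clinical)
        rows = []
        if not cm.empty:
            for phenotype in assoc_mod.PHENOTYPES:
                try:
                    results = assoc_mod.cnv_phenotype_scan(
                        cm, clin, phenotype, alpha=cfg.association_alpha
                    )
                except ValidationError as exc:
                    logger.warning("phenotype %s skipped: %s", phenotype, exc)
                    continue
                for r in results:
                    rows.append(
                        {
                            "region": r.region, "phenotype": r.phenotype,
                            "chi2": r.chi2, "df": r.df, "p": r.p,
                            "significant": r.significant,
                        }
                    )
        adf = pd.DataFrame(rows, columns=["region", "phenotype", "chi2", "df",
                                          "p", "significant"])
        _write_tsv(adf, out_path("association.tsv"), cfg, "associate",
                   f"alpha={cfg.association_alpha}", index=False)

    # --- survival -----------------------------------------------------------
    with stage_guard("survival"):
        sub = prognostic_subcohort(clinical)
        has_events = any(r.recurrence_event for r in sub)
        cols = ["covariate", "coef", "se", "p", "hazard_ratio",
                "ci95_low", "ci95_high", "n", "n_events"]
        if cm.empty or not has_events:
            logger.warning(
                "survival stage: %s; writing empty results",
                "no recurrent regions" if cm.empty else "no events in subcohort",
            )
            uni = pd.DataFrame(columns=cols)
            multi = pd.DataFrame(columns=cols)
        else:
            uni, multi = recurrence_scan(cm, clinical, alpha=cfg.survival_alpha)
        _write_tsv(uni, out_path("survival_univariate.tsv"), cfg, "survival",
                   f"alpha={cfg.survival_alpha}", index=False)
        _write_tsv(multi, out_path("survival_multivariate.tsv"), cfg, "survival",
                   f"alpha={cfg.survival_alpha}", index=False)

        # combined risk over the multivariately significant loss regions
        risk_rows = []
        if not multi.empty:
            region_cols = [
                c for c in multi["covariate"]
                if c in cm.columns and c.endswith(":loss")
                and multi.set_index("covariate").loc[c, "p"] <= cfg.survival_alpha
            ]
            if region_cols:
                flags = (cm[region_cols] == "loss").astype(int)
                flags = flags.loc[[r.patient_id for r in sub]]
                curves, chi2, p, per_cnv = combined_risk(sub, flags)
                if per_cnv is not None:
                    risk_rows.append(
                        {
                            "regions": ";".join(region_cols),
                            "logrank_chi2": chi2, "logrank_p": p,
                            "hr_per_cnv": per_cnv.hazard_ratio,
                            "hr_ci95_low": per_cnv.ci95_low,
                            "hr_ci95_high": per_cnv.ci95_high,
                            "p_per_cnv": per_cnv.p,
                        }
                    )
        rdf = pd.DataFrame(risk_rows, columns=["regions", "logrank_chi2", "logrank_p",
                                               "hr_per_cnv", "hr_ci95_low",
                                               "hr_ci95_high", "p_per_cnv"])
        _write_tsv(rdf, out_path("combined_risk.tsv"), cfg, "survival", index=False)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# Published-table fixture runner
# ---------------------------------------------------------------------------


def fixtures_tables() -> pd.DataFrame:
    """Reproduce every bundled published value; one pass/fail row each.

    Chi-square p-values are recomputed from the bundled contingency counts
    and compared with the published values at each entry's tolerance;
    carrier counts are reconciled with the published region frequencies,
    and the cohort gender ratio is recomputed.
    """
    rows = []
    for fx in tables.CONTINGENCY_TABLES:
        chi2, df, p = assoc_mod.pearson_chi2(np.array(fx.counts))
        ok = abs(p - fx.published_p) <= fx.rel_tol * fx.published_p
        rows.append(
            {
                "check": f"chi2 {fx.region} x {fx.phenotype}",
                "computed": p, "published": fx.published_p,
                "tolerance": f"rel {fx.rel_tol}", "pass": bool(ok),
            }
        )
    for (region, cnv_type), (count, pct) in tables.FREQUENCY_CHECKS.items():
        computed = 100.0 * count / tables.COHORT_SIZE
        ok = abs(computed - pct) <= 0.005
        rows.append(
            {
                "check": f"frequency {region} {cnv_type} ({count}/{tables.COHORT_SIZE})",
                "computed": round(computed, 2), "published": pct,
                "tolerance": "abs 0.005", "pass": bool(ok),
            }
        )
    ratio = tables.N_FEMALE / tables.N_MALE
    # published ratio is truncated to 2 decimals (2.2457 -> 2.24)
    rows.append(
        {
            "check": f"cohort female:male ({tables.N_FEMALE}/{tables.N_MALE})",
            "computed": round(ratio, 4), "published": tables.FEMALE_MALE_RATIO,
            "tolerance": "abs 0.01",
            "pass": bool(abs(ratio - tables.FEMALE_MALE_RATIO) < 0.01),
        }
    )
    return pd.DataFrame(rows)
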