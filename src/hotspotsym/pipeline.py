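"""One-command orchestration: simulate → filter → assign → call → attribute
→ symmetry → phenotype statistics, with a machine-readable JSON report.

A single master seed deterministically spawns per-stage streams, so the
whole run — files and report alike — is byte-identical under a fixed
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, assign, attribute, peaks, phenostats, symmetry, synthdata

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All thresholds of the analysis in one auditable place."""

    sim: synthdata.SimConfig = field(default_factory=synthdata.SimConfig)
    peak_params: peaks.PeakParams = field(default_factory=peaks.PeakParams)
    phenotype_groups: list[synthdata.GroupParams] = field(
        default_factory=synthdata.default_phenotype_groups
    )
    phenotype_laws: synthdata.PhenotypeLaws = field(default_factory=synthdata.PhenotypeLaws)
    matched_band: tuple[float, float] = symmetry.MATCHED_BAND
    min_reads: int = 5
    max_dist: int = 500
    epsilon: float | None = None  # None: derived from sim.seq_error_rate
    min_base_quality: int = 20
    pseudo_count: float = 2.0
    n_boot: int = 200
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["matched_band"] = list(self.matched_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = synthdata.SimConfig.from_dict(d["sim"])
        if "peak_params" in d:
            d["peak_params"] = peaks.PeakParams(**d["peak_params"])
        if "phenotype_groups" in d:
            d["phenotype_groups"] = [synthdata.GroupParams(**g) for g in d["phenotype_groups"]]
        if "phenotype_laws" in d:
            d["phenotype_laws"] = synthdata.PhenotypeLaws(**d["phenotype_laws"])
        if "matched_band" in d:
            d["matched_band"] = tuple(d["matched_band"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Every violated invariant, as data; an empty list means valid."""
    errors: list[str] = []
    errors.extend(config.sim.validate())
    errors.extend(config.peak_params.validate())
    lo, hi = config.matched_band
    if not (0.0 <= lo < hi <= 1.0):
        errors.append(f"matched band low must be < high, within [0,1]; got ({lo}, {hi})")
    if config.epsilon is not None and not 0.0 <= config.epsilon < 0.5:
        errors.append("epsilon must satisfy 0 ≤ epsilon < 0.5")
    if config.min_reads < 1:
        errors.append("min_reads must be ≥ 1")
    if config.max_dist < 0:
        errors.append("max_dist must be nonnegative")
    if config.pseudo_count <= 0:
        errors.append("pseudo_count must be positive")
    if config.n_boot < 0:
        errors.append("n_boot must be nonnegative")
    for g in config.phenotype_groups:
        if not 0.0 <= g.p_synapsis <= 1.0:
            errors.append(f"p_synapsis out of [0,1] for group {g.name}")
    if not 0.0 <= config.phenotype_laws.tau <= 1.0:
        errors.append("tau must be in [0, 1]")
    return errors


def _spawn_seed(master: int, key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(key,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write per-stage outputs plus ``report.json``."""
    errors = validate_config(config)
    if errors:
        raise synthdata.InvalidConfigError("; ".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_cfg = dataclasses.replace(config.sim, seed=_spawn_seed(config.seed, 0))
    stage = "simulate"
    try:
        data = synthdata.simulate_dataset(sim_cfg, out)
        hotspots = data["hotspots"]
        truth = data["truth"]
        paths = data["paths"]

        stage = "variants"
        sites = _quiet_load(paths["vcf"])
        site_index = assign.SiteIndex(sites) if not isinstance(sites, assign.SiteIndex) else sites

        stage = "assign"
        assignments, assign_summary = assign.assign_all(
            paths["sam"], site_index, min_base_quality=config.min_base_quality
        )
        assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)

        stage = "peaks"
        called = peaks.call_peaks(paths["sam"], config.peak_params)
        peaks.write_peaks_bed(called, out / "peaks.bed")
        peak_frame = peaks.peaks_to_frame(called)
        counts = peaks.attach_reads(called, assignments)
        counts.to_csv(out / "peak_counts.tsv", sep="\t", index=False)

        stage = "attribute"
        map1 = attribute.AlleleMap.from_centers(
            synthdata.ALLELE1,
            sim_cfg.chrom_name,
            [h.center for h in hotspots if h.allele == synthdata.ALLELE1],
        )
        map2 = attribute.AlleleMap.from_centers(
            synthdata.ALLELE2,
            sim_cfg.chrom_name,
            [h.center for h in hotspots if h.allele == synthdata.ALLELE2],
        )
        attributions = attribute.attribute_peaks(peak_frame, map1, map2, max_dist=config.max_dist)
        attributions.to_csv(out / "attributions.tsv", sep="\t", index=False)

        stage = "symmetry"
        eps = (
            config.epsilon
            if config.epsilon is not None
            else assign.effective_misassignment_rate(sim_cfg.seq_error_rate)
        )
        sym = symmetry.summarize_peaks(
            counts, epsilon=eps, min_reads=config.min_reads, band=config.matched_band
        )
        sym.to_csv(out / "symmetry.tsv", sep="\t", index=False)
        read_totals = (counts.set_index("id")["n_B6"] + counts.set_index("id")["n_ALT"])
        dominance = attribute.dominance_summary(attributions, read_totals)
        matched = {}
        for allele in (synthdata.ALLELE1, synthdata.ALLELE2):
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                matched[allele] = symmetry.matched_read_proportion(sym, attributions, allele)

        stage = "phenotypes"
        pheno = synthdata.simulate_phenotypes(
            config.phenotype_groups, seed=_spawn_seed(config.seed, 1), laws=config.phenotype_laws
        )
        pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        pheno_report = _phenotype_report(pheno, config)
    except (PipelineError, synthdata.InvalidConfigError):
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    truth_matched = {
        allele: synthdata.truth_matched_proportion(
            hotspots,
            truth,
            allele,
            band=config.matched_band,
            snp_positions=data["haplotypes"].snp_pos,
        )
        for allele in (synthdata.ALLELE1, synthdata.ALLELE2)
    }

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "thresholds_used": {
            "matched_band": list(config.matched_band),
            "min_reads": config.min_reads,
            "max_dist": config.max_dist,
            "epsilon": eps,
            "q_threshold": config.peak_params.q_threshold,
            "pseudo_count": config.pseudo_count,
            "min_base_quality": config.min_base_quality,
        },
        "n_informative_snps": len(sites),
        "assignment_summary": assign_summary,
        "n_peaks": len(called),
        "class_counts": symmetry.class_counts(sym),
        "matched_proportion": matched,
        "truth_matched_proportion": truth_matched,
        "dominance": dominance,
        "phenotypes": pheno_report,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return report


def _quiet_load(vcf_path: str):
    from .variants import load_informative_snps

    return load_informative_snps(vcf_path)


def _phenotype_report(pheno, config: PipelineConfig) -> dict:
    df = pheno.copy()
    df["synapsis"] = df["nuclei_synapsed"] / df["nuclei_total"]
    df["testis_norm"] = df["testis_weight_mg"] / df["lean_body_weight_g"]
    groups = list(dict.fromkeys(df["group"]))
    ref = groups[0]
    tests = {}
    for g in groups[1:]:
        a = df[df["group"] == ref]
        b = df[df["group"] == g]
        tests[f"{ref}_vs_{g}"] = {
            var: phenostats.group_ttest(a[var], b[var])
            for var in ("synapsis", "testis_norm", "sperm_count")
        }
    fit = phenostats.fit_cliff_edge(
        df, pseudo_count=config.pseudo_count, n_boot=config.n_boot, seed=_spawn_seed(config.seed, 2)
    )
    summary = phenostats.cohort_summary(pheno)
    return {
        "n_mice": int(len(df)),
        "group_summary": summary.to_dict(orient="records"),
        "t_tests": tests,
        "cliff_edge": {
            "tau_hat": fit.tau_hat,
            "mean_below_log10": fit.mean_below,
            "mean_above_log10": fit.mean_above,
            "sse": fit.sse,
            "ci_tau": list(fit.ci_tau) if fit.ci_tau else None,
            "degenerate": fit.degenerate,
            "valid": fit.valid,
        },
    }
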