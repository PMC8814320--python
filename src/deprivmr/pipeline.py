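"""End-to-end pipeline: simulate -> constructs -> associate -> mediate ->
genotype QC -> Mendelian randomization, driven by one YAML configuration.

Each stage writes its tabular output as CSV plus a JSON sidecar recording
the stage parameters and a SHA-256 checksum of the CSV; the consolidated
report reproduces the shapes of the study's five tables (cohort
descriptives, mutually adjusted associations, mediation decomposition, MR
for continuous outcomes, MR for binary outcomes). Runs are deterministic
under a fixed seed, and every output carries the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, geno, income, mediation, mr, synthetic

log = logging.getLogger("deprivmr.pipeline")

_STAGES = ("simulate", "constructs", "associate", "mediate", "qc", "mr")

_DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "deprivmr_run",
    "stages": {s: True for s in _STAGES},
    "inputs": {"cohort_csv": None, "genotype": None, "pedigree_tsv": None},
    "simulate": {},               # SimConfig overrides
    "constructs": {},
    "associate": {"binary_method": "cluster_robust", "alpha": 0.05},
    "mediate": {"outcome": "sbp", "n_boot": 1000},
    "qc": {"snp_missing_max": 0.02, "sample_missing_max": 0.02,
           "maf_min": 0.05, "hwe_p_min": 1e-6, "het_sd": 3.0,
           "ld_r2_max": 0.01, "n_pcs": 10},
    "mr": {"continuous_outcomes": ["bmi", "bodyfat", "sbp", "dbp"],
           "binary_outcomes": ["cvd", "diabetes"], "n_boot": 1000},
    "report": {"write_tables": True},
}


@dataclass
class PipelineConfig:
    raw: dict
    path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw=raw, path=str(path))

    def validate(self) -> dict:
        """Merge with defaults, rejecting unknown keys at both levels."""
        merged = json.loads(json.dumps(_DEFAULT_CONFIG))
        unknown = set(self.raw) - set(merged)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in self.raw.items():
            if isinstance(merged.get(key), dict) and isinstance(val, dict):
                if key != "simulate":  # SimConfig validates its own fields
                    bad = set(val) - set(merged[key])
                    if bad:
                        raise ValueError(f"unknown keys under {key!r}: {sorted(bad)}")
                merged[key].update(val)
            else:
                merged[key] = val
        bad_stages = set(merged["stages"]) - set(_STAGES)
        if bad_stages:
            raise ValueError(f"unknown stages: {sorted(bad_stages)}")
        if merged["stages"].get("mr") and not merged["stages"].get("simulate") \
                and not merged["inputs"].get("genotype"):
            raise ValueError("mr stage enabled but no genotype input and "
                             "simulation disabled")
        if not merged["stages"].get("simulate") and not merged["inputs"].get("cohort_csv"):
            raise ValueError("no cohort input and simulation disabled")
        return merged

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_stage(df: pd.DataFrame, out_dir: Path, name: str, params: dict,
                 cfg_hash: str) -> None:
    csv = out_dir / f"{name}.csv"
    df.to_csv(csv, index=False)
    sidecar = {"stage": name, "params": params, "config_hash": cfg_hash,
               "rows": len(df), "sha256": _sha256(csv)}
    (out_dir / f"{name}.json").write_text(json.dumps(sidecar, indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; returns a report bundle
    mapping stage -> output path. Raises with the stage name on failure;
    partial outputs are retained."""
    cfg = config.validate()
    cfg_hash = config.config_hash()
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    file_handler = logging.FileHandler(out_dir / "run.log")
    log.addHandler(file_handler)
    report: dict = {"config_hash": cfg_hash, "outputs": {}, "timings_s": {}}

    state: dict = {}
    try:
        for stage in _STAGES:
            if not cfg["stages"].get(stage, False):
                continue
            t0 = time.perf_counter()
            log.info("stage %s: starting", stage)
            try:
                _run_stage(stage, cfg, cfg_hash, out_dir, state, report)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            report["timings_s"][stage] = round(time.perf_counter() - t0, 3)
            log.info("stage %s: done in %.2fs", stage, report["timings_s"][stage])
        if cfg["report"]["write_tables"]:
            _write_report_tables(out_dir, state, report)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    finally:
        log.removeHandler(handler)
        log.removeHandler(file_handler)
        file_handler.close()
    return report


def _run_stage(stage, cfg, cfg_hash, out_dir, state, report):
    seed = int(cfg["seed"])
    if stage == "simulate":
        sim_cfg = synthetic.SimConfig(seed=seed, **cfg["simulate"])
        cohort, G, ped, truth = synthetic.generate_cohort(sim_cfg)
        state.update(cohort=cohort, genotypes=G, pedigree=ped, truth=truth)
        synthetic.write_cohort_csv(cohort, out_dir / "cohort.csv")
        synthetic.write_pedigree_tsv(ped, out_dir / "pedigree.tsv")
        geno.write_dosage_tsv(G, out_dir / "dosages.tsv")
        geno.write_vcf(G, out_dir / "genotypes.vcf")
        _write_stage(cohort, out_dir, "simulate",
                     {"seed": seed, **cfg["simulate"]}, cfg_hash)
        report["outputs"]["simulate"] = str(out_dir / "cohort.csv")
        return

    if "cohort" not in state:
        state["cohort"] = synthetic.read_cohort_csv(cfg["inputs"]["cohort_csv"])
    cohort = state["cohort"]

    if stage == "constructs":
        cons = income.compute_constructs(cohort)
        state["constructs"] = cons
        _write_stage(cons, out_dir, "constructs", cfg["constructs"], cfg_hash)
        report["outputs"]["constructs"] = str(out_dir / "constructs.csv")
    elif stage == "associate":
        cons = state.get("constructs")
        if cons is None:
            cons = income.compute_constructs(cohort)
        res = assoc.fit_income_models(
            cohort, cons, binary_method=cfg["associate"]["binary_method"],
            alpha=cfg["associate"]["alpha"])
        frame = assoc.results_to_frame(res)
        state["assoc"] = frame
        _write_stage(frame, out_dir, "associate", cfg["associate"], cfg_hash)
        report["outputs"]["associate"] = str(out_dir / "associate.csv")
    elif stage == "mediate":
        cons = state.get("constructs")
        if cons is None:
            cons = income.compute_constructs(cohort)
        df = cohort.merge(cons, on="individual_id")
        df["yitzhaki_1000"] = df["yitzhaki"] / 1000.0
        df["log_cortisol"] = np.log(df["cortisol"])
        med = mediation.mediation_bootstrap(
            df, n_boot=int(cfg["mediate"]["n_boot"]), seed=seed,
            outcome=cfg["mediate"]["outcome"])
        frame = pd.DataFrame([{
            "outcome": cfg["mediate"]["outcome"], "nde": med.nde, "nie": med.nie,
            "te": med.te, "proportion_mediated": med.proportion_mediated,
            "p_interaction": med.p_interaction, "n": med.n,
            **{f"{k}_ci_low": v[0] for k, v in med.ci.items()},
            **{f"{k}_ci_high": v[1] for k, v in med.ci.items()},
        }])
        state["mediate"] = frame
        _write_stage(frame, out_dir, "mediate", cfg["mediate"], cfg_hash)
        report["outputs"]["mediate"] = str(out_dir / "mediate.csv")
    elif stage == "qc":
        G = state.get("genotypes")
        if G is None:
            path = cfg["inputs"]["genotype"]
            G = geno.read_vcf(path) if str(path).endswith(".vcf") \
                else geno.read_dosage_tsv(path)
        q = cfg["qc"]
        G_clean, rep = geno.qc_filter(
            G, snp_missing_max=q["snp_missing_max"],
            sample_missing_max=q["sample_missing_max"], maf_min=q["maf_min"],
            hwe_p_min=q["hwe_p_min"], het_sd=q["het_sd"])
        kept = geno.ld_prune(G_clean, q["ld_r2_max"])
        n_pcs = min(q["n_pcs"], len(kept), G_clean.n_samples - 1)
        pcs = geno.pca(G_clean, n_components=n_pcs, snp_subset=kept)
        state.update(genotypes_qc=G_clean, pcs=pcs, qc_report=rep)
        (out_dir / "qc_report.json").write_text(rep.to_json())
        geno.write_dosage_tsv(G_clean, out_dir / "dosages_qc.tsv")
        report["outputs"]["qc"] = str(out_dir / "qc_report.json")
    elif stage == "mr":
        _run_mr_stage(cfg, cfg_hash, out_dir, state, report, seed)


def _run_mr_stage(cfg, cfg_hash, out_dir, state, report, seed):
    cohort = state["cohort"]
    G = state.get("genotypes_qc") or state.get("genotypes")
    if G is None:
        raise ValueError("mr stage requires genotypes (run qc/simulate or "
                         "provide inputs.genotype)")
    if "pedigree" in state:
        K, ids = geno.kinship_from_pedigree(state["pedigree"])
        order = {s: i for i, s in enumerate(ids)}
        sel = [order[s] for s in G.sample_ids]
        K = K[np.ix_(sel, sel)]
    else:
        K = geno.kinship_from_genotypes(G)

    df = cohort.set_index("individual_id").loc[G.sample_ids]
    ok = df["cortisol"].notna().to_numpy()
    log_cort = np.log(df["cortisol"].to_numpy(float))
    age = df["age"].to_numpy(float)
    male = (df["sex"] == "male").to_numpy(float)
    pcs = state.get("pcs")
    cov_w = np.column_stack([age, male] if pcs is None else [age, male, pcs])

    Gc = G.subset(samples=ok)
    weights = mr.gls_snp_weights(log_cort[ok], Gc, K[np.ix_(ok, ok)], cov_w[ok])
    pgs = mr.build_pgs(Gc, weights)
    covs = np.column_stack([age[ok], male[ok]])

    rows = []
    for out in cfg["mr"]["continuous_outcomes"]:
        y = df.loc[ok, out].to_numpy(float)
        cc = ~np.isnan(y)
        obs = mr.observational_reference(y[cc], log_cort[ok][cc], covs[cc])
        res = mr.tsls(y[cc], log_cort[ok][cc], pgs[cc], covs[cc],
                      obs_result=(obs["estimate"], obs["variance"]))
        rows.append(_mr_row(out, res, obs))
    for out in cfg["mr"]["binary_outcomes"]:
        y = df.loc[ok, out].to_numpy(float)
        cc = ~np.isnan(y)
        obs = mr.observational_reference(y[cc], log_cort[ok][cc], covs[cc])
        res = mr.mgmm(y[cc], log_cort[ok][cc], pgs[cc], covs[cc],
                      n_boot=int(cfg["mr"]["n_boot"]), seed=seed,
                      obs_result=(obs["log_estimate"], obs["variance"]))
        rows.append(_mr_row(out, res, obs))
    frame = pd.DataFrame(rows)
    state["mr"] = frame
    _write_stage(frame, out_dir, "mr", cfg["mr"], cfg_hash)
    report["outputs"]["mr"] = str(out_dir / "mr.csv")


def _mr_row(outcome, res: mr.MRResult, obs: dict) -> dict:
    return {"outcome": outcome, "method": res.method, "n": res.n,
            "obs_estimate": obs["estimate"], "obs_ci_low": obs["ci"][0],
            "obs_ci_high": obs["ci"][1], "mr_estimate": res.estimate,
            "mr_ci_low": res.ci_low, "mr_ci_high": res.ci_high,
            "first_stage_F": res.first_stage_F,
            "first_stage_partial_r2": res.first_stage_partial_r2,
            "hausman_p": res.hausman_p, "warnings": "; ".join(res.warnings)}


def _write_report_tables(out_dir: Path, state: dict, report: dict) -> None:
    cohort = state.get("cohort")
    if cohort is not None:
        cont = cohort.select_dtypes("number")
        table1 = pd.DataFrame({
            "variable": cont.columns,
            "n": cont.notna().sum().to_numpy(),
            "mean": cont.mean().round(3).to_numpy(),
            "sd": cont.std().round(3).to_numpy(),
        })
        table1.to_csv(out_dir / "table1_descriptives.csv", index=False)
        report["outputs"]["table1"] = str(out_dir / "table1_descriptives.csv")
    mapping = {"assoc": "table2_associations.csv", "mediate": "table3_mediation.csv"}
    for key, fname in mapping.items():
        if key in state:
            state[key].to_csv(out_dir / fname, index=False)
            report["outputs"][fname.split("_")[0]] = str(out_dir / fname)
    if "mr" in state:
        mr_frame = state["mr"]
        mr_frame[mr_frame["method"] == "2SLS"].to_csv(
            out_dir / "table4_mr_continuous.csv", index=False)
        mr_frame[mr_frame["method"] == "MGMM"].to_csv(
            out_dir / "table5_mr_binary.csv", index=False)
        report["outputs"]["table4"] = str(out_dir / "table4_mr_continuous.csv")
        report["outputs"]["table5"] = str(out_dir / "table5_mr_binary.csv")
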