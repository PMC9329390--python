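"""Config-driven orchestration of a full discovery/replication MR study.

``run_study`` executes, for every configured exposure-outcome pair:
instrument selection (p <= threshold, greedy LD clumping) -> harmonization
-> IVW, weighted median, MR-Egger, contamination mixture and MR-PRESSO per
stage -> fixed-effect combination of the stage IVW estimates -> Bonferroni
tiering -> heterogeneity/pleiotropy diagnostics, followed by any
multivariable-MR and mediation blocks. ``run_reverse`` swaps the roles,
taking the disease instruments from a configured file. All randomness
derives from the config seed, and a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .estimators import (MRResult, contamination_mixture, egger, ivw,
                         weighted_median)
from .instruments import (LDTable, SelectionConfig, f_statistic, greedy_clump,
                          select_instruments, variance_explained)
from .meta_power import (PowerSpec, classify_association, detectable_or,
                         fixed_effect_meta)
from .mvmr import mediation, multi_harmonize, mvmr_ivw
from .presso import PressoConfig, mr_presso
from .summary_io import (AssociationTable, HarmonizationPolicy, HarmonizedSet,
                         harmonize, read_association_table)

__all__ = ["StudyConfig", "StudyReport", "load_config", "run_study", "run_reverse"]

_RESULT_COLS = ["exposure", "outcome", "stage", "method", "estimate", "se",
                "ci_low", "ci_high", "pvalue", "odds_ratio", "n_snps", "tier"]
_DIAG_COLS = ["exposure", "outcome", "stage", "n_snps", "cochran_q", "q_df",
              "q_pvalue", "egger_intercept", "egger_intercept_p",
              "presso_global_p", "presso_outliers", "presso_distortion_p"]
_STRENGTH_COLS = ["exposure", "n_snps", "variance_explained", "f_statistic",
                  "weak_instruments", "detectable_or_discovery",
                  "detectable_or_replication"]


@dataclass
class ExposureSpec:
    label: str
    file: str
    unit: str = ""
    p_threshold: float | None = None


@dataclass
class OutcomeStage:
    file: str
    n_cases: int | None = None
    n_controls: int | None = None


@dataclass
class StudyConfig:
    seed: int
    exposures: list[ExposureSpec]
    outcome_label: str
    discovery: OutcomeStage
    replication: OutcomeStage | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    harmonization: HarmonizationPolicy = field(default_factory=HarmonizationPolicy)
    ld_file: str | None = None
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    n_exposures_for_bonferroni: int | None = None
    mvmr_blocks: list[list[str]] = field(default_factory=list)
    mediation_blocks: list[tuple[str, str]] = field(default_factory=list)
    reverse: dict | None = None
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        if not self.exposures:
            raise ValueError("config needs at least one exposure entry")

    @property
    def n_bonferroni(self) -> int:
        return self.n_exposures_for_bonferroni or len(self.exposures)


def load_config(path: str | Path) -> StudyConfig:
    """Parse and validate a YAML study configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")

    def need(key):
        if key not in raw:
            raise ValueError(f"{path}: missing required key '{key}'")
        return raw[key]

    seed = int(need("seed"))
    exposures = [ExposureSpec(label=e["label"], file=e["file"],
                              unit=e.get("unit", ""),
                              p_threshold=e.get("p_threshold"))
                 for e in need("exposures")]
    out = need("outcome")
    discovery = OutcomeStage(**out["discovery"]) if isinstance(out["discovery"], dict) \
        else OutcomeStage(file=out["discovery"])
    replication = None
    if out.get("replication"):
        rep = out["replication"]
        replication = OutcomeStage(**rep) if isinstance(rep, dict) \
            else OutcomeStage(file=rep)

    sel = SelectionConfig(**raw.get("selection", {}))
    harm = HarmonizationPolicy(**raw.get("harmonization", {}))
    est = raw.get("estimators", {})
    med = [(m["exposure"], m["mediator"]) for m in raw.get("mediation", [])]
    return StudyConfig(
        seed=seed,
        exposures=exposures,
        outcome_label=out.get("label", "outcome"),
        discovery=discovery,
        replication=replication,
        selection=sel,
        harmonization=harm,
        ld_file=raw.get("ld_file"),
        ivw_model=est.get("ivw_model", "multiplicative_random"),
        n_boot=int(est.get("n_boot", 1000)),
        presso_n_sim=int(est.get("presso_n_sim", 1000)),
        n_exposures_for_bonferroni=raw.get("n_exposures_for_bonferroni"),
        mvmr_blocks=[list(b["exposures"]) for b in raw.get("mvmr", [])],
        mediation_blocks=med,
        reverse=raw.get("reverse_mr"),
        base_dir=path.parent)


@dataclass
class StudyReport:
    results: pd.DataFrame
    diagnostics: pd.DataFrame
    strength: pd.DataFrame
    mvmr: pd.DataFrame
    mediation: pd.DataFrame
    errors: list[dict]
    metadata: dict

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        for name, df in (("results", self.results), ("diagnostics", self.diagnostics),
                         ("strength", self.strength), ("mvmr", self.mvmr),
                         ("mediation", self.mediation)):
            df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False,
                      float_format=fmt)
        with open(out_dir / "run_metadata.txt", "w") as fh:
            for k, v in sorted(self.metadata.items()):
                fh.write(f"{k}\t{v}\n")
            for err in self.errors:
                fh.write(f"error\t{json.dumps(err, sort_keys=True)}\n")


def _derived_seed(base: int, *tags: int) -> int:
    h = hashlib.sha256(("/".join(str(t) for t in (base, *tags))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _result_row(exposure, outcome, stage, res: MRResult, tier="") -> dict:
    return {"exposure": exposure, "outcome": outcome, "stage": stage,
            "method": res.method, "estimate": res.estimate, "se": res.se,
            "ci_low": res.ci_low, "ci_high": res.ci_high, "pvalue": res.pvalue,
            "odds_ratio": math.exp(res.estimate), "n_snps": res.n_snps,
            "tier": tier}


def _resolve(base_dir: Path, file: str) -> Path:
    p = Path(file)
    return p if p.is_absolute() else base_dir / p


def _prepare_instruments(cfg: StudyConfig, exp: ExposureSpec,
                         ld: LDTable | None) -> AssociationTable:
    table = read_association_table(_resolve(cfg.base_dir, exp.file),
                                   trait_label=exp.label)
    sel = cfg.selection if exp.p_threshold is None else \
        SelectionConfig(p_threshold=exp.p_threshold,
                        r2_threshold=cfg.selection.r2_threshold)
    table = select_instruments(table, sel)
    return greedy_clump(table, ld, sel)


def _stage_analyses(cfg: StudyConfig, hs: HarmonizedSet, exposure: str,
                    stage: str, pair_i: int, stage_i: int,
                    results: list, diags: list) -> MRResult | None:
    """Run the five estimators plus diagnostics on one harmonized stage."""
    n_bonf = cfg.n_bonferroni
    ivw_res, qres = ivw(hs, model=cfg.ivw_model)
    tier, _ = classify_association(ivw_res.pvalue, n_bonf)
    results.append(_result_row(exposure, cfg.outcome_label, stage, ivw_res, tier))

    diag = {"exposure": exposure, "outcome": cfg.outcome_label, "stage": stage,
            "n_snps": hs.n_snps,
            "cochran_q": qres.q if qres else float("nan"),
            "q_df": qres.df if qres else float("nan"),
            "q_pvalue": qres.pvalue if qres else float("nan"),
            "egger_intercept": float("nan"), "egger_intercept_p": float("nan"),
            "presso_global_p": float("nan"), "presso_outliers": 0,
            "presso_distortion_p": float("nan")}

    if hs.n_snps >= 3:
        wm = weighted_median(hs, n_boot=cfg.n_boot,
                             seed=_derived_seed(cfg.seed, pair_i, stage_i, 1))
        tier, _ = classify_association(wm.pvalue, n_bonf)
        results.append(_result_row(exposure, cfg.outcome_label, stage, wm, tier))

        eg = egger(hs)
        tier, _ = classify_association(eg.slope.pvalue, n_bonf)
        results.append(_result_row(exposure, cfg.outcome_label, stage, eg.slope, tier))
        diag["egger_intercept"] = eg.intercept
        diag["egger_intercept_p"] = eg.intercept_pvalue

    if hs.n_snps >= 2:
        cm = contamination_mixture(hs)
        cm_row = {"exposure": exposure, "outcome": cfg.outcome_label,
                  "stage": stage, "method": "contamination_mixture",
                  "estimate": cm.estimate, "se": float("nan"),
                  "ci_low": cm.ci_low, "ci_high": cm.ci_high,
                  "pvalue": float("nan"), "odds_ratio": math.exp(cm.estimate),
                  "n_snps": cm.n_snps, "tier": ""}
        results.append(cm_row)

    if hs.n_snps >= 4:
        pres = mr_presso(hs, PressoConfig(
            n_sim=cfg.presso_n_sim,
            seed=_derived_seed(cfg.seed, pair_i, stage_i, 2)))
        corrected = pres.corrected_estimate
        tier, _ = classify_association(corrected.pvalue, n_bonf)
        row = _result_row(exposure, cfg.outcome_label, stage, corrected, tier)
        row["method"] = "presso_corrected"
        results.append(row)
        diag["presso_global_p"] = pres.global_p
        diag["presso_outliers"] = len(pres.outlier_ids)
        diag["presso_distortion_p"] = pres.distortion_p

    diags.append(diag)
    return ivw_res


def _strength_row(cfg: StudyConfig, exp: ExposureSpec,
                  instruments: AssociationTable) -> dict:
    row = {"exposure": exp.label, "n_snps": len(instruments),
           "variance_explained": float("nan"), "f_statistic": float("nan"),
           "weak_instruments": "", "detectable_or_discovery": float("nan"),
           "detectable_or_replication": float("nan")}
    try:
        r2 = variance_explained(instruments)
    except ValueError:
        return row
    row["variance_explained"] = r2
    n = instruments.data["n"].dropna()
    if len(n) and 0 < r2 < 1:
        rep = f_statistic(r2, int(n.max()), len(instruments))
        row["f_statistic"] = rep.f_stat
        row["weak_instruments"] = str(rep.weak_flag)
        for stage_name, stage in (("discovery", cfg.discovery),
                                  ("replication", cfg.replication)):
            if stage and stage.n_cases and stage.n_controls:
                or_hi, _ = detectable_or(PowerSpec(stage.n_cases,
                                                   stage.n_controls, r2))
                row[f"detectable_or_{stage_name}"] = or_hi
    return row


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute the configured study; per-pair failures are recorded, not fatal."""
    ld = LDTable.from_tsv(_resolve(cfg.base_dir, cfg.ld_file)) if cfg.ld_file else None
    stages: list[tuple[str, OutcomeStage]] = [("discovery", cfg.discovery)]
    if cfg.replication:
        stages.append(("replication", cfg.replication))
    outcome_tables = {}
    for stage_name, stage in stages:
        outcome_tables[stage_name] = read_association_table(
            _resolve(cfg.base_dir, stage.file), trait_label=cfg.outcome_label)

    results: list[dict] = []
    diags: list[dict] = []
    strength: list[dict] = []
    errors: list[dict] = []
    instrument_sets: dict[str, AssociationTable] = {}
    harmonized: dict[tuple[str, str], HarmonizedSet] = {}

    for pair_i, exp in enumerate(cfg.exposures):
        try:
            instruments = _prepare_instruments(cfg, exp, ld)
            if len(instruments) == 0:
                raise ValueError(f"no instruments pass selection for '{exp.label}'")
            instrument_sets[exp.label] = instruments
            strength.append(_strength_row(cfg, exp, instruments))
            stage_ivws: list[tuple[float, float]] = []
            stage_ns: list[int] = []
            for stage_i, (stage_name, _) in enumerate(stages):
                hs = harmonize(instruments, outcome_tables[stage_name],
                               cfg.harmonization)
                harmonized[(exp.label, stage_name)] = hs
                ivw_res = _stage_analyses(cfg, hs, exp.label, stage_name,
                                          pair_i, stage_i, results, diags)
                stage_ivws.append((ivw_res.estimate, ivw_res.se))
                stage_ns.append(hs.n_snps)
            if len(stage_ivws) == 2:
                est, se, p = fixed_effect_meta(stage_ivws)
                combined = MRResult.from_normal("ivw_combined", est, se,
                                                min(stage_ns))
                tier, _ = classify_association(combined.pvalue, cfg.n_bonferroni)
                results.append(_result_row(exp.label, cfg.outcome_label,
                                           "combined", combined, tier))
        except Exception as exc:  # per-pair isolation by design
            errors.append({"exposure": exp.label, "error": str(exc)})

    mvmr_rows: list[dict] = []
    mediation_rows: list[dict] = []
    label_to_spec = {e.label: e for e in cfg.exposures}

    def _joint_set(labels: list[str], stage_name: str):
        tables = [instrument_sets[l] for l in labels]
        union_ids = sorted(set().union(*[set(t.data["variant_id"]) for t in tables]))
        full = [read_association_table(_resolve(cfg.base_dir,
                                                label_to_spec[l].file),
                                       trait_label=l) for l in labels]
        sub = []
        for t in full:
            present = t.data["variant_id"].isin(union_ids)
            sub.append(t.subset(present))
        # joint re-clump at the same r2 threshold keeping the smallest
        # exposure-association p across the contributing exposures
        if ld is not None:
            best_p = pd.concat([t.data[["variant_id", "pvalue"]] for t in sub]) \
                .groupby("variant_id")["pvalue"].min().reset_index()
            pool = sub[0].data.drop(columns=["pvalue"]).merge(best_p, on="variant_id")
            pooled = AssociationTable(pool, trait_label="joint")
            keep = set(greedy_clump(pooled, ld, cfg.selection).data["variant_id"])
            sub = [t.subset(t.data["variant_id"].isin(keep)) for t in sub]
        return multi_harmonize(sub, outcome_tables[stage_name], cfg.harmonization)

    combined_stage = "combined" if cfg.replication else "discovery"

    for labels in cfg.mvmr_blocks:
        try:
            per_stage: dict[str, list] = {}
            for stage_name, _ in stages:
                mset = _joint_set(labels, stage_name)
                per_stage[stage_name] = mvmr_ivw(mset)
            for i, lab in enumerate(labels):
                ests = [(per_stage[s][i].estimate, per_stage[s][i].se)
                        for s, _ in stages]
                est, se, p = fixed_effect_meta(ests)
                mvmr_rows.append({
                    "model": "+".join(labels), "exposure": lab,
                    "stage": combined_stage, "estimate": est, "se": se,
                    "odds_ratio": math.exp(est),
                    "ci_low": est - 1.959963984540054 * se,
                    "ci_high": est + 1.959963984540054 * se,
                    "pvalue": p, "n_snps": per_stage[stages[0][0]][i].n_snps})
        except Exception as exc:
            errors.append({"mvmr": "+".join(labels), "error": str(exc)})

    for exp_label, med_label in cfg.mediation_blocks:
        try:
            totals, directs = [], []
            for stage_name, _ in stages:
                hs = harmonized[(exp_label, stage_name)]
                total_res, _ = ivw(hs, model=cfg.ivw_model)
                totals.append((total_res.estimate, total_res.se))
                mset = _joint_set([exp_label, med_label], stage_name)
                direct_res = mvmr_ivw(mset)[0]
                directs.append((direct_res.estimate, direct_res.se))
            t_est, t_se, _ = fixed_effect_meta(totals)
            d_est, d_se, _ = fixed_effect_meta(directs)
            med = mediation((t_est, t_se), (d_est, d_se))
            mediation_rows.append({
                "model": f"{exp_label} adjusted for {med_label}",
                "stage": combined_stage,
                "total_or": math.exp(t_est), "direct_or": math.exp(d_est),
                "direct_ci_low": math.exp(d_est - 1.959963984540054 * d_se),
                "direct_ci_high": math.exp(d_est + 1.959963984540054 * d_se),
                "proportion_pct": 100 * med.proportion,
                "proportion_ci_low_pct": 100 * med.ci_low,
                "proportion_ci_high_pct": 100 * med.ci_high})
        except Exception as exc:
            errors.append({"mediation": f"{exp_label}/{med_label}",
                           "error": str(exc)})

    if not results and errors:
        raise RuntimeError(f"all exposure-outcome pairs failed: {errors}")

    metadata = {"package_version": __version__, "seed": cfg.seed,
                "n_exposures_for_bonferroni": cfg.n_bonferroni,
                "ivw_model": cfg.ivw_model,
                "config_hash": hashlib.sha256(
                    repr(cfg).encode()).hexdigest()[:16]}
    return StudyReport(
        results=pd.DataFrame(results, columns=_RESULT_COLS),
        diagnostics=pd.DataFrame(diags, columns=_DIAG_COLS),
        strength=pd.DataFrame(strength, columns=_STRENGTH_COLS),
        mvmr=pd.DataFrame(mvmr_rows),
        mediation=pd.DataFrame(mediation_rows),
        errors=errors, metadata=metadata)


def run_reverse(cfg: StudyConfig) -> StudyReport:
    """Reverse-direction MR: disease instruments from the configured file,
    former exposures as outcomes."""
    if not cfg.reverse:
        raise ValueError("config has no reverse_mr block")
    block = cfg.reverse
    if "instrument_file" not in block or "outcome_files" not in block:
        raise ValueError("reverse_mr block needs 'instrument_file' and "
                         "'outcome_files'")
    instr = read_association_table(
        _resolve(cfg.base_dir, block["instrument_file"]),
        trait_label=block.get("label", cfg.outcome_label))
    # instruments are taken from the file as-is: no significance filter
    exposures = [ExposureSpec(label=f"{instr.trait_label}->{out_label}",
                              file=block["instrument_file"], p_threshold=1.0)
                 for out_label in block["outcome_files"]]
    results: list[dict] = []
    diags: list[dict] = []
    errors: list[dict] = []
    for pair_i, (out_label, out_file) in enumerate(
            sorted(block["outcome_files"].items())):
        try:
            out_table = read_association_table(_resolve(cfg.base_dir, out_file),
                                               trait_label=out_label)
            hs = harmonize(instr, out_table, cfg.harmonization)
            rev_cfg = StudyConfig(
                seed=cfg.seed, exposures=[exposures[pair_i]],
                outcome_label=out_label, discovery=cfg.discovery,
                selection=cfg.selection, harmonization=cfg.harmonization,
                ivw_model=cfg.ivw_model, n_boot=cfg.n_boot,
                presso_n_sim=cfg.presso_n_sim,
                n_exposures_for_bonferroni=cfg.n_bonferroni)
            hs.exposure_label = instr.trait_label
            _stage_analyses(rev_cfg, hs, instr.trait_label, "reverse",
                            1000 + pair_i, 0, results, diags)
        except Exception as exc:
            errors.append({"outcome": out_label, "error": str(exc)})
    if not results and errors:
        raise RuntimeError(f"all reverse pairs failed: {errors}")
    metadata = {"package_version": __version__, "seed": cfg.seed,
                "direction": "reverse"}
    empty = pd.DataFrame()
    return StudyReport(results=pd.DataFrame(results, columns=_RESULT_COLS),
                       diagnostics=pd.DataFrame(diags, columns=_DIAG_COLS),
                       strength=pd.DataFrame(columns=_STRENGTH_COLS),
                       mvmr=empty, mediation=empty,
                       errors=errors, metadata=metadata)
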