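"""End-to-end orchestration of the onset-modifier design.

Runs simulate -> extreme-group selection -> QC -> association scan ->
candidate selection/LD collapse -> confirmation (siblings, four-group
trend, GRS) -> susceptibility checks (family-based test, matched
case-control), writing one TSV artifact per stage plus a run log and the
resolved configuration, so a run is reproducible byte-for-byte from
(config, seed).

All randomness derives from the single root seed through a fixed
per-stage spawn order; any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, confirm, famcc, qc, syndata
from .gio import write_pheno_tsv, write_results_tsv
from .syndata import SimulationConfig

__all__ = ["PipelineConfig", "run_full", "report"]

_STAGES = ("simulate", "fixture", "qc", "scan", "perm", "controls")


@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run.

    Threshold defaults are the conventional printed values: sample and
    marker call rate 0.98, MAF 0.05, HWE 0.001, suggestive 1e-4,
    genome-wide 7.2e-8, LD r^2 0.8, matching ratio 5.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_extreme: int = 95
    n_middle: int = 66
    sample_call: float = 0.98
    marker_call: float = 0.98
    maf_thresh: float = 0.05
    hwe_thresh: float = 0.001
    kinship_thresh: float = 0.354
    ancestry_z: float = 5.0
    mds_k: int = 4
    suggestive: float = assoc.SUGGESTIVE_P
    genomewide: float = assoc.GENOMEWIDE_P
    r2_thresh: float = 0.8
    ld_window_bp: int = 500_000
    perm_B: int = 2000
    ratio: int = 5
    age_bin_years: float = 5.0
    n_control_pool: int = 20_000
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sim"]["maf_range"] = list(d["sim"]["maf_range"])
        d["sim"]["modifier_effects_years"] = list(
            d["sim"]["modifier_effects_years"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("sim", {})
        sim["maf_range"] = tuple(sim.get("maf_range", (0.05, 0.5)))
        sim["modifier_effects_years"] = tuple(
            sim.get("modifier_effects_years", (-4.0,)))
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        cfg = cls(sim=SimulationConfig(**{k: v for k, v in sim.items()
                                          if k in known}))
        for k, v in d.items():
            if hasattr(cfg, k):
                setattr(cfg, k, v)
        return cfg


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(len(_STAGES))
    return {s: int(v % (2 ** 31)) for s, v in zip(_STAGES, state)}


def run_full(config: PipelineConfig, out_dir) -> Path:
    """Execute every stage and persist artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    log: list[dict] = []

    def note(stage, **kw):
        log.append({"stage": stage, **kw})

    # -- simulate and select the design groups -------------------------
    sim_cfg = replace(config.sim, seed=seeds["simulate"])
    cohort = syndata.simulate_cohort(sim_cfg)
    ped = syndata.rank_and_select_extremes(cohort, config.n_extreme,
                                           config.n_middle)
    cohort.pedigree = ped
    write_pheno_tsv(ped, out / "pedigree.tsv")
    note("simulate", seed=seeds["simulate"],
         n_individuals=len(ped), n_markers=cohort.genotypes.n_markers,
         true_modifiers=list(cohort.true_modifiers))

    extreme = ped[(ped["role"] == "proband")
                  & ped["aao_group"].isin(["earliest", "latest"])]
    g_pro = cohort.genotypes.subset(samples=list(extreme["iid"]))

    # -- QC -------------------------------------------------------------
    s_report, mds = qc.sample_qc(g_pro, call_thresh=config.sample_call,
                                 kinship_thresh=config.kinship_thresh,
                                 z_thresh=config.ancestry_z,
                                 mds_k=config.mds_k)
    kept = [s for s in g_pro.samples
            if s not in set(s_report.removed_samples["iid"])]
    g_kept = g_pro.subset(samples=kept)
    m_report = qc.marker_filters(g_kept, call_thresh=config.marker_call,
                                 maf_thresh=config.maf_thresh,
                                 hwe_thresh=config.hwe_thresh)
    bad = set(m_report.removed_markers["marker"])
    good_markers = [m for m in g_kept.markers.index if m not in bad]
    g_scan = g_kept.subset(markers=good_markers)
    s_report.removed_samples.to_csv(out / "qc_removed_samples.tsv",
                                    sep="\t", index=False)
    m_report.removed_markers.to_csv(out / "qc_removed_markers.tsv",
                                    sep="\t", index=False)
    mds.coords.rename_axis("iid").to_csv(out / "mds.tsv", sep="\t")
    note("qc", samples_in=g_pro.n_samples, samples_out=len(kept),
         samples_removed=int(len(s_report.removed_samples)),
         markers_in=g_kept.n_markers, markers_out=len(good_markers),
         markers_removed=int(len(m_report.removed_markers)))

    # -- extreme-group scan ---------------------------------------------
    groups = ped.set_index("iid").loc[kept, "aao_group"]
    results = assoc.gwas_scan(g_scan, groups, mds)
    lam = qc.genomic_inflation(p_values=results["p_wald"].dropna())
    write_results_tsv(results, out / "gwas_results.tsv")
    note("scan", n_markers=len(results), lambda_gc=round(lam, 4),
         mds_components=results.attrs.get("mds_components_used", []))

    candidates = None
    n_suggestive = int((results["p_wald"] < config.suggestive).sum())
    if n_suggestive:
        candidates = assoc.select_candidates(results, g_scan,
                                             suggestive=config.suggestive,
                                             genomewide=config.genomewide)
        candidates = assoc.ld_collapse(candidates, g_scan,
                                       r2_thresh=config.r2_thresh,
                                       window_bp=config.ld_window_bp)
        # permutation empirical p for the retained candidates
        retained = candidates[candidates["status"] == "retained"]
        emp = {}
        for m in retained["marker"]:
            p_emp, _ = assoc.empirical_p(g_scan, groups, m, mds,
                                         B_max=config.perm_B,
                                         seed=seeds["perm"])
            emp[m] = p_emp
        candidates["p_empirical"] = candidates["marker"].map(emp)
        write_results_tsv(candidates, out / "candidates.tsv")
    note("candidates", n_suggestive=n_suggestive,
         n_retained=0 if candidates is None
         else int((candidates["status"] == "retained").sum()),
         n_collapsed=0 if candidates is None
         else int((candidates["status"] == "ld_collapsed").sum()))

    if candidates is not None:
        cand_markers = list(
            candidates.loc[candidates["status"] == "retained", "marker"])
        _confirmation(config, cohort, ped, kept, results, cand_markers,
                      seeds, out, note)

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    config.to_yaml(out / "config_resolved.yaml")
    return out


def _confirmation(config, cohort, ped, kept_probands, results, cand_markers,
                  seeds, out: Path, note) -> None:
    g_all = cohort.genotypes
    pedi = ped.set_index("iid")
    kept_fids = set(pedi.loc[kept_probands, "fid"])

    # sibling replication in the extreme families that survived QC
    sib_mask = ((ped["role"] == "co_sib")
                & ped["aao_group"].isin(["earliest", "latest"])
                & ped["fid"].isin(kept_fids))
    sib_ids = list(ped.loc[sib_mask, "iid"])
    m_tests = len(cand_markers)
    sib_groups = pedi.loc[sib_ids, "aao_group"]
    replication = confirm.sibling_replication(
        g_all.subset(markers=cand_markers), sib_groups, m_tests=m_tests)
    write_results_tsv(replication.rename(columns={"p_wald": "p_wald"}),
                      out / "replication.tsv")
    note("replication", n_sibs=len(sib_ids), m_tests=m_tests,
         threshold=0.05 / m_tests,
         n_significant=int(replication["significant"].sum()))

    # four-group ordinal trend over all selected probands
    pro4 = ped[(ped["role"] == "proband") & (ped["aao_group"] != "none")]
    trend = confirm.ordinal_trend(
        g_all.subset(markers=cand_markers),
        pro4.set_index("iid")["aao_group"])
    write_results_tsv(trend.drop(columns=["group_maf"]), out / "trend.tsv")
    note("trend", n_probands=len(pro4),
         n_significant=int((trend["p_trend"] < 0.05).sum()))

    # GRS: learn on the surviving extreme probands, apply everywhere
    g_learn = g_all.subset(samples=kept_probands, markers=cand_markers)
    profile = confirm.grs_learn(results, g_learn, cand_markers)
    score_pro = confirm.grs_score(profile, g_learn)
    score_sib = confirm.grs_score(
        profile, g_all.subset(samples=sib_ids, markers=cand_markers))
    score_pro4 = confirm.grs_score(
        profile, g_all.subset(samples=list(pro4["iid"]),
                              markers=cand_markers))
    groups_pro = pedi.loc[score_pro.index, "aao_group"]
    u_p, z_p, p_pro = confirm.mann_whitney(
        score_pro[groups_pro == "earliest"],
        score_pro[groups_pro == "latest"])
    u_s, z_s, p_sib = confirm.mann_whitney(
        score_sib[sib_groups.loc[score_sib.index] == "earliest"],
        score_sib[sib_groups.loc[score_sib.index] == "latest"])
    slope, t_stat, p_trend_grs = confirm.grs_group_trend(
        score_pro4, pro4.set_index("iid")["aao_group"])
    scores = pd.concat([
        score_pro.rename("grs").to_frame().assign(set="probands"),
        score_sib.rename("grs").to_frame().assign(set="siblings"),
    ])
    scores.rename_axis("iid").to_csv(out / "grs_scores.tsv", sep="\t")
    note("grs", p_mw_probands=p_pro, p_mw_siblings=p_sib,
         trend_slope=slope, p_trend=p_trend_grs)

    # susceptibility side: family-based test + matched case-control
    fbat_rows = [famcc.fbat_additive(g_all, ped[ped["fid"].isin(kept_fids)], m)
                 for m in cand_markers]
    fbat = pd.DataFrame(fbat_rows)
    write_results_tsv(fbat, out / "fbat.tsv")

    ctl_ped, ctl_g = syndata.simulate_control_pool(
        config.n_control_pool, cohort.marker_maf, g_all.markers,
        seed=seeds["controls"])
    cases = ped[ped["iid"].isin(kept_probands)]
    matched = famcc.match_controls(cases, ctl_ped, ratio=config.ratio,
                                   age_bin_years=config.age_bin_years,
                                   seed=seeds["controls"])
    covars = pd.concat([cases.set_index("iid")[["age", "sex"]],
                        matched.set_index("iid")[["age", "sex"]]])
    cc = famcc.case_control_assoc(
        g_all.subset(samples=kept_probands, markers=cand_markers),
        ctl_g.subset(samples=list(matched["iid"]), markers=cand_markers),
        covars)
    write_results_tsv(cc, out / "casecontrol.tsv")
    note("famcc", n_cases=len(cases), n_controls=len(matched),
         fbat_min_p=float(fbat["p"].min()) if len(fbat) else np.nan,
         cc_min_p=float(cc["p_wald"].min()) if len(cc) else np.nan)


def report(run_dir) -> str:
    """Human-readable markdown summary of a completed run."""
    run = Path(run_dir)
    lines = [f"# Run summary: {run.name}", ""]
    log_path = run / "run_log.json"
    if not log_path.exists():
        return "\n".join(lines + ["(no run log found)"])
    log = json.loads(log_path.read_text())
    by_stage = {e["stage"]: e for e in log}

    if "qc" in by_stage:
        e = by_stage["qc"]
        lines += ["## Quality control",
                  f"- samples: {e['samples_in']} in, {e['samples_out']} kept, "
                  f"{e['samples_removed']} removed",
                  f"- markers: {e['markers_in']} in, {e['markers_out']} kept, "
                  f"{e['markers_removed']} removed", ""]
    if "scan" in by_stage:
        e = by_stage["scan"]
        lines += ["## Association scan",
                  f"- markers tested: {e['n_markers']}",
                  f"- genomic inflation factor: {e['lambda_gc']}",
                  f"- MDS covariates used: {e['mds_components'] or 'none'}", ""]
    if "candidates" in by_stage:
        e = by_stage["candidates"]
        lines += ["## Candidates",
                  f"- suggestive markers: {e['n_suggestive']}",
                  f"- retained after LD collapse: {e['n_retained']} "
                  f"(+{e['n_collapsed']} collapsed)", ""]
        if e["n_suggestive"] == 0:
            lines += ["No candidates; confirmation stages skipped.", ""]
    if "replication" in by_stage:
        e = by_stage["replication"]
        lines += ["## Sibling replication",
                  f"- {e['n_sibs']} co-affected siblings, "
                  f"Bonferroni threshold {e['threshold']:.4f} "
                  f"({e['m_tests']} tests)",
                  f"- significant markers: {e['n_significant']}", ""]
    if "grs" in by_stage:
        e = by_stage["grs"]
        lines += ["## Genetic risk score",
                  f"- Mann-Whitney earliest vs latest, probands: "
                  f"p = {e['p_mw_probands']:.3g}",
                  f"- Mann-Whitney earliest vs latest, siblings: "
                  f"p = {e['p_mw_siblings']:.3g}",
                  f"- four-group trend slope {e['trend_slope']:.3f}, "
                  f"p = {e['p_trend']:.3g}", ""]
    if "famcc" in by_stage:
        e = by_stage["famcc"]
        lines += ["## Susceptibility checks",
                  f"- matched case-control: {e['n_cases']} cases, "
                  f"{e['n_controls']} controls",
                  f"- smallest family-based p: {e['fbat_min_p']:.3g}",
                  f"- smallest case-control p: {e['cc_min_p']:.3g}", ""]
    text = "\n".join(lines)
    (run / "report.md").write_text(text)
    return text
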