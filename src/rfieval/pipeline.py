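"""End-to-end orchestration: simulate -> phenotypes -> matrices -> REML ->
GBLUP -> cohort analyses, from a single :class:`rfieval.config.RunConfig`."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .config import RunConfig, SimulationConfig, stage_seed
from .cohorts import assign_groups, count_close_relatives, fit_power_curve, rank_cross_tab
from .gblup import GBLUP
from .phenotypes import filter_daily_records, fit_cow_rfi, fit_heifer_rfi, summarize_cows, summarize_heifers
from .relationships import build_A, build_G, stabilize
from .simulate import (
    simulate_cow_daily_records,
    simulate_genotypes,
    simulate_heifer_records,
    simulate_pedigree,
    simulate_true_breeding_values,
)
from .varcomp import BivariateAnimalModel, UnivariateAnimalModel

log = logging.getLogger("rfieval")

__all__ = ["run_pipeline", "run_recovery_study", "RunReport"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunReport(dict):
    """Per-stage record counts, estimates and a hashed file manifest."""

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self, indent=2, default=str))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    Every output file lands in ``config.outdir`` and is listed in the report
    manifest with a content hash; the archived config plus the seed
    reproduce the run.
    """
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(stages={}, seed=config.seed)
    (out / "run_config.json").write_text(config.to_json())

    sim = config.simulation
    state: dict = {}

    if "simulate" in config.stages:
        seed = stage_seed(config.seed, "simulate")
        rng = np.random.default_rng(seed)
        ped = simulate_pedigree(sim, seed=rng.integers(2**31 - 1))
        gm = simulate_genotypes(ped, sim, seed=rng.integers(2**31 - 1))
        A = build_A(ped)
        tbv = simulate_true_breeding_values(
            A.values, sim.genetic_covariance, seed=rng.integers(2**31 - 1)
        )
        # phenotype the youngest generation as cows; the same animals also
        # have earlier heifer trials
        last_gen = ped["generation"].max()
        pheno_ids = ped.loc[ped["generation"] == last_gen, "animal"].to_numpy()
        idx = {a: i for i, a in enumerate(ped["animal"])}
        rows = np.array([idx[a] for a in pheno_ids])
        daily = simulate_cow_daily_records(
            pheno_ids, tbv[rows, 1], sim, seed=rng.integers(2**31 - 1)
        )
        sbw, hdmi, hmeta = simulate_heifer_records(
            pheno_ids, tbv[rows, 0], sim, seed=rng.integers(2**31 - 1)
        )
        rio.write_pedigree(ped, out / "pedigree.tsv")
        rio.write_genotypes_traw(gm, out / "genotypes.traw")
        rio.write_genotypes_matrix(gm, out / "genotypes.tsv")
        daily.to_csv(out / "cow_daily.csv", index=False)
        sbw.to_csv(out / "heifer_serial_bw.csv", index=False)
        hdmi.to_csv(out / "heifer_daily_dmi.csv", index=False)
        hmeta.to_csv(out / "heifer_meta.csv", index=False)
        state.update(ped=ped, gm=gm, A=A, tbv=tbv, daily=daily, sbw=sbw,
                     hdmi=hdmi, hmeta=hmeta, pheno_ids=pheno_ids)
        report["stages"]["simulate"] = {
            "n_animals": len(ped),
            "n_phenotyped": len(pheno_ids),
            "n_snps": gm.n_snps,
            "n_daily_records": len(daily),
        }
        log.info("simulate: %d animals, %d cows with daily records",
                 len(ped), len(pheno_ids))
    else:
        state["ped"] = rio.read_pedigree(config.pedigree_path)
        state["A"] = build_A(state["ped"])
        state["daily"] = pd.read_csv(config.cow_daily_path)
        if config.genotype_path:
            state["gm"] = rio.read_genotypes_traw(config.genotype_path)

    if "phenotypes" in config.stages:
        filtered, qc = filter_daily_records(state["daily"])
        cows = summarize_cows(filtered)
        rfi_cow, _ = fit_cow_rfi(cows)
        state["cows"] = cows
        state["rfi_cow"] = rfi_cow
        cows.to_csv(out / "cow_traits.csv", index=False)
        rfi_cow.rename_axis("animal_id").to_csv(out / "rfi_cow.csv")
        (out / "qc_report.json").write_text(qc.to_json())
        stage_rep = {
            "n_cows": len(cows),
            "daily_fraction_removed": qc.fraction_removed,
            "n_animals_removed": len(qc.animals_removed),
        }
        if "sbw" in state:
            heifers = summarize_heifers(state["sbw"], state["hdmi"], state["hmeta"])
            rfi_h, _ = fit_heifer_rfi(heifers)
            state["heifers"] = heifers
            state["rfi_heifer"] = rfi_h
            heifers.to_csv(out / "heifer_traits.csv", index=False)
            rfi_h.rename_axis("animal_id").to_csv(out / "rfi_heifer.csv")
            stage_rep["n_heifers"] = len(heifers)
        report["stages"]["phenotypes"] = stage_rep
        log.info("phenotypes: %d cows, %.2f%% daily records removed",
                 len(cows), 100 * qc.fraction_removed)

    if "matrices" in config.stages and "gm" in state:
        from .relationships import qc_genotypes

        gqc, qrep = qc_genotypes(state["gm"])
        G = build_G(gqc)
        state["G"] = G
        report["stages"]["matrices"] = {
            **qrep,
            "mean_G_diagonal": float(np.mean(np.diag(G.values))),
        }

    if "reml" in config.stages:
        rfi = state["rfi_cow"]
        ids = rfi.index.to_numpy()
        A_sub = state["A"].submatrix(ids)
        res = UnivariateAnimalModel(rfi.to_numpy(), A_sub).fit()
        state["uni"] = res
        rep = {
            "sigma_a2": res.sigma_a2,
            "sigma_e2": res.sigma_e2,
            "h2": res.h2,
            "h2_se": res.h2_se("delta"),
            "loglike": res.loglike,
            "n_iter": res.n_iter,
        }
        if "rfi_heifer" in state:
            rh = state["rfi_heifer"].reindex(ids)
            biv = BivariateAnimalModel(
                rh.to_numpy(), rfi.to_numpy(), A_sub
            ).fit()
            state["biv"] = biv
            rep["rg"] = biv.rg
            try:
                rep["rg_se"] = biv.rg_se(n_draws=20_000)
            except RuntimeError as err:  # boundary fit: asymptotics unusable
                rep["rg_se"] = None
                rep["rg_se_note"] = str(err)
        report["stages"]["reml"] = rep
        (out / "reml.json").write_text(json.dumps(rep, indent=2))
        log.info("reml: h2=%.3f", res.h2)

    if "gblup" in config.stages and "G" in state:
        rfi = state["rfi_cow"]
        G = state["G"]
        geno_ids = [a for a in G.ids if a in set(rfi.index)]
        rng = np.random.default_rng(stage_seed(config.seed, "gblup"))
        n_train = max(2, int(len(geno_ids) * config.gblup_training_fraction))
        train_ids = list(rng.permutation(geno_ids)[:n_train])
        pred_ids = [a for a in G.ids if a not in set(train_ids)]
        G_TT = stabilize(
            type(G)(values=G.submatrix(train_ids), ids=np.array(train_ids), kind="G")
        )
        res = GBLUP(
            rfi.loc[train_ids].to_numpy(),
            G_TT.values,
            state["uni"].sigma_a2,
            state["uni"].sigma_e2,
            ids=np.array(train_ids),
        ).fit()
        G_PT = G.submatrix(pred_ids, train_ids)
        diag_PP = np.diag(G.submatrix(pred_ids)) + 0.01
        table = res.gebv_table(G_PT, diag_PP, prediction_ids=np.array(pred_ids))
        table.to_csv(out / "gebv.csv", index=False)
        state["gblup"] = res
        state["gebv_table"] = table
        state["train_ids"], state["pred_ids"] = train_ids, pred_ids
        tr = table[table["population"] == "training"]["reliability"]
        pr = table[table["population"] != "training"]["reliability"]
        report["stages"]["gblup"] = {
            "n_training": len(train_ids),
            "n_prediction": len(pred_ids),
            "mean_reliability_training": float(tr.mean()),
            "mean_reliability_prediction": float(pr.mean()) if len(pr) else None,
        }

    if "cohorts" in config.stages and "gebv_table" in state:
        groups, unresolved = assign_groups(
            state["ped"], state["train_ids"], state["pred_ids"]
        )
        G = state["G"]
        G_PT = G.submatrix(state["pred_ids"], state["train_ids"])
        counts = count_close_relatives(G_PT, config.close_relative_threshold)
        pred_tab = state["gebv_table"]
        pred_tab = pred_tab[pred_tab["population"] != "training"]
        curve = None
        if len(counts) >= 3 and np.ptp(counts) > 0:
            curve = fit_power_curve(pred_tab["reliability"].to_numpy(), counts)
        groups.to_csv(out / "groups.csv", index=False)
        pd.DataFrame(
            {"animal_id": state["pred_ids"], "n_close_relatives": counts}
        ).to_csv(out / "close_relatives.csv", index=False)
        rep = {"n_unresolved": len(unresolved),
               "group_sizes": groups["group"].value_counts().to_dict()}
        if curve is not None:
            rep["power_curve"] = {"a": curve.a, "b": curve.b, "rss": curve.rss}
        if "rfi_heifer" in state:
            common = state["rfi_heifer"].index.intersection(state["rfi_cow"].index)
            if len(common) >= 20:
                ct = rank_cross_tab(
                    state["rfi_heifer"].loc[common], state["rfi_cow"].loc[common]
                )
                ct.table.to_csv(out / "rank_cross_tab.csv")
                rep["cross_tab_diagonal"] = [
                    float(ct.table.iloc[i, i]) for i in range(3)
                ]
        report["stages"]["cohorts"] = rep

    manifest = {}
    for f in sorted(out.glob("*")):
        if f.is_file():
            manifest[f.name] = _sha256(f)
    report["manifest"] = manifest
    report["wall_time_s"] = round(time.time() - t0, 2)
    report.save(out / "run_report.json")
    return report


def _recovery_replicate(sim: SimulationConfig, rep_seed: int, bivariate: bool):
    """One replicate: pedigree -> A -> breeding values + residuals under the
    RFI model (mean + animal + residual) -> REML."""
    rng = np.random.default_rng(rep_seed)
    ped = simulate_pedigree(sim, seed=rng.integers(2**31 - 1))
    A = build_A(ped)
    n = len(ped)
    if bivariate:
        K = sim.genetic_covariance
        u = simulate_true_breeding_values(A.values, K, seed=rng.integers(2**31 - 1))
        R = sim.residual_covariance
        e = rng.multivariate_normal(np.zeros(2), R, size=n)
        y = u + e
        res = BivariateAnimalModel(y[:, 0], y[:, 1], A.values).fit()
        return {
            "h2_heifer": res.h2[0],
            "h2_cow": res.h2[1],
            "rg": res.rg,
            "converged": res.converged,
        }
    u = simulate_true_breeding_values(
        A.values, sim.cow.additive, seed=rng.integers(2**31 - 1)
    )
    e = rng.normal(0.0, np.sqrt(sim.cow.residual), size=n)
    res = UnivariateAnimalModel(u + e, A.values).fit()
    return {
        "sigma_a2": res.sigma_a2,
        "sigma_e2": res.sigma_e2,
        "h2": res.h2,
        "converged": res.converged,
    }


def run_recovery_study(
    sim: SimulationConfig,
    n_replicates: int,
    seed: int = 0,
    bivariate: bool = False,
    max_failure_fraction: float = 0.2,
) -> pd.DataFrame:
    """Parameter-recovery study: replicate simulation + REML fits.

    Replicate k uses seed ``seed + k`` so any single replicate can be re-run
    in isolation.  Replicate failures are recorded; more than
    ``max_failure_fraction`` failing aborts.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rows = []
    failures = 0
    for k in range(n_replicates):
        try:
            row = _recovery_replicate(sim, seed + k, bivariate)
        except Exception as err:  # recorded, not fatal
            failures += 1
            row = {"error": str(err)}
        row["replicate"] = k
        row["seed"] = seed + k
        rows.append(row)
        if failures > max_failure_fraction * n_replicates:
            raise RuntimeError(
                f"{failures} of {k + 1} replicates failed; aborting"
            )
    return pd.DataFrame(rows)
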