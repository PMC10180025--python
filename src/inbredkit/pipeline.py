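"""Genotyped-vs-imputation concordance study across SNP panels.

For each panel, inbreeding coefficients are estimated twice: on the panel's
genotyped SNP (the chip ∩ imputation-set markers) and on the full imputation
set after masking the non-panel SNP and re-imputing them.  Pearson and
Spearman correlations between the two arms, and of each arm against pedigree
inbreeding, quantify how much the imputation channel distorts each estimator
as panel overlap falls.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .estimators import (ESTIMATOR_COLUMNS, RohParameters, all_estimators,
                         allele_frequencies)
from .impute import ImputationConfig, impute
from .io import (GenotypeDataset, PanelDefinition, panel_overlap_percentage,
                 subset_to_panel, write_panel, write_plink_text)
from .pedigree import Pedigree, compute_f_ped
from .qc import QcThresholds, apply_snp_qc
from .simulate import (DEFAULT_PANEL_FRACTIONS, SimulationConfig, define_panels,
                       gene_drop, simulate_pedigree, true_autozygosity)

logger = logging.getLogger("inbredkit")


class ConfigError(ValueError):
    """Raised for study configuration schema violations, naming the key path."""


def _corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pairwise-complete Pearson and Spearman; NaN when degenerate."""
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return float("nan"), float("nan")
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return float("nan"), float("nan")
    pear = float(np.corrcoef(xs, ys)[0, 1])
    spear = float(stats.spearmanr(xs, ys).statistic)
    return pear, spear


def panel_concordance(full_ds: GenotypeDataset, panel: PanelDefinition,
                      ped: Pedigree, f_ped: Mapping[str, float],
                      roh_params: RohParameters = RohParameters(),
                      imp_cfg: ImputationConfig = ImputationConfig(seed=0),
                      qc_thresholds: Optional[QcThresholds] = None
                      ) -> pd.DataFrame:
    """One panel's concordance rows (one per estimator).

    The genotyped arm runs every estimator on the panel subset of the full
    dataset; the imputation arm masks the non-panel SNP, re-imputes them and
    runs the estimators on the full map (optionally after SNP QC).
    Correlations are pairwise-complete over samples; degenerate cells are
    reported as NaN.
    """
    if full_ds.n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")

    genotyped = subset_to_panel(full_ds, panel)

    masked = full_ds.copy()
    keep = np.fromiter((s in panel.snp_ids for s in full_ds.map.snp_id),
                       dtype=bool, count=full_ds.n_snp)
    masked.dosage[:, ~keep] = -1
    ref_freqs = allele_frequencies(full_ds)
    imputed = impute(masked, full_ds.map, ped, ref_freqs, imp_cfg)
    if qc_thresholds is not None:
        imputed, _ = apply_snp_qc(imputed, ped, qc_thresholds)

    got = all_estimators(genotyped, f_ped, roh_params)
    imp = all_estimators(imputed, f_ped, roh_params)
    fp = np.array([f_ped[s] for s in full_ds.samples], dtype=float)

    rows = []
    for est in ESTIMATOR_COLUMNS:
        g = got[est].to_numpy(dtype=float)
        m = imp[est].to_numpy(dtype=float)
        pear, spear = _corr(g, m)
        pg, _ = _corr(g, fp)
        pi, _ = _corr(m, fp)
        rows.append({
            "panel": panel.name,
            "overlap_pct": panel_overlap_percentage(panel, full_ds.map),
            "estimator": est,
            "pearson_genotyped_vs_imputation": pear,
            "spearman_genotyped_vs_imputation": spear,
            "pearson_vs_fped_genotyped": pg,
            "pearson_vs_fped_imputation": pi,
            "n_samples": full_ds.n_samples,
        })
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean and median concordance per panel (over estimators) and per
    estimator (over panels), for Pearson and Spearman separately; undefined
    entries are ignored."""
    if table.empty:
        raise ValueError("empty concordance table")
    cols = ["pearson_genotyped_vs_imputation", "spearman_genotyped_vs_imputation"]

    def agg(by: str) -> pd.DataFrame:
        g = table.groupby(by, sort=False)[cols]
        out = pd.concat({"mean": g.mean(), "median": g.median()}, axis=1)
        out.columns = [f"{c}_{stat}" for stat, c in out.columns]
        return out.reset_index()

    per_panel = agg("panel")
    order = table.groupby("panel", sort=False)["overlap_pct"].first()
    per_panel.insert(1, "overlap_pct", per_panel["panel"].map(order))
    return per_panel, agg("estimator")


def soft_checks(table: pd.DataFrame) -> list[str]:
    """Data-dependent expectations, reported as warnings rather than errors.

    Checks that Spearman correlations exceed Pearson on average, and that the
    genotyped arm tracks pedigree inbreeding at least as well as the
    imputation arm for the low-overlap half of the panels.
    """
    msgs = []
    d = table.dropna(subset=["pearson_genotyped_vs_imputation",
                             "spearman_genotyped_vs_imputation"])
    if len(d) and d["spearman_genotyped_vs_imputation"].mean() < \
            d["pearson_genotyped_vs_imputation"].mean():
        msgs.append("mean Spearman correlation below mean Pearson correlation")
    med = table["overlap_pct"].median()
    low = table[table["overlap_pct"] < med].dropna(
        subset=["pearson_vs_fped_genotyped", "pearson_vs_fped_imputation"])
    if len(low) and low["pearson_vs_fped_genotyped"].mean() < \
            low["pearson_vs_fped_imputation"].mean():
        msgs.append("imputation arm tracks F_ped better than the genotyped arm "
                    "on low-overlap panels")
    return msgs


# ---------------------------------------------------------------------------
# End-to-end study driver
# ---------------------------------------------------------------------------

_SCHEMA = {
    "seed": int,
    "simulation": dict, "panels": dict, "roh": dict,
    "imputation": dict, "qc": dict, "output": dict,
}


def _check_keys(section: Mapping, allowed: set[str], path: str) -> None:
    for key in section:
        if key not in allowed:
            raise ConfigError(f"unknown config key {path}.{key}")


def load_config(config: str | Path | Mapping) -> dict:
    """Load and validate a study configuration (YAML path or mapping)."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)
    _check_keys(cfg, set(_SCHEMA), path="<root>")
    for key, typ in _SCHEMA.items():
        if key in cfg and not isinstance(cfg[key], typ):
            raise ConfigError(f"config key {key} must be a {typ.__name__}")
    if "seed" not in cfg:
        raise ConfigError("missing required config key: seed")

    sim = dict(cfg.get("simulation", {}))
    _check_keys(sim, {f.name for f in
                      SimulationConfig.__dataclass_fields__.values()} - {"seed"},
                "simulation")
    panels = dict(cfg.get("panels", {}))
    _check_keys(panels, {"overlap_fractions", "names"}, "panels")
    roh = dict(cfg.get("roh", {}))
    _check_keys(roh, {f.name for f in RohParameters.__dataclass_fields__.values()},
                "roh")
    qc = dict(cfg.get("qc", {}))
    _check_keys(qc, {"enabled"} |
                {f.name for f in QcThresholds.__dataclass_fields__.values()}, "qc")
    imp = dict(cfg.get("imputation", {}))
    _check_keys(imp, {"mode"}, "imputation")
    out = dict(cfg.get("output", {}))
    _check_keys(out, {"dir", "write_genotypes"}, "output")
    return {"seed": int(cfg["seed"]), "simulation": sim, "panels": panels,
            "roh": roh, "imputation": imp, "qc": qc, "output": out}


def run_study(config: str | Path | Mapping,
              out_dir: Optional[str | Path] = None) -> dict:
    """Run the full synthetic concordance study and write its report directory.

    Stages: pedigree simulation -> gene drop -> pedigree inbreeding -> panel
    definition -> per-panel concordance (imputation arm, optional SNP QC) ->
    summaries.  All randomness derives from the single root seed, split per
    stage.  Returns a dict with the in-memory tables and output paths.
    """
    cfg = load_config(config)
    root_seed = cfg["seed"]
    # hierarchical per-stage seeds from the root
    stage_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(root_seed).spawn(4)]
    sim_cfg = SimulationConfig(**cfg["simulation"], seed=stage_seeds[0])
    roh_params = RohParameters(**cfg["roh"])
    qc_enabled = bool(cfg["qc"].pop("enabled", True))
    qc_thresholds = QcThresholds(**cfg["qc"]) if qc_enabled else None

    out = Path(out_dir or cfg["output"].get("dir", "inbredkit_study"))
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "study.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        logger.info("simulating pedigree (%d founders, %d generations)",
                    sim_cfg.n_founders, sim_cfg.n_generations)
        ped = simulate_pedigree(sim_cfg)
        full_ds, tracks = gene_drop(ped, sim_cfg)
        f_ped = compute_f_ped(ped, max_depth=None)
        truth = true_autozygosity(tracks)

        fractions = cfg["panels"].get("overlap_fractions",
                                      list(DEFAULT_PANEL_FRACTIONS))
        names = cfg["panels"].get("names")
        panels = define_panels(full_ds.map, fractions, seed=stage_seeds[1],
                               names=names)

        tables = []
        for k, panel in enumerate(panels):
            logger.info("panel %s: %d SNP", panel.name, len(panel))
            imp_cfg = ImputationConfig(
                seed=int((stage_seeds[2] + 7919 * k) % (2 ** 31)),
                mode=cfg["imputation"].get("mode", "family_then_frequency"))
            tables.append(panel_concordance(full_ds, panel, ped, f_ped,
                                            roh_params, imp_cfg, qc_thresholds))
        table = pd.concat(tables, ignore_index=True)
        per_panel, per_estimator = summarize(table)
        for msg in soft_checks(table):
            logger.warning("soft check: %s", msg)

        ped.write_tsv(out / "pedigree.tsv")
        truth_df = pd.DataFrame({
            "sample": full_ds.samples,
            "true_autozygosity": truth.reindex(full_ds.samples).to_numpy(),
            "f_ped": [f_ped[s] for s in full_ds.samples]})
        truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
        panel_dir = out / "panels"
        panel_dir.mkdir(exist_ok=True)
        for panel in panels:
            write_panel(panel, panel_dir / f"{panel.name}.txt")
        if cfg["output"].get("write_genotypes", False):
            write_plink_text(full_ds, out / "genotypes.ped", out / "genotypes.map")
        table.to_csv(out / "concordance.tsv", sep="\t", index=False)
        per_panel.to_csv(out / "summary_by_panel.tsv", sep="\t", index=False)
        per_estimator.to_csv(out / "summary_by_estimator.tsv", sep="\t",
                             index=False)
        manifest = {
            "package": "inbredkit", "version": __version__,
            "root_seed": root_seed, "stage_seeds": stage_seeds,
            "config": {k: v for k, v in cfg.items()},
            "n_samples": full_ds.n_samples, "n_snp": full_ds.n_snp,
            "elapsed_s": round(time.time() - t0, 2),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        logger.info("study complete in %.1fs", time.time() - t0)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {"out_dir": out, "concordance": table, "per_panel": per_panel,
            "per_estimator": per_estimator, "pedigree": ped, "dataset": full_ds,
            "f_ped": f_ped, "truth": truth}
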