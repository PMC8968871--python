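"""End-to-end pipeline: simulate -> bin -> select -> normalise -> classify.

``run_pipeline`` drives a reproducible run from a configuration mapping
(or YAML/JSON file) to a directory of CSV outputs plus a manifest recording
the configuration, seeds and package versions actually used.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binning import BinnedTable, apply_abundance_floor, assemble_table
from .evaluation import DEFAULT_THRESHOLDS, locso_splits, rate_table, split_80_20
from .features import (
    SCHEMES,
    SelectionConfig,
    correlation_matrix,
    multiway_anova,
    normalize,
    refine_per_voltage,
    select_bins,
    weekly_profiles,
)
from .forest import (
    ForestConfig,
    fit_forest,
    oob_vote_profiles,
    permutation_importance,
    predict_external,
    triplicate_conclusion,
)
from .lda import fit_lda, posterior_table
from .synthetic import (
    BatchShift,
    DesignConfig,
    default_model,
    generate_design,
    generate_external_batch,
    simulate_spectra,
    write_metadata_csv,
    write_sidecar,
    write_spectra_csv,
)
from .welch import run_welch_replicates

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 20210317,
    "design": {},                      # DesignConfig overrides
    "selection": {"pct_threshold": 0.3, "min_spectra": 50},
    "abundance_floor": 120.0,
    "normalization": "ion_current",    # scheme used by the classifiers
    "welch": {"n_replicates": 20, "scope": "full", "min_difference": 0},
    "forest": {"n_trees": 500},
    "external": {"enabled": True, "n_cards": 11},
    "elimination": {"enabled": False, "folds": 12, "n_trees": 150},
}


class PipelineStageError(RuntimeError):
    """An error raised by a named pipeline stage."""


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source: str | Path | Mapping | None) -> dict:
    if source is None:
        cfg: Mapping = {}
    elif isinstance(source, Mapping):
        cfg = source
    else:
        text = Path(source).read_text()
        cfg = yaml.safe_load(text) or {}
    return _merge(DEFAULT_CONFIG, cfg)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # propagate with the stage name
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def prepare_dataset(
    config: Mapping | None = None, seed: int | None = None
) -> tuple[BinnedTable, list, dict]:
    """Simulate and bin the main data set; returns (binned table, selected
    variables, resolved config)."""
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = seed
    design_cfg = DesignConfig(**cfg["design"], seed=cfg["seed"]) if "seed" not in cfg["design"] \
        else DesignConfig(**cfg["design"])
    design = generate_design(design_cfg)
    model = default_model()
    spectra = simulate_spectra(design, model, seed=design_cfg.seed)
    floor = cfg["abundance_floor"]
    spectra = [apply_abundance_floor(s, floor) for s in spectra]
    binned = assemble_table(spectra, design, voltages=design_cfg.voltages)
    sel = SelectionConfig(**cfg["selection"])
    candidates = select_bins(binned, sel)
    variables = refine_per_voltage(binned, candidates, sel)
    return binned, variables, cfg


def run_pipeline(
    config: str | Path | Mapping | None = None,
    outdir: str | Path = "dartiso_run",
    seed: int | None = None,
) -> dict[str, Any]:
    """Run the full workflow and write every declared CSV plus a manifest.

    Returns a dictionary of the headline numbers computed during the run.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = seed
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}

    # --- simulate ---------------------------------------------------------
    @_stage("simulate")
    def _simulate():
        design_cfg = DesignConfig(**{**cfg["design"], "seed": cfg["seed"]})
        design = generate_design(design_cfg)
        model = default_model()
        spectra = simulate_spectra(design, model, seed=design_cfg.seed)
        write_spectra_csv(spectra, out / "spectra.csv")
        write_metadata_csv(design, out / "metadata.csv")
        write_sidecar(design_cfg, design_cfg.seed, out / "run_config.json")
        return design_cfg, design, model, spectra

    design_cfg, design, model, spectra = _simulate()

    # --- bin --------------------------------------------------------------
    @_stage("bin")
    def _bin():
        floored = [apply_abundance_floor(s, cfg["abundance_floor"]) for s in spectra]
        binned = assemble_table(floored, design, voltages=design_cfg.voltages)
        binned.to_csv(out / "binned_raw.csv")
        return binned

    binned = _bin()

    # --- select -----------------------------------------------------------
    @_stage("select")
    def _select():
        sel = SelectionConfig(**cfg["selection"])
        candidates = select_bins(binned, sel)
        variables = refine_per_voltage(binned, candidates, sel)
        pd.DataFrame(
            [(k.bin_upper, k.voltage) for k in variables],
            columns=["bin_upper", "voltage"],
        ).to_csv(out / "selected_variables.csv", index=False)
        return variables

    variables = _select()
    results["n_variables"] = len(variables)

    # --- normalize --------------------------------------------------------
    @_stage("normalize")
    def _normalize():
        ntables = {s: normalize(binned, variables, s) for s in SCHEMES}
        for s, t in ntables.items():
            t.to_csv(out / f"normalized_{s}.csv")
        return ntables

    ntables = _normalize()
    scheme = cfg["normalization"]
    ntable = ntables[scheme]

    # --- anova ------------------------------------------------------------
    @_stage("anova")
    def _anova():
        res = multiway_anova(ntable)
        res.to_csv(out / "anova.csv")
        weekly_profiles(ntable, "per_week").to_csv(out / "weekly_means.csv", index=False)
        weekly_profiles(ntable, "accumulating").to_csv(
            out / "accumulating_means.csv", index=False
        )
        correlation_matrix(ntable).to_csv(out / "correlations.csv")
        return res

    anova = _anova()
    results["anova_isomer_median_p"] = float(anova["p_isomer"].median())

    # --- welch ------------------------------------------------------------
    @_stage("welch")
    def _welch():
        wcfg = cfg["welch"]
        run = run_welch_replicates(
            ntables, n_replicates=wcfg["n_replicates"], scope=wcfg["scope"],
            seed=cfg["seed"],
        )
        for i, rep in enumerate(run.replicates, start=1):
            pd.DataFrame(
                {"threshold": rep.roc.thresholds, "fpr": rep.roc.fpr, "tpr": rep.roc.tpr}
            ).to_csv(out / f"welch_roc_replicate_{i:02d}.csv", index=False)
        pd.DataFrame(
            {
                "threshold": run.averaged_roc.thresholds,
                "fpr": run.averaged_roc.fpr,
                "tpr": run.averaged_roc.tpr,
            }
        ).to_csv(out / "welch_roc_averaged.csv", index=False)
        pd.DataFrame(
            {
                "replicate": range(1, len(run.replicates) + 1),
                "confidence": [r.confidence for r in run.replicates],
                "scheme": [r.scheme for r in run.replicates],
                "auc": [r.roc.auc for r in run.replicates],
            }
        ).to_csv(out / "welch_auc.csv", index=False)
        run.per_bin_accuracy.rename_axis("variable").to_csv(out / "welch_bin_accuracy.csv")
        return run

    welch_run = _welch()
    results["welch_averaged_auc"] = welch_run.averaged_roc.auc

    # --- lda --------------------------------------------------------------
    @_stage("lda")
    def _lda():
        meta = ntable.metadata
        scored = []
        for _, test_idx, train_idx in locso_splits(meta):
            m = fit_lda(ntable.values.loc[train_idx], meta.loc[train_idx, "isomer"])
            post = posterior_table(m, ntable.values.loc[test_idx])
            for sid, row in post.iterrows():
                scored.append((meta.loc[sid, "isomer"], row.to_dict()))
        table = rate_table(scored, DEFAULT_THRESHOLDS)
        table.to_csv(out / "lda_rates_locso.csv")
        full = fit_lda(ntable.values, meta["isomer"])
        posterior_table(full, ntable.values).to_csv(out / "lda_posteriors.csv")
        from .lda import project, scaling_influence

        project(full, ntable.values).to_csv(out / "lda_scores.csv")
        scaling_influence(full).to_csv(out / "lda_scaling.csv")
        post = posterior_table(full, ntable.values)
        ranked = np.sort(post.to_numpy(), axis=1)
        lr = ranked[:, -1] / np.maximum(ranked[:, -2], np.finfo(float).tiny)
        pd.DataFrame({"likelihood_ratio": lr}, index=post.index).to_csv(out / "lda_lr.csv")
        return table

    lda_rates = _lda()
    results["lda_locso_error_at_0.50"] = float(lda_rates.loc[0.50, "error"])

    # --- rf ---------------------------------------------------------------
    @_stage("rf")
    def _rf():
        meta = ntable.metadata
        fcfg = ForestConfig(**cfg["forest"], seed=cfg["seed"])
        f = fit_forest(ntable.values, meta["isomer"], fcfg)
        oob = oob_vote_profiles(f)
        oob.to_csv(out / "rf_oob_votes.csv")
        imp = permutation_importance(f)
        imp.to_csv(out / "rf_importance.csv")
        scored = [
            (meta.loc[sid, "isomer"], row[list(f.classes)].to_dict())
            for sid, row in oob.iterrows()
        ]
        oob_rates = rate_table(scored, DEFAULT_THRESHOLDS)
        oob_rates.to_csv(out / "rf_rates_oob.csv")

        train_idx, test_idx = split_80_20(meta, seed=cfg["seed"])
        f2 = fit_forest(ntable.values.loc[train_idx], meta.loc[train_idx, "isomer"], fcfg)
        from .forest import predict_vote_profiles

        test_profiles = predict_vote_profiles(f2, ntable.values.loc[test_idx])
        scored_test = [
            (meta.loc[sid, "isomer"], row[list(f2.classes)].to_dict())
            for sid, row in test_profiles.iterrows()
        ]
        test_rates = rate_table(scored_test, DEFAULT_THRESHOLDS)
        test_rates.to_csv(out / "rf_rates_test20.csv")

        pred = oob[list(f.classes)].to_numpy().argmax(axis=1)
        truth = np.array([f.classes.index(c) for c in meta["isomer"]])
        oob_err = float((pred != truth).mean())
        return f, oob, test_rates, oob_err

    f, oob, test_rates, oob_err = _rf()
    results["rf_oob_error"] = oob_err
    results["rf_test_success_at_0.50"] = float(test_rates.loc[0.50, "success"])

    # --- external ---------------------------------------------------------
    if cfg["external"]["enabled"]:
        @_stage("external")
        def _external():
            model_ = default_model()
            ext_spectra, ext_meta = generate_external_batch(
                model_, n_cards=cfg["external"]["n_cards"], shift=BatchShift(),
                seed=cfg["seed"] + 1,
            )
            ext_spectra = [apply_abundance_floor(s, cfg["abundance_floor"]) for s in ext_spectra]
            ext_binned = assemble_table(ext_spectra, ext_meta, voltages=design_cfg.voltages)
            ext_ntable = normalize(ext_binned, variables, scheme)
            profiles = predict_external(f, ext_ntable)
            profiles.to_csv(out / "rf_external_votes.csv")
            scored = [
                (ext_ntable.metadata.loc[sid, "isomer"], row[list(f.classes)].to_dict())
                for sid, row in profiles.iterrows()
            ]
            rate_table(scored, DEFAULT_THRESHOLDS).to_csv(out / "rf_rates_external.csv")
            for rule in ("all_match", "majority", "highest"):
                rows = []
                for thr in DEFAULT_THRESHOLDS:
                    items = []
                    for (card, cls), grp in ext_ntable.metadata.groupby(["card_id", "isomer"]):
                        c = triplicate_conclusion(
                            profiles.loc[grp.index], rule, thr, id=f"{card}:{cls}"
                        )
                        items.append((cls, c))
                    from .evaluation import rate_table_from_conclusions

                    rows.append({"threshold": thr, **rate_table_from_conclusions(items)})
                pd.DataFrame(rows).set_index("threshold").to_csv(
                    out / f"rf_rates_external_{rule}.csv"
                )
            return profiles

        _external()

    # --- elimination ------------------------------------------------------
    if cfg["elimination"]["enabled"]:
        @_stage("elimination")
        def _elim():
            from .forest import elimination_curve

            curve = elimination_curve(
                ntable.values, ntable.metadata["isomer"],
                folds=cfg["elimination"]["folds"],
                config=ForestConfig(n_trees=cfg["elimination"]["n_trees"], seed=cfg["seed"]),
                seed=cfg["seed"],
            )
            curve.to_csv(out / "rf_elimination_curve.csv", index=False)
            return curve

        _elim()

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": cfg,
        "seed": cfg["seed"],
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "results": results,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results
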