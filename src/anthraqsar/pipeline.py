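"""End-to-end study orchestration.

Two complementary modes are reported side by side:

* **printed-columns mode** — every training/test statistic is recomputed
  from the packaged prediction columns of the 41-compound table.  These
  numbers are exactly reproducible and serve as the reference checks.
* **refit mode** — descriptors are computed by this package's own engine,
  the five-descriptor model is refit, cross-validated and analysed for its
  applicability domain.  Because descriptor engines differ, refit statistics
  are expected to differ from the printed ones; they demonstrate the method,
  not the printed numbers.

The optional 3D stage aligns every compound onto the most active one
(compound 30) by maximum-common-substructure superposition, computes the
steric/electrostatic field matrix, and fits the field-PLS model.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import addomain, chemio, descriptors, field3d, mlr, validation

__all__ = ["StudyReport", "run_study", "predict_designed", "printed_columns_report"]

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": {"printed": True, "refit": True, "comfa": False, "designed": False},
    "alpha_enter": 0.05,
    "alpha_remove": 0.10,
    "grid_spacing": 2.0,
    "grid_margin": 4.0,
    "sigma_min": 6.0,
    "max_components": 10,
    "table": "packaged-fixture",
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {**base}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class StudyReport:
    printed: dict | None
    refit: dict | None
    comfa: dict | None
    designed: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def printed_columns_report(table: chemio.ActivityTable) -> dict:
    """All deterministic statistics recomputable from the shipped columns."""
    tr, te = table.train, table.test
    y_tr = np.array([c.pec50 for c in tr])
    y_te = np.array([c.pec50 for c in te])
    out = {"n_train": len(tr), "n_test": len(te)}
    for tag, attr in (("mlr", "pred_mlr"), ("comfa", "pred_comfa")):
        p_tr = np.array([getattr(c, attr) for c in tr], dtype=float)
        p_te = np.array([getattr(c, attr) for c in te], dtype=float)
        if np.isnan(p_tr).any() or np.isnan(p_te).any():
            continue
        out[tag] = {
            "r2_train": validation.r_squared(y_tr, p_tr),
            "rmse_train": validation.rmse(y_tr, p_tr),
            "r2_test": validation.r_squared(y_te, p_te),
            "rmse_test": validation.rmse(y_te, p_te),
        }
    m = len(mlr.PUBLISHED_MLR_2016.descriptor_names)
    out["warning_leverage"] = addomain.warning_leverage(m, len(tr))
    out["f_critical_0.005"] = validation.f_critical(0.005, m, len(tr) - m - 1)
    if "mlr" in out:
        out["mlr"]["f_stat_from_r2"] = validation.f_statistic(
            out["mlr"]["r2_train"], len(tr), m
        )
        s = out["mlr"]["rmse_train"]
        p_tr = np.array([c.pred_mlr for c in tr], dtype=float)
        out["mlr"]["max_abs_std_residual_train"] = float(
            np.abs(addomain.standardized_residuals(y_tr, p_tr, s)).max()
        )
    return out


def _refit_report(table, desc, config) -> dict:
    tr_ids = [c.id for c in table.train]
    te_ids = [c.id for c in table.test]
    X_tr = desc.loc[tr_ids]
    X_te = desc.loc[te_ids]
    y_tr = np.array([table[i].pec50 for i in tr_ids])
    y_te = np.array([table[i].pec50 for i in te_ids])

    selected, model = mlr.stepwise_select(
        X_tr, y_tr, config["alpha_enter"], config["alpha_remove"]
    )
    # the five-descriptor refit regardless of what stepwise picked, for
    # comparability with the published equation
    model5 = mlr.fit_ols(X_tr[list(mlr.PUBLISHED_MLR_2016.descriptor_names)], y_tr)
    yhat_tr = model5.predict(X_tr)
    yhat_te = model5.predict(X_te)
    report = validation.validation_report(
        y_tr, yhat_tr, y_te, yhat_te,
        n_descriptors=len(model5.descriptor_names),
        X_train=X_tr[list(model5.descriptor_names)].to_numpy(),
    )
    yr = validation.y_randomization(
        X_tr[list(model5.descriptor_names)].to_numpy(), y_tr, k=10,
        seed=config["seed"],
    )
    ad = addomain.williams_report(
        X_tr[list(model5.descriptor_names)].to_numpy(), y_tr, yhat_tr,
        X_te[list(model5.descriptor_names)].to_numpy(), y_te, yhat_te,
        ids_train=tr_ids, ids_test=te_ids,
    )
    collin = mlr.collinearity_report(X_tr[list(model5.descriptor_names)])
    return {
        "stepwise_selected": list(selected),
        "model": model5.to_dict(),
        "validation": report.to_dict(),
        "y_randomization": {
            "r2": yr.r2.tolist(), "q2": yr.q2.tolist(), "seed": yr.seed,
        },
        "vif": dict(zip(collin.names, map(float, collin.vif))),
        "ad": {
            "h_star": ad.h_star,
            "x_outliers": ad.x_outliers,
            "y_outliers": ad.y_outliers,
        },
    }


def _comfa_report(table, config, seed) -> tuple[dict, object, dict]:
    template_id = "30"
    template = chemio.generate_conformer(table[template_id].structure, seed=seed)
    aligned = {template_id: template}
    for c in table:
        if c.id == template_id:
            continue
        conf = chemio.generate_conformer(c.structure, seed=seed)
        pairs = chemio.common_scaffold_mapping(c, table[template_id])
        moved, _ = chemio.align_to_template(conf, template, pairs)
        aligned[c.id] = moved
    order = [c.id for c in table]
    confs = [aligned[i] for i in order]
    lattice = field3d.build_lattice(
        confs, spacing=config["grid_spacing"], margin=config["grid_margin"]
    )
    block = field3d.compute_field_block(confs, lattice)
    block = field3d.column_filter(block, sigma_min=config["sigma_min"])
    tr_idx = [k for k, i in enumerate(order) if table[i].split == "train"]
    te_idx = [k for k, i in enumerate(order) if table[i].split == "test"]
    y = np.array([table[i].pec50 for i in order])
    tr_block = field3d.FieldBlock(block.matrix[tr_idx], lattice, block.retained_columns)
    n_comp, q2 = field3d.select_components(tr_block, y[tr_idx], config["max_components"])
    model = field3d.fit_pls(tr_block, y[tr_idx], n_comp)
    yhat = model.intercept + block.retained_matrix @ model.coefficients
    grid = field3d.contour_grid(model, tr_block)
    rep = {
        "n_components": n_comp,
        "q2_loo": q2,
        "r2_train": model.r2,
        "r2_test": validation.r_squared(y[te_idx], yhat[te_idx]),
        "rmse_test": validation.rmse(y[te_idx], yhat[te_idx]),
        "contributions": {
            "steric": model.contributions[0],
            "electrostatic": model.contributions[1],
        },
        "retained_columns": int(block.retained_columns.size),
        "lattice_dims": list(lattice.dims),
    }
    return rep, model, {"aligned": aligned, "block": block, "grid": grid,
                        "template": template}


def predict_designed(models: dict, seed: int = 0, designed: pd.DataFrame | None = None) -> pd.DataFrame:
    """Predict the designed compounds (T30, N1-N9) with the available models.

    ``models`` may contain ``'mlr'`` (an :class:`~anthraqsar.mlr.MLRModel`)
    and/or ``'comfa'`` (a fitted field model with its alignment context).
    Descriptors are computed by this package's engine, so the linear-model
    predictions approximate — not reproduce — the published column, which is
    included for reference.
    """
    if designed is None:
        designed = chemio.load_designed_table()
    rows = {}
    lin = models.get("mlr", mlr.PUBLISHED_MLR_2016)
    for cid, row in designed.iterrows():
        d = descriptors.compute_descriptors(row["structure"], seed=seed)
        x = pd.DataFrame([d.values])
        rows[cid] = {
            "pred_mlr_engine": float(mlr.predict_mlr(lin, x)[0]),
            "published_mlr": row.get("pred_mlr"),
            "published_comfa": row.get("pred_comfa"),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "id"
    return out.sort_values("pred_mlr_engine", ascending=False)


def run_study(config: dict | str | None = None) -> StudyReport:
    """Execute the configured stages and return a consolidated report."""
    if isinstance(config, str):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    t0 = time.time()
    if cfg["table"] == "packaged-fixture":
        table = chemio.load_fxr_table()
    else:
        table = chemio.load_activity_table(cfg["table"])

    printed = printed_columns_report(table) if cfg["stages"]["printed"] else None

    refit = comfa = designed = None
    desc = None
    if cfg["stages"]["refit"] or cfg["stages"]["designed"]:
        desc = descriptors.compute_descriptor_matrix(table, seed=seed)
        descriptors.validate_descriptor_matrix(desc)
    if cfg["stages"]["refit"]:
        refit = _refit_report(table, desc, cfg)
    comfa_ctx = {}
    if cfg["stages"]["comfa"]:
        comfa, _, comfa_ctx = _comfa_report(table, cfg, seed)
    if cfg["stages"]["designed"]:
        designed = predict_designed({}, seed=seed).to_dict(orient="index")

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    prov = {
        "seed": seed,
        "config_hash": cfg_hash,
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": cfg["stages"],
    }
    return StudyReport(printed, refit, comfa, designed, prov)
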