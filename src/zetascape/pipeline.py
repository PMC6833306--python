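"""End-to-end study workflow: data -> covariate screen -> richness models ->
zeta decline and piecewise fits -> MS-GDM suite -> summary report.

Every stage writes a machine-readable artifact into the output directory and
contributes to a single summary JSON keyed by species category.  The run is
fully determined by the configuration and seed (a config hash and the seed
are stamped into every artifact), so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    CATEGORIES,
    beta_summary,
    dbmem,
    fit_piecewise,
    fit_richness,
    generate_crete_like,
    read_community,
    read_site_table,
    retention_rate,
    run_model_suite,
    vif_screen,
    write_community,
    write_site_table,
    zeta_decline,
)
from .community import CommunityMatrix, SiteTable

log = logging.getLogger("zetascape")

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of a full study run.

    Either ``matrix_path``/``sites_path``/``categories_path`` point at input
    CSVs, or ``synthetic`` requests the built-in island-flora generator with
    ``synthetic_scale``.  Seeds are explicit; there is no wall-clock seeding.
    """

    matrix_path: str | None = None
    sites_path: str | None = None
    categories_path: str | None = None
    synthetic: bool = True
    synthetic_scale: float = 1.0
    categories: list[str] = field(default_factory=lambda: list(CATEGORIES))
    max_order: int = 20
    n_samples: int = 1000
    msgdm_orders: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    scheme: str = "sorensen"
    models: list[str] = field(default_factory=lambda: ["abiotic", "biotic1", "biotic2"])
    vif_threshold: float = 10.0
    seed: int = 0
    out_dir: str = "zetascape_run"

    def __post_init__(self) -> None:
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        if any(o < 1 for o in self.msgdm_orders):
            raise ValueError("orders must be >= 1")

    def config_hash(self) -> str:
        """Hash of the analytic configuration (the output path does not
        affect results, so two runs into different directories still match)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(cfg: RunConfig) -> tuple[CommunityMatrix, SiteTable]:
    if cfg.synthetic:
        study = generate_crete_like(seed=cfg.seed, scale=cfg.synthetic_scale)
        return study.community, study.sites
    if not (cfg.matrix_path and cfg.sites_path and cfg.categories_path):
        raise ValueError("non-synthetic runs need matrix, sites and categories paths")
    cm = read_community(cfg.matrix_path, cfg.categories_path)
    return cm, read_site_table(cfg.sites_path).aligned_to(cm)


def run_study(config: RunConfig) -> dict:
    """Execute the full workflow; returns the summary dict (also written as
    JSON).  A stage failure aborts with :class:`StageError`; artifacts of
    completed stages are retained in the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash(),
            "schema_version": SCHEMA_VERSION}
    summary: dict = {"meta": meta, "categories": {}}
    timings: dict[str, float] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                log.error("stage %s failed: %s", name, exc)
                raise StageError(name, exc) from exc
            timings[name] = time.perf_counter() - t0
            log.info("stage %s done in %.2fs", name, timings[name])
            return result
        return wrap

    cm, sites = stage("load")(lambda: _load_inputs(config))
    if config.synthetic:
        write_community(cm, out / "community.csv", out / "categories.csv")
        write_site_table(sites, out / "sites.csv")

    retained, drop_log = stage("vif_screen")(
        lambda: vif_screen(sites, sites.covariate_names(), config.vif_threshold)
    )
    summary["covariates"] = {"retained": retained,
                             "dropped": [{"name": n, "vif": v} for n, v in drop_log]}

    spatial = stage("dbmem")(lambda: dbmem(sites))
    summary["spatial"] = {"n_eigenvectors": int(spatial.k),
                          "truncation_km": float(spatial.truncation)}

    decline_rows = []
    for label in config.categories:
        sub = cm.subset_by_category(label)
        if sub.n_species == 0:
            continue
        entry: dict = {}

        entry["beta"] = stage(f"beta[{label}]")(lambda s=sub: beta_summary(s))

        dec = stage(f"zeta[{label}]")(
            lambda s=sub: zeta_decline(s, max_order=min(config.max_order, s.n_sites))
        )
        ret = retention_rate(dec)
        for o, z in zip(dec.orders, dec.zeta):
            decline_rows.append({"category": label, "order": int(o), "zeta": float(z)})
        entry["zeta"] = [float(z) for z in dec.zeta]
        entry["retention"] = [None if np.isnan(r) else float(r) for r in ret]

        def _fits(d=dec, r=ret):
            rare, wide, bp = fit_piecewise(d, r)
            return {
                "breakpoint": bp.order, "breakpoint_rule": bp.rule,
                "rare": {"orders": list(rare.segment), "exp_coeff": rare.exp_coeff,
                         "exp_p": rare.exp_p, "pl_coeff": rare.pl_coeff,
                         "pl_p": rare.pl_p, "aic": rare.aic},
                "widespread": {"orders": list(wide.segment), "exp_coeff": wide.exp_coeff,
                               "exp_p": wide.exp_p, "pl_coeff": wide.pl_coeff,
                               "pl_p": wide.pl_p, "aic": wide.aic},
            }
        entry["decline_fit"] = stage(f"fit[{label}]")(_fits)

        rich = sub.richness()

        def _richfit(r=rich):
            fit = fit_richness(r, sites, retained, spatial)
            return {
                "deviance_explained": fit.deviance_explained,
                "pseudo_r2": fit.pseudo_r2,
                "covariate_pvalues": fit.covariate_pvalues,
                "converged": fit.converged,
            }
        entry["richness_model"] = stage(f"richness[{label}]")(_richfit)

        models = [m for m in config.models if not (m == "biotic1" and label == "NON_E")]
        if models:
            def _suite(s=sub, lbl=label, mods=tuple(models)):
                fits = run_model_suite(
                    cm, sites, lbl, config.msgdm_orders, scheme=config.scheme,
                    covariates=retained, n_samples=config.n_samples,
                    seed=config.seed + 101, models=mods,
                )
                return {
                    str(o): {m: {"variance_explained": f.variance_explained,
                                 "importance": f.importance}
                             for m, f in per.items()}
                    for o, per in fits.items()
                }
            entry["msgdm"] = stage(f"msgdm[{label}]")(_suite)

        summary["categories"][label] = entry

    pd.DataFrame(decline_rows).to_csv(out / "decline.csv", index=False)
    # timings are non-deterministic: kept out of the summary so that reruns
    # with the same config and seed are byte-identical
    with open(out / "timings.json", "w") as fh:
        json.dump({k: round(v, 3) for k, v in timings.items()}, fh, indent=2)
    _validate_summary(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _validate_summary(summary: dict) -> None:
    """Structural validation of the summary before writing."""
    if summary.get("meta", {}).get("schema_version") != SCHEMA_VERSION:
        raise ValueError("summary schema version mismatch")
    for key in ("categories", "covariates", "spatial"):
        if key not in summary:
            raise ValueError(f"summary missing section {key!r}")
    for label, entry in summary["categories"].items():
        for section in ("beta", "zeta", "retention", "decline_fit", "richness_model"):
            if section not in entry:
                raise ValueError(f"category {label!r} missing section {section!r}")
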