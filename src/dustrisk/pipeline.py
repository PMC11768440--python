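"""End-to-end orchestration: concentrations -> risk -> PCA -> FA -> t-SNE ->
hyperparameter optimization -> cluster quality -> cluster-vs-risk concordance.

Every stage writes machine-readable CSV/JSON into the output directory and a
``run_manifest.json`` records the configuration echo, master seed, per-stage
wall time and any stage failure.  Stage seeds derive from the master seed via
a counter scheme (SeedSequence spawn per stage name), so stages are
individually reproducible and mutually independent.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import factor as _factor
from . import optimize as _optimize
from . import pca as _pca
from . import risk as _risk
from . import synthetic as _synthetic
from . import tsne as _tsne
from .io import read_concentration_csv, write_concentration_csv

logger = logging.getLogger("dustrisk")

ALL_STAGES = ("risk", "pca", "fa", "tsne", "opt", "concordance")

__all__ = ["PipelineConfig", "ConcordanceReport", "concordance_report", "run_pipeline", "ALL_STAGES"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``input_csv`` points at a concentration table or ``synthetic``
    holds a generator configuration (used when ``input_csv`` is None).
    ``advisory_hi`` is a narrative monitoring threshold reported in the
    concordance output; the formal risk flag stays HI > 1.
    """

    input_csv: str | None = None
    synthetic: _synthetic.SyntheticConfig | None = None
    exposure: _risk.ExposureFactors = field(default_factory=_risk.ExposureFactors.adult_default)
    rfd: _risk.ReferenceDoseTable = field(default_factory=_risk.ReferenceDoseTable.default)
    cumvar_threshold: float = 0.80
    n_factors: int | None = None  # None -> BIC rule
    tsne: _tsne.TsneParams = field(default_factory=_tsne.TsneParams)
    opt_objectives: tuple[str, ...] = ("kl",)
    opt_budget: int = 30
    cluster_k: int | None = None  # None -> silhouette-selected k
    stages: tuple[str, ...] = ALL_STAGES
    outdir: str = "dustrisk_out"
    seed: int = 0
    advisory_hi: float = 0.5

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build a config from a plain (YAML/JSON-loaded) mapping."""
        cfg = cls()
        raw = dict(raw)
        if "exposure" in raw:
            cfg.exposure = _risk.ExposureFactors(**raw.pop("exposure"))
        if "rfd" in raw:
            base = {m: dict(v) for m, v in cfg.rfd.doses.items()}
            for metal, entry in raw.pop("rfd").items():
                base.setdefault(metal, {}).update(entry)
            cfg.rfd = _risk.ReferenceDoseTable(base)
        if "tsne" in raw:
            cfg.tsne = _tsne.TsneParams(**raw.pop("tsne"))
        if "synthetic" in raw:
            cfg.synthetic = _synthetic.SyntheticConfig(**raw.pop("synthetic"))
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key in ("stages", "opt_objectives"):
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg


@dataclass
class ConcordanceReport:
    """Cluster-level hazard summary linking embedding clusters to risk.

    ``per_cluster`` has one row per cluster (mean/min/max HI, member
    sites); ``ranking`` orders cluster ids by decreasing mean HI;
    ``crosstab`` counts sites per (HI tercile, cluster) cell, terciles on
    the empirical HI distribution with ties to the lower band.
    """

    per_cluster: pd.DataFrame
    ranking: list[int]
    degenerate: bool
    crosstab: pd.DataFrame
    advisory_sites: list[str]

    def to_dict(self) -> dict:
        return {
            "per_cluster": self.per_cluster.reset_index().to_dict(orient="records"),
            "ranking_by_mean_hi": self.ranking,
            "degenerate_ranking": self.degenerate,
            "crosstab": {
                str(t): {str(c): int(v) for c, v in row.items()}
                for t, row in self.crosstab.to_dict(orient="index").items()
            },
            "advisory_sites": self.advisory_sites,
        }


def _terciles(hi: np.ndarray) -> np.ndarray:
    """Tercile band (0=low, 1=mid, 2=high) with ties to the lower band."""
    q1, q2 = np.quantile(hi, [1 / 3, 2 / 3])
    return np.where(hi <= q1, 0, np.where(hi <= q2, 1, 2))


def concordance_report(
    hi: pd.Series, labels: np.ndarray, advisory_hi: float = 0.5
) -> ConcordanceReport:
    """Aggregate per-site HI by embedding cluster."""
    labels = np.asarray(labels)
    if len(labels) != len(hi):
        raise ValueError("cluster labels and HI series cover different site sets")
    df = pd.DataFrame({"HI": hi.to_numpy(dtype=float), "cluster": labels}, index=hi.index)
    per = df.groupby("cluster")["HI"].agg(["mean", "min", "max", "count"])
    per["sites"] = [list(df.index[df["cluster"] == c]) for c in per.index]
    ranking = list(per.sort_values("mean", ascending=False).index)
    degenerate = bool(np.isclose(per["mean"].max(), per["mean"].min()))
    bands = _terciles(df["HI"].to_numpy())
    crosstab = pd.crosstab(pd.Series(bands, index=df.index, name="hi_tercile"), df["cluster"])
    advisory = list(df.index[df["HI"] > advisory_hi])
    return ConcordanceReport(
        per_cluster=per,
        ranking=[int(c) for c in ranking],
        degenerate=degenerate,
        crosstab=crosstab,
        advisory_sites=[str(s) for s in advisory],
    )


def _stage_seed(master: int, stage: str) -> int:
    digest = sum((i + 1) * b for i, b in enumerate(stage.encode())) % 10007
    return int(np.random.SeedSequence([master, digest]).generate_state(1)[0] % (2**31))


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages; returns the output directory.

    A stage failure is recorded in the manifest and the dependent stages
    are skipped; the manifest's ``failed`` field is then non-empty.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "stage_seconds": {},
        "failed": {},
        "skipped": [],
    }

    if config.input_csv is not None:
        conc = read_concentration_csv(config.input_csv, config.rfd)
        manifest["input"] = str(config.input_csv)
    else:
        syn = config.synthetic or _synthetic.SyntheticConfig(seed=config.seed)
        dataset = _synthetic.generate_dataset(syn)
        conc = dataset.concentrations
        write_concentration_csv(conc, out / "concentrations.csv")
        manifest["input"] = "synthetic"
    manifest["n_sites"], manifest["n_metals"] = map(int, conc.shape)

    state: dict = {"conc": conc}
    runners = {
        "risk": _run_risk,
        "pca": _run_pca,
        "fa": _run_fa,
        "tsne": _run_tsne,
        "opt": _run_opt,
        "concordance": _run_concordance,
    }
    requires = {"concordance": ("risk", "tsne")}
    done: set[str] = set()
    for stage in config.stages:
        missing = [d for d in requires.get(stage, ()) if d not in done]
        if missing:
            manifest["skipped"].append({"stage": stage, "missing": missing})
            continue
        t0 = time.perf_counter()
        try:
            logger.info("stage %s starting (seed %d)", stage, _stage_seed(config.seed, stage))
            runners[stage](config, state, out)
            done.add(stage)
        except Exception as exc:  # recorded, downstream stages skipped
            logger.exception("stage %s failed", stage)
            manifest["failed"][stage] = f"{type(exc).__name__}: {exc}"
        manifest["stage_seconds"][stage] = round(time.perf_counter() - t0, 3)
        if stage in manifest["failed"]:
            break
    _write_json(out / "run_manifest.json", manifest)
    if manifest["failed"]:
        raise RuntimeError(f"pipeline stage(s) failed: {manifest['failed']}")
    return out


def _run_risk(config: PipelineConfig, state: dict, out: Path) -> None:
    result = _risk.hazard_quotients(state["conc"], config.exposure, config.rfd)
    state["hazard"] = result
    add_long = result.ADD.stack(["metal", "path"], future_stack=True).rename("value").reset_index()
    add_long.columns = ["site_id", "metal", "path", "value"]
    add_long.to_csv(out / "hazard_add.csv", index=False)
    hq_long = result.HQ_path.stack(["metal", "path"], future_stack=True).rename("value").reset_index()
    hq_long.columns = ["site_id", "metal", "path", "value"]
    hq_long.to_csv(out / "hazard_hq.csv", index=False)
    pd.DataFrame({"HI": result.HI, "flag": result.risk_flag}).rename_axis("site_id").to_csv(
        out / "hazard_hi.csv"
    )
    summary = _risk.summarize_add(result)
    summary.scaled_table.assign(scale=summary.scale).to_csv(out / "add_summary.csv")


def _run_pca(config: PipelineConfig, state: dict, out: Path) -> None:
    model = _pca.CorrelationPCA(cumvar_threshold=config.cumvar_threshold).fit(state["conc"])
    state["pca"] = model
    model.eigen_table().to_csv(out / "pca_eigen.csv", index=False)
    cols = [f"PC{j + 1}" for j in range(model.n_features_in_)]
    pd.DataFrame(model.scores_, index=state["conc"].index, columns=cols).to_csv(out / "pca_scores.csv")
    metals = list(state["conc"].columns)
    pd.DataFrame(model.cos2_variables_, index=metals, columns=cols).to_csv(out / "pca_cos2.csv")
    pd.DataFrame(model.contributions_, index=metals, columns=cols).to_csv(out / "pca_contrib.csv")
    _write_json(out / "pca_selection.json", model.select().to_dict())


def _run_fa(config: PipelineConfig, state: dict, out: Path) -> None:
    conc = state["conc"]
    n = conc.shape[0]
    Z = np.asarray(_pca.standardize(conc))
    R = Z.T @ Z / (n - 1)
    sel = _factor.select_m(R, n, data=conc, seed=_stage_seed(config.seed, "fa"))
    m = config.n_factors or sel.selected_m["default"]
    model = _factor.MLFactorAnalysis(n_factors=m).fit(conc)
    state["fa"] = model
    model.loadings_table().rename_axis("metal").to_csv(out / "fa_loadings.csv")
    _write_json(out / "fa_fit.json", {"m": m, **model.fit_stats_.to_dict(),
                                      "heywood": model.heywood_})
    _write_json(out / "fa_selection.json", sel.to_dict())


def _run_tsne(config: PipelineConfig, state: dict, out: Path) -> None:
    conc = state["conc"]
    Z = np.asarray(_pca.standardize(conc))
    params = _tsne.TsneParams(
        out_dims=config.tsne.out_dims,
        perplexity=config.tsne.perplexity,
        learning_rate=config.tsne.learning_rate,
        momentum=config.tsne.momentum,
        max_iter=config.tsne.max_iter,
        seed=_stage_seed(config.seed, "tsne"),
    )
    result = _tsne.tsne_run(Z, params)
    state["tsne"] = result
    state["Z"] = Z
    emb = pd.DataFrame(result.Y, index=conc.index,
                       columns=[f"dim{j + 1}" for j in range(params.out_dims)])
    emb.to_csv(out / "tsne_embedding.csv")
    pd.DataFrame({"iteration": np.arange(1, len(result.kl_trace) + 1),
                  "kl": result.kl_trace}).to_csv(out / "tsne_trace.csv", index=False)


def _run_opt(config: PipelineConfig, state: dict, out: Path) -> None:
    Z = state.get("Z")
    if Z is None:
        Z = np.asarray(_pca.standardize(state["conc"]))
        state["Z"] = Z
    seed = _stage_seed(config.seed, "opt")
    rows = []
    best_overall = None
    for objective in config.opt_objectives:
        result = _optimize.optimize_tsne(Z, objective=objective, budget=config.opt_budget,
                                         seed=seed, base=config.tsne)
        for i, (params, value) in enumerate(result.eval_trace):
            rows.append({"objective": objective, "eval": i, **params, "value": value})
        if objective == "kl" or best_overall is None:
            best_overall = result
    pd.DataFrame(rows).to_csv(out / "bayesopt_trace.csv", index=False)
    state["opt"] = best_overall
    # re-embed at the winning hyperparameters for the quality report
    best_i = int(np.argmin([v for _, v in best_overall.eval_trace]))
    params = _tsne.TsneParams(
        out_dims=config.tsne.out_dims,
        perplexity=best_overall.best_params["perplexity"],
        learning_rate=best_overall.best_params["learning_rate"],
        momentum=best_overall.best_params["momentum"],
        max_iter=config.tsne.max_iter,
        seed=_optimize.evaluation_seed(seed, best_i),
    )
    refit = _tsne.tsne_run(Z, params)
    state["tsne"] = refit
    assignment = _cluster.assign_clusters(refit.Y, k=config.cluster_k, seed=seed)
    state["clusters"] = assignment
    pd.DataFrame({"site_id": state["conc"].index, "cluster": assignment.labels}).to_csv(
        out / "cluster_labels.csv", index=False
    )
    report = _cluster.quality_report(refit.Y, assignment.labels, X=Z)
    _write_json(out / "cluster_quality.json", {
        **report.to_dict(),
        "best_params": best_overall.best_params,
        "best_objective": best_overall.best_objective,
        "objective": best_overall.objective,
    })


def _run_concordance(config: PipelineConfig, state: dict, out: Path) -> None:
    if "clusters" not in state:
        # opt stage skipped: cluster the plain embedding
        assignment = _cluster.assign_clusters(
            state["tsne"].Y, k=config.cluster_k, seed=_stage_seed(config.seed, "opt")
        )
        state["clusters"] = assignment
        pd.DataFrame({"site_id": state["conc"].index, "cluster": assignment.labels}).to_csv(
            out / "cluster_labels.csv", index=False
        )
    report = concordance_report(state["hazard"].HI, state["clusters"].labels, config.advisory_hi)
    state["concordance"] = report
    _write_json(out / "concordance.json", report.to_dict())
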