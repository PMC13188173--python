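"""End-to-end orchestration: simulate -> fit-sdm -> select-vars -> stack ->
detect -> sem, from one YAML config, with per-stage caching and provenance.

Stage outputs land in subdirectories of the output directory; every stage
can be re-run in isolation as long as its upstream outputs are present
(otherwise a :class:`DependencyError` names the missing stage).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geodetector as gd
from . import maxent, selection, sem, simulate, stacking
from .grids import EnvStack, read_ascii_grid, read_occurrences_csv, \
    write_ascii_grid, write_occurrences_csv

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit-sdm", "select-vars", "stack", "detect", "sem")


class ConfigError(ValueError):
    pass


class DependencyError(RuntimeError):
    pass


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "richscape_out",
    "log_level": "INFO",
    "simulate": {
        "shape": [100, 100],
        "group_sizes": dict(simulate.DEFAULT_GROUP_SIZES),
        "structural": dict(simulate.DEFAULT_STRUCTURAL),
        "corr_range": 5.0,
        "member_loading": 0.8,
        "n_species": 14,
        "n_points": 300,
    },
    "sdm": {
        "beta": 0.05,
        "split": 0.75,
        "reps": 10,
        "features": ["linear", "quadratic"],
        "n_perm": 3,
    },
    "selection": {"cum_pct": 95.0, "corr_threshold": 0.8},
    "stacking": {"k": 2},
    "geodetector": {"method": "jenks", "k": 5, "group_k": 3, "min_count": 10,
                    "modes": ["combined", "mean-pairwise"]},
    "sem": {"method": "pc1", "bootstrap": 0},
}

_RANGES = {
    ("sdm", "split"): (0.0, 1.0, False),
    ("sdm", "beta"): (0.0, float("inf"), True),
    ("selection", "cum_pct"): (0.0, 100.0, True),
    ("selection", "corr_threshold"): (0.0, 1.0, True),
}


def validate_config(config: dict | None) -> dict:
    """Fill defaults, reject unknown keys, range-check thresholds."""
    config = copy.deepcopy(config or {})
    out = copy.deepcopy(DEFAULT_CONFIG)
    unknown = set(config) - set(out)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for key, val in config.items():
        if isinstance(out[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{key!r} must be a mapping")
            bad = set(val) - set(out[key])
            if bad:
                raise ConfigError(f"unknown key(s) under {key!r}: {sorted(bad)}")
            out[key].update(val)
        else:
            out[key] = val
    for (sec, name), (lo, hi, inclusive) in _RANGES.items():
        v = out[sec][name]
        ok = lo <= v <= hi if inclusive else lo < v < hi
        if not ok:
            raise ConfigError(f"{sec}.{name}={v} outside "
                              f"{'[' if inclusive else '('}{lo}, {hi}"
                              f"{']' if inclusive else ')'}")
    if out["sdm"]["reps"] < 1:
        raise ConfigError("sdm.reps must be >= 1")
    if int(out["seed"]) != out["seed"]:
        raise ConfigError("seed must be an integer")
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing {path.name}; run the {stage!r} stage first")
    return path


def _load_env(outdir: Path) -> EnvStack:
    envdir = _require(outdir / "env", "simulate")
    groups = json.loads(_require(envdir / "groups.json", "simulate").read_text())
    layers = {name: read_ascii_grid(envdir / f"{name}.asc", name=name)
              for name in groups}
    return EnvStack(layers, groups)


def stage_simulate(cfg: dict, outdir: Path) -> None:
    sc = cfg["simulate"]
    lc = simulate.LandscapeConfig(
        shape=tuple(sc["shape"]), group_sizes=sc["group_sizes"],
        structural=sc["structural"], corr_range=sc["corr_range"],
        member_loading=sc["member_loading"], n_species=sc["n_species"],
        n_points=sc["n_points"], seed=int(cfg["seed"]))
    ds = simulate.make_dataset(lc)
    envdir = outdir / "env"
    envdir.mkdir(parents=True, exist_ok=True)
    for name, grid in ds.env.layers.items():
        write_ascii_grid(grid, envdir / f"{name}.asc")
    (envdir / "groups.json").write_text(json.dumps(ds.env.groups, indent=1))
    write_occurrences_csv(ds.occurrences, outdir / "occurrences.csv")
    write_ascii_grid(ds.richness_true, outdir / "richness_true.asc")
    truth = {"structural_coeffs": ds.truth.structural_coeffs,
             "noise_sd": ds.truth.noise_sd,
             "field_range": ds.truth.field_range,
             "seed": ds.truth.seed,
             "true_weights": {k: v.tolist()
                              for k, v in ds.truth.true_weights.items()}}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def stage_fit_sdm(cfg: dict, outdir: Path) -> None:
    env = _load_env(outdir)
    occ = read_occurrences_csv(_require(outdir / "occurrences.csv", "simulate"))
    sdm = cfg["sdm"]
    kinds = tuple(sdm["features"])
    auc_rows, contrib_rows = [], []
    bg_table = env.pixel_table
    for i, o in enumerate(occ):
        model, cells = maxent.fit_species(o, env, beta=sdm["beta"], kinds=kinds)
        pres_table = env.cells_to_table(cells)
        contrib = maxent.variable_contributions(
            model, pres_table, bg_table, n_perm=sdm["n_perm"],
            seed=int(cfg["seed"]) + 500 + i)
        for cov, pct in contrib.items():
            contrib_rows.append({"species": o.species, "covariate": cov,
                                 "contribution_pct": pct})
        report = maxent.evaluate_auc(o, env, beta=sdm["beta"],
                                     split=sdm["split"], reps=sdm["reps"],
                                     seed=int(cfg["seed"]) + 900 + i,
                                     kinds=kinds)
        auc_rows.append({"species": o.species, "mean_auc": report.mean_auc,
                         "sd_auc": report.sd_auc,
                         "mean_train_auc": report.mean_train_auc,
                         "n_presences": report.n_presences})
        logger.info("%s: mean test AUC %.3f", o.species, report.mean_auc)
    pd.DataFrame(auc_rows).to_csv(outdir / "auc.csv", index=False)
    pd.DataFrame(contrib_rows).to_csv(outdir / "contributions.csv", index=False)


def _contribution_table(outdir: Path) -> pd.DataFrame:
    path = _require(outdir / "contributions.csv", "fit-sdm")
    df = pd.read_csv(path)
    return df.pivot(index="species", columns="covariate",
                    values="contribution_pct").fillna(0.0)


def stage_select_vars(cfg: dict, outdir: Path) -> None:
    env = _load_env(outdir)
    table = _contribution_table(outdir)
    sel = selection.select_covariates(
        table, env.pixel_table, cum_pct=cfg["selection"]["cum_pct"],
        threshold=cfg["selection"]["corr_threshold"])
    sel["frequency"].rename("frequency").to_csv(outdir / "frequency.csv")
    sel["top3"].rename("top3_count").to_csv(outdir / "top3.csv")
    pd.Series(sel["retained"], name="covariate").to_csv(
        outdir / "retained.csv", index=False)
    pd.DataFrame([d.__dict__ for d in sel["prune_log"]]).to_csv(
        outdir / "prune_log.csv", index=False)
    env.pixel_table.corr().to_csv(outdir / "correlation_matrix.csv")


def _retained_env(cfg: dict, outdir: Path) -> EnvStack:
    env = _load_env(outdir)
    retained = pd.read_csv(_require(outdir / "retained.csv", "select-vars"))
    return env.subset(list(retained["covariate"]))


def stage_stack(cfg: dict, outdir: Path) -> None:
    env = _retained_env(cfg, outdir)
    occ = read_occurrences_csv(_require(outdir / "occurrences.csv", "simulate"))
    sdm = cfg["sdm"]
    suitdir = outdir / "suitability"
    suitdir.mkdir(exist_ok=True)
    binary_maps, thresholds = [], []
    for o in occ:
        model, _ = maxent.fit_species(o, env, beta=sdm["beta"],
                                      kinds=tuple(sdm["features"]))
        _, suit = maxent.predict_suitability(model, env)
        suit.name = o.species
        write_ascii_grid(suit, suitdir / f"{o.species}.asc")
        t, meta = stacking.species_threshold(suit, k=cfg["stacking"]["k"])
        thresholds.append({"species": o.species, "threshold": t, **{
            k: v for k, v in meta.items() if k != "breakpoints"}})
        bmap = stacking.binarize(suit, t)
        write_ascii_grid(bmap, suitdir / f"{o.species}_binary.asc")
        binary_maps.append(bmap)
    richness = stacking.stack_richness(binary_maps)
    write_ascii_grid(richness.grid, outdir / "richness.asc")
    pd.DataFrame(thresholds).to_csv(outdir / "thresholds.csv", index=False)
    full_env = _load_env(outdir)
    stacking.richness_correlations(richness.grid, full_env).rename(
        "pearson_r").to_csv(outdir / "richness_correlations.csv")


def stage_detect(cfg: dict, outdir: Path) -> None:
    env = _retained_env(cfg, outdir)
    richness = read_ascii_grid(_require(outdir / "richness.asc", "stack"))
    g = cfg["geodetector"]
    flat = env.pixel_table.index.to_numpy()
    resp = richness.values.ravel()[flat]
    ok = np.isfinite(resp)
    sub_table = env.pixel_table[ok]
    sub_env = env  # strata built from the joint table below
    response = resp[ok]
    # rebuild a stack view restricted to jointly valid pixels
    factor_table = gd.factor_q_table(response, _TableStack(sub_table, env.groups),
                                     method=g["method"], k=g["k"])
    factor_table.to_csv(outdir / "factor_q.csv")
    gd.pairwise_interaction_matrix(
        response, _TableStack(sub_table, env.groups), method=g["method"],
        k=g["k"]).to_csv(outdir / "interaction_matrix.csv")
    tables = gd.group_interaction_table(
        response, _TableStack(sub_table, env.groups), per_factor_k=g["k"],
        group_k=g["group_k"], method=g["method"], min_count=g["min_count"])
    for mode in g["modes"]:
        tables[mode].to_csv(outdir / f"group_q_{mode}.csv")


class _TableStack:
    """EnvStack-shaped view over a plain pixel table (detector stages only
    need the table, names and group labels)."""

    def __init__(self, table: pd.DataFrame, groups: dict[str, str]):
        self.pixel_table = table
        self.groups = {n: groups[n] for n in table.columns}
        self.names = list(table.columns)

    def group_members(self, group: str) -> list[str]:
        return [n for n, g in self.groups.items() if g == group]


def stage_sem(cfg: dict, outdir: Path) -> None:
    env = _load_env(outdir)
    richness = read_ascii_grid(_require(outdir / "richness.asc", "stack"))
    flat = env.pixel_table.index.to_numpy()
    resp = richness.values.ravel()[flat]
    ok = np.isfinite(resp)
    table = env.pixel_table[ok]
    indices = sem.build_indices(table, env.groups, resp[ok],
                                method=cfg["sem"]["method"])
    model = sem.fit_path_model(indices, bootstrap=cfg["sem"]["bootstrap"],
                               seed=int(cfg["seed"]) + 7)
    sem.path_table(model).to_csv(outdir / "path_coefficients.csv", index=False)
    effects = sem.effects_decomposition(model)
    effects.to_frame().to_csv(outdir / "effects.csv")
    fi = sem.fit_indices(indices, model)
    pd.DataFrame([{"chi_square": fi.chi_square, "df": fi.df,
                   "CFI": fi.cfi, "NFI": fi.nfi, "GFI": fi.gfi}]).to_csv(
        outdir / "fit_indices.csv", index=False)
    (outdir / "path_diagram.txt").write_text(sem.edge_list(model) + "\n")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit-sdm": stage_fit_sdm,
    "select-vars": stage_select_vars,
    "stack": stage_stack,
    "detect": stage_detect,
    "sem": stage_sem,
}


def run_pipeline(config: dict | None = None, stages: list[str] | None = None,
                 outdir: str | Path | None = None) -> Path:
    """Run the requested stages in order; returns the artifact directory.

    On failure, outputs of completed stages are retained and the failing
    stage is named in the raised error.
    """
    cfg = validate_config(config)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    todo = list(STAGES) if stages is None else [
        s for s in STAGES if s in set(stages)]
    bad = set(stages or []) - set(STAGES)
    if bad:
        raise ConfigError(f"unknown stage(s): {sorted(bad)}")
    provenance = {"config": cfg,
                  "config_hash": hashlib.sha256(
                      json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
                  "stages": {}}
    for stage in todo:
        t0 = time.time()
        logger.info("stage %s ...", stage)
        try:
            _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        provenance["stages"][stage] = {
            "seconds": round(time.time() - t0, 2),
            "outputs": {p.name: _digest(p) for p in sorted(out.glob("*"))
                        if p.is_file()},
        }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return out


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
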