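"""End-to-end pipeline: describe -> Ising per wave -> stability ->
comparison -> CLPN -> centrality, driven by one config document.

Outputs are plain CSV/JSON files plus a reproducibility manifest
(seeds, package version, parameter echo, drop counts, stage timings).
Outputs are a pure function of the input data and the config.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clpn import CrossLaggedModel
from .comparison import invariance_test
from .data import BinarySymptomMatrix, read_panel_csv, recode_cesd
from .descriptives import cronbach_alpha, paired_change_table
from .io import write_network
from .ising import IsingModel, fit_ising
from .resampling import bootstrap_edges, cs_coefficient
from .simulate import cohort_preset, sample_two_wave

log = logging.getLogger("symptomnet.pipeline")

__all__ = ["load_defaults", "merge_config", "run_pipeline"]


def load_defaults() -> dict:
    """The checked-in analysis defaults."""
    text = resources.files("symptomnet").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def merge_config(user: dict | None) -> dict:
    """Defaults overlaid with a user config (one level of nesting)."""
    cfg = copy.deepcopy(load_defaults())
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _get_waves(cfg: dict) -> tuple[BinarySymptomMatrix, BinarySymptomMatrix, dict]:
    """Load or simulate the binary two-wave panel."""
    inp = cfg.get("input")
    if not inp:
        raise KeyError("config key 'input' is required")
    if "csv" in inp:
        panel, report = read_panel_csv(inp["csv"], inp)
        w1, w2 = recode_cesd(panel)
        meta = {
            "source": str(inp["csv"]),
            "n_read": report.n_read,
            "n_kept": report.n_kept,
            "n_dropped": report.n_dropped,
        }
    elif "simulate" in inp or inp.get("mode") == "simulate":
        sim = {**cfg["simulate"], **(inp.get("simulate") or {})}
        params = cohort_preset(int(sim.get("preset_seed", 0)))
        w1, w2 = sample_two_wave(
            params, int(sim["n"]), seed=int(cfg["seed"]),
            burn_in=int(sim.get("burn_in", 1000)),
        )
        meta = {"source": "simulate", "n": int(sim["n"]), "seed": int(cfg["seed"])}
    else:
        raise KeyError("config 'input' needs either a 'csv' or a 'simulate' block")
    return w1, w2, meta


def run_pipeline(config: dict, outdir) -> dict:
    """Run the full analysis and write a report bundle to ``outdir``.

    Returns the manifest dictionary (also written as manifest.json).
    """
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    stage_seeds = {
        name: s for name, s in zip(
            ["stability1", "stability2", "compare", "clpn"], ss.spawn(4)
        )
    }
    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "config": cfg,
        "stages": {},
    }

    def _stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            dt = time.perf_counter() - t0
            manifest["stages"][name] = {"seconds": round(dt, 3)}
            log.info("stage %s: done in %.2fs", name, dt)
            return out
        return wrap

    w1, w2, input_meta = _stage("input")(lambda: _get_waves(cfg))
    manifest["input"] = input_meta

    def _describe():
        tab = paired_change_table(w1, w2, correction=cfg["describe"]["correction"])
        tab.to_csv(outdir / "describe.csv", index=False)
        return {
            "alpha_wave1": cronbach_alpha(w1),
            "alpha_wave2": cronbach_alpha(w2),
        }

    manifest["describe"] = _stage("describe")(_describe)

    icfg = cfg["ising"]
    nets = {}
    for tag, wave in (("wave1", w1), ("wave2", w2)):
        def _ising(wave=wave, tag=tag):
            res = IsingModel(
                wave,
                gamma=icfg["gamma"],
                rule=icfg["rule"],
                n_lambda=icfg["n_lambda"],
                lambda_min_ratio=icfg["lambda_min_ratio"],
                standardize=icfg["standardize"],
            ).fit()
            write_network(outdir / f"ising_{tag}", res.network)
            res.centrality(
                metrics=("strength", "expected_influence", "closeness", "betweenness")
            ).to_csv(outdir / f"centrality_{tag}.csv", index=False)
            return res
        nets[tag] = _stage(f"ising_{tag}")(_ising)
    manifest["ising"] = {
        tag: {
            "global_strength": res.global_strength,
            "n_nonzero_edges": int(np.count_nonzero(res.network.edge_vector())),
        }
        for tag, res in nets.items()
    }

    scfg = cfg["stability"]
    grid = tuple(
        np.round(
            np.arange(scfg["grid_step"], scfg["grid_max"] + 1e-9, scfg["grid_step"]), 10
        )
    )
    est = lambda m: fit_ising(
        m, gamma=icfg["gamma"], rule=icfg["rule"], n_lambda=icfg["n_lambda"],
        lambda_min_ratio=icfg["lambda_min_ratio"],
    )

    def _stability():
        out = {}
        for tag, wave, skey in (
            ("wave1", w1, stage_seeds["stability1"]),
            ("wave2", w2, stage_seeds["stability2"]),
        ):
            bs_seed, cs_seed = skey.spawn(2)
            boot = bootstrap_edges(wave, est, B=scfg["boots"], seed=bs_seed.generate_state(1)[0] % (2**31))
            import pandas as pd

            iu, ju = boot.edge_index
            labels = wave.item_labels
            pd.DataFrame(
                {
                    "node1": [labels[i] for i in iu],
                    "node2": [labels[j] for j in ju],
                    "observed": boot.observed.weights[iu, ju],
                    "boot_mean": boot.boot_mean,
                    "ci_lower": boot.ci_lower,
                    "ci_upper": boot.ci_upper,
                }
            ).to_csv(outdir / f"edge_ci_{tag}.csv", index=False)
            cs = cs_coefficient(
                wave, est, grid=grid, B=scfg["boots"],
                threshold_r=scfg["threshold_r"], confidence=scfg["confidence"],
                method=scfg["method"], seed=cs_seed.generate_state(1)[0] % (2**31),
            )
            out[tag] = {
                "cs_strength": cs.cs,
                "degenerate_boot_replicates": boot.n_degenerate_replicates,
            }
        (outdir / "stability.json").write_text(json.dumps(out, indent=2))
        return out

    manifest["stability"] = _stage("stability")(_stability)

    ccfg = cfg["compare"]

    def _compare():
        res = invariance_test(
            w1, w2, estimator=est, n_perm=ccfg["perms"], paired=ccfg["paired"],
            seed=stage_seeds["compare"].generate_state(1)[0] % (2**31),
        )
        out = {
            "M": res.M, "p_M": res.p_M, "S1": res.S1, "S2": res.S2,
            "delta_S": res.delta_S, "p_S": res.p_S,
            "phi": None if np.isnan(res.phi) else res.phi,
            "rho": None if np.isnan(res.rho) else res.rho,
            "paired": res.paired, "n_permutations": res.n_permutations,
        }
        (outdir / "compare.json").write_text(json.dumps(out, indent=2))
        return out

    manifest["compare"] = _stage("compare")(_compare)

    lcfg = cfg["clpn"]

    def _clpn():
        res = CrossLaggedModel(
            w1, w2, k_folds=lcfg["folds"], rule=lcfg["rule"],
            n_lambda=lcfg["n_lambda"], lambda_min_ratio=lcfg["lambda_min_ratio"],
            stratify=lcfg["stratify"], standardize=lcfg["standardize"],
        ).fit(seed=stage_seeds["clpn"].generate_state(1)[0] % (2**31))
        write_network(outdir / "clpn", res.network)
        res.centrality().to_csv(outdir / "centrality_clpn.csv", index=False)
        return {
            "n_nonzero_crosslagged": int(
                np.count_nonzero(
                    res.network.coefficients
                    - np.diag(np.diag(res.network.coefficients))
                )
            )
        }

    manifest["clpn"] = _stage("clpn")(_clpn)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
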