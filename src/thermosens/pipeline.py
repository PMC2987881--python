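"""One-command pipeline runs from a validated config mapping.

A run executes: synthesize data -> build objective -> requested sensitivity
methods and/or census -> write every result as TSV/JSON plus a manifest
(config, config hash, derived stage seeds, package version).  Every stochastic
stage derives its seed deterministically from the master seed, so two runs of
the same config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import yaml

from . import __version__
from .global_sensitivity import (
    EfastConfig,
    HdmrConfig,
    SensitivityResult,
    efast_indices,
    global_local,
    hdmr_expansion,
)
from .io import FLOAT_FORMAT, write_constructs_json, write_dataset_tsv, write_profiles_tsv
from .local_sensitivity import local_profile
from .objectives import make_objective
from .param_census import RelationshipRule, census_report, run_census
from .parameter_space import ParameterSpace, default_fakhouri_space, default_zinzen_space
from .synthetic_data import (
    DesignSpec,
    TruthSpec,
    make_fakhouri_constructs,
    make_repressor_gradient,
    make_zinzen_profiles,
    simulate_dataset,
    zinzen_dataset,
)
from .thermo_models import default_binning

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("simulate", "local", "globallocal", "efast", "hdmr", "census")
_METHOD_NAMES = ("local", "globallocal", "efast", "hdmr", "census")


def _stage_seed(master: int, stage: str) -> int:
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence((int(master), idx)).generate_state(1)[0] % (2 ** 31))


class ConfigError(ValueError):
    pass


class RunConfig:
    """Validated pipeline configuration.

    Accepts a mapping (already parsed) or a path to a YAML file.  Validation
    errors name the offending field path.
    """

    def __init__(self, source: Union[Mapping, str, Path]):
        if isinstance(source, (str, Path)):
            raw = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
        else:
            raw = dict(source)
        if not isinstance(raw, Mapping):
            raise ConfigError("config root must be a mapping")
        self.raw = dict(raw)

        self.model_family = self._get("model_family", str, default="fakhouri")
        if self.model_family not in ("fakhouri", "zinzen"):
            raise ConfigError(f"model_family: unknown family {self.model_family!r}")
        self.seed = self._get("seed", int, default=0)
        self.output_dir = Path(self._get("output_dir", str, default="thermosens_run"))
        default_kind = "rmse" if self.model_family == "fakhouri" else "pearson"
        self.objective_kind = self._get("objective", str, default=default_kind)
        if self.objective_kind not in ("rmse", "pearson"):
            raise ConfigError(f"objective: unknown kind {self.objective_kind!r}")

        syn = self.raw.get("synthetic", {}) or {}
        if not isinstance(syn, Mapping):
            raise ConfigError("synthetic: must be a mapping")
        self.synthetic = {
            "design": syn.get("design", "original"),
            "n_conditions": int(syn.get("n_conditions", 11)),
            "noise_sd": float(syn.get("noise_sd", 0.05)),
            "placement": syn.get("placement", "mid-range"),
            "n_positions": int(syn.get("n_positions", 60)),
            "set_index": int(syn.get("set_index", 0)),
        }
        self.cooperativity_mode = self.raw.get("cooperativity_mode", "binding")
        self.pairing = self.raw.get("pairing", "two_term")

        space_records = self.raw.get("space")
        if space_records is not None:
            try:
                self.space = ParameterSpace.from_records(space_records)
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(f"space: {exc}") from exc
        elif self.model_family == "fakhouri":
            self.space = default_fakhouri_space()
        else:
            self.space = default_zinzen_space(scale=self.raw.get("sampling_scale", "linear"))

        methods = self.raw.get("methods", [])
        if not isinstance(methods, list):
            raise ConfigError("methods: must be a list")
        self.methods: list[dict] = []
        for i, m in enumerate(methods):
            if isinstance(m, str):
                m = {"name": m}
            if not isinstance(m, Mapping) or "name" not in m:
                raise ConfigError(f"methods[{i}]: must be a name or mapping with a 'name'")
            if m["name"] not in _METHOD_NAMES:
                raise ConfigError(f"methods[{i}].name: unknown method {m['name']!r}")
            if m["name"] == "census" and self.model_family != "zinzen":
                raise ConfigError(f"methods[{i}]: the census applies to the zinzen family")
            self.methods.append(dict(m))

    def _get(self, key: str, typ, default):
        v = self.raw.get(key, default)
        try:
            return typ(v)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{key}: expected {typ.__name__}, got {v!r}") from exc

    def canonical_json(self) -> str:
        cfg = dict(self.raw)
        cfg.setdefault("seed", self.seed)
        return json.dumps(cfg, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _write_sensitivity(result: SensitivityResult, stem: Path, created: list) -> None:
    tsv = stem.with_suffix(".tsv")
    result.to_frame().to_csv(tsv, sep="\t", index=False, float_format=FLOAT_FORMAT)
    created.append(tsv)
    meta = {
        "method": result.method,
        "config": result.config,
        "f0": result.f0,
        "variance": result.variance,
        "first_order_raw": [float(v) for v in result.first_order_raw],
    }
    if result.total_order_raw is not None:
        meta["total_order_raw"] = [float(v) for v in result.total_order_raw]
    if result.second_order is not None:
        pairs_tsv = stem.parent / (stem.name + "_pairs.tsv")
        import pandas as pd

        rows = []
        names = result.names
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    {"param_i": names[i], "param_j": names[j], "S2": result.second_order[i, j]}
                )
        pd.DataFrame(rows).to_csv(pairs_tsv, sep="\t", index=False, float_format=FLOAT_FORMAT)
        created.append(pairs_tsv)
    js = stem.parent / (stem.name + "_meta.json")
    js.write_text(json.dumps(meta, indent=1, default=str) + "\n", encoding="utf-8")
    created.append(js)


def run_pipeline(
    config: Union[Mapping, str, Path, RunConfig],
    output_dir: Optional[Union[str, Path]] = None,
    seed: Optional[int] = None,
) -> dict:
    """Execute a config end to end; returns the in-memory result bundle.

    Partial outputs are removed if any stage fails.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig(config)
    if seed is not None:
        cfg.seed = int(seed)
    out = Path(output_dir) if output_dir is not None else cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    results: dict = {}
    try:
        sim_seed = _stage_seed(cfg.seed, "simulate")
        syn = cfg.synthetic
        if cfg.model_family == "fakhouri":
            binning = default_binning()
            design = make_fakhouri_constructs(DesignSpec(design=syn["design"]), binning)
            gradient = make_repressor_gradient(syn["n_conditions"])
            truth = TruthSpec(placement=syn["placement"], noise_sd=syn["noise_sd"], seed=sim_seed)
            dataset = simulate_dataset(
                design.constructs, truth, gradient, binning, cfg.space,
                pairing=cfg.pairing, cooperativity_mode=cfg.cooperativity_mode,
            )
            write_constructs_json(design.constructs, out / "constructs.json")
            created.append(out / "constructs.json")
            design.bin_table.to_csv(out / "bin_table.tsv", sep="\t")
            created.append(out / "bin_table.tsv")
            write_dataset_tsv(dataset, out / "dataset.tsv")
            created.append(out / "dataset.tsv")
            results["design"] = design
        else:
            profiles = make_zinzen_profiles(
                syn["n_positions"], seed=sim_seed, space=cfg.space,
                noise_sd=syn["noise_sd"], set_index=syn["set_index"],
            )
            dataset = zinzen_dataset(profiles)
            write_profiles_tsv(profiles.frame, out / "profiles.tsv")
            created.append(out / "profiles.tsv")
            results["profiles"] = profiles
        results["dataset"] = dataset

        objective = make_objective(
            dataset, cfg.model_family, cfg.space, kind=cfg.objective_kind,
            **(
                {"pairing": cfg.pairing, "cooperativity_mode": cfg.cooperativity_mode}
                if cfg.model_family == "fakhouri"
                else {}
            ),
        )
        results["objective"] = objective

        stage_seeds = {"simulate": sim_seed}
        for m in cfg.methods:
            name = m["name"]
            mseed = _stage_seed(cfg.seed, name)
            stage_seeds[name] = mseed
            if name == "local":
                point = np.asarray(m.get("point", cfg.space.midpoint()), dtype=float)
                res = local_profile(objective, point, m.get("rel_step", 1e-4), cfg.space)
                res.to_frame().to_csv(
                    out / "local.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
                )
                created.append(out / "local.tsv")
                results["local"] = res
            elif name == "globallocal":
                res = global_local(
                    objective, cfg.space, n=int(m.get("n", 10_000)), seed=mseed,
                    weighting=m.get("weighting", "inverse-objective"),
                )
                _write_sensitivity(res, out / "globallocal", created)
                results["globallocal"] = res
            elif name == "efast":
                ecfg = EfastConfig(
                    M=int(m.get("M", 4)), Nr=int(m.get("Nr", 5)),
                    Ns=m.get("Ns"), omega_cap=int(m.get("omega_cap", 512)), seed=mseed,
                )
                res = efast_indices(objective, cfg.space, ecfg)
                _write_sensitivity(res, out / "efast", created)
                results["efast"] = res
            elif name == "hdmr":
                hcfg = HdmrConfig(
                    N=int(m.get("N", 10_000)), k1=int(m.get("k1", 3)),
                    k2=int(m.get("k2", 2)), seed=mseed,
                )
                res = hdmr_expansion(objective, cfg.space, hcfg)
                _write_sensitivity(res, out / "hdmr", created)
                results["hdmr"] = res
            elif name == "census":
                rule = RelationshipRule(dt_fold=m.get("dt_fold"))
                res = run_census(
                    objective, cfg.space, n=int(m.get("n", 100_000)),
                    threshold=float(m.get("threshold", 0.981)), seed=mseed, rule=rule,
                    label=str(cfg.synthetic["set_index"] + 1),
                )
                census_report(res).to_csv(out / "census.tsv", sep="\t", index=False)
                created.append(out / "census.tsv")
                if res.accepted is not None:
                    res.accepted.to_csv(
                        out / "census_accepted.tsv", sep="\t", index=False,
                        float_format=FLOAT_FORMAT,
                    )
                    created.append(out / "census_accepted.tsv")
                meta = {
                    "n": res.n_sampled, "threshold": res.threshold, "seed": res.seed,
                    "total_accepted": res.total_accepted, "counts": res.counts,
                    "sampling_scales": res.sampling_scales,
                }
                (out / "census_meta.json").write_text(
                    json.dumps(meta, indent=1) + "\n", encoding="utf-8"
                )
                created.append(out / "census_meta.json")
                results["census"] = res

        manifest = {
            "version": __version__,
            "config": cfg.raw,
            "config_hash": cfg.config_hash(),
            "master_seed": cfg.seed,
            "stage_seeds": stage_seeds,
            "outputs": [p.name for p in created],
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n", encoding="utf-8"
        )
        results["manifest"] = manifest
        return results
    except Exception:
        for p in created:
            try:
                p.unlink()
            except OSError:
                pass
        raise
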