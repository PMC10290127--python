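"""End-to-end pipeline: simulate/load -> scan -> fit -> assign -> survival -> adjust.

All randomness flows from one root seed through named substreams (generator,
EM restarts, bootstrap), so a fixed configuration reproduces every artifact
byte-for-byte.  Stage timings go to the logger (stderr), never into the
output files, so output directories are deterministic.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, read_cohort, write_cohort
from .synthetic import GeneratorConfig, default_config, simulate_cohort
from . import lca
from .survival import aalen_johansen, naive_cif, multi_state_model, sup_distance
from .adjustment import class_mixture_cif, adjustment_report

log = logging.getLogger(__name__)

_GENERATOR_KEYS = {
    "n_patients", "class_prevalence", "item_response", "levels",
    "baseline_hazards", "cause_hr", "subtype_given_class", "subtype_levels",
    "subtype_cause1_hr", "censor_admin_months", "dropout_hazard",
    "dropout_hazard_by_class", "seed",
}


@dataclass
class LCASettings:
    k_range: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    n_restarts: int = 10
    tol: float = 1e-8
    max_iter: int = 1000
    cutoff: float = 0.5
    use_bootstrap_lrt: bool = False
    lrt_bootstrap: int = 99

    def validate(self):
        if not self.k_range:
            raise ValueError("lca.k_range must be non-empty")
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("lca.cutoff must lie in [0, 1]")
        if self.n_restarts < 1 or self.max_iter < 1 or self.tol <= 0:
            raise ValueError("lca settings out of range")


@dataclass
class AdjustmentSettings:
    min_stratum: int = 50
    endpoints: list[str] = field(default_factory=lambda: ["overall", "cancer"])

    def validate(self):
        if self.min_stratum < 1:
            raise ValueError("adjustment.min_stratum must be >= 1")
        bad = set(self.endpoints) - {"overall", "cancer"}
        if bad:
            raise ValueError(f"unknown endpoint(s) {sorted(bad)}")


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration (strict: unknown keys rejected)."""

    seed: int = 0
    cohort_path: str | None = None
    generator: GeneratorConfig | None = None
    lca: LCASettings = field(default_factory=LCASettings)
    adjustment: AdjustmentSettings = field(default_factory=AdjustmentSettings)

    def validate(self):
        if self.cohort_path is None and self.generator is None:
            raise ValueError("config needs a cohort path or a generator section")
        self.lca.validate()
        self.adjustment.validate()
        if self.generator is not None:
            self.generator.validate()

    def to_dict(self) -> dict:
        d = {
            "seed": int(self.seed),
            "lca": {
                "k_range": list(self.lca.k_range),
                "n_restarts": self.lca.n_restarts,
                "tol": self.lca.tol,
                "max_iter": self.lca.max_iter,
                "cutoff": self.lca.cutoff,
                "use_bootstrap_lrt": self.lca.use_bootstrap_lrt,
                "lrt_bootstrap": self.lca.lrt_bootstrap,
            },
            "adjustment": {
                "min_stratum": self.adjustment.min_stratum,
                "endpoints": list(self.adjustment.endpoints),
            },
        }
        if self.cohort_path is not None:
            d["cohort_path"] = str(self.cohort_path)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        known = {"seed", "cohort_path", "generator", "lca", "adjustment"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        gen = None
        if "generator" in raw:
            gsec = dict(raw["generator"])
            if gsec.get("profile") == "default":
                gsec.pop("profile")
                gen = default_config(
                    n_patients=int(gsec.pop("n_patients", 20_000)),
                    seed=int(gsec.pop("seed", 0)),
                )
                if gsec:
                    raise ValueError(f"unknown generator key(s): {sorted(gsec)}")
            else:
                unknown = set(gsec) - _GENERATOR_KEYS
                if unknown:
                    raise ValueError(f"unknown generator key(s): {sorted(unknown)}")
                gen = GeneratorConfig.from_dict(gsec)
        lca_sec = dict(raw.get("lca", {}))
        unknown = set(lca_sec) - set(LCASettings().__dict__)
        if unknown:
            raise ValueError(f"unknown lca key(s): {sorted(unknown)}")
        adj_sec = dict(raw.get("adjustment", {}))
        unknown = set(adj_sec) - set(AdjustmentSettings().__dict__)
        if unknown:
            raise ValueError(f"unknown adjustment key(s): {sorted(unknown)}")
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            cohort_path=raw.get("cohort_path"),
            generator=gen,
            lca=LCASettings(**lca_sec),
            adjustment=AdjustmentSettings(**adj_sec),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ReportBundle:
    """Everything run_pipeline computed, reproducible from config + seed."""

    config: PipelineConfig
    selected_k: int
    scan_table: pd.DataFrame | None
    params: lca.LCAParameters
    class_profile: pd.DataFrame
    modal_shares: dict[str, float]
    unassigned_fraction: float
    hazard_ratios: pd.DataFrame
    cif_comparison: pd.DataFrame
    adjustment: pd.DataFrame | None

    def summary_dict(self) -> dict:
        out = {
            "provenance": {
                "package_version": __version__,
                "seed": int(self.config.seed),
                "settings": self.config.to_dict(),
            },
            "selected_k": int(self.selected_k),
            "class_prevalence_pct": [
                round(float(100 * p), 4) for p in self.params.class_prevalence
            ],
            "modal_shares_pct": {k: round(100 * v, 4) for k, v in self.modal_shares.items()},
            "unassigned_fraction": round(float(self.unassigned_fraction), 6),
            "log_likelihood": float(self.params.log_likelihood),
        }
        return out


def _seed_stream(root_seed: int, k: int) -> int:
    """Named substream k of the root seed, kept below 2**31."""
    return int(np.random.SeedSequence([root_seed, k]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, out_dir) -> ReportBundle:
    """Execute the full chain deterministically and write all artifacts."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        log.info("stage %s at %.2fs", name, _time.perf_counter() - t0)

    t0 = _time.perf_counter()

    # 1. cohort ----------------------------------------------------------
    if config.generator is not None:
        cohort = simulate_cohort(config.generator, seed=_seed_stream(config.seed, 1))
        write_cohort(cohort, out / "cohort.csv")
    else:
        cohort = read_cohort(config.cohort_path)
    _stage("cohort")

    # 2. model scan / fit ------------------------------------------------
    ks = config.lca.k_range
    scan_table = None
    if len(ks) > 1:
        scan = lca.scan_models(
            cohort, ks,
            rules=lca.SelectionRules(
                use_bootstrap_lrt=config.lca.use_bootstrap_lrt,
                lrt_bootstrap=config.lca.lrt_bootstrap,
            ),
            seed=_seed_stream(config.seed, 2),
            n_restarts=config.lca.n_restarts,
            tol=config.lca.tol,
            max_iter=config.lca.max_iter,
        )
        scan_table = scan.table
        scan_table.to_csv(out / "scan.csv", index=False)
        if scan.selected_k is None:
            raise RuntimeError("model scan found no admissible class count")
        selected_k = scan.selected_k
        params = scan.fits[selected_k]
    else:
        selected_k = ks[0]
        params = lca.em_fit(
            cohort, selected_k,
            n_restarts=config.lca.n_restarts,
            tol=config.lca.tol,
            max_iter=config.lca.max_iter,
            seed=_seed_stream(config.seed, 2),
        )
        params, _ = lca.reorder_classes(params)
    _stage("fit")

    post = lca.posterior(params, cohort)
    assign = lca.assign_classes(post, cutoff=config.lca.cutoff)
    with open(out / "parameters.yaml", "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)
    assign.to_frame().to_csv(out / "assignment.csv", index=False)

    profile_rows = []
    for name, lv in params.levels.items():
        for k_idx, level in enumerate(lv):
            row = {"indicator": name, "level": level}
            for c in range(params.n_classes):
                row[f"class_{c + 1}_pct"] = round(
                    100 * float(params.item_response[name][c, k_idx]), 2
                )
            profile_rows.append(row)
    class_profile = pd.DataFrame(profile_rows)
    class_profile.to_csv(out / "class_profile.csv", index=False)
    modal_shares = {
        f"class_{c + 1}": float(np.mean(assign.labels == c + 1))
        for c in range(params.n_classes)
    }
    _stage("assign")

    # 3. survival --------------------------------------------------------
    t, e = cohort.time, cohort.event
    assigned = assign.labels != lca.UNASSIGNED
    label_str = np.array([f"class_{c}" for c in assign.labels])

    curves = []
    for lv in sorted(set(label_str[assigned])):
        m = assigned & (label_str == lv)
        cs = aalen_johansen(t[m], e[m])
        for cause, curve in cs.cif.items():
            df = curve.to_frame()
            df.insert(0, "cause", cause)
            df.insert(0, "group", lv)
            curves.append(df)
    pd.concat(curves, ignore_index=True).to_csv(out / "cif_curves.csv", index=False)

    msm = multi_state_model(t[assigned], e[assigned], label_str[assigned])
    hr_table = pd.concat([msm[1].table, msm[2].table], ignore_index=True)
    hr_table.to_csv(out / "hazard_ratios.csv", index=False)
    _stage("survival")

    # 4. CIF estimator comparison ---------------------------------------
    comparison_rows = []
    for cause in (1, 2):
        aj = aalen_johansen(t, e).cif[cause]
        naive = naive_cif(t, e, cause)
        mixture = class_mixture_cif(
            t, e, cause, label_str, min_stratum=config.adjustment.min_stratum
        )
        comparison_rows.append(
            {
                "cause": cause,
                "sup_naive_vs_aj": sup_distance(naive, aj),
                "sup_mixture_vs_aj": sup_distance(mixture, aj),
            }
        )
    cif_comparison = pd.DataFrame(comparison_rows)
    cif_comparison.to_csv(out / "cif_comparison.csv", index=False)
    _stage("cif-comparison")

    # 5. subtype adjustment ---------------------------------------------
    adj = None
    if cohort.has_subtype:
        frames = []
        for endpoint in config.adjustment.endpoints:
            flag = (e > 0) if endpoint == "overall" else (e == 1)
            rep = adjustment_report(
                t, flag, cohort.data["subtype"].to_numpy(), label_str
            )
            rep.insert(0, "endpoint", endpoint)
            frames.append(rep)
        adj = pd.concat(frames, ignore_index=True)
        adj.to_csv(out / "adjustment.csv", index=False)
    _stage("adjustment")

    bundle = ReportBundle(
        config=config,
        selected_k=selected_k,
        scan_table=scan_table,
        params=params,
        class_profile=class_profile,
        modal_shares=modal_shares,
        unassigned_fraction=assign.unassigned_fraction,
        hazard_ratios=hr_table,
        cif_comparison=cif_comparison,
        adjustment=adj,
    )
    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(bundle.summary_dict(), fh, sort_keys=True)
    return bundle
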