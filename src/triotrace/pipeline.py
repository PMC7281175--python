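"""End-to-end run: peak table → screen → differential → patterns → enrichment.

:func:`run_pipeline` wires the stages with one validated configuration and
writes per-stage CSVs plus a JSON run report carrying provenance (seed,
thresholds, package version, per-stage record counts). Deterministic for a
fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .differential import DemCriteria, call_dem, pairwise_compare
from .enrichment import builtin_pathways, enrich
from .patterns import build_trajectory, classify_table
from .preprocess import impute_missing, iqr_denoise, normalize_internal_standard
from .synthetic import SyntheticSpec, generate_peak_table
from .tables import read_table, write_results

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Validated configuration for a full pipeline run.

    Either ``table``/``design`` paths or ``synthetic`` (a SyntheticSpec or
    its keyword dict) must be given. Unknown keys in ``from_dict`` are
    rejected before anything runs.
    """

    table: str | None = None
    design: str | None = None
    synthetic: SyntheticSpec | dict | None = None
    groups: tuple[str, str, str] = ("W", "P", "T")
    alpha: float = 0.05
    quantile_cut: float = 0.0
    internal_standard_id: str | None = None
    impute: str = "half_min"
    test: str = "student"
    mode: str = "metabolite"
    run_enrichment: bool = True
    out_dir: str = "triotrace_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 <= self.quantile_cut < 1.0:
            raise ConfigError("quantile_cut must be in [0, 1)")
        if self.impute not in ("half_min", "none"):
            raise ConfigError(f"unknown impute method {self.impute!r}")
        if self.test not in ("student", "welch"):
            raise ConfigError(f"unknown test {self.test!r}")
        if self.mode not in ("metabolite", "gene"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if len(self.groups) != 3:
            raise ConfigError("groups must name exactly three labels")
        if self.table is None and self.synthetic is None:
            raise ConfigError("either table/design paths or synthetic must be set")
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticSpec(**{**self.synthetic, "seed": self.seed})

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "groups" in d:
            d = {**d, "groups": tuple(d["groups"])}
        return cls(**d)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run denoise → differential → pattern → enrichment and write outputs.

    Returns the run report (also written as ``report.json`` in the output
    directory): per-stage counts, parameters, and output file paths. Any
    stage failure aborts with the stage name prefixed to the cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "provenance": {
            "package": "triotrace",
            "version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "quantile_cut": config.quantile_cut,
            "test": config.test,
            "mode": config.mode,
            "groups": list(config.groups),
        },
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # annotate with the failing stage
                raise type(exc)(f"[stage {name}] {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return deco

    @stage("load")
    def table_and_truth():
        if config.synthetic is not None:
            return generate_peak_table(config.synthetic)
        table = read_table(config.table, kind="peak", design=config.design)
        return table, None

    table, truth = table_and_truth
    report["stages"]["load"] = {"n_analytes": len(table.analyte_ids), "n_samples": len(table.sample_ids)}

    @stage("preprocess")
    def preprocessed():
        t = impute_missing(table, method=config.impute)
        if config.internal_standard_id:
            t = normalize_internal_standard(t, config.internal_standard_id)
        t, denoise_report = iqr_denoise(t, quantile_cut=config.quantile_cut)
        return t, denoise_report

    clean, denoise_report = preprocessed
    report["stages"]["preprocess"] = {
        "n_input_peaks": denoise_report.n_input_peaks,
        "n_retained": denoise_report.n_retained,
        "threshold_used": denoise_report.threshold_used,
    }

    criteria = DemCriteria(alpha=config.alpha)
    g1, g2, g3 = config.groups
    pairs = [(g1, g2), (g2, g3), (g1, g3)]

    @stage("differential")
    def differential():
        per_pair = {
            pair: pairwise_compare(clean, *pair, criteria=criteria, test=config.test)
            for pair in pairs
        }
        dems = {
            pair: call_dem(res, criteria=criteria, mode=config.mode)
            for pair, res in per_pair.items()
        }
        return per_pair, dems

    per_pair, dems = differential
    dem_union = sorted({r.analyte_id for res in dems.values() for r in res})
    report["stages"]["differential"] = {
        f"dem_{a}_vs_{b}": len(dems[(a, b)]) for a, b in pairs
    }
    report["stages"]["differential"]["dem_union"] = len(dem_union)
    for (a, b), res in per_pair.items():
        write_results(res, out / f"pairwise_{a}_vs_{b}.csv")

    @stage("pattern")
    def pattern():
        profiles = []
        for i, analyte in enumerate(clean.analyte_ids):
            triple = [per_pair[pair][i] for pair in pairs]
            profiles.append(build_trajectory(triple, groups=config.groups))
        return classify_table(profiles)

    calls, counts = pattern
    report["stages"]["pattern"] = {
        "counts": {f"{cat}|{sub}" if sub else cat: n for (cat, sub), n in sorted(counts.items())}
    }
    write_results(calls, out / "pattern_calls.csv")
    if truth is not None:
        by_id = {c.analyte_id: c for c in calls}
        classified_truth = [t for t in truth if t.analyte_id in by_id]
        agree = sum(
            1 for t in classified_truth if by_id[t.analyte_id].category == t.category
        )
        report["stages"]["pattern"]["category_agreement_with_truth"] = (
            agree / len(classified_truth) if classified_truth else None
        )

    if config.run_enrichment:
        @stage("enrichment")
        def enrichment():
            hits = [c.analyte_id for c in calls if c.category != "unclassified"]
            universe = clean.analyte_ids
            return enrich(hits, universe, builtin_pathways())

        results = enrichment
        report["stages"]["enrichment"] = {
            "n_pathways": len(results),
            "top": results[0].pathway if results else None,
        }
        write_results(results, out / "enrichment.csv", allow_empty=True)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
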