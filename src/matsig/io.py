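"""File formats, pipeline configuration, and the end-to-end pipeline.

Tables are CSV (UTF-8, '.' decimal); models and configs are JSON.  The
pipeline executes simulate -> exclude -> means -> consistency -> signatures ->
correlations -> PCA -> genericity and writes every intermediate to the output
directory, together with a manifest naming the config hash and seeds, so two
runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import design as design_mod
from . import qc, signatures, structure, synth
from .design import StudyDesign, default_design, design_counts
from .synth import RATING_COLUMNS, GroundTruth, default_truth, simulate_ratings

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# rating-record CSV round trip

class RatingsFormatError(ValueError):
    pass


def write_ratings(records: pd.DataFrame, path) -> None:
    records[RATING_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_ratings(path, slider_min: float = 0.0, slider_max: float = 100.0) -> pd.DataFrame:
    """Read and validate a rating-record CSV.

    Malformed rows are rejected with their 1-based file line numbers; ratings
    outside the slider bounds and non-positive response times are errors.
    """
    df = pd.read_csv(path)
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise RatingsFormatError(f"{path}: missing columns {missing}")
    problems = []
    value = pd.to_numeric(df["value"], errors="coerce")
    rt = pd.to_numeric(df["response_time_s"], errors="coerce")
    rep = pd.to_numeric(df["repetition"], errors="coerce")
    bad_value = value.isna() | (value < slider_min) | (value > slider_max)
    bad_rt = rt.isna() | (rt <= 0)
    bad_rep = rep.isna() | (rep < 1) | (rep != rep.round())
    for name, mask in [("value outside slider bounds or non-numeric", bad_value),
                       ("non-positive or non-numeric response time", bad_rt),
                       ("invalid repetition index", bad_rep)]:
        for i in np.flatnonzero(mask.to_numpy())[:10]:
            problems.append(f"line {i + 2}: {name}")
    if problems:
        raise RatingsFormatError(f"{path}: " + "; ".join(problems))
    df["value"] = value
    df["response_time_s"] = rt
    df["repetition"] = rep.astype(int)
    df["set_id"] = df["set_id"].astype(int)
    return df[RATING_COLUMNS]


def write_truth(truth: GroundTruth, path) -> None:
    doc = {
        "mu": {"index": list(truth.mu.index), "columns": list(truth.mu.columns),
               "values": truth.mu.to_numpy().tolist()},
        "sigma_taste": truth.sigma_taste,
        "sigma_noise": truth.sigma_noise,
        "sigma_stim": truth.sigma_stim,
        "stim_cov": None if truth.stim_cov is None else np.asarray(truth.stim_cov).tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_truth(path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    mu = pd.DataFrame(doc["mu"]["values"], index=doc["mu"]["index"],
                      columns=doc["mu"]["columns"])
    cov = doc["stim_cov"]
    return GroundTruth(mu=mu, sigma_taste=doc["sigma_taste"], sigma_noise=doc["sigma_noise"],
                       sigma_stim=doc.get("sigma_stim", 0.0),
                       stim_cov=None if cov is None else np.asarray(cov))


# --------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """Everything needed to reproduce one end-to-end run."""

    design: StudyDesign = field(default_factory=default_design)
    seed_assignment: int = 1
    seed_simulation: int = 2
    seed_baseline: int = 3
    rt_exclusion_s: float = 1.0
    spammer_fraction: float = 0.05
    n_participants: int = 198
    pca_center: bool = True
    pca_scale: bool = True
    pca_components: int = 2
    baseline_reps: int = 10_000
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        for name in ("seed_assignment", "seed_simulation", "seed_baseline"):
            if int(getattr(self, name)) != getattr(self, name):
                raise ValueError(f"{name} must be an integer")
        if self.rt_exclusion_s <= 0:
            raise ValueError("rt_exclusion_s must be positive")

    def to_json(self) -> str:
        d = asdict(self)
        d["design"]["materials"] = list(d["design"]["materials"])
        d["design"]["attributes"] = list(d["design"]["attributes"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["design"] = StudyDesign(**d["design"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, truth: GroundTruth | None = None) -> dict:
    """Execute the full analysis and write all outputs under ``config.out_dir``.

    Returns a dict of the in-memory results keyed by stage name.  Any stage
    failure aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    des = config.design
    truth = truth or default_truth(des)
    results: dict = {"config": config}
    stage = "setup"
    try:
        stage = "simulate"
        logger.info("stage %s", stage)
        stimuli = design_mod.partition_sets(des, config.seed_assignment)
        records = simulate_ratings(des, truth, config.seed_simulation, stimuli=stimuli,
                                   spammer_fraction=config.spammer_fraction,
                                   n_participants=config.n_participants)
        stimuli.to_csv(out / "stimuli.csv", index=False)
        write_ratings(records, out / "ratings.csv")
        write_truth(truth, out / "truth.json")
        results.update(stimuli=stimuli, records=records, truth=truth)

        stage = "exclude"
        logger.info("stage %s", stage)
        kept, excluded = qc.exclude_fast_raters(records, config.rt_exclusion_s)
        excluded.to_csv(out / "excluded_tasks.csv", index=False)
        results.update(kept=kept, excluded=excluded)

        stage = "consistency"
        logger.info("stage %s", stage)
        consistency = qc.consistency_table(kept, des)
        consistency.to_csv(out / "consistency.csv", index=False, float_format="%.6f")
        results["consistency"] = consistency

        stage = "means"
        logger.info("stage %s", stage)
        means = signatures.stimulus_means(kept, des, stimuli=stimuli)
        means.to_csv(out / "means.csv", float_format="%.6f")
        results["means"] = means

        stage = "signatures"
        logger.info("stage %s", stage)
        sig = signatures.signature_table(means, des)
        sig.to_csv(out / "signatures.csv", float_format="%.6f")
        results["signatures"] = sig

        stage = "correlations"
        logger.info("stage %s", stage)
        corr = signatures.attribute_correlations(means)
        corr.r.to_csv(out / "attribute_correlations.csv", float_format="%.6f")
        corr.tiers.to_csv(out / "attribute_correlation_tiers.csv")
        results["correlations"] = corr

        stage = "pca"
        logger.info("stage %s", stage)
        global_pca = structure.fit_pca(means, k=config.pca_components,
                                       center=config.pca_center, scale=config.pca_scale)
        (out / "pca.json").write_text(json.dumps({
            "explained_variance_ratio": global_pca.explained_variance_ratio.tolist(),
            "loadings": {"index": list(global_pca.loadings.index),
                         "columns": list(global_pca.loadings.columns),
                         "values": global_pca.loadings.to_numpy().tolist()},
        }, indent=2))
        results["global_pca"] = global_pca

        stage = "genericity"
        logger.info("stage %s", stage)
        gen = structure.genericity_with_baseline(
            global_pca, means, n_reps=config.baseline_reps,
            seed=config.seed_baseline, k=config.pca_components)
        gen.to_csv(out / "genericity.csv", index=False, float_format="%.6f")
        results["genericity"] = gen

        stage = "manifest"
        manifest = {
            "config_hash": config.config_hash(),
            "seeds": {"assignment": config.seed_assignment,
                      "simulation": config.seed_simulation,
                      "baseline": config.seed_baseline},
            "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "config.json").write_text(config.to_json())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
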