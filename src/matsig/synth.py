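"""Synthetic crowdsourced rating generator.

Generates slider ratings (and response times) with the statistical structure
the downstream analysis assumes, standing in for unreleased crowdsourced data:

* a material x attribute mean matrix ``mu`` — the true material signature;
* a per-stimulus deviation around its material signature, drawn once per
  stimulus from a (generally anisotropic) attribute covariance, so that
  within-material variation shares the attribute correlation structure of the
  between-material variation — as real perceptual data do;
* a rater x stimulus "taste" term, fixed across repetitions, modelling stable
  idiosyncratic disagreement between raters;
* fresh repetition noise per trial;
* a small fraction of "spammer" tasks whose ratings are uniform noise and
  whose response times average well under one second.

A single integer seed expands into independent substreams keyed by purpose and
cell, so that e.g. adding raters to one cell does not perturb another cell's
records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StudyDesign, default_design, design_counts, partition_sets

# substream tags (arbitrary fixed constants)
_S_ASSIGN, _S_DELTA, _S_CELL = 11, 12, 13


@dataclass
class GroundTruth:
    """Generative parameters of the synthetic rating model, in rating units (0-100 scale).

    ``value = clip(mu[m(i), a] + delta[i, a] + gamma[o, i, a] + eps, lo, hi)``

    where ``delta`` is fixed per stimulus (drawn from ``stim_cov``), ``gamma``
    is fixed per rater x stimulus x attribute (SD ``sigma_taste``) and ``eps``
    is fresh per repetition (SD ``sigma_noise``).
    """

    mu: pd.DataFrame                     # materials x attributes
    sigma_taste: float
    sigma_noise: float
    stim_cov: np.ndarray | None = None   # attributes x attributes; None -> sigma_stim^2 * I
    sigma_stim: float = 0.0              # used only when stim_cov is None

    def __post_init__(self) -> None:
        if self.sigma_taste < 0 or self.sigma_noise < 0 or self.sigma_stim < 0:
            raise ValueError("standard deviations must be >= 0")
        if not np.isfinite(self.mu.to_numpy()).all():
            raise ValueError("mu entries must be finite")
        if self.stim_cov is not None:
            c = np.asarray(self.stim_cov, float)
            if c.shape != (self.mu.shape[1],) * 2:
                raise ValueError("stim_cov must be n_attributes x n_attributes")
            if np.any(np.diag(c) < 0):
                raise ValueError("stim_cov diagonal must be >= 0")
            self.stim_cov = c

    @property
    def stim_var(self) -> np.ndarray:
        """Per-attribute variance of the per-stimulus deviation."""
        if self.stim_cov is None:
            return np.full(self.mu.shape[1], self.sigma_stim**2)
        return np.diag(self.stim_cov).copy()

    def stim_cov_matrix(self) -> np.ndarray:
        if self.stim_cov is None:
            return np.eye(self.mu.shape[1]) * self.sigma_stim**2
        return self.stim_cov


@dataclass(frozen=True)
class RaterProfile:
    rater_id: str
    mean_rt: float
    is_spammer: bool = False

    def __post_init__(self) -> None:
        if self.mean_rt <= 0:
            raise ValueError("mean_rt must be positive")


#: CSV column order for rating records.
RATING_COLUMNS = [
    "rater_id", "stimulus_id", "attribute", "set_id",
    "repetition", "value", "response_time_s",
]


def _solve_noise_sds(S: float, intra: float, inter: float, reps: int) -> tuple[float, float]:
    """Invert the consistency formulas for (sigma_taste, sigma_noise) given signal variance S."""
    tot = S / (inter * (1.0 + (1.0 - intra) / (intra * reps)))  # = S + sigma_taste^2
    taste2 = tot - S
    noise2 = (1.0 - intra) / intra * tot
    if taste2 < -1e-9 or noise2 < 0:
        raise ValueError("consistency targets unattainable for this signal variance")
    return math.sqrt(max(taste2, 0.0)), math.sqrt(noise2)


def default_truth(
    design: StudyDesign | None = None,
    intra_target: float = 0.76,
    inter_target: float = 0.48,
) -> GroundTruth:
    """Ground truth calibrated so the expected intra/inter-observer correlations
    match the targets (defaults 0.76 / 0.48).

    The signature matrix ``mu`` is built once, deterministically, from a
    3-dimensional latent attribute structure (materials differ along a few
    correlated attribute axes, e.g. hard materials rate low on bendable), plus
    small unstructured variation, centred at 50 on the slider.  Per-stimulus
    deviations share the same low-rank attribute covariance, blended with an
    isotropic component.  Noise SDs are then solved analytically from the
    consistency formulas of :func:`expected_consistency`.
    """
    design = design or default_design()
    rng = np.random.default_rng(np.random.SeedSequence(20200707))
    n_m, n_a = design.n_materials, design.n_attributes

    # latent structure: material scores (n_m x 3) and attribute loadings (3 x n_a)
    L = rng.standard_normal((n_m, 3))
    F = rng.standard_normal((3, n_a))
    F /= np.linalg.norm(F, axis=1, keepdims=True)
    mu_arr = 50.0 + 15.0 * (L @ F) + 4.0 * rng.standard_normal((n_m, n_a))
    mu_arr = np.clip(mu_arr, 12.0, 88.0)
    mu = pd.DataFrame(mu_arr, index=list(design.materials), columns=list(design.attributes))

    # per-stimulus deviation covariance: 60% along the latent axes, 40% isotropic
    s2 = 9.0**2
    C = F.T @ F
    C *= n_a / np.trace(C)
    stim_cov = s2 * (0.6 * C + 0.4 * np.eye(n_a))

    # per-attribute signal variance: between-material + per-stimulus deviation
    S_a = mu_arr.var(axis=0, ddof=0) + np.diag(stim_cov)
    sigma_taste, sigma_noise = _calibrate_noise(
        S_a, intra_target, inter_target, design.repetitions)
    return GroundTruth(mu=mu, sigma_taste=sigma_taste, sigma_noise=sigma_noise, stim_cov=stim_cov)


def _calibrate_noise(S_a: np.ndarray, intra: float, inter: float, reps: int
                     ) -> tuple[float, float]:
    """Solve (sigma_taste, sigma_noise) so the attribute-averaged consistency
    ratios hit the targets exactly."""
    from scipy import optimize

    t0, n0 = _solve_noise_sds(float(np.mean(S_a)), intra, inter, reps)

    def eqs(x):
        T, N = np.exp(x)
        return [np.mean((S_a + T) / (S_a + T + N)) - intra,
                np.mean(S_a / (S_a + T + N / reps)) - inter]

    sol = optimize.root(eqs, np.log([t0**2, n0**2]), method="hybr")
    if not sol.success:
        raise ValueError(f"consistency calibration failed: {sol.message}")
    T, N = np.exp(sol.x)
    return math.sqrt(T), math.sqrt(N)


def expected_consistency(truth: GroundTruth, design: StudyDesign) -> tuple[float, float]:
    """Analytic (clip-free) intra- and inter-observer correlations implied by the truth.

    With per-attribute signal variance ``S_a = Var_materials(mu[:, a]) + stim_var_a``,
    taste variance ``T`` and repetition-noise variance ``N``:

    * intra_r (between two repetitions of one rater)          = (S+T) / (S+T+N)
    * inter_r (between two raters' repetition-averaged means) = S / (S+T+N/R)

    averaged over attributes.  Undefined (raises) when every S_a is zero.
    """
    mu = truth.mu.to_numpy()
    S_a = mu.var(axis=0, ddof=0) + truth.stim_var
    if np.all(S_a == 0):
        raise ValueError("signal variance is zero; correlations undefined")
    T = truth.sigma_taste**2
    N = truth.sigma_noise**2
    R = design.repetitions
    intra = float(np.mean((S_a + T) / (S_a + T + N)))
    inter = float(np.mean(S_a / (S_a + T + N / R)))
    return intra, inter


def fisher_yates(items: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Classic Fisher-Yates shuffle (explicit, as used to order trials)."""
    out = np.array(items, copy=True)
    for i in range(len(out) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        out[i], out[j] = out[j], out[i]
    return out


def trial_order(set_stimuli, repetitions: int, seed) -> list:
    """Trial sequence for one task: ``repetitions`` concatenated Fisher-Yates
    permutations of the set, so no stimulus repeats within a block.

    ``seed`` may be an int or a Generator.  90 stimuli x 3 repetitions -> 270 trials.
    """
    stimuli = list(set_stimuli)
    if not stimuli:
        raise ValueError("set_stimuli must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order: list = []
    idx = np.arange(len(stimuli))
    for _ in range(repetitions):
        perm = fisher_yates(idx, rng)
        order.extend(stimuli[i] for i in perm)
    return order


def _lognormal(rng: np.random.Generator, mean: float, sigma_log: float, size: int) -> np.ndarray:
    mu_log = math.log(mean) - sigma_log**2 / 2.0
    return rng.lognormal(mu_log, sigma_log, size)


def simulate_ratings(
    design: StudyDesign,
    truth: GroundTruth,
    seed: int,
    stimuli: pd.DataFrame | None = None,
    spammer_fraction: float = 0.05,
    n_participants: int = 198,
    honest_rt_mean: float = 2.5,
    spammer_rt_mean: float = 0.5,
    rt_sigma_log: float = 0.35,
) -> pd.DataFrame:
    """Simulate the full experiment; returns one row per judgment.

    Produces exactly ``design_counts(design).total_judgments`` records.  Honest
    raters follow the additive model of :class:`GroundTruth`, clipped to the
    slider bounds; spammer tasks emit uniform ratings with sub-second mean
    response times.  Deterministic given ``seed``; each set x attribute cell
    uses its own substream.

    Parameters beyond the design and truth set the observation layer: the
    participant pool size (default 198, giving ~2.5 tasks per participant at
    500 tasks), the fraction of spammer tasks, and lognormal response-time
    means for honest (2.5 s) and spammer (0.5 s) raters.
    """
    if truth.mu.shape != (design.n_materials, design.n_attributes):
        raise ValueError("truth.mu shape does not match design")
    if not 0 <= spammer_fraction <= 1:
        raise ValueError("spammer_fraction must be in [0, 1]")
    seed = int(seed)

    if stimuli is None:
        stimuli = partition_sets(design, np.random.default_rng(
            np.random.SeedSequence([seed, _S_ASSIGN])).integers(2**31))
    stimuli = stimuli.sort_values("stimulus_id", kind="stable").reset_index(drop=True)
    sid = stimuli["stimulus_id"].to_numpy()
    sid_index = pd.Series(np.arange(len(sid)), index=sid)

    # per-stimulus deviation delta[i, a], one draw per stimulus from stim_cov
    rng_delta = np.random.default_rng(np.random.SeedSequence([seed, _S_DELTA]))
    cov = truth.stim_cov_matrix()
    # eigh-based square root: robust for rank-deficient covariances
    w, V = np.linalg.eigh(cov)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    delta = rng_delta.standard_normal((len(sid), design.n_attributes)) @ root.T

    mu_lookup = truth.mu.to_numpy()
    mat_idx = np.array([list(design.materials).index(m) for m in stimuli["material"]])

    pad = len(str(n_participants))
    lo, hi = design.slider_min, design.slider_max
    frames = []
    cell_idx = 0
    for set_id in range(1, design.n_sets + 1):
        in_set = stimuli["set_id"].to_numpy() == set_id
        set_sids = sid[in_set]
        set_rows = sid_index[set_sids].to_numpy()
        for a_i, attr in enumerate(design.attributes):
            cell_rng = np.random.default_rng(np.random.SeedSequence([seed, _S_CELL, cell_idx]))
            raters = cell_rng.choice(n_participants, size=design.raters_per_cell, replace=False)
            base = mu_lookup[mat_idx[set_rows], a_i] + delta[set_rows, a_i]
            for slot in range(design.raters_per_cell):
                r_rng = np.random.default_rng(
                    np.random.SeedSequence([seed, _S_CELL, cell_idx, slot]))
                rater_id = f"P{raters[slot]:0{pad}d}"
                is_spammer = r_rng.random() < spammer_fraction
                order = trial_order(np.arange(len(set_sids)), design.repetitions, r_rng)
                order = np.asarray(order)
                n_trials = len(order)
                if is_spammer:
                    values = r_rng.uniform(lo, hi, n_trials)
                    rts = _lognormal(r_rng, spammer_rt_mean, rt_sigma_log, n_trials)
                else:
                    gamma = r_rng.normal(0.0, truth.sigma_taste, len(set_sids))
                    eps = r_rng.normal(0.0, truth.sigma_noise, n_trials)
                    values = np.clip(base[order] + gamma[order] + eps, lo, hi)
                    rts = _lognormal(r_rng, honest_rt_mean, rt_sigma_log, n_trials)
                reps = np.repeat(np.arange(1, design.repetitions + 1), len(set_sids))
                frames.append(pd.DataFrame({
                    "rater_id": rater_id,
                    "stimulus_id": set_sids[order],
                    "attribute": attr,
                    "set_id": set_id,
                    "repetition": reps,
                    "value": values,
                    "response_time_s": rts,
                }))
            cell_idx += 1
    records = pd.concat(frames, ignore_index=True)
    assert len(records) == design_counts(design).total_judgments
    return records[RATING_COLUMNS]
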