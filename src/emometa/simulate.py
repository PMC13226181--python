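"""Generative simulator for rating and forced-choice emotion experiments.

The simulator produces trial tables with the statistical structure the
analysis pipeline assumes, with separately controllable first-order
(perceptual/report) and second-order (metacognitive) noise, so the whole
pipeline can be exercised and parameter-recovery studies run without any
collected data.

Rating design
-------------
Each stimulus has a latent normative mean mu_s per dimension (uniform on
[10, 90] unless supplied). A participant's internal evidence on a trial is
``e = mu_s + b_p + eps`` with a stable participant bias ``b_p ~ N(0, sigma_b)``
and first-order noise ``eps ~ N(0, sigma_1)``; the reported rating is ``e``
clipped to [0, 100] and rounded. The others-estimate is ``mu_s + N(0,
sigma_o)``, likewise clipped/rounded. Confidence tracks the quantity the
accuracy rule actually scores: the trial's rating-norm difference, read
through metacognitive noise ``N(0, sigma_m)``, compared against the
participant's running mean difference. Small sigma_m means confidence is a
near-deterministic function of how deviant the trial is (high AUROC2); large
sigma_m decouples confidence from accuracy (AUROC2 -> 0.5).

Forced-choice design
--------------------
Standard equal-variance SDT: class means +/- d_true/2, unit variance,
response by sign of the decision variable against criterion 0; confidence is
``|x|`` corrupted by ``N(0, sigma_m)`` and mapped affinely into 1..100.

All randomness flows from a single seed through per-participant child
streams (``numpy.random.SeedSequence.spawn``), so tables are reproducible
bit-for-bit and participant-level generation order cannot leak across
participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import category_label, validate_stimulus_meta, validate_trials

__all__ = ["SimConfig", "simulate_rating_experiment", "simulate_2afc_experiment"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the designs the analysis targets: 60 stimuli (15 per
    valence x arousal quadrant) and a mid-fifties sample for one session of
    the rating task. Noise SDs are on the 0-100 rating scale; ``d_true`` is
    on the usual SDT evidence scale.
    """

    n_stimuli: int = 60
    n_participants: int = 55
    sessions: int = 1
    seed: int = 0
    #: stimulus normative means per dimension; drawn uniform [10, 90] if None
    mu_valence: np.ndarray | None = field(default=None, repr=False)
    mu_arousal: np.ndarray | None = field(default=None, repr=False)
    sigma_b: float = 10.0  # participant bias SD (rating points)
    sigma_1: float = 12.0  # first-order report noise SD (rating points)
    sigma_o: float = 10.0  # others-estimate noise SD (rating points)
    sigma_m: float = 10.0  # metacognitive (second-order) noise SD
    #: across-participant SD of the per-participant metacognitive noise
    sigma_m_spread: float = 0.0
    d_true: float = 1.5  # 2AFC type-1 sensitivity

    def __post_init__(self) -> None:
        for name in ("sigma_b", "sigma_1", "sigma_o", "sigma_m", "sigma_m_spread"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_stimuli < 2 or self.n_participants < 1:
            raise ValueError("need >= 2 stimuli and >= 1 participant")
        if self.sessions not in (1, 2):
            raise ValueError("sessions must be 1 or 2")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")


def _participant_rngs(cfg: SimConfig) -> tuple[np.random.Generator, list]:
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(cfg.n_participants + 1)
    return np.random.default_rng(streams[0]), [
        np.random.default_rng(s) for s in streams[1:]
    ]


def _affine_to_scale(z: np.ndarray, lo: int = 1, hi: int = 100) -> np.ndarray:
    """Affinely map a vector onto [lo, hi] (midpoint if degenerate), rounded."""
    zmin, zmax = float(np.min(z)), float(np.max(z))
    if zmax - zmin < 1e-12:
        return np.full(z.shape, (lo + hi) // 2, dtype=int)
    scaled = lo + (hi - lo) * (z - zmin) / (zmax - zmin)
    return np.round(scaled).astype(int)


def _clip_round(x: np.ndarray) -> np.ndarray:
    return np.round(np.clip(x, 0, 100)).astype(int)


def _stimulus_ids(n: int) -> list[str]:
    return [f"s{i + 1:03d}" for i in range(n)]


def simulate_rating_experiment(cfg: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a slider-rating experiment.

    Returns the trial table (valid under the ``rating`` schema) and a hidden
    truth record: stimulus means, participant biases and per-participant
    metacognitive noise, and per-trial latent evidence.
    """
    stim_rng, prngs = _participant_rngs(cfg)
    stim_ids = _stimulus_ids(cfg.n_stimuli)
    mu = {}
    for dim, supplied in (("valence", cfg.mu_valence), ("arousal", cfg.mu_arousal)):
        if supplied is not None:
            arr = np.asarray(supplied, dtype=float)
            if arr.shape != (cfg.n_stimuli,):
                raise ValueError(f"mu_{dim} must have length n_stimuli")
            mu[dim] = arr
        else:
            mu[dim] = stim_rng.uniform(10, 90, cfg.n_stimuli)

    rows: list[dict] = []
    truth_trials: list[dict] = []
    bias: dict[str, dict[str, float]] = {}
    sigma_m_p: dict[str, float] = {}
    n_clipped = 0
    for p, rng in enumerate(prngs):
        pid = f"p{p + 1:03d}"
        b = {dim: rng.normal(0.0, cfg.sigma_b) for dim in ("valence", "arousal")}
        bias[pid] = b
        sm = max(0.0, rng.normal(cfg.sigma_m, cfg.sigma_m_spread))
        sigma_m_p[pid] = sm
        for session in range(1, cfg.sessions + 1):
            per_dim = {}
            for dim in ("valence", "arousal"):
                e = mu[dim] + b[dim] + rng.normal(0.0, cfg.sigma_1, cfg.n_stimuli)
                rating = _clip_round(e)
                n_clipped += int(np.sum((e < 0) | (e > 100)))
                others = _clip_round(
                    mu[dim] + rng.normal(0.0, cfg.sigma_o, cfg.n_stimuli)
                )
                # metacognitive readout of the rating-norm difference vs. the
                # participant's running mean difference
                d_noisy = (rating - mu[dim]) + rng.normal(0.0, sm, cfg.n_stimuli)
                running_mean = np.cumsum(d_noisy) / np.arange(1, cfg.n_stimuli + 1)
                conf = _affine_to_scale(-np.abs(d_noisy - running_mean))
                per_dim[dim] = (rating, others, conf, e)
            fam = _clip_round(rng.normal(70.0, 20.0, cfg.n_stimuli))
            for i, sid in enumerate(stim_ids):
                rows.append(
                    {
                        "participant_id": pid,
                        "session": session,
                        "stimulus_id": sid,
                        "valence": per_dim["valence"][0][i],
                        "arousal": per_dim["arousal"][0][i],
                        "valence_confidence": per_dim["valence"][2][i],
                        "arousal_confidence": per_dim["arousal"][2][i],
                        "others_valence": per_dim["valence"][1][i],
                        "others_arousal": per_dim["arousal"][1][i],
                        "familiarity": fam[i],
                    }
                )
                truth_trials.append(
                    {
                        "participant_id": pid,
                        "session": session,
                        "stimulus_id": sid,
                        "evidence_valence": float(per_dim["valence"][3][i]),
                        "evidence_arousal": float(per_dim["arousal"][3][i]),
                    }
                )
    trials = pd.DataFrame(rows)
    validate_trials(trials, "rating")
    truth = {
        "mu_valence": mu["valence"].tolist(),
        "mu_arousal": mu["arousal"].tolist(),
        "stimulus_ids": stim_ids,
        "participant_bias": bias,
        "participant_sigma_m": sigma_m_p,
        "n_clipped": n_clipped,
        "trials": truth_trials,
    }
    return trials, truth


def _balanced_meta(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Stimulus metadata balanced over the four valence x arousal quadrants."""
    if cfg.n_stimuli % 4:
        raise ValueError("2AFC design needs n_stimuli divisible by 4")
    per = cfg.n_stimuli // 4
    rows = []
    quadrants = [("high", "high"), ("high", "low"), ("low", "low"), ("low", "high")]
    ids = _stimulus_ids(cfg.n_stimuli)
    i = 0
    for vclass, aclass in quadrants:
        for _ in range(per):
            dbv = rng.uniform(5.5, 8.5) if vclass == "high" else rng.uniform(1.5, 4.5)
            dba = rng.uniform(5.5, 8.5) if aclass == "high" else rng.uniform(1.5, 4.5)
            rows.append(
                {
                    "stimulus_id": ids[i],
                    "database": "IAPS",
                    "db_valence": round(dbv, 2),
                    "db_arousal": round(dba, 2),
                    "valence_class": vclass,
                    "arousal_class": aclass,
                    "category": category_label(vclass, aclass),
                }
            )
            i += 1
    meta = pd.DataFrame(rows)
    validate_stimulus_meta(meta)
    return meta


def simulate_2afc_experiment(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a forced-choice experiment with balanced stimulus categories.

    Returns the trial table (valid under the ``afc`` schema), the stimulus
    metadata, and the hidden truth (per-trial decision variables,
    per-participant metacognitive noise).
    """
    if cfg.d_true <= 0:
        raise ValueError("d_true must be > 0 for the forced-choice design")
    stim_rng, prngs = _participant_rngs(cfg)
    meta = _balanced_meta(cfg, stim_rng)
    high = {
        dim: (meta[f"{dim}_class"] == "high").to_numpy()
        for dim in ("valence", "arousal")
    }
    high_label = {"valence": "pleasant", "arousal": "high"}
    low_label = {"valence": "unpleasant", "arousal": "low"}

    rows: list[dict] = []
    truth_trials: list[dict] = []
    sigma_m_p: dict[str, float] = {}
    for p, rng in enumerate(prngs):
        pid = f"p{p + 1:03d}"
        sm = max(0.0, rng.normal(cfg.sigma_m, cfg.sigma_m_spread))
        sigma_m_p[pid] = sm
        for session in range(1, cfg.sessions + 1):
            per_dim = {}
            for dim in ("valence", "arousal"):
                mu = np.where(high[dim], cfg.d_true / 2.0, -cfg.d_true / 2.0)
                x = mu + rng.normal(0.0, 1.0, cfg.n_stimuli)
                resp = np.where(x > 0, high_label[dim], low_label[dim])
                conf = _affine_to_scale(
                    np.abs(x) + rng.normal(0.0, sm, cfg.n_stimuli)
                )
                per_dim[dim] = (resp, conf, x)
            fam = _clip_round(rng.normal(70.0, 20.0, cfg.n_stimuli))
            for i, sid in enumerate(meta["stimulus_id"]):
                rows.append(
                    {
                        "participant_id": pid,
                        "session": session,
                        "stimulus_id": sid,
                        "valence_response": per_dim["valence"][0][i],
                        "arousal_response": per_dim["arousal"][0][i],
                        "valence_confidence": per_dim["valence"][1][i],
                        "arousal_confidence": per_dim["arousal"][1][i],
                        "familiarity": fam[i],
                    }
                )
                truth_trials.append(
                    {
                        "participant_id": pid,
                        "session": session,
                        "stimulus_id": sid,
                        "x_valence": float(per_dim["valence"][2][i]),
                        "x_arousal": float(per_dim["arousal"][2][i]),
                    }
                )
    trials = pd.DataFrame(rows)
    validate_trials(trials, "afc")
    truth = {
        "d_true": cfg.d_true,
        "participant_sigma_m": sigma_m_p,
        "trials": truth_trials,
    }
    return trials, meta, truth


def with_sigma_m(cfg: SimConfig, sigma_m: float) -> SimConfig:
    """Copy of the config at a different metacognitive-noise level."""
    return replace(cfg, sigma_m=sigma_m)
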