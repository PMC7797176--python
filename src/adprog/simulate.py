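"""Synthetic ADNI-like longitudinal cohorts.

Each subject follows a latent disease stage z(t) = logistic((t - onset)/rate)
that is monotone in time.  The 22 continuous markers are affine links of the
stage (anchored so that z = 0.5 maps to the population mean and the stage
swing spans roughly +/- one population SD, with the clinical direction of
each marker), plus a per-subject random intercept and visit-level Gaussian
noise.  Diagnosis arises from thresholding a noisy copy of the stage with
hysteresis, so NC -> MCI -> AD transitions dominate and reversions are rare.
Visits are spaced ~6 months apart with jitter; missingness is independent
Bernoulli per feature per visit with ADNI-like observed fractions (an
optional "block" mode drops whole modalities per visit instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, SubjectTrajectory, trajectory_from_visits
from .schema import DEFAULT_SCHEMA, DX_LABELS, FeatureSchema

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_subject",
    "simulate_cohort",
    "simulate_lss_sequences",
]

# modality blocks for the structural ("block") missingness mode
_BLOCKS = {
    "cognitive": ["CDRSB", "ADAS11", "ADAS13", "MMSE", "RAVLT_immediate",
                  "RAVLT_learning", "RAVLT_forgetting", "RAVLT_perc_forgetting",
                  "FAQ"],
    "moca": ["MOCA"],
    "mri": ["Ventricles", "Hippocampus", "WholeBrain", "Entorhinal",
            "Fusiform", "MidTemp", "ICV"],
    "av45": ["AV45"],
    "fdg": ["FDG"],
    "csf": ["ABETA", "TAU", "PTAU"],
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulated cohort.

    Defaults emulate the ADNI/TADPOLE cohort structure: ~7.3 +/- 4.0 visits
    per subject at ~6-month spacing with +/-2-month jitter, per-feature
    observed fractions from the marker table, and mostly-forward diagnosis
    transitions.  All randomness is driven by ``seed``.
    """

    n_subjects: int = 100
    seed: int = 0
    visit_interval_mean: float = 6.0
    visit_interval_jitter: float = 2.0  # uniform +/- jitter around the mean
    n_visits_mean: float = 7.3
    n_visits_sd: float = 4.0
    n_visits_max: int = 24
    # marker model
    stage_amplitude: float = 1.0  # SD units spanned by the stage swing
    subject_intercept_sd: float = 0.4  # SD units, per-subject marker offset
    noise_sd: float = 0.25  # visit-level noise, SD units
    dx_noise_sd: float = 0.15  # noise on the thresholded stage copy
    # stage dynamics (months)
    onset_mean: float = -25.0  # baseline disease time skews pre-onset (more NC)
    onset_sd: float = 45.0  # spread of baseline disease time across subjects
    rate_log_mean: float = np.log(0.022)  # stage slope ~ 0.022 logits/month
    rate_log_sd: float = 0.45
    # diagnosis thresholds on z in (0,1), with hysteresis against reversion
    dx_thresholds: tuple[float, float] = (0.35, 0.65)
    dx_hysteresis: float = 0.08
    # missingness
    missing_rates: dict[str, float] | None = None  # observed fraction overrides
    block_missing: bool = False
    resolution: int = 1
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def observed_fracs(self) -> np.ndarray:
        fracs = self.schema.observed_fracs.copy()
        if self.missing_rates:
            for name, frac in self.missing_rates.items():
                if not 0 < frac <= 1:
                    raise ValueError(f"observed fraction for {name!r} must be in (0,1]")
                fracs[self.schema.feature_index(name)] = frac
        return fracs


@dataclass
class GroundTruth:
    """Complete pre-missingness record kept alongside each simulated subject."""

    subject_id: str
    visit_months: np.ndarray  # (V,)
    stage: np.ndarray  # (V,) latent z in (0,1), nondecreasing
    full_values: np.ndarray  # (V, 25) noise-included, missingness-free
    dx_sequence: list[str]
    onset: float
    rate: float


from functools import lru_cache


@lru_cache(maxsize=32)
def _visit_count_loc(target_mean: float, sd: float, vmax: int) -> float:
    """Location of the truncated normal whose [1, vmax]-truncated mean equals
    ``target_mean`` (truncation at 1 visit would otherwise inflate the mean)."""
    from scipy.stats import truncnorm

    loc = target_mean
    for _ in range(25):
        a, b = (0.5 - loc) / sd, (vmax + 0.5 - loc) / sd
        loc -= truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean
    return loc


def _n_visits(cfg: SimConfig, rng: np.random.Generator) -> int:
    # rejection-sampled rounded normal, truncated to [1, n_visits_max];
    # the location is offset so the truncated mean matches n_visits_mean
    loc = _visit_count_loc(cfg.n_visits_mean, cfg.n_visits_sd, cfg.n_visits_max)
    while True:
        v = int(round(rng.normal(loc, cfg.n_visits_sd)))
        if 1 <= v <= cfg.n_visits_max:
            return v


def _dx_from_stage(z_noisy: np.ndarray, cfg: SimConfig) -> list[str]:
    lo, hi = cfg.dx_thresholds
    h = cfg.dx_hysteresis
    state = 0
    out = []
    for z in z_noisy:
        if state == 0:
            if z >= hi:
                state = 2
            elif z >= lo:
                state = 1
        elif state == 1:
            if z >= hi:
                state = 2
            elif z < lo - h:
                state = 0
        else:  # AD
            if z < hi - h:
                state = 1
        out.append(DX_LABELS[state])
    return out


def simulate_subject(
    cfg: SimConfig, rng: np.random.Generator, subject_id: str
) -> tuple[SubjectTrajectory, GroundTruth]:
    """Draw one subject's visits, markers, diagnoses and missingness."""
    schema = cfg.schema
    V = _n_visits(cfg, rng)
    intervals = cfg.visit_interval_mean + rng.uniform(
        -cfg.visit_interval_jitter, cfg.visit_interval_jitter, size=max(V - 1, 0)
    )
    months = np.concatenate([[0.0], np.cumsum(intervals)])

    onset = rng.normal(cfg.onset_mean, cfg.onset_sd)
    rate = float(np.exp(rng.normal(cfg.rate_log_mean, cfg.rate_log_sd)))
    logits = (months - (-onset)) * rate  # baseline disease time = onset
    z = 1.0 / (1.0 + np.exp(-logits))  # monotone in t since rate > 0

    dirs = schema.directions.astype(float)
    means, sds = schema.means, schema.sds
    intercept = rng.normal(0.0, cfg.subject_intercept_sd, size=schema.n_continuous)
    noise = rng.normal(0.0, cfg.noise_sd, size=(V, schema.n_continuous))
    # affine-in-logistic link: z=0.5 anchors the population mean
    swing = cfg.stage_amplitude * (2.0 * z[:, None] - 1.0) * dirs[None, :]
    cont = means[None, :] + sds[None, :] * (swing + intercept[None, :] + noise)

    z_noisy = z + rng.normal(0.0, cfg.dx_noise_sd, size=V)
    dx_seq = _dx_from_stage(z_noisy, cfg)

    full = np.zeros((V, schema.n_values))
    for t, label in enumerate(dx_seq):
        full[t, DX_LABELS.index(label)] = 1.0
    full[:, 3:] = cont

    fracs = cfg.observed_fracs()
    if cfg.block_missing:
        observed = np.zeros((V, schema.n_features), dtype=bool)
        observed[:, 0] = rng.random(V) < fracs[0]
        for members in _BLOCKS.values():
            idx = [schema.feature_index(m) for m in members]
            block_rate = float(np.mean(fracs[idx]))
            keep = rng.random(V) < block_rate
            for i in idx:
                observed[:, i] = keep
    else:
        observed = rng.random((V, schema.n_features)) < fracs[None, :]
    # rows with nothing observed would be dropped by the reader; keep at
    # least the diagnosis of the first visit so every subject survives
    if not observed.any():
        observed[0, 0] = True

    values = np.full_like(full, np.nan)
    values[:, :3] = np.where(observed[:, [0]], full[:, :3], np.nan)
    values[:, 3:] = np.where(observed[:, 1:], full[:, 3:], np.nan)

    keep_rows = observed.any(axis=1)
    traj = trajectory_from_visits(
        subject_id, months[keep_rows], values[keep_rows], observed[keep_rows],
        cfg.resolution,
    )
    truth = GroundTruth(
        subject_id=subject_id,
        visit_months=months,
        stage=z,
        full_values=full,
        dx_sequence=dx_seq,
        onset=onset,
        rate=rate,
    )
    return traj, truth


def simulate_cohort(cfg: SimConfig) -> tuple[Cohort, list[GroundTruth]]:
    """Simulate ``cfg.n_subjects`` independent subjects from seed substreams."""
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    subjects, truths = [], []
    width = max(4, len(str(max(cfg.n_subjects - 1, 1))))
    for i, ss in enumerate(streams):
        sid = f"S{i:0{width}d}"
        traj, truth = simulate_subject(cfg, np.random.default_rng(ss), sid)
        subjects.append(traj)
        truths.append(truth)
    return Cohort(subjects, schema=cfg.schema), truths


def simulate_lss_sequences(
    seed: int = 0,
    d: int = 6,
    n_cont: int = 22,
    T: int = 15,
    n_subjects: int = 60,
) -> Cohort:
    """Noiseless sequences from a known stable linear state-space system.

    Used as a recovery oracle: a linear forecaster trained on these
    sequences should drive its one-step-ahead error toward zero.  The
    diagnosis channel is never observed, so only the continuous dynamics
    matter; the transition matrix is scaled to spectral norm 0.85 and the
    output gain kept small so trajectories stay bounded.
    """
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(d, d))
    A *= 0.85 / np.linalg.norm(A, 2)
    B = 0.2 * rng.normal(size=(d, 3 + n_cont))
    Wg = 0.25 * rng.normal(size=(n_cont, d))
    bg = 0.1 * rng.normal(size=n_cont)
    subs = []
    for i in range(n_subjects):
        h = np.zeros(d)
        x = np.zeros((T, 3 + n_cont))
        x[0, 3:] = rng.normal(size=n_cont)
        for t in range(T - 1):
            h = A @ h + B @ x[t]
            x[t + 1, 3:] = Wg @ h + bg
        obs = np.zeros((T, 1 + n_cont), dtype=bool)
        obs[:, 1:] = True
        subs.append(SubjectTrajectory(
            subject_id=f"S{i:03d}",
            grid_months=np.arange(T),
            values=x.copy(),
            observed=obs,
            visit_months=np.arange(T, dtype=float),
            visit_values=x.copy(),
            visit_observed=obs.copy(),
            resolution=1,
        ))
    return Cohort(subs)
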