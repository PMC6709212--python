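"""Synthetic behavioral and BOLD data with known ground truth.

The behavioral generator draws participants from the same hierarchy the
model assumes: participant-level coefficients are normal around group means,
choices are Bernoulli through the logistic model, and response times are
gamma with mean alpha0 + alpha1 * d.  Default group parameters reproduce the
study conditions: 108 trials per participant over three counterbalanced risk
levels, rewards uniform on the $0.05-$0.95 cent grid, strong reward seeking
and risk aversion (group means near beta1 = -1.9, beta2 = -4.2,
beta3 = 10.7), and a conflict-RT slope implying a 0.456 s mean RT increase
at maximal conflict.  Responses slower than the 3.5 s window are censored to
missing (choice and RT together), mirroring the task's response cutoff.

The BOLD generator builds voxel time series as a linear model on HRF-
convolved task regressors plus AR(1)-correlated noise, with disjoint
"deliberation-only" voxels (duration-scaled signal only) and
"conflict-sensitive" voxels (amplitude additionally scaled by d) so that the
variable- versus fixed-epoch dissociation can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design as fmri_design
from .model import conflict, likelihood_of_take
from .task import generate_design

__all__ = [
    "GroupParameters",
    "simulate_participants",
    "simulate_bold",
    "SyntheticBold",
    "make_ground_truth_masks",
    "simulate_conflict_study",
    "write_behavior",
    "read_behavior",
    "events_from_bids",
]

RESPONSE_WINDOW = 3.5  # s


@dataclass
class GroupParameters:
    """Group-level generating parameters of the behavioral hierarchy.

    ``beta_G``: (intercept, 50%-risk, 90%-risk, reward) group means on the
    logit scale.  ``alpha1_G`` is seconds per unit of d on the raw
    d in [0, 0.25] scale; the default 1.824 implies a 0.456 s mean-RT
    increase at maximal conflict.  ``k_shape`` sets the typical gamma shape
    (RT coefficient of variation 1/sqrt(k)).
    """

    beta_G: tuple = (1.0, -1.922, -4.180, 10.652)
    beta_sd: tuple = (1.5, 1.0, 1.2, 2.5)
    alpha0_G: float = 1.0
    alpha1_G: float = 1.824
    alpha_sd: tuple = (0.2, 0.4)
    k_shape: float = 20.0
    k_log_sd: float = 0.3

    def __post_init__(self):
        if any(s <= 0 for s in (*self.beta_sd, *self.alpha_sd)):
            raise ValueError("group SDs must be positive")
        if self.alpha0_G <= 0 or self.k_shape <= 0:
            raise ValueError("alpha0_G and k_shape must be positive")
        if self.alpha0_G + self.alpha1_G * 0.25 <= 0:
            raise ValueError("gamma mean must stay positive at maximal conflict")


def simulate_participants(
    group: GroupParameters,
    n_participants: int,
    design: pd.DataFrame | None = None,
    response_window: float = RESPONSE_WINDOW,
    seed: int = 0,
    censor: bool = True,
    conflict_scale: str = "raw",
    max_retries: int = 100,
) -> pd.DataFrame:
    """Simulate a behavioral dataset from the generative hierarchy.

    Participant parameters are drawn normal around the group means
    (redrawn, boundedly, until every trial's gamma mean is positive); per
    trial, choices are Bernoulli(theta) and RTs gamma with mean
    alpha0 + alpha1 * d.  With ``censor`` on, RTs exceeding the response
    window mark both choice and RT missing.  Ground-truth ``true_theta`` and
    ``true_d`` columns are included.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    if conflict_scale not in ("raw", "unit"):
        raise ValueError("conflict_scale must be 'raw' or 'unit'")
    if design is None:
        design = generate_design(seed=seed)
    rng = np.random.default_rng(seed)
    risk = design["risk"].to_numpy()
    rz = design["reward_z"].to_numpy(dtype=float)
    n_trials = len(design)

    frames = []
    for j in range(n_participants):
        for attempt in range(max_retries):
            beta = np.asarray(group.beta_G) + np.asarray(group.beta_sd) * rng.standard_normal(4)
            a0 = group.alpha0_G + group.alpha_sd[0] * rng.standard_normal()
            a1 = group.alpha1_G + group.alpha_sd[1] * rng.standard_normal()
            if a0 <= 0:
                continue
            theta = likelihood_of_take(beta, risk, rz)
            d = conflict(theta)
            d_eff = d / 0.25 if conflict_scale == "unit" else d
            mu = a0 + a1 * d_eff
            if np.all(mu > 0.05):
                break
        else:
            raise RuntimeError("could not draw a participant with positive RT means")
        k = float(np.exp(np.log(group.k_shape) + group.k_log_sd * rng.standard_normal()))
        y = rng.random(n_trials) < theta
        z = rng.gamma(shape=k, scale=mu / k)
        choice = y.astype(float)
        rt = z.copy()
        if censor:
            late = z > response_window
            choice[late] = np.nan
            rt[late] = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "participant": f"sub-{j + 1:02d}",
                    "trial": design["trial"].to_numpy(),
                    "risk": risk,
                    "reward": design["reward"].to_numpy(),
                    "reward_z": rz,
                    "choice": choice,
                    "rt": rt,
                    "true_theta": theta,
                    "true_d": d,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_behavior(dataset: pd.DataFrame, path) -> None:
    dataset.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_behavior(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def events_from_bids(events: pd.DataFrame, design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Convert a BIDS events table to the behavioral-dataset dialect.

    Expects columns ``onset``, ``duration`` plus ``risk``, ``reward`` (or
    ``trial_type`` encoding risk like ``risky-50``), ``choice`` or
    ``response`` (1/"risky" = risky) and ``response_time``.  Reward is
    re-standardized over the run unless a ``design`` with ``reward_z`` is
    supplied.
    """
    from .task import normalize_reward

    ev = events.copy()
    if "risk" not in ev.columns:
        if "trial_type" not in ev.columns:
            raise ValueError("events need a 'risk' or 'trial_type' column")
        ev["risk"] = (
            ev["trial_type"].astype(str).str.extract(r"(\d+)")[0].astype(float) / 100.0
        )
    if "choice" not in ev.columns:
        if "response" not in ev.columns:
            raise ValueError("events need a 'choice' or 'response' column")
        ev["choice"] = ev["response"].map(
            lambda r: np.nan if pd.isna(r) else float(r in (1, "1", "risky", "take"))
        )
    rt_col = "response_time" if "response_time" in ev.columns else "rt"
    out = pd.DataFrame(
        {
            "trial": np.arange(1, len(ev) + 1),
            "onset": ev["onset"].to_numpy(dtype=float),
            "risk": ev["risk"].to_numpy(dtype=float),
            "reward": ev["reward"].to_numpy(dtype=float),
            "choice": ev["choice"].to_numpy(dtype=float),
            "rt": ev[rt_col].to_numpy(dtype=float),
        }
    )
    if design is not None:
        out["reward_z"] = design["reward_z"].to_numpy(dtype=float)
    else:
        out["reward_z"] = normalize_reward(out["reward"].to_numpy())
    # a missing response voids both the choice and the RT
    missing = out["choice"].isna() | out["rt"].isna()
    out.loc[missing, ["choice", "rt"]] = np.nan
    return out


# --------------------------------------------------------------------------
# synthetic BOLD
# --------------------------------------------------------------------------

@dataclass
class SyntheticBold:
    """4-D synthetic BOLD series with its generating ground truth."""

    data: np.ndarray                     # (x, y, z, t)
    tr: float
    onsets: np.ndarray                   # s, per trial
    durations: np.ndarray                # s, per trial
    true_beta_maps: dict = field(default_factory=dict)   # regressor -> 3-D map
    motion: np.ndarray | None = None     # (t, 6)
    noise_model: str = "iid"

    @property
    def n_scans(self) -> int:
        return self.data.shape[-1]

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(self.data.astype(np.float32), affine=np.eye(4))


def _ar1_noise(rng, shape, n_scans, noise_sd, ar):
    white = rng.standard_normal(shape + (n_scans,))
    if ar == 0.0 or noise_sd == 0.0:
        return noise_sd * white
    out = np.empty_like(white)
    out[..., 0] = white[..., 0]
    scale = np.sqrt(1.0 - ar * ar)
    for t in range(1, n_scans):
        out[..., t] = ar * out[..., t - 1] + scale * white[..., t]
    return noise_sd * out


def simulate_bold(
    task_regressors: np.ndarray,
    true_beta_maps: np.ndarray,
    n_scans: int,
    tr: float,
    noise_sd: float = 1.0,
    ar_coefficient: float = 0.2,
    baseline: float = 100.0,
    seed: int = 0,
    onsets: np.ndarray | None = None,
    durations: np.ndarray | None = None,
) -> SyntheticBold:
    """Y = baseline + sum_r beta_r(voxel) * x_r(t) + AR(1) noise.

    ``task_regressors`` is (n_scans, R); ``true_beta_maps`` is
    (R, nx, ny, nz).  With ``noise_sd = 0`` a first-level GLM containing the
    same regressors recovers the beta maps exactly.
    """
    X = np.asarray(task_regressors, dtype=float)
    B = np.asarray(true_beta_maps, dtype=float)
    if X.ndim != 2 or X.shape[0] != n_scans:
        raise ValueError("task_regressors must be (n_scans, R)")
    if B.ndim != 4 or B.shape[0] != X.shape[1]:
        raise ValueError("true_beta_maps must be (R, nx, ny, nz)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    shape = B.shape[1:]
    signal = np.einsum("tr,rxyz->xyzt", X, B)
    noise = _ar1_noise(rng, shape, n_scans, noise_sd, ar_coefficient)
    data = baseline + signal + noise
    return SyntheticBold(
        data=data,
        tr=tr,
        onsets=np.asarray(onsets) if onsets is not None else np.array([]),
        durations=np.asarray(durations) if durations is not None else np.array([]),
        true_beta_maps={f"reg_{r}": B[r] for r in range(B.shape[0])},
        noise_model=f"ar1({ar_coefficient})" if ar_coefficient else "iid",
    )


def make_ground_truth_masks(shape=(12, 12, 12)):
    """Disjoint cuboid voxel sets: deliberation-only and conflict-sensitive.

    Each block is 27 voxels (>= the 20-voxel cluster-extent criterion).
    """
    delib = np.zeros(shape, dtype=bool)
    confl = np.zeros(shape, dtype=bool)
    delib[1:4, 1:4, 1:4] = True
    confl[7:10, 7:10, 7:10] = True
    return delib, confl


def simulate_conflict_study(
    n_subjects: int = 10,
    n_trials: int = 36,
    shape=(12, 12, 12),
    tr: float = 1.75,
    iti: float = 10.5,
    amp_delib: float = 1.0,
    amp_conflict: float = 4.0,
    noise_sd: float = 0.25,
    ar_coefficient: float = 0.2,
    subject_sd: float = 0.1,
    seed: int = 0,
):
    """Multi-subject synthetic study for the variable/fixed epoch dissociation.

    Every voxel's signal is built from variable-duration (response-time)
    boxcars.  Deliberation-only voxels have constant unit amplitude — their
    signal varies with time on task only.  Conflict-sensitive voxels are
    additionally amplitude-modulated by the (centered) per-trial conflict d.
    Response times rise linearly with d, so under fixed epochs the
    duration-driven signal masquerades as conflict modulation.

    Returns (events, subject_bolds, delib_mask, conflict_mask); ``events``
    has columns onset / rt / d_hat shared across subjects.
    """
    rng = np.random.default_rng(seed)
    delib, confl = make_ground_truth_masks(shape)

    # trial-level conflict and RTs: d spans [0, 0.25], RT = 1 + 1.824 d + noise
    d = rng.uniform(0.0, 0.25, size=n_trials)
    rt = np.clip(1.0 + 1.824 * d + 0.15 * rng.standard_normal(n_trials), 0.3, 3.4)
    onsets = 10.0 + iti * np.arange(n_trials)
    n_scans = int(np.ceil((onsets[-1] + 35.0) / tr))
    frame_times = np.arange(n_scans) * tr
    events = pd.DataFrame({"onset": onsets, "rt": rt, "d_hat": d})

    dc = d - d.mean()
    bolds = []
    for s in range(n_subjects):
        gain = 1.0 + subject_sd * rng.standard_normal()
        delib_ep = fmri_design.EpochSpec(onsets, rt, np.ones(n_trials))
        confl_ep = fmri_design.EpochSpec(onsets, rt, 1.0 + amp_conflict * dc)
        x_delib = fmri_design.convolve_regressor(delib_ep, frame_times)
        x_confl = fmri_design.convolve_regressor(confl_ep, frame_times)
        signal = np.zeros(shape + (n_scans,))
        signal[delib] = gain * amp_delib * x_delib
        signal[confl] = gain * amp_delib * x_confl
        noise = _ar1_noise(rng, shape, n_scans, noise_sd, ar_coefficient)
        bolds.append(
            SyntheticBold(
                data=100.0 + signal + noise,
                tr=tr,
                onsets=onsets,
                durations=rt,
                true_beta_maps={"delib": delib.astype(float), "conflict": confl.astype(float)},
                noise_model=f"ar1({ar_coefficient})",
            )
        )
    return events, bolds, delib, confl
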