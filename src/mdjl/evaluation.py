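"""Survival metrics and the repeated 70/30 trial protocol.

The concordance index is authored here with the exact pair rule used
throughout the package (events anchor comparable pairs; ties in the
prediction get half credit).  Kaplan-Meier estimation and the two-group
log-rank test are delegated to lifelines behind this module's surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.model_selection import train_test_split

from .io import OmicsDataset
from .model import TrainConfig, train_mdjl


def concordance_index(phi: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's C: fraction of comparable pairs ranked concordantly.

    A pair (i, j) is comparable when sample i dies (event_i = 1) strictly
    before t_j; it is concordant when the predicted hazard is higher for
    the earlier death (phi_i > phi_j), and a prediction tie scores 1/2.
    """
    phi = np.asarray(phi, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ev = np.flatnonzero(event == 1)
    # comparable[i, j]: event i occurs strictly before time j
    comparable = time[ev][:, None] < time[None, :]
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pair (all times tied or no events)")
    diff = phi[ev][:, None] - phi[None, :]
    concordant = ((diff > 0) & comparable).sum()
    tied = ((diff == 0) & comparable).sum()
    return float((concordant + 0.5 * tied) / n_pairs)


def median_risk_split(phi: np.ndarray) -> np.ndarray:
    """High-risk (True) iff the hazard strictly exceeds the cohort median."""
    phi = np.asarray(phi, float)
    if phi.size < 2:
        raise ValueError("need at least two samples to split")
    return phi > np.median(phi)


@dataclass
class KMCurve:
    """Product-limit survival estimate as a step function."""

    times: np.ndarray              # event-time grid (steps)
    survival: np.ndarray           # S(t) at each grid point
    at_risk: np.ndarray            # number at risk entering each time
    censor_times: np.ndarray       # times of censored observations (tick marks)


def km_curve(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier estimate over the distinct event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    event_times = np.unique(time[event == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(time >= t).sum() for t in event_times])
    return KMCurve(event_times, surv, at_risk, np.sort(time[event == 0]))


def logrank_test(time: np.ndarray, event: np.ndarray,
                 groups: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups).astype(bool)
    if groups.all() or (~groups).all():
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(time[groups], time[~groups],
                      event_observed_A=event[groups], event_observed_B=event[~groups])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class TrialResult:
    trial_id: int
    seed: int
    c_index: float
    n_train: int
    n_test: int
    variant: str = "mdjl"


@dataclass
class TrialSummary:
    trials: list[TrialResult]
    mean_c_index: float
    sd_c_index: float
    variant: str = "mdjl"

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "mean_c_index": self.mean_c_index,
            "sd_c_index": self.sd_c_index,
            "per_trial": [t.c_index for t in self.trials],
        }


def split_masks(n: int, event: np.ndarray, train_frac: float,
                seed: int) -> np.ndarray:
    """Boolean train mask for a stratified split preserving the censoring ratio."""
    idx = np.arange(n)
    train_idx, _ = train_test_split(idx, train_size=train_frac,
                                    stratify=np.asarray(event, int),
                                    random_state=int(seed) % (2 ** 31))
    mask = np.zeros(n, bool)
    mask[train_idx] = True
    return mask


def run_trials(dataset: OmicsDataset, config: TrainConfig, n_trials: int = 20,
               train_frac: float = 0.7, master_seed: int = 0) -> TrialSummary:
    """The repeated-split protocol: re-split 70/30 and re-fit for each trial.

    Every trial draws a fresh stratified split and a fresh model
    initialization from seeds spawned off ``master_seed``; the summary
    reports the mean and sd of the held-out C-index across trials.
    """
    seeds = np.random.SeedSequence(master_seed).generate_state(2 * n_trials) % (2 ** 31)
    results = []
    surv = dataset.survival
    for t in range(n_trials):
        split_seed, init_seed = int(seeds[2 * t]), int(seeds[2 * t + 1])
        mask = split_masks(dataset.n_samples, surv.event, train_frac, split_seed)
        cfg = TrainConfig(**{**config.__dict__, "seed": init_seed})
        fit = train_mdjl(dataset, mask, cfg, trial_id=t)
        test = fit.prediction.test_mask
        c = concordance_index(fit.prediction.phi[test], surv.time[test], surv.event[test])
        results.append(TrialResult(t, split_seed, c, int(mask.sum()),
                                   int((~mask).sum()), config.variant))
    cs = np.array([r.c_index for r in results])
    return TrialSummary(results, float(cs.mean()), float(cs.std(ddof=1)) if n_trials > 1 else 0.0,
                        config.variant)
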