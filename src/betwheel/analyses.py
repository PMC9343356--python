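"""The betting-game analyses: spread-error coupling, profile-vs-error
distribution matching, bet-order error curves, and undo diagnostics.

The entry point is the statsmodels-style pair
:class:`BettingGameModel` / :class:`BettingGameResults`:

>>> ds = simulate_dataset(kind="sampling", seed=1)
>>> res = BettingGameModel(ds).fit()
>>> print(res.summary())

Four analysis families are computed per participant and aggregated:

1. **Spread-error coupling** — does the spread of a trial's bets track the
   error of its first bet?  Per participant, the Pearson correlation
   between |bet-1 error| and a per-trial spread measure (median absolute
   adjacent-bet distance by default, or the sd/IQR of the drawn profile),
   Fisher-transformed and tested against zero at the group level.  A
   positive group mean indicates awareness of trial-by-trial imprecision.

2. **Profile vs error distribution** — does the average drawn profile
   (target-aligned) match the across-trial distribution of first-bet
   errors?  Compared by a two-sample KS test against a deterministic
   inverse-CDF pseudo-sample from the averaged profile; a mirrored
   ("flipped") profile serves as the asymmetry control.

3. **Bet-order curves** — mean absolute error of each individual bet, and
   of the running circular mean of bets 1..k, each submitted to a one-way
   repeated-measures ANOVA over bet order.  A falling cumulative curve is
   the signature that later bets carry target information beyond the
   first response.

4. **Undo diagnostics** — usage rate of the erase option and the error of
   undone versus replacement bets (mis-clicks land near the 90-degree
   chance level; deliberate bets do not).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as bstats
from .circular import (
    N_BINS,
    UndefinedCircularMeanError,
    abs_error,
    cumulative_means,
    nearest_bin,
    rotate_profile,
    signed_delta,
)
from .observers import Dataset, Trial
from .profile_engine import PenaltyParams, build_profile, profile_spread

__all__ = [
    "adjacent_bet_spread",
    "spread_error_analysis",
    "average_aligned_profile",
    "profile_vs_error_ks",
    "bet_order_analysis",
    "undo_summary",
    "BettingGameModel",
    "BettingGameResults",
]

CHANCE_ERROR_DEG = 90.0


# ---------------------------------------------------------------------------
# per-trial quantities

def bet_errors(trial: Trial):
    """Signed error of each bet relative to the trial's target."""
    return signed_delta(np.asarray(trial.bets), trial.target)


def adjacent_bet_spread(trial: Trial) -> float:
    """Median absolute circular distance between consecutively placed bets."""
    bets = np.asarray(trial.bets, dtype=float)
    steps = abs_error(bets[1:], bets[:-1])
    return float(np.median(steps))


def _trial_spread(trial: Trial, measure: str, params: PenaltyParams) -> float:
    if measure == "adjacent":
        return adjacent_bet_spread(trial)
    if measure in ("profile_sd", "profile_iqr"):
        prof = build_profile(trial.bets, params)
        return profile_spread(prof, trial.target, measure.split("_")[1])
    raise ValueError(f"unknown spread measure: {measure!r}")


# ---------------------------------------------------------------------------
# 1. spread-error coupling

@dataclass(frozen=True)
class SpreadErrorResult:
    per_participant: pd.DataFrame  # participant_id, r, z, p, n_trials
    group_test: bstats.TestResult  # one-sample t of z vs 0
    mean_r: float
    mean_z: float
    n_significant: int  # participants with per-participant p < .05 and r > 0
    measure: str
    excluded: tuple = ()


def spread_error_analysis(
    dataset: Dataset,
    spread_measure: str = "adjacent",
    params: Optional[PenaltyParams] = None,
) -> SpreadErrorResult:
    """Correlate |first-bet error| with per-trial bet spread, per participant.

    Participants with zero variance in either variable are excluded with a
    warning.  Group-level inference is a one-sample t-test on the Fisher-z
    values against zero.
    """
    from scipy.stats import pearsonr

    params = params or PenaltyParams()
    rows, excluded = [], []
    for pid in dataset.participant_ids:
        trials = dataset.trials_of(pid)
        if len(trials) < 3:
            excluded.append(pid)
            continue
        err1 = np.array([abs(bet_errors(t)[0]) for t in trials])
        spread = np.array([_trial_spread(t, spread_measure, params) for t in trials])
        if np.std(err1) == 0 or np.std(spread) == 0:
            warnings.warn(
                f"participant {pid}: zero variance, correlation undefined; excluded"
            )
            excluded.append(pid)
            continue
        res = pearsonr(err1, spread)
        rows.append(
            {
                "participant_id": pid,
                "r": float(res.statistic),
                "z": bstats.fisher_z(float(np.clip(res.statistic, -0.999999, 0.999999))),
                "p": float(res.pvalue),
                "n_trials": len(trials),
            }
        )
    per = pd.DataFrame(rows)
    if len(per) < 2:
        raise ValueError("need at least two participants with defined correlations")
    group = bstats.one_sample_t(per["z"].to_numpy(), 0.0)
    n_sig = int(((per["p"] < 0.05) & (per["r"] > 0)).sum())
    return SpreadErrorResult(
        per_participant=per,
        group_test=group,
        mean_r=float(per["r"].mean()),
        mean_z=float(per["z"].mean()),
        n_significant=n_sig,
        measure=spread_measure,
        excluded=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# 2. profile vs first-bet-error distribution (KS)

def average_aligned_profile(
    trials, params: Optional[PenaltyParams] = None, mirror_about_bet1: bool = False
):
    """Average of the trials' profiles after rotating each target to bin 0.

    With ``mirror_about_bet1`` each trial's profile is first reflected
    about its bet-1 position (the symmetry axis a confidence-only account
    would predict).
    """
    params = params or PenaltyParams()
    trials = list(trials)
    if not trials:
        raise ValueError("need at least one trial")
    acc = np.zeros(N_BINS)
    for t in trials:
        prof = build_profile(t.bets, params)
        if mirror_about_bet1:
            prof = _mirror_profile(prof, t.bets[0])
        acc += rotate_profile(prof, nearest_bin(t.target))
    return acc / len(trials)


def _mirror_profile(profile, axis_deg):
    """Reflect a profile about the given wheel position: out[i] = in[2c - i]."""
    c = nearest_bin(axis_deg)
    idx = np.mod(2 * c - np.arange(N_BINS), N_BINS)
    return np.asarray(profile)[idx]


def profile_pseudo_sample(profile, n: int):
    """Deterministic size-n pseudo-sample from a target-aligned profile.

    Inverse-CDF draws at the equally spaced quantiles (i - 0.5)/n on the
    signed-error axis (-180, 180], with linear interpolation inside the
    one-degree bins.  Reproducible by construction: no randomness.
    """
    profile = np.asarray(profile, dtype=float)
    total = profile.sum()
    if total <= 0:
        raise ValueError("profile has zero mass")
    p = np.concatenate([profile[181:], profile[:181]]) / total
    edges = np.concatenate([[-179.5], np.concatenate([np.arange(-179.0, 0.0), np.arange(0.0, 181.0)]) + 0.5])
    cdf = np.concatenate([[0.0], np.cumsum(p)])
    cdf[-1] = 1.0
    q = (np.arange(1, n + 1) - 0.5) / n
    return np.interp(q, cdf, edges)


def _profile_cdf_callable(profile):
    profile = np.asarray(profile, dtype=float)
    p = np.concatenate([profile[181:], profile[:181]]) / profile.sum()
    edges = np.concatenate([[-179.5], np.concatenate([np.arange(-179.0, 0.0), np.arange(0.0, 181.0)]) + 0.5])
    cdf = np.concatenate([[0.0], np.cumsum(p)])
    cdf[-1] = 1.0
    return lambda x: np.interp(x, edges, cdf)


def profile_vs_error_ks(
    trials,
    flipped: bool = False,
    params: Optional[PenaltyParams] = None,
    min_trials: int = 20,
    flip_axis: str = "target",
    variant: str = "pseudo_sample",
    holdout: bool = True,
) -> bstats.TestResult:
    """KS comparison of first-bet errors against the averaged drawn profile.

    Sample A is the participant's signed first-bet errors; the averaged
    target-aligned profile provides the comparison distribution — either a
    deterministic pseudo-sample of equal size (``variant='pseudo_sample'``,
    standard two-sample KS) or a continuous CDF (``variant='continuous'``,
    one-sample KS).  ``flipped`` mirrors the profile before comparison:
    about the aligned target (``flip_axis='target'``) or about each
    trial's first bet (``flip_axis='bet1'``).

    With ``holdout`` (default) the error sample comes from even-indexed
    trials and the profile from odd-indexed trials.  The first bet is
    itself part of the drawn profile, so comparing both sides on the same
    trials couples their finite-sample noise: the unflipped D is then
    biased low and the flipped control spuriously "significant" even for
    a perfectly symmetric observer.  The split makes the two sides
    independent, which the KS null assumes; ``holdout=False`` gives the
    same-trials comparison.
    """
    from scipy.stats import kstest

    params = params or PenaltyParams()
    trials = list(trials)
    if len(trials) < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {len(trials)}")
    if holdout:
        error_trials = trials[0::2]
        profile_trials = trials[1::2]
    else:
        error_trials = profile_trials = trials
    errors = np.array([bet_errors(t)[0] for t in error_trials])

    if flipped and flip_axis == "bet1":
        avg = average_aligned_profile(profile_trials, params, mirror_about_bet1=True)
    else:
        avg = average_aligned_profile(profile_trials, params)
        if flipped:  # mirror about the aligned target at bin 0
            avg = avg[np.mod(-np.arange(N_BINS), N_BINS)]

    if variant == "pseudo_sample":
        pseudo = profile_pseudo_sample(avg, len(errors))
        return bstats.ks_two_sample(errors, pseudo)
    if variant == "continuous":
        res = kstest(errors, _profile_cdf_callable(avg))
        return bstats.TestResult(statistic=float(res.statistic), p=float(res.pvalue))
    raise ValueError(f"unknown KS variant: {variant!r}")


@dataclass(frozen=True)
class KSResult:
    per_participant: pd.DataFrame  # participant_id, D, p, D_flipped, p_flipped
    mean_D: float
    mean_D_flipped: float
    flip_test: bstats.TestResult  # paired t: D_flipped - D
    n_nonsignificant: int  # participants whose unflipped p > .05
    n_nonsignificant_flipped: int


def ks_analysis(
    dataset: Dataset,
    params: Optional[PenaltyParams] = None,
    min_trials: int = 20,
    flip_axis: str = "target",
    variant: str = "pseudo_sample",
    holdout: bool = True,
) -> KSResult:
    """Per-participant KS comparison, unflipped and flipped, with the paired
    flip-sensitivity test across participants."""
    rows = []
    for pid in dataset.participant_ids:
        trials = dataset.trials_of(pid)
        plain = profile_vs_error_ks(trials, False, params, min_trials, flip_axis, variant, holdout)
        flip = profile_vs_error_ks(trials, True, params, min_trials, flip_axis, variant, holdout)
        rows.append(
            {
                "participant_id": pid,
                "D": plain.statistic,
                "p": plain.p,
                "D_flipped": flip.statistic,
                "p_flipped": flip.p,
            }
        )
    per = pd.DataFrame(rows)
    flip_test = bstats.paired_t(per["D_flipped"].to_numpy(), per["D"].to_numpy())
    return KSResult(
        per_participant=per,
        mean_D=float(per["D"].mean()),
        mean_D_flipped=float(per["D_flipped"].mean()),
        flip_test=flip_test,
        n_nonsignificant=int((per["p"] > 0.05).sum()),
        n_nonsignificant_flipped=int((per["p_flipped"] > 0.05).sum()),
    )


# ---------------------------------------------------------------------------
# 3. bet-order error curves

@dataclass(frozen=True)
class BetOrderResult:
    individual: pd.DataFrame  # participants x 6 mean |bet-k error|
    cumulative: pd.DataFrame  # participants x 6 mean |cumulative-mean error|
    individual_mean: np.ndarray  # group mean curve, 6 values
    cumulative_mean: np.ndarray
    anova_individual: bstats.TestResult
    anova_cumulative: bstats.TestResult
    n_excluded_trials: int


def bet_order_analysis(dataset: Dataset) -> BetOrderResult:
    """Mean individual and cumulative absolute error per bet index, with
    one-way repeated-measures ANOVAs over bet order.

    Trials whose running circular mean is undefined for some prefix
    (near-zero resultant) are excluded with a warning.
    """
    ind_rows, cum_rows = [], []
    n_excluded = 0
    for pid in dataset.participant_ids:
        trials = dataset.trials_of(pid)
        ind, cum = [], []
        for t in trials:
            try:
                cmeans = cumulative_means(np.asarray(t.bets))
            except UndefinedCircularMeanError:
                n_excluded += 1
                continue
            ind.append(np.abs(bet_errors(t)))
            cum.append(abs_error(cmeans, t.target))
        if not ind:
            raise ValueError(f"participant {pid}: no usable trials")
        ind_rows.append(np.mean(ind, axis=0))
        cum_rows.append(np.mean(cum, axis=0))
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} trials with undefined cumulative means")
    pids = dataset.participant_ids
    cols = [f"bet{k}" for k in range(1, len(ind_rows[0]) + 1)]
    ind_df = pd.DataFrame(ind_rows, index=pids, columns=cols)
    cum_df = pd.DataFrame(cum_rows, index=pids, columns=cols)
    return BetOrderResult(
        individual=ind_df,
        cumulative=cum_df,
        individual_mean=ind_df.to_numpy().mean(axis=0),
        cumulative_mean=cum_df.to_numpy().mean(axis=0),
        anova_individual=bstats.rm_anova_oneway(ind_df.to_numpy()),
        anova_cumulative=bstats.rm_anova_oneway(cum_df.to_numpy()),
        n_excluded_trials=n_excluded,
    )


# ---------------------------------------------------------------------------
# 4. undo diagnostics

@dataclass(frozen=True)
class UndoSummary:
    usage_rate: float  # fraction of trials with an undo
    undone_mean_error: Optional[float]  # mean |error| of erased bets
    replacement_mean_error: Optional[float]  # mean |error| of their replacements
    by_bet_index: dict  # bet index (1-based) -> undo count


def undo_summary(dataset: Dataset) -> UndoSummary:
    """Usage rate of the erase option and error of undone vs replacement bets."""
    n_trials = len(dataset.trials)
    if n_trials == 0:
        raise ValueError("empty dataset")
    undone_err, repl_err = [], []
    by_index: dict = {}
    n_undo = 0
    for t in dataset.trials:
        ev = t.undo_event
        if ev is None:
            continue
        n_undo += 1
        undone_err.append(float(abs_error(ev.original_deg, t.target)))
        repl_err.append(float(abs_error(t.bets[ev.bet_index], t.target)))
        by_index[ev.bet_index + 1] = by_index.get(ev.bet_index + 1, 0) + 1
    return UndoSummary(
        usage_rate=n_undo / n_trials,
        undone_mean_error=float(np.mean(undone_err)) if undone_err else None,
        replacement_mean_error=float(np.mean(repl_err)) if repl_err else None,
        by_bet_index=by_index,
    )


# ---------------------------------------------------------------------------
# Model / Results

class BettingGameModel:
    """Full betting-game analysis of one dataset (real or simulated).

    Parameters
    ----------
    dataset : Dataset
        Trials to analyze; build one with ``observers.simulate_dataset``
        or load one with ``io.read_dataset`` / ``from_dataframe``.
    penalty : PenaltyParams, optional
        Scoring-engine parameters used wherever profiles are rebuilt.
    spread_measure : {'adjacent', 'profile_sd', 'profile_iqr'}
    ks_min_trials : int
        Minimum trials per participant for the KS comparison.
    flip_axis : {'target', 'bet1'}
        Mirror axis for the flipped-profile control.
    ks_variant : {'pseudo_sample', 'continuous'}
    """

    def __init__(
        self,
        dataset: Dataset,
        penalty: Optional[PenaltyParams] = None,
        spread_measure: str = "adjacent",
        ks_min_trials: int = 20,
        flip_axis: str = "target",
        ks_variant: str = "pseudo_sample",
    ):
        self.dataset = dataset
        self.penalty = penalty or PenaltyParams()
        self.spread_measure = spread_measure
        self.ks_min_trials = ks_min_trials
        self.flip_axis = flip_axis
        self.ks_variant = ks_variant

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "BettingGameModel":
        """Build a model from a tidy trial table (the CSV schema of ``io``)."""
        from .io import dataset_from_frame

        return cls(dataset_from_frame(df), **kwargs)

    def fit(self, run_ks: bool = True) -> "BettingGameResults":
        """Run all analysis families and return a results object."""
        spread = spread_error_analysis(self.dataset, self.spread_measure, self.penalty)
        order = bet_order_analysis(self.dataset)
        ks = (
            ks_analysis(
                self.dataset,
                self.penalty,
                self.ks_min_trials,
                self.flip_axis,
                self.ks_variant,
            )
            if run_ks
            else None
        )
        undo = undo_summary(self.dataset)
        return BettingGameResults(self, spread, ks, order, undo)


@dataclass
class BettingGameResults:
    """Fitted betting-game analyses; see :meth:`summary` for the headline table."""

    model: BettingGameModel
    spread_error: SpreadErrorResult
    ks: Optional[KSResult]
    bet_order: BetOrderResult
    undo: UndoSummary

    def to_dict(self) -> dict:
        """JSON-serializable report of the group-level quantities."""
        se, bo = self.spread_error, self.bet_order
        out = {
            "spread_error": {
                "measure": se.measure,
                "mean_r": se.mean_r,
                "mean_z": se.mean_z,
                "t": se.group_test.statistic,
                "df": se.group_test.df,
                "p": se.group_test.p,
                "ci95": list(se.group_test.ci),
                "n_significant_positive": se.n_significant,
                "n_participants": int(len(se.per_participant)),
            },
            "bet_order": {
                "individual_mean_error": [float(v) for v in bo.individual_mean],
                "cumulative_mean_error": [float(v) for v in bo.cumulative_mean],
                "anova_individual": _test_dict(bo.anova_individual),
                "anova_cumulative": _test_dict(bo.anova_cumulative),
                "n_excluded_trials": bo.n_excluded_trials,
            },
            "undo": {
                "usage_rate": self.undo.usage_rate,
                "undone_mean_error": self.undo.undone_mean_error,
                "replacement_mean_error": self.undo.replacement_mean_error,
                "by_bet_index": {str(k): v for k, v in sorted(self.undo.by_bet_index.items())},
            },
        }
        if self.ks is not None:
            out["ks"] = {
                "mean_D": self.ks.mean_D,
                "mean_D_flipped": self.ks.mean_D_flipped,
                "flip_t": self.ks.flip_test.statistic,
                "flip_p": self.ks.flip_test.p,
                "n_nonsignificant": self.ks.n_nonsignificant,
                "n_nonsignificant_flipped": self.ks.n_nonsignificant_flipped,
            }
        return out

    def summary(self) -> str:
        """Human-readable group-level summary table."""
        se, bo = self.spread_error, self.bet_order
        lines = [
            "Betting-game analysis summary",
            "=" * 64,
            f"Participants: {len(self.dataset_participants)}   "
            f"Trials: {len(self.model.dataset)}",
            "",
            f"Spread-error coupling ({se.measure}):",
            f"  mean r = {se.mean_r:.3f}, mean z = {se.mean_z:.3f}, "
            f"t({se.group_test.df}) = {se.group_test.statistic:.2f}, "
            f"p = {se.group_test.p:.3g}",
            f"  participants with positive r, p<.05: "
            f"{se.n_significant}/{len(se.per_participant)}",
            "",
            "Bet-order error curves (degrees):",
            "  individual: "
            + " ".join(f"{v:5.1f}" for v in bo.individual_mean),
            "  cumulative: "
            + " ".join(f"{v:5.1f}" for v in bo.cumulative_mean),
            f"  ANOVA individual: F{bo.anova_individual.df} = "
            f"{bo.anova_individual.statistic:.2f}, p = {bo.anova_individual.p:.3g}, "
            f"eta2 = {bo.anova_individual.effect_size:.3f}",
            f"  ANOVA cumulative: F{bo.anova_cumulative.df} = "
            f"{bo.anova_cumulative.statistic:.2f}, p = {bo.anova_cumulative.p:.3g}, "
            f"eta2 = {bo.anova_cumulative.effect_size:.3f}",
        ]
        if self.ks is not None:
            lines += [
                "",
                "Profile vs first-bet-error KS:",
                f"  mean D = {self.ks.mean_D:.3f} (flipped {self.ks.mean_D_flipped:.3f}), "
                f"flip paired t = {self.ks.flip_test.statistic:.2f}, "
                f"p = {self.ks.flip_test.p:.3g}",
                f"  non-significant participants: {self.ks.n_nonsignificant} unflipped, "
                f"{self.ks.n_nonsignificant_flipped} flipped",
            ]
        if self.undo.usage_rate > 0:
            lines += [
                "",
                "Undo usage:",
                f"  rate = {100 * self.undo.usage_rate:.1f}% of trials; "
                f"undone mean error = {self.undo.undone_mean_error:.1f} deg, "
                f"replacement = {self.undo.replacement_mean_error:.1f} deg",
            ]
        return "\n".join(lines)

    @property
    def dataset_participants(self):
        return self.model.dataset.participant_ids


def _test_dict(t: bstats.TestResult) -> dict:
    d = {"statistic": t.statistic, "p": t.p, "df": t.df, "effect_size": t.effect_size}
    d.update(t.extras)
    return d
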