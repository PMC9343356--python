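"""Simulated participants for the betting game.

Three generative accounts of what a participant knows about the briefly
presented shape, each producing six ordered bets per trial:

``sampling``
    The participant holds a trial-specific internal probability
    distribution (center ``m`` = target + encoding noise, width ``w``
    drawn per trial) and every bet — including the first — is an
    independent sample from it.  Later bets accrue extra motor/decay
    noise growing linearly with bet index.

``discrete``
    Only a point estimate ``m`` is available.  Bet 1 is placed exactly at
    ``m``; bets 2–6 scatter symmetrically about ``m`` with a width that is
    statistically independent of the encoding error.

``discrete_confidence``
    As ``discrete``, but the scatter width co-varies with the magnitude of
    the (unobservable) encoding error — a point estimate plus a sense of
    confidence, without access to a full distribution.

The accounts are distinguished downstream by the cumulative-error
signature: averaging independent samples pulls the running mean toward the
target (cumulative error falls below the first bet's error), whereas
symmetric scatter about a point estimate can only dilute it.

Every bet is independently replaced by a uniform mis-click with
probability ``lapse_rate``.  With ``undo_enabled`` (the control
experiment), the first mis-click of a trial is noticed and erased with a
fixed probability, recorded as an undo event, and replaced by a fresh
draw from the observer's normal process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .circular import wrap

__all__ = [
    "ObserverParams",
    "UndoEvent",
    "Trial",
    "Dataset",
    "simulate_trial",
    "simulate_dataset",
    "default_hyper_ranges",
]

N_BETS = 6

#: probability that a mis-click is noticed and undone (undo-enabled runs);
#: with the default per-bet lapse rate this yields ~2% of trials undone
UNDO_DETECT_PROB = 0.67

GENERATOR_VERSION = "1.0"


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated participant.

    Width and noise parameters are standard deviations in degrees.
    ``internal_sd_mean``/``internal_sd_spread`` govern the per-trial draw
    of the internal-distribution width ``w`` (floored at 1 degree).
    ``skew`` is a unitless asymmetry of the internal distribution
    (0 = symmetric); ``confidence_coupling`` in [0, 1] sets how strongly
    ``w`` tracks the encoding-error magnitude for the
    ``discrete_confidence`` account.
    """

    kind: str = "sampling"
    encoding_sd: float = 12.0
    internal_sd_mean: float = 10.0
    internal_sd_spread: float = 3.0
    bet_noise_growth: float = 2.0
    skew: float = 0.0
    confidence_coupling: float = 0.0
    lapse_rate: float = 0.005
    undo_enabled: bool = False
    noise_model: str = "wrapped_normal"

    def __post_init__(self):
        if self.kind not in ("sampling", "discrete", "discrete_confidence"):
            raise ValueError(f"unknown observer kind: {self.kind!r}")
        for name in ("encoding_sd", "internal_sd_mean", "internal_sd_spread"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bet_noise_growth < 0:
            raise ValueError("bet_noise_growth must be nonnegative")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")
        if not 0.0 <= self.confidence_coupling <= 1.0:
            raise ValueError("confidence_coupling must lie in [0, 1]")
        if self.noise_model not in ("wrapped_normal", "von_mises"):
            raise ValueError(f"unknown noise model: {self.noise_model!r}")


@dataclass(frozen=True)
class UndoEvent:
    """A bet that was erased and replaced: index (0-based) and the erased center."""

    bet_index: int
    original_deg: float


@dataclass(frozen=True)
class Trial:
    participant_id: int
    trial_index: int
    target: float
    bets: tuple  # 6 confirmed bet centers, degrees in [0, 360)
    experiment: int = 1
    undo_event: Optional[UndoEvent] = None


@dataclass
class Dataset:
    """A cohort of trials plus, for synthetic data, its generative record."""

    trials: list
    params_by_participant: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def participant_ids(self):
        return sorted({t.participant_id for t in self.trials})

    def trials_of(self, participant_id):
        return [t for t in self.trials if t.participant_id == participant_id]

    def __len__(self):
        return len(self.trials)


def _circ_noise(rng, sd, size=None, model="wrapped_normal"):
    """Zero-mean circular noise in degrees; wrapping happens at bet level."""
    if sd == 0:
        return np.zeros(size) if size is not None else 0.0
    if model == "von_mises":
        kappa = 1.0 / np.deg2rad(sd) ** 2
        return np.rad2deg(rng.vonmises(0.0, kappa, size))
    return rng.normal(0.0, sd, size)


def _internal_draw(rng, w, skew, model):
    """One sample offset from the internal distribution (width w, optional skew).

    Skew is a two-component mixture with zero mean: N(+skew*w, s) with
    weight 1/4 and N(-skew*w/3, s) with weight 3/4, where the component
    width s = w / (1 + |skew|/2) shrinks as the offsets grow so the
    asymmetry is carried by the offsets rather than washed out by the
    component tails.  skew = 0 reduces exactly to N(0, w).
    """
    if skew == 0.0:
        return _circ_noise(rng, w, model=model)
    loc = skew * w if rng.random() < 0.25 else -skew * w / 3.0
    s = w / (1.0 + abs(skew) / 2.0)
    return loc + _circ_noise(rng, s, model=model)


def _draw_width(rng, params, abs_encoding_error):
    # floor at 5% of the mean width so a low draw can't go degenerate
    floor = 0.05 * params.internal_sd_mean
    w = max(floor, rng.normal(params.internal_sd_mean, params.internal_sd_spread))
    if params.kind == "discrete_confidence" and params.confidence_coupling > 0:
        # scale |error| so the coupled term has the same mean width
        scale = params.internal_sd_mean / (params.encoding_sd * np.sqrt(2.0 / np.pi))
        c = params.confidence_coupling
        w = max(floor, (1.0 - c) * w + c * scale * abs_encoding_error)
    return w


def _draw_bet(rng, params, m, w, bet_index):
    """One confirmed bet center (before any lapse), degrees on the wheel."""
    growth = _circ_noise(
        rng, params.bet_noise_growth * bet_index, model=params.noise_model
    )
    if params.kind == "sampling":
        offset = _internal_draw(rng, w, params.skew, params.noise_model)
    elif bet_index == 0:
        offset = 0.0
    else:
        offset = _internal_draw(rng, w, 0.0, params.noise_model)
    return float(wrap(m + offset + growth))


def simulate_trial(
    params: ObserverParams,
    target: float,
    rng: np.random.Generator,
    participant_id: int = 0,
    trial_index: int = 0,
) -> Trial:
    """Generate one six-bet trial for the given observer."""
    eps = _circ_noise(rng, params.encoding_sd, model=params.noise_model)
    m = wrap(target + eps)
    w = _draw_width(rng, params, abs(eps))

    bets = []
    undo_event = None
    for k in range(N_BETS):
        bet = _draw_bet(rng, params, m, w, k)
        if rng.random() < params.lapse_rate:
            lapse = float(rng.uniform(0.0, 360.0))
            if (
                params.undo_enabled
                and undo_event is None
                and rng.random() < UNDO_DETECT_PROB
            ):
                undo_event = UndoEvent(bet_index=k, original_deg=lapse)
                bet = _draw_bet(rng, params, m, w, k)  # replacement draw
            else:
                bet = lapse
        bets.append(bet)

    return Trial(
        participant_id=participant_id,
        trial_index=trial_index,
        target=float(wrap(target)),
        bets=tuple(bets),
        experiment=2 if params.undo_enabled else 1,
        undo_event=undo_event,
    )


def default_hyper_ranges():
    """Uniform ranges the per-participant parameters are drawn from.

    Centered on a regime where mean first-bet error lands in the mid-teens
    of degrees, as in typical brief-presentation shape reports.
    """
    return {
        "encoding_sd": (9.0, 15.0),
        "internal_sd_mean": (7.0, 13.0),
        "internal_sd_spread": (2.0, 4.0),
        "bet_noise_growth": (1.0, 3.0),
    }


def simulate_dataset(
    n_participants: int = 40,
    n_trials: int = 150,
    kind: str = "sampling",
    seed: int = 0,
    base_params: ObserverParams | None = None,
    hyper_ranges: dict | None = None,
    heterogeneous: bool = True,
) -> Dataset:
    """Simulate a cohort: ``n_participants`` observers x ``n_trials`` trials.

    Targets are uniform on the wheel.  Each participant gets an
    independent random substream derived from ``seed``, so adding
    participants never perturbs earlier ones; per-participant parameters
    are drawn from ``hyper_ranges`` around ``base_params`` (or taken
    verbatim from ``base_params`` when ``heterogeneous`` is False).
    """
    if n_participants < 1 or n_trials < 1:
        raise ValueError("need at least one participant and one trial")
    base = base_params or ObserverParams(kind=kind)
    ranges = default_hyper_ranges() if hyper_ranges is None else hyper_ranges

    root = np.random.SeedSequence(seed)
    children = root.spawn(n_participants)

    trials = []
    params_by_participant = {}
    for pid, child in enumerate(children):
        rng = np.random.default_rng(child)
        if heterogeneous:
            drawn = {k: float(rng.uniform(*v)) for k, v in ranges.items()}
            p = ObserverParams(**{**asdict(base), **drawn})
        else:
            p = base
        params_by_participant[pid] = p
        targets = rng.uniform(0.0, 360.0, n_trials)
        for t_idx in range(n_trials):
            trials.append(
                simulate_trial(p, targets[t_idx], rng, pid, t_idx)
            )

    provenance = {
        "seed": int(seed),
        "generator_version": GENERATOR_VERSION,
        "kind": base.kind,
        "n_participants": n_participants,
        "n_trials": n_trials,
        "heterogeneous": heterogeneous,
        "hyper_ranges": {k: list(v) for k, v in ranges.items()} if heterogeneous else {},
        "base_params": asdict(base),
    }
    return Dataset(trials, params_by_participant, provenance)
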