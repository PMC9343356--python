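"""Optional figures: bet-order error curves and profile/error overlays.

Matplotlib is imported lazily so the rest of the package works without a
plotting backend.
"""

from __future__ import annotations

import numpy as np

from .analyses import BetOrderResult, average_aligned_profile, bet_errors
from .circular import bin_signed_coords


def plot_error_curves(result: BetOrderResult, ax=None):
    """Individual (red) and cumulative (blue) mean error vs bet order."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    k = np.arange(1, len(result.individual_mean) + 1)
    ax.plot(k, result.individual_mean, "o-", color="tab:red", label="individual")
    ax.plot(k, result.cumulative_mean, "s-", color="tab:blue", label="cumulative")
    ax.set_xlabel("bet order")
    ax.set_ylabel("mean absolute error (deg)")
    ax.legend()
    return ax


def plot_profile_vs_error(trials, params=None, ax=None, half_range=60):
    """Averaged target-aligned profile (blue) over the first-bet error
    density (red) for one participant's trials."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    trials = list(trials)
    avg = average_aligned_profile(trials, params)
    order = np.argsort(bin_signed_coords())
    x = bin_signed_coords()[order]
    dens = (avg / avg.sum())[order]
    errors = np.array([bet_errors(t)[0] for t in trials])
    ax.hist(errors, bins=np.arange(-half_range, half_range + 4, 4), density=True,
            color="tab:red", alpha=0.4, label="first-bet errors")
    ax.plot(x, dens, color="tab:blue", label="avg drawn profile")
    ax.set_xlim(-half_range, half_range)
    ax.set_xlabel("signed error (deg)")
    ax.set_ylabel("density")
    ax.legend()
    return ax
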