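"""Optional diagnostic plots (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .prs import PRSProfile
from .simulate import AdmixedCohort


def prs_regression_plot(cohort: AdmixedCohort, profile: PRSProfile, path: str) -> None:
    """Scatter of log2 B12 against PRS with the fitted regression line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.log2(cohort.phenotype)
    s = profile.scores
    slope, intercept = np.polyfit(s, y, 1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(s, y, s=12, alpha=0.6)
    grid = np.linspace(s.min(), s.max(), 50)
    ax.plot(grid, slope * grid + intercept, color="crimson")
    ax.set_xlabel("polygenic risk score")
    ax.set_ylabel("log2 plasma B12 (pmol/L)")
    ax.set_title(f"R² = {profile.r_squared:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ordered_prs_plot(profile: PRSProfile, path: str) -> None:
    """Individuals in ascending order of PRS, colored by tercile."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(profile.scores, kind="stable")
    colors = {"T1": "#4477aa", "T2": "#ccbb44", "T3": "#ee6677"}
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(
        np.arange(len(order)),
        profile.scores[order],
        color=[colors[t] for t in profile.terciles[order]],
        width=1.0,
    )
    ax.set_xlabel("individuals (ascending PRS)")
    ax.set_ylabel("PRS")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
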