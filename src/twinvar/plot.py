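"""Optional plotting: per-stratum SD estimates against a proxy variable.

Requires matplotlib (the ``plot`` extra); imported lazily so the core
pipeline has no plotting dependency.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError
from .meta import PROXIES


def plot_sd_vs_proxy(stratum_table, proxy: str = "obesity_pct", outcome: str = "A",
                     tau2: float = 0.0, ax=None):
    """Bubble plot of stratum A-SD (or E-SD) against a proxy.

    Circle area is proportional to the stratum's random-effects weight
    1/(se^2 + tau2); a weighted least-squares line is overlaid.
    """
    try:
        import matplotlib.pyplot as plt
    except ImportError as e:  # pragma: no cover
        raise ConfigError("plotting requires matplotlib (install the 'plot' extra)") from e
    if proxy not in PROXIES:
        raise ConfigError(f"unknown proxy {proxy!r}")
    ycol, secol = ("agsd", "agsd_se") if outcome == "A" else ("esd", "esd_se")
    t = stratum_table[stratum_table["fit_valid"]] if "fit_valid" in stratum_table else stratum_table
    x = t[proxy].to_numpy(dtype=float)
    y = t[ycol].to_numpy(dtype=float)
    w = 1.0 / (t[secol].to_numpy(dtype=float) ** 2 + tau2)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=40 * w / w.mean(), alpha=0.4, edgecolor="k", linewidth=0.3)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T * w @ X, X.T * w @ y)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, beta[0] + beta[1] * grid, "r-", lw=1.5)
    ax.set_xlabel(proxy.replace("_", " "))
    ax.set_ylabel({"A": "additive genetic SD (kg/m$^2$)",
                   "E": "unique environmental SD (kg/m$^2$)"}[outcome])
    return ax
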