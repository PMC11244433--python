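"""Stacked-bar view of the SS decomposition.

One bar per trait: interspecific (fixed) and intraspecific (intra)
between-treatment SS stacked as percentages, the specific (total)
share drawn as a horizontal marker, and the gap between marker and
stack reading as the covariation term — above the stack when positive,
crossing it when negative.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def decomposition_barplot(decomposition: pd.DataFrame, scheme: str,
                          path: str | Path) -> Path:
    """Render the between-treatment decomposition for one scheme."""
    sub = decomposition[(decomposition["scheme"] == scheme)
                        & (decomposition["stratum"] == "between")]
    if sub.empty:
        raise ValueError(f"no decomposition rows for scheme {scheme!r}")
    traits = sub["trait"].tolist()
    x = np.arange(len(traits))
    fixed = sub["percent_fixed"].to_numpy(dtype=float)
    intra = sub["percent_intra"].to_numpy(dtype=float)
    total = fixed + intra + sub["percent_cov"].to_numpy(dtype=float)

    fig, ax = plt.subplots(figsize=(1.6 * len(traits) + 1.5, 4.0))
    ax.bar(x, fixed, width=0.6, label="interspecific (fixed)",
           color="#7f9fcf", edgecolor="black")
    ax.bar(x, intra, width=0.6, bottom=fixed, label="intraspecific",
           color="#e8a06a", edgecolor="black")
    ax.hlines(total, x - 0.35, x + 0.35, colors="black", linewidth=2.0,
              label="total (specific)")
    ax.axhline(0.0, color="grey", linewidth=0.8)
    ax.set_xticks(x, traits)
    ax.set_ylabel("% of trait variability explained")
    ax.set_title(f"{scheme}: treatment-explained trait variability")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
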