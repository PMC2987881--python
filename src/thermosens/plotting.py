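"""Bar-chart rendering of sensitivity indices, mirroring the usual
first-order / total-order figure layout."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .global_sensitivity import SensitivityResult

__all__ = ["plot_indices"]


def plot_indices(result: SensitivityResult, path: Union[str, Path], title: str = "") -> None:
    """Grouped bars: S1 per parameter, plus ST (or S1 + pairwise sum) if present."""
    k = len(result.names)
    x = np.arange(k)
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * k), 4))
    if result.total_order is not None:
        ax.bar(x - 0.2, result.first_order, width=0.4, color="0.6", label="first order")
        ax.bar(x + 0.2, result.total_order, width=0.4, color="0.1", label="total (approx.)")
        ax.legend(frameon=False)
    else:
        ax.bar(x, result.first_order, width=0.6, color="0.4")
    ax.set_xticks(x)
    ax.set_xticklabels(result.names, rotation=45, ha="right")
    ax.set_ylabel("sensitivity index")
    ax.set_title(title or result.method)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
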