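"""Minimal plotting: grouped box plots of per-sample fold expression."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from .containers import CASE, CONTROL
from .quant import RelQuantTable


def plot_fold_expression(
    quant_by_cohort: Mapping[str, RelQuantTable],
    targets: Sequence[str],
    path: str | Path,
) -> Path:
    """Box plots of 2^-ddCt per target, split by group and cohort."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    targets = list(targets)
    fig, axes = plt.subplots(
        1, max(len(targets), 1), figsize=(2.2 * max(len(targets), 1), 3.5), squeeze=False
    )
    for ax, target in zip(axes[0], targets):
        data, labels = [], []
        for cohort, rq in quant_by_cohort.items():
            for group in (CASE, CONTROL):
                data.append(rq.expression(target, group).to_numpy())
                labels.append(f"{group[:4]}.{cohort}")
        ax.boxplot(data, tick_labels=labels, whis=1.5)
        ax.set_title(target, fontsize=9)
        ax.tick_params(axis="x", rotation=90, labelsize=7)
        ax.set_ylabel("fold expression 2^-ddCt", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
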