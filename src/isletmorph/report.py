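"""Figure-style summary report assembly.

Renders the standard panel styles used for islet-morphogenesis
quantitation: clustering hull volume versus time; morphology (area,
circularity, solidity) box-whisker panels with 10-90% whiskers and the
mean marked "+"; filopodium rate and maximal-length box-whiskers in the
same style; and islet-volume boxes with 25th-75th percentile boxes,
5th-95th percentile whiskers, median line and "+" mean.  Missing inputs
produce placeholder notes; the report is still written.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["figure_parity_report"]


def _box(ax, groups: dict[str, np.ndarray], whiskers: tuple[float, float], ylabel: str) -> None:
    labels = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    ax.boxplot(data, tick_labels=labels, whis=whiskers, showmeans=True,
               meanprops={"marker": "+", "markeredgecolor": "black"})
    ax.set_ylabel(ylabel)


def figure_parity_report(
    out_dir: str | Path,
    clustering: pd.DataFrame | None = None,
    morphology: pd.DataFrame | None = None,
    rates: dict[str, np.ndarray] | None = None,
    max_lengths: dict[str, np.ndarray] | None = None,
    islet_volumes: pd.DataFrame | None = None,
    title: str = "isletmorph run report",
) -> Path:
    """Write panel PNGs plus a markdown report; returns the report path.

    Parameters are the long-form outputs of the upstream modules:
    ``clustering`` needs columns ``time_min, hull_volume_um3``
    (optionally ``sample``); ``morphology`` needs ``group, area_um2,
    circularity, solidity``; ``rates``/``max_lengths`` map labels to
    value arrays; ``islet_volumes`` needs ``group, volume_um3``.
    Any ``None`` or empty input becomes a placeholder note in the
    report instead of a panel.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = [f"# {title}", ""]
    missing = []

    if clustering is not None and len(clustering):
        fig, ax = plt.subplots(figsize=(5, 4))
        if "sample" in clustering.columns:
            for sample, sub in clustering.groupby("sample"):
                ax.plot(sub["time_min"], sub["hull_volume_um3"], marker="o", label=str(sample))
            ax.legend(fontsize=8)
        else:
            ax.plot(clustering["time_min"], clustering["hull_volume_um3"], marker="o")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("convex hull volume (µm³)")
        fig.savefig(out / "clustering_volume.png", dpi=100)
        plt.close(fig)
        lines.append("![clustering](clustering_volume.png)\n")
    else:
        missing.append("clustering series")

    if morphology is not None and len(morphology):
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        for ax, col, label in zip(
            axes,
            ["area_um2", "circularity", "solidity"],
            ["cell area (µm²)", "circularity", "solidity"],
        ):
            _box(ax, {g: sub[col].to_numpy() for g, sub in morphology.groupby("group")},
                 whiskers=(10, 90), ylabel=label)
        fig.tight_layout()
        fig.savefig(out / "morphology_panels.png", dpi=100)
        plt.close(fig)
        lines.append("![morphology](morphology_panels.png)\n")
    else:
        missing.append("morphology table")

    if rates or max_lengths:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        if rates:
            _box(axes[0], rates, whiskers=(10, 90), ylabel="rate (µm/min)")
        if max_lengths:
            _box(axes[1], max_lengths, whiskers=(10, 90), ylabel="maximal length (µm)")
        fig.tight_layout()
        fig.savefig(out / "filopodia_panels.png", dpi=100)
        plt.close(fig)
        lines.append("![filopodia](filopodia_panels.png)\n")
    else:
        missing.append("filopodia kinetics")

    if islet_volumes is not None and len(islet_volumes):
        fig, ax = plt.subplots(figsize=(5, 4))
        _box(ax, {g: sub["volume_um3"].to_numpy() for g, sub in islet_volumes.groupby("group")},
             whiskers=(5, 95), ylabel="islet volume (µm³)")
        fig.savefig(out / "islet_volumes.png", dpi=100)
        plt.close(fig)
        lines.append("![islets](islet_volumes.png)\n")
    else:
        missing.append("islet volume table")

    for item in missing:
        lines.append(f"*Panel omitted — no input for: {item}.*\n")
    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
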