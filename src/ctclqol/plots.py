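"""Figure analogues: category curves, test information, Wright map."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import diagnostics
from .rasch import CalibrationResult

FREQ_LABELS = ["never", "rarely", "sometimes", "often", "always"]
INT_LABELS = ["not at all", "a little bit", "somewhat", "quite a bit", "very much"]


def plot_category_curves(result: CalibrationResult, group: str, path: Path):
    cc = diagnostics.category_curves(result, group)
    labels = FREQ_LABELS if group == "frequency" else INT_LABELS
    fig, ax = plt.subplots(figsize=(6, 4))
    for k in range(cc["probs"].shape[1]):
        ax.plot(cc["grid"], cc["probs"][:, k], label=labels[k])
    ax.set_xlabel(r"$\theta - \delta$ (logits)")
    ax.set_ylabel("category probability")
    ax.set_title(f"Category response curves: {group} items")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_test_information(result: CalibrationResult, path: Path):
    ti = diagnostics.test_information(result)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ti["theta_grid"], ti["information"])
    ax.set_xlabel(r"$\theta$ (logits)")
    ax.set_ylabel("test information")
    ax.set_title("Test information curve")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_wright_map(result: CalibrationResult, path: Path):
    m = diagnostics.person_item_map(result)
    fig, (axp, axi) = plt.subplots(
        1, 2, figsize=(6, 6), sharey=True, gridspec_kw={"width_ratios": [2, 1]}
    )
    axp.hist(m["persons"].to_numpy(), bins=20, orientation="horizontal",
             color="steelblue")
    axp.set_xlabel("persons")
    axp.set_ylabel("logits")
    for iid, d in m["items"].items():
        axi.plot([0, 1], [d, d], color="gray", lw=0.8)
        axi.text(1.02, d, str(iid), fontsize=7, va="center")
    axi.set_xticks([])
    axi.set_xlabel("items")
    fig.suptitle("Person-to-item map")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_all(result: CalibrationResult, out_dir: Path):
    out_dir = Path(out_dir)
    for g in result.params.tau:
        plot_category_curves(result, g, out_dir / f"category_curves_{g}.svg")
    plot_test_information(result, out_dir / "test_information.svg")
    plot_wright_map(result, out_dir / "person_item_map.svg")
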