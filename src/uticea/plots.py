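"""Cost-effectiveness plane and acceptability-curve plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe default
import matplotlib.pyplot as plt  # noqa: E402

from .sensitivity import PSAResults, ceac  # noqa: E402

__all__ = ["plot_ce_plane", "plot_ceac", "plot_tornado"]


def plot_ce_plane(psa: PSAResults, ax=None):
    """Scatter of per-draw incremental QALYs vs incremental cost."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    d = psa.draws
    ax.scatter(d["delta_qaly"], d["delta_cost"], s=8, alpha=0.4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    lo, hi = ax.get_xlim()
    ax.plot([lo, hi], [psa.wtp * lo, psa.wtp * hi], "--", color="tab:red",
            lw=0.8, label=f"£{psa.wtp:,.0f}/QALY")
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (£)")
    ax.set_title("Cost-effectiveness plane")
    ax.legend(frameon=False)
    return ax


def plot_ceac(psa: PSAResults, ax=None, lambda_grid=None):
    """Probability of cost-effectiveness against willingness to pay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    curve = ceac(psa, lambda_grid)
    ax.plot(curve["lambda"], curve["probability"])
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Willingness to pay (£/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_title("Cost-effectiveness acceptability curve")
    return ax


def plot_tornado(table, ax=None, top: int = 12):
    """Horizontal bars of NMB at each parameter's range endpoints."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * min(top, len(table)) + 1))
    t = table.head(top).iloc[::-1]
    base = t["nmb_base"].iloc[0]
    ax.barh(t["parameter"], t["nmb_high"] - t["nmb_low"], left=t["nmb_low"],
            color="tab:blue", alpha=0.7)
    ax.axvline(base, color="k", lw=0.8)
    ax.set_xlabel("Net monetary benefit (£)")
    ax.set_title("One-way sensitivity")
    return ax
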