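"""DGC and DVH plotting.

The combined plot shares the dose axis (% of reference) between the DVH
(left y-axis, volume %) and the cumulative DGC (right y-axis, mm) so target
coverage and dose fall-off can be judged together.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .dgc import DGCTable
from .metrics import DVHCurve

__all__ = ["plot_dgc"]

_KINDS = ("differential", "normalized", "cumulative", "combined")


def plot_dgc(
    table: DGCTable,
    dvh: DVHCurve | None = None,
    kind: str = "differential",
    label: str | None = None,
    ax=None,
):
    """Render one DGC plot option and return the matplotlib figure.

    ``kind`` is one of ``differential``, ``normalized``, ``cumulative`` or
    ``combined`` (cumulative DGC + DVH, dual y-axis).  The cumulative plot
    runs from the reference dose down to the truncation dose; differential
    plots cover the full analysed range.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    if len(table) == 0:
        raise ValueError("empty DGC table")
    if kind == "combined" and dvh is None:
        raise ValueError("combined plot needs a DVH")
    scale = table.config.dose_scale
    xlabel = "Dose (% of reference)" if scale == "percent" else "Dose (Gy)"
    levels = table.levels
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure

    if kind in ("differential", "normalized"):
        col = "ddgi_mm" if kind == "differential" else "ddgi_norm_mm"
        y = table.frame[col].to_numpy()
        ok = np.isfinite(y)
        if not ok.any():
            raise ValueError(f"no {kind} values in table")
        ax.plot(levels[ok], y[ok], "-", lw=1.5, label=label)
        unit = "mm" if kind == "differential" else (
            "mm/%" if scale == "percent" else "mm/Gy"
        )
        ax.set_ylabel(f"{'dDGI' if kind == 'differential' else 'normalized dDGI'} ({unit})")
    else:
        y = table.frame["cdgi_mm"].to_numpy()
        ok = np.isfinite(y)
        if not ok.any():
            raise ValueError("no cumulative values in table")
        if kind == "cumulative":
            ax.plot(levels[ok], y[ok], "-", lw=1.5, label=label)
            ax.set_ylabel("cDGI (mm)")
        else:
            ref = table.config.reference_dose
            dvh_x = dvh.dose / ref * 100.0 if scale == "percent" else dvh.dose
            ax.plot(dvh_x, 100.0 * dvh.volume_fraction, "-", lw=1.5,
                    label=f"DVH {label}" if label else "DVH")
            ax.set_ylabel("Volume (%)")
            ax.set_ylim(0, 105)
            ax2 = ax.twinx()
            ax2.plot(levels[ok], y[ok], "--", lw=1.5, color="C3",
                     label=f"cDGC {label}" if label else "cDGC")
            ax2.set_ylabel("cDGI (mm)")
            ax2.legend(loc="center right", fontsize=8)
    ax.set_xlabel(xlabel)
    if label and kind != "combined":
        ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
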