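"""Static three-panel waveform plot (pressure / flow / tidal volume).

Convenience helper, not a contract surface.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_waveform"]


def plot_waveform(record: pd.DataFrame, fig=None):
    """Stacked airway-pressure, flow and volume panels vs time.

    Returns the matplotlib Figure.  Imports matplotlib lazily so the
    simulation stack stays import-light on headless systems.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if fig is None:
        fig, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 7))
    else:
        axes = fig.subplots(3, 1, sharex=True)
    t = record["time_s"]
    axes[0].plot(t, record["pressure_mmhg"], lw=0.8)
    axes[0].set_ylabel("lung pressure\n(mmHg)")
    axes[1].plot(t, record["flow_slpm"], lw=0.8, color="tab:green")
    axes[1].set_ylabel("inspiratory flow\n(SLPM)")
    axes[2].plot(t, record["volume_ml"], lw=0.8, color="tab:orange")
    axes[2].set_ylabel("lung volume\n(mL)")
    axes[2].set_xlabel("time (s)")
    fig.tight_layout()
    return fig
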