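"""Closed-loop pressure-control ventilation: the in vivo scenario.

Simulates 30 s of the large-animal configuration (PIP 14 mmHg, PEEP
2 mmHg, RR 12 bpm, I/E 2, FiO2 40 %, lung R = 10 mbar/(L*s),
C = 30 mL/mbar) and prints the per-breath metrics.  Optionally writes
the waveform CSV and a three-panel plot next to this script.
"""

import sys

from ventsim import breath_metrics, sheep_scenario, simulate

scenario = sheep_scenario(duration=30.0, seed=1)
record = simulate(scenario)
metrics = breath_metrics(record)

print(metrics.round(3).to_string(index=False))
print(
    "\nEach row is one completed breath: the threshold-gated solenoids hold"
    "\nthe pressure plateau at PIP (14 mmHg) and end expiration at PEEP"
    "\n(2 mmHg); the rate is exactly the set 12 bpm because timing is"
    "\nclock-driven.  The first breath starts from an empty lung, so summaries"
    "\nconventionally drop it."
)

if "--save" in sys.argv:
    from pathlib import Path

    from ventsim.plotting import plot_waveform

    out = Path(__file__).with_suffix("")
    record.to_csv(out.with_name("sheep_waveform.csv"), index=False)
    plot_waveform(record).savefig(out.with_name("sheep_waveform.png"), dpi=150)
    print("\nwrote sheep_waveform.csv and sheep_waveform.png")
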