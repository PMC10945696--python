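"""Build the three assay protocols and write their epoch tables.

The conditioning protocol pairs odor A with pulsed red light (3 training
cycles, 2 preference tests), the activation protocol applies six 10 s LED
stimuli spaced 100 s apart, and the light-preference protocol runs two 30 s
lit-quadrant tests with opposite quadrants illuminated, 150 s apart.
"""

from pathlib import Path

from flyarena import build_schedule, write_schedule

OUT = Path(__file__).resolve().parents[1] / "results" / "schedules"
OUT.mkdir(parents=True, exist_ok=True)

for name in ("conditioning_v1", "activation_v1", "light_preference_v1"):
    sched = build_schedule(name)
    write_schedule(sched, OUT / f"{name}.csv")
    n_on = len(sched.led_on)
    print(
        f"{name}: {len(sched.epochs)} epochs over {sched.duration:.0f} s "
        f"({n_on} LED-on epochs) -> {OUT / (name + '.csv')}"
    )
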