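"""Ingesting a recorded gaze stream instead of simulating an observer.

Writes a small gaze table in the supported format (header t_ms,x_deg,y_deg;
one sample per row; empty coordinates mark tracker dropouts), reads it back,
and runs the fixation filter on it.
"""

import numpy as np

from gdea import read_gaze_file, detect_fixations_idt

rows = ["t_ms,x_deg,y_deg"]
t = 0.0
for _ in range(30):  # 250 ms steady fixation at (-8.5, 6)
    rows.append(f"{t:.2f},{-8.5 + np.random.default_rng(int(t)).normal(0, 0.05):.3f},6.0")
    t += 1000 / 120
rows.append(f"{t:.2f},,")  # one dropout sample
t += 1000 / 120
for _ in range(30):  # 250 ms fixation at (8.5, -6)
    rows.append(f"{t:.2f},8.5,-6.0")
    t += 1000 / 120

with open("recorded_gaze.csv", "w") as fh:
    fh.write("\n".join(rows) + "\n")

stream = read_gaze_file("recorded_gaze.csv")
print(f"read {len(stream)} samples, {int((~stream.valid).sum())} invalid")

for fx in detect_fixations_idt(stream):
    print(
        f"fixation {fx.onset_ms:7.1f}-{fx.offset_ms:7.1f} ms "
        f"at ({fx.x:+.2f}, {fx.y:+.2f}) deg"
    )

# Two fixations should be reported, one per cluster; the dropout splits the
# stream, so no fixation spans the gap. Recorded streams can replace the
# simulated observer anywhere a GazeStream is accepted.
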