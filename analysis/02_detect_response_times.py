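"""Detect the pH response time of each simulated film: the first frame from
which the moving-averaged |gradient| of the hue trajectory stays below
0.001 units/frame through the end of the recording (>= 50 qualifying
frames). Writes results/analysis/response_times.json.
"""

import json
from pathlib import Path

from halochrom import stabilization, synthetic

OUT = Path("results/analysis")


def main() -> None:
    rows = []
    for path in sorted(OUT.glob("kinetics_ph*.csv")):
        series = stabilization.clean_series(synthetic.read_series_csv(path))
        res = stabilization.response_time(series)
        rows.append({"series": path.name, **res.to_dict()})
        status = f"{res.stabilization_time_s:.0f} s" if res.stabilized else "no stabilization"
        print(f"{path.name}: hue response time {status}")
    (OUT / "response_times.json").write_text(json.dumps(rows, indent=2))


if __name__ == "__main__":
    main()
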