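"""Which color channels discriminate pH? Correlation-matrix PCA with the
Kaiser criterion, and multiclass ReliefF, on frames pooled across the
simulated pH series. Writes results/analysis/feature_selection.json.
"""

import json
from pathlib import Path

import pandas as pd

from halochrom import feature_selection, synthetic
from halochrom.color import CHANNELS

OUT = Path("results/analysis")
SEED = 0


def main() -> None:
    frames, labels = [], []
    for path in sorted(OUT.glob("kinetics_ph*.csv")):
        series = synthetic.read_series_csv(path)
        ph = int(path.stem.replace("kinetics_ph", ""))
        sub = series.iloc[::5]  # thin to ~120 frames per film
        frames.append(sub[list(CHANNELS)])
        labels.extend([ph] * len(sub))
    table = pd.concat(frames, ignore_index=True)

    pca = feature_selection.pca_correlation(table)
    print(f"PCA eigenvalues: {[round(float(v), 2) for v in pca.eigenvalues[:5]]} ...")
    print(f"Kaiser criterion retains {pca.retained} components")

    weights = feature_selection.relieff(table, labels, k=10, seed=SEED)
    ranked = feature_selection.rank_features(weights, top_n=12)
    print("ReliefF ranking:", ", ".join(ranked[:5]), "...")
    print("top 3 channels:", ranked[:3])

    payload = {
        "eigenvalues": pca.eigenvalues.tolist(),
        "retained": pca.retained,
        "relieff_weights": weights,
        "ranked_features": ranked,
    }
    (OUT / "feature_selection.json").write_text(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
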