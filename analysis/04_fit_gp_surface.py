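"""Fit a multigene symbolic-regression model of response time on (PEG, BTB)
to the 180-record formulation dataset, at the study's evolution budget
(population 100, 50 generations, 20 genes max, depth 10).

Writes results/analysis/gp_model.json and gp_expression.txt.
"""

from pathlib import Path

import pandas as pd

from halochrom import gp

OUT = Path("results/analysis")
SEED = 0


def main() -> None:
    dataset = pd.read_csv(OUT / "formulation_dataset.csv")
    model = gp.evolve(dataset, gp.GPHyperparams(), seed=SEED)
    sd = dataset["response_time_s"].std()
    print(
        f"evolved {len(model.genes)} genes, train RMSE {model.train_rmse:.1f} s "
        f"(response SD {sd:.1f} s)"
    )
    (OUT / "gp_model.json").write_text(model.to_json())
    expr = gp.model_to_expression(model)
    (OUT / "gp_expression.txt").write_text(expr + "\n")
    print("expression:", expr[:120], "...")


if __name__ == "__main__":
    main()
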