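#!/usr/bin/env python
"""Environmental-driver attribution with exact Shapley values.

Fits the boosted-regression model of the synthetic composite response (a
known positive primary-productivity / negative temperature link with a
PP x Bm interaction) on the 11 per-cell environmental variables, then
decomposes predictions with exactly enumerated Shapley values and reports
the mean-|phi| importance ranking with signed directions.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ipcz.attribution import exact_shapley, fit_gbm, rank_and_sign
from ipcz.grid import GridSpec
from ipcz.synthetic import ENV_VARIABLES, default_scenario, generate_env_cells, synthetic_composite_link


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--n-obs", type=int, default=60)
    ap.add_argument("--n-background", type=int, default=30)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = Path(args.out)
    spec = GridSpec()

    scenario = default_scenario(args.seed)
    env = generate_env_cells(scenario, spec)
    y = synthetic_composite_link(env, seed=args.seed)
    X = env[list(ENV_VARIABLES)]

    model = fit_gbm(X, y, seed=args.seed)
    pred = model.predict(np.asarray(X, dtype=float))
    print(f"boosted model on {len(X)} cells: training R^2 = {1 - np.var(y - pred) / np.var(y):.4f}")

    rng = np.random.default_rng(args.seed)
    obs = X.iloc[rng.choice(len(X), args.n_obs, replace=False)]
    bg = X.iloc[rng.choice(len(X), args.n_background, replace=False)]
    shap = exact_shapley(model, obs, bg)
    eff = np.abs(shap.phi.sum(1) - (shap.predictions - shap.baseline)).max()
    print(f"exact Shapley over 2^11 coalitions, {args.n_obs} cells vs {args.n_background} background; "
          f"max efficiency error {eff:.2e}")

    report = rank_and_sign(shap, obs)
    print("\nimportance ranking (mean |phi|, direction):")
    print(report.table.to_string(float_format=lambda v: f"{v:.4f}"))
    report.table.to_csv(out / "shap_importance.csv")
    pd.DataFrame(shap.phi, columns=shap.feature_names).to_csv(out / "shap_values.csv", index=False)


if __name__ == "__main__":
    main()
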