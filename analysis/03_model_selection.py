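"""Rank the candidate mixed models for every response by AICc.

Aggregates frames to per-(bird x step) means, fits the null-to-saturated
candidate set for each response (surface temperatures, bill heat loss,
bill share, humidity), and writes per-response comparison tables plus
model-averaged prediction curves with unconditional SEs.
"""

import argparse

import pandas as pd

from billheat.pipeline import RunConfig, models_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed, outdir=args.outdir)
    budgets = pd.read_csv(f"{cfg.outdir}/heat_budget.csv")
    for col in ("q_bill", "q_legs", "q_body", "q_total"):
        budgets[col] = budgets[f"{col}_mw"] / 1000.0
    results = models_stage(cfg, budgets)
    for response, res in results.items():
        top = res["comparison"].table.iloc[0]
        print(
            f"{response:>15}: top model '{top['model']}' "
            f"(K={top['K']}, weight {top['weight']:.3f})"
        )


if __name__ == "__main__":
    main()
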