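"""Abiotic surrogacy: ranking cells by an environmental scalar layer.

Sweeps the layer's rank correlation with target richness from strongly
negative to strongly positive (with a 12% missing-data mask excluded
from the landscape, as for a water-stress layer) and estimates the SAI
under both strategies. An uninformative layer should straddle SAI = 0;
an anticorrelated layer orders cells worst-first and must go negative.

Usage: python analysis/04_abiotic_surrogacy.py [--seed 0]
"""

import argparse
from pathlib import Path

import pandas as pd

from surrosai import (
    CoDistributionSpec,
    LandscapeSpec,
    RunConfig,
    evaluate_surrogacy,
    generate_abiotic,
    generate_correlated_group,
    generate_occurrences,
)

CORRELATIONS = (-1.0, -0.5, 0.0, 0.5, 1.0)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    cfg = RunConfig(master_seed=args.seed)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    surrogate = generate_occurrences(
        LandscapeSpec(cfg.n_rows, cfg.n_cols, cfg.n_surrogate_species,
                      cfg.range_size_distribution, cfg.contiguity,
                      seed=cfg.seed("synthesis.surrogate"))
    )
    targets = generate_correlated_group(
        surrogate, CoDistributionSpec(cfg.overlap, seed=cfg.seed("synthesis.target")),
        cfg.n_target_species, cfg.range_size_distribution, cfg.contiguity,
    )

    rows = []
    for corr in CORRELATIONS:
        layer = generate_abiotic(
            targets.grid, targets, correlation=corr,
            missing_fraction=cfg.missing_fraction,
            seed=cfg.seed(f"synthesis.abiotic.{corr}"),
        )
        for algorithm in cfg.algorithms:
            res = evaluate_surrogacy(
                layer, targets, algorithm=algorithm,
                n_runs=cfg.n_runs, n_random=cfg.n_random,
                seed=cfg.seed(f"sai.abiotic.{algorithm}.{corr}"),
            )
            rows.append({
                "layer_correlation": corr, "algorithm": algorithm,
                "missing_pct": round(100 * layer.missing.mean(), 1),
                "sai_median": round(res.sai_median, 3),
                "ci_low": round(res.ci_low, 3), "ci_high": round(res.ci_high, 3),
                "descriptor": res.descriptor,
            })
            print(f"layer corr={corr:+.1f} {algorithm}: SAI = {res.sai_median:+.3f} "
                  f"[{res.ci_low:+.3f}, {res.ci_high:+.3f}] ({res.descriptor})")

    pd.DataFrame(rows).to_csv(out / "sai_abiotic.csv", index=False)
    print(f"table written to {out}/sai_abiotic.csv")


if __name__ == "__main__":
    main()
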