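#!/usr/bin/env python
"""Score the two misclassification models against observed rates.

Compares the country-specific and homogeneous fits from 02_fit_misclass.py
on average absolute loss against the observed (empirical) misclassification
rates, the share of cells with smaller error, and the Winkler interval
score — the same summaries used to judge whether modelling cross-country
heterogeneity pays off.  Writes results/analysis/evaluation.{json,csv}.
"""

import json
from pathlib import Path

import numpy as np

from vacalib import compare_models, observed_rates
from vacalib.evaluate import comparison_report
from vacalib.io import read_inventory, read_paired_counts
from vacalib.core import CauseMap

ROOT = Path(__file__).resolve().parents[1] / "results" / "analysis"
DATA = ROOT / "data"
SCENARIO = "eta1"


def main() -> None:
    if not (ROOT / "inventory_country.json").exists():
        raise SystemExit("run analysis/02_fit_misclass.py first")
    truth = json.loads((DATA / f"truth_{SCENARIO}.json").read_text())
    cm = CauseMap.from_dict(truth["cause_map"])
    data = read_paired_counts(DATA / f"paired_{SCENARIO}.csv", cm)
    obs = observed_rates(data)

    def load(model):
        inv = read_inventory(ROOT / f"inventory_{model}.json")
        draws = np.stack([inv.draws_for(c) for c in data.countries], axis=1)
        return (draws.mean(axis=0),
                (np.quantile(draws, 0.025, axis=0),
                 np.quantile(draws, 0.975, axis=0)))

    est_cs, int_cs = load("country")
    est_hom, int_hom = load("homogeneous")
    comp = compare_models(est_cs, est_hom, obs, int_cs, int_hom)
    print(f"avg absolute loss: country-specific {comp.loss_model_a:.4f} vs "
          f"homogeneous {comp.loss_model_b:.4f} "
          f"({comp.percent_reduction:.1f}% reduction)")
    print(f"share of cells improved: {100 * comp.share_cells_improved:.1f}%")
    print(f"interval score: {comp.interval_score_a:.3f} vs "
          f"{comp.interval_score_b:.3f} "
          f"({comp.interval_score_reduction:.1f}% reduction)")
    with open(ROOT / "evaluation.json", "w") as fh:
        json.dump(comp.__dict__, fh, indent=1)
    comparison_report(est_cs, est_hom, obs, int_cs, int_hom).to_csv(
        ROOT / "evaluation.csv", index=False)
    print(f"wrote {ROOT / 'evaluation.json'} and evaluation.csv")


if __name__ == "__main__":
    main()
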