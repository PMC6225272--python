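#!/usr/bin/env python
"""PLS toxicity model with validation statistics and applicability domain.

Fits the latent-variable regression on a seeded synthetic descriptor/
activity dataset with three planted components (activity noise 0.1, a 3:1
activity-stratified train/test split), scans 1..8 components by
leave-one-out q2, and reports the model statistics, the held-out
predictive r2 and the Williams-plot applicability-domain flags.
"""

import json
from pathlib import Path

from aconiqstr import ad, pls
from aconiqstr.synthetic import gen_latent_qstr

OUT = Path("results")
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    ds = gen_latent_qstr(n_mol=32, n_cols=120, n_comp=3, noise_sd=0.1, seed=SEED)
    model = pls.evaluate(ds, max_components=8)
    s = model.stats
    print(f"optimum components: {s['onc']} (3 planted)")
    print(f"q2 = {s['q2']:.3f}, r2 = {s['r2']:.3f}, SEE = {s['see']:.3f}, "
          f"F = {s['f']:.1f}, r2pred = {s['r2_pred']:.3f}")
    print("model acceptable (q2 > 0.5 and r2 > 0.6):", model.is_good)

    report = ad.williams_report(model, ds)
    summary = ad.summary(report)
    print(f"applicability domain: h* = {summary['h_star']:.3f}, "
          f"{summary['n_outliers']} outliers, "
          f"{summary['n_high_leverage']} high-leverage compounds")

    pls.predictions_frame(model, ds).to_csv(OUT / "qstr_predictions.csv")
    report.to_csv(OUT / "qstr_ad_report.csv")
    with open(OUT / "qstr_model.json", "w") as fh:
        json.dump({"stats": {k: v for k, v in s.items()},
                   "ad": summary}, fh, indent=2, sort_keys=True, default=float)
    print(f"wrote qstr_predictions.csv, qstr_ad_report.csv, qstr_model.json to {OUT}/")


if __name__ == "__main__":
    main()
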