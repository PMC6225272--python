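#!/usr/bin/env python
"""Overview of the bundled reference tables.

Loads the hash-verified activity, ranking and protein tables, summarizes
them and writes tidy copies under results/. The 33-compound set carries 7
externally held-out compounds; the protein list seeds the cardiotoxicity
interaction network.
"""

from pathlib import Path

from aconiqstr.synthetic import load_fixtures

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    fx = load_fixtures()

    print(f"{len(fx.activities)} compounds; pLD50 range "
          f"{fx.activities['pld50'].min():.2f}-{fx.activities['pld50'].max():.2f}; "
          f"{int(fx.activities['is_test'].sum())} held out as external test set")
    print(f"{len(fx.proteins)} seed proteins; most reported: "
          f"{fx.proteins['frequency'].idxmax()} "
          f"({fx.proteins['frequency'].max()} articles)")
    print(f"ranking table: {fx.ranking.n} compounds x "
          f"{len(fx.ranking.orderings)} orderings")

    fx.activities.to_csv(OUT / "activities.csv")
    fx.proteins.to_csv(OUT / "proteins.csv")
    fx.ranking_frame.to_csv(OUT / "ranking_inputs.csv", index=False)
    print(f"wrote activities.csv, proteins.csv, ranking_inputs.csv to {OUT}/")


if __name__ == "__main__":
    main()
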