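"""Invasion-risk statistics around the superhighway.

Tests whether invaded lakes sit closer to the superhighway than lakes
overall (Welch two-sample t-test per invader group), builds cumulative
distance curves, identifies invaded-to-uninvaded high-risk connections and
the per-county percentage of incoming weighted connections at high risk,
and lists superspreader / vulnerable hub lakes.  Writes results/risk/.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

from invnet import PipelineConfig, run_pipeline
from invnet import io as invio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=101)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "risk")
    args = ap.parse_args()

    ds = invio.load_dataset(args.data)
    bundle = run_pipeline(PipelineConfig(seed=args.seed), ds)
    args.out.mkdir(parents=True, exist_ok=True)

    print("distance to the invasion superhighway (km):")
    for taxon, res in bundle.ttests.items():
        print(f"  {taxon:13s} mean {res.mean_1:6.1f} vs all lakes {res.mean_2:6.1f}  "
              f"[{res.format()}]")
    (args.out / "ttests.json").write_text(
        json.dumps({k: asdict(v) for k, v in bundle.ttests.items()}, indent=2)
    )
    for name, curve in bundle.curves.items():
        curve.to_csv(args.out / f"curve_{name}.csv", index=False)

    frac = bundle.risk_fraction
    print(f"movement from invaded to uninvaded lakes: "
          f"{100 * frac['count_fraction']:.1f}% of movements "
          f"({100 * frac['weight_fraction']:.1f}% by weight)")

    county = bundle.county_table
    county.to_csv(args.out / "county_risk.csv", index=False)
    with_data = county[~county["no_data"]]
    print(f"county risk: {len(with_data)} of {len(county)} counties receive flow; "
          f"high-risk share ranges {with_data['pct_high_risk'].min():.1f}% to "
          f"{with_data['pct_high_risk'].max():.1f}%")

    hubs = bundle.hub_table
    hubs.to_csv(args.out / "hubs.csv", index=False)
    top_spread = hubs[hubs["role"] == "superspreader"].nlargest(3, "out_strength")
    top_vuln = hubs[hubs["role"] == "vulnerable"].nlargest(3, "in_strength")
    print("top superspreader lakes (invaded, highest weighted out-strength):")
    for r in top_spread.itertuples(index=False):
        print(f"  {r.lake_id} (county {r.region_id}): out-strength {r.out_strength:.1f}")
    print("top vulnerable lakes (uninvaded, highest weighted in-strength):")
    for r in top_vuln.itertuples(index=False):
        print(f"  {r.lake_id} (county {r.region_id}): in-strength {r.in_strength:.1f}")


if __name__ == "__main__":
    main()
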